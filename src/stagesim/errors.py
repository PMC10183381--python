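"""Exception hierarchy for the simulator."""


class StageSimError(Exception):
    """Base class for all simulator errors."""


class GeometryError(StageSimError):
    """Arch generation produced overlapping or non-watertight bodies."""


class PlacementError(StageSimError):
    """An attachment does not fit on the requested crown face."""


class LandmarkError(StageSimError):
    """A landmark rule could not be evaluated (e.g. empty cross-section)."""


class FrameError(StageSimError):
    """Degenerate landmarks prevent defining the occlusal coordinate frame."""


class FoundationError(StageSimError):
    """PDL foundation sampling is empty or degenerate."""


class AlignerBuildError(StageSimError):
    """The aligner shell could not be generated."""


class BandError(StageSimError):
    """An interdental deformation band could not be constructed."""


class RefitError(StageSimError):
    """Aligner wear-in registration failed to converge."""


class SolverError(StageSimError):
    """Equilibrium iteration failed; carries the residual history."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []
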