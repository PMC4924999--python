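"""Exception types shared across the package."""


class AxobeatError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AxobeatError, ValueError):
    """A waveform table does not conform to the documented dialect."""


class GeometryError(AxobeatError, ValueError):
    """A tracked frame is degenerate (zero-length segment, self-intersection)."""


class NoPeriodicBeatError(AxobeatError, RuntimeError):
    """No spectral peak above the noise floor: the series has no periodic beat."""


class NoOscillatorySolutionError(AxobeatError, RuntimeError):
    """The boundary determinant is bounded away from zero at the supplied basal
    impedance: the model admits no critical oscillatory mode there."""

    def __init__(self, message: str, det_abs: float | None = None):
        super().__init__(message)
        self.det_abs = det_abs


class FitError(AxobeatError, RuntimeError):
    """Optimizer failure; ``best_so_far`` carries the best result reached."""

    def __init__(self, message: str, best_so_far=None):
        super().__init__(message)
        self.best_so_far = best_so_far
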