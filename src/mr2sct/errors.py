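"""Typed errors shared across the pipeline."""


class Mr2SctError(Exception):
    """Base class for package errors."""


class GeometryError(Mr2SctError, ValueError):
    """Volumes that should share a grid (shape/spacing) do not."""


class DegenerateHistogramError(Mr2SctError, ValueError):
    """An intensity histogram is too degenerate to threshold or standardize."""


class MissingContrastError(Mr2SctError, KeyError):
    """A tissue label has no entry in the contrast model."""


class SamplingError(Mr2SctError, RuntimeError):
    """No admissible patch position exists under the requested constraints."""


class DivergenceError(Mr2SctError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class VolumeIOError(Mr2SctError, OSError):
    """A volume file could not be read or written."""


class VolumeDimensionError(VolumeIOError):
    """A volume file does not contain 3D scalar data."""


class NoEntryError(Mr2SctError, RuntimeError):
    """A beam ray does not intersect the body mask."""
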