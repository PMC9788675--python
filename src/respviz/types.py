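"""Core domain containers shared across the pipeline.

An :class:`AudioEvent` is the unit of classification: one pre-segmented,
labelled respiratory sound (a single cough or breathing period).  Time-
frequency analysis turns it into a :class:`TimeFrequencyMatrix`, which is
rendered to a square 8-bit :class:`RenderedImage` suitable as classifier
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical class tags: wet cough, dry cough, whooping cough, restricted breathing.
CLASS_LABELS = ("wC", "dC", "whC", "RB")

#: Side length of the classifier input image (AlexNet-compatible geometry).
IMAGE_SIDE = 227


@dataclass
class AudioEvent:
    """A labelled mono waveform.

    Parameters
    ----------
    samples : ndarray of float
        Mono waveform, finite, amplitude within [-1, 1].
    sample_rate : int
        Sampling rate in Hz, > 0.
    label : str
        Class tag (one of ``CLASS_LABELS``, or any task label downstream).
    source_id : str
        Stable identifier used for provenance tracking through the pipeline.
    """

    samples: np.ndarray
    sample_rate: int
    label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("samples: expected a mono (1-D) waveform")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples: contains NaN or Inf values")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValidationError("samples: amplitude exceeds [-1, 1]")
        if int(self.sample_rate) <= 0:
            raise ValidationError("sample_rate: must be positive")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration(self) -> float:
        """Event length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class TimeFrequencyMatrix:
    """Non-negative power (or magnitude) matrix over a time-frequency grid.

    Rows are frequencies (``freq_axis``, Hz, strictly increasing), columns
    are time (``time_axis``, s, strictly increasing). ``scale_tag`` records
    the frequency-axis spacing: ``linear``, ``log``, ``mel`` or ``wavelet``.
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    scale_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values: expected a 2-D matrix")
        if self.values.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValidationError(
                "values: shape %r does not match axes (%d, %d)"
                % (self.values.shape, self.freq_axis.size, self.time_axis.size)
            )
        if self.values.size and np.min(self.values) < 0:
            raise ValidationError("values: must be non-negative")
        for name, ax in (("freq_axis", self.freq_axis), ("time_axis", self.time_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValidationError(f"{name}: must be strictly increasing")


@dataclass
class RenderedImage:
    """A square 3-channel 8-bit image, the classifier input.

    ``method_tag`` is one of ``linear``, ``log``, ``mel``, ``wavelet`` or
    ``aggregate``; ``provenance`` is the source event's ``source_id``.
    """

    pixels: np.ndarray
    method_tag: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValidationError("pixels: must be 8-bit (uint8)")
        if self.pixels.shape != (IMAGE_SIDE, IMAGE_SIDE, 3):
            raise ValidationError(
                "pixels: expected %dx%dx3, got %r"
                % (IMAGE_SIDE, IMAGE_SIDE, self.pixels.shape)
            )


@dataclass
class ImageRecord:
    """A rendered image plus the bookkeeping the dataset builder needs."""

    image: RenderedImage
    event_id: str
    label: str
    task_label: str | None = None
    duplicated: bool = False
    split: str | None = None
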