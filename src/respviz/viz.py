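"""Time-frequency visualizations of respiratory events.

Five image representations are produced from each standardized (20 kHz)
event:

1. **linear spectrogram** — STFT power on the native linear frequency axis;
2. **logarithmic spectrogram** — the same power resampled onto a log-spaced
   frequency axis, expanding the low-frequency range where most respiratory
   energy lives;
3. **Mel-spectrogram** — STFT power projected through a triangular mel
   filterbank (wide low-frequency bands, narrow high-frequency bands);
4. **wavelet scalogram** — magnitude of the continuous wavelet transform
   with an analytic Morlet wavelet, rows ordered by pseudo-frequency;
5. **aggregate image** — the grayscale renderings of (1), (3) and (4)
   stacked as the red, green and blue channels of one RGB image, so a
   single classifier input carries all three complementary views.

Each is rendered to a 227x227x3 8-bit image (the AlexNet input geometry):
power in dB, clipped to a fixed dynamic range below the maximum, mapped
through a monotone-luma colormap, and bilinearly resized without preserving
aspect ratio.

STFT normalization is pinned: an entry is ``|DFT(window * frame)|**2`` with
no further scaling, one-sided, so Parseval's identity reads
``sum_k |X_k|^2 = N * sum_n |w_n x_n|^2`` over the *full* (two-sided)
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from PIL import Image
from scipy import signal

from .errors import ValidationError
from .types import IMAGE_SIDE, AudioEvent, RenderedImage, TimeFrequencyMatrix

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform parameters.

    Defaults: 25 ms Hamming window (500 samples at 20 kHz), 512-point FFT,
    90% overlap. 90% overlap increases pixel density so the rendered image
    resembles a natural photograph more closely; 50% is supported for the
    cheaper variant.
    """

    window_length: int = 500
    overlap_fraction: float = 0.90
    fft_length: int = 512
    window_kind: str = "hamming"

    def validate(self) -> None:
        if self.window_length < 2:
            raise ValidationError("window_length: must be >= 2 samples")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction: must lie in [0, 1)")
        if self.fft_length < self.window_length:
            raise ValidationError("fft_length: must be >= window_length")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.window_length * (1.0 - self.overlap_fraction))))


@dataclass(frozen=True)
class MelConfig:
    """Triangular mel filterbank spanning [f_min, f_max]."""

    n_mel_bands: int = 64
    f_min: float = 20.0
    f_max: float = 4000.0

    def validate(self) -> None:
        if self.n_mel_bands < 1:
            raise ValidationError("n_mel_bands: must be >= 1")
        if not 0 <= self.f_min < self.f_max:
            raise ValidationError("f_min/f_max: require 0 <= f_min < f_max")


@dataclass(frozen=True)
class LogAxisConfig:
    """Logarithmically spaced frequency axis for the log spectrogram."""

    n_bins: int = 64
    f_min: float = 20.0
    f_max: float = 4000.0

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins: must be >= 2")
        if not 0 < self.f_min < self.f_max:
            raise ValidationError("f_min/f_max: require 0 < f_min < f_max")


@dataclass(frozen=True)
class CwtConfig:
    """Continuous wavelet transform settings (analytic Morlet family)."""

    wavelet_kind: str = "cmor1.5-1.0"
    voices_per_octave: int = 12
    freq_limits: tuple = (20.0, 4000.0)

    def validate(self) -> None:
        if self.voices_per_octave < 1:
            raise ValidationError("voices_per_octave: must be >= 1")
        lo, hi = self.freq_limits
        if not 0 < lo < hi:
            raise ValidationError("freq_limits: require 0 < low < high")


# ---------------------------------------------------------------------------
# STFT and derived spectrograms


def _window(cfg: StftConfig) -> np.ndarray:
    return signal.get_window(cfg.window_kind, cfg.window_length, fftbins=True)


def stft_power(x: np.ndarray, sample_rate: int, cfg: StftConfig):
    """One-sided STFT power matrix plus its frequency and time axes.

    Entry (k, t) is ``|sum_n w[n] x[t*hop + n] exp(-2i pi k n / N)|**2``
    with N = ``fft_length`` — no window or length normalization.
    """
    cfg.validate()
    if x.size < cfg.window_length:
        raise ValidationError(
            "event: shorter than one analysis window (%d < %d samples)"
            % (x.size, cfg.window_length)
        )
    hop, W = cfg.hop, cfg.window_length
    n_frames = 1 + (x.size - W) // hop
    idx = np.arange(W)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * _window(cfg)[None, :]
    spec = np.fft.rfft(frames, n=cfg.fft_length, axis=1)
    power = np.abs(spec).T ** 2
    freqs = np.fft.rfftfreq(cfg.fft_length, d=1.0 / sample_rate)
    times = (hop * np.arange(n_frames) + W / 2) / sample_rate
    return power, freqs, times


def linear_spectrogram(event: AudioEvent, cfg: StftConfig | None = None) -> TimeFrequencyMatrix:
    """STFT power on the linear frequency axis, 0 Hz to Nyquist."""
    cfg = cfg or StftConfig()
    power, freqs, times = stft_power(event.samples, event.sample_rate, cfg)
    return TimeFrequencyMatrix(power, freqs, times, "linear")


def log_spectrogram(
    event: AudioEvent,
    cfg: StftConfig | None = None,
    axis_cfg: LogAxisConfig | None = None,
) -> TimeFrequencyMatrix:
    """Linear spectrogram resampled onto a log-spaced frequency axis.

    Low frequencies occupy many more rows than they do on the linear axis,
    which is where most respiratory energy sits.
    """
    cfg = cfg or StftConfig()
    axis_cfg = axis_cfg or LogAxisConfig()
    axis_cfg.validate()
    lin = linear_spectrogram(event, cfg)
    log_freqs = np.geomspace(axis_cfg.f_min, axis_cfg.f_max, axis_cfg.n_bins)
    out = np.empty((axis_cfg.n_bins, lin.time_axis.size))
    for j in range(lin.time_axis.size):
        out[:, j] = np.interp(log_freqs, lin.freq_axis, lin.values[:, j])
    return TimeFrequencyMatrix(out, log_freqs, lin.time_axis, "log")


def hz_to_mel(f):
    """HTK mel scale: 2595 * log10(1 + f / 700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: MelConfig, fft_freqs: np.ndarray) -> np.ndarray:
    """Triangular mel filterbank matrix of shape (n_mel_bands, n_fft_bins).

    Band edges are equally spaced on the mel scale between f_min and f_max.
    A band whose triangle is narrower than the FFT bin spacing would capture
    no bin; such a band is given unit weight at its nearest bin so every
    filter's weights sum to a positive value.
    """
    cfg.validate()
    edges = mel_to_hz(np.linspace(hz_to_mel(cfg.f_min), hz_to_mel(cfg.f_max),
                                  cfg.n_mel_bands + 2))
    fb = np.zeros((cfg.n_mel_bands, fft_freqs.size))
    for b in range(cfg.n_mel_bands):
        lo, center, hi = edges[b], edges[b + 1], edges[b + 2]
        up = (fft_freqs - lo) / max(center - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
        if fb[b].sum() == 0.0:
            fb[b, np.argmin(np.abs(fft_freqs - center))] = 1.0
    return fb


def mel_band_centers(cfg: MelConfig) -> np.ndarray:
    """Center frequency (Hz) of each mel band."""
    edges = mel_to_hz(np.linspace(hz_to_mel(cfg.f_min), hz_to_mel(cfg.f_max),
                                  cfg.n_mel_bands + 2))
    return edges[1:-1]


def mel_spectrogram(
    event: AudioEvent,
    mel_cfg: MelConfig | None = None,
    stft_cfg: StftConfig | None = None,
) -> TimeFrequencyMatrix:
    """STFT power projected through the triangular mel filterbank."""
    mel_cfg = mel_cfg or MelConfig()
    stft_cfg = stft_cfg or StftConfig()
    lin = linear_spectrogram(event, stft_cfg)
    fb = mel_filterbank(mel_cfg, lin.freq_axis)
    values = fb @ lin.values
    return TimeFrequencyMatrix(values, mel_band_centers(mel_cfg),
                               lin.time_axis, "mel")


# ---------------------------------------------------------------------------
# wavelet scalogram


def cwt_frequencies(cfg: CwtConfig) -> np.ndarray:
    """Geometric pseudo-frequency grid, ``voices_per_octave`` per octave."""
    cfg.validate()
    lo, hi = cfg.freq_limits
    n = int(np.floor(np.log2(hi / lo) * cfg.voices_per_octave)) + 1
    freqs = lo * 2.0 ** (np.arange(n) / cfg.voices_per_octave)
    return freqs[freqs <= hi * (1 + 1e-9)]


def cwt_scalogram(event: AudioEvent, cfg: CwtConfig | None = None) -> TimeFrequencyMatrix:
    """Magnitude of the analytic-Morlet CWT, rows ordered by pseudo-frequency.

    The wavelet trades time for frequency resolution across scales: short
    transients (cough bursts) stay sharp at high frequency while sustained
    narrowband sounds (wheeze, whoop) form long ridges at low frequency.
    """
    cfg = cfg or CwtConfig()
    cfg.validate()
    if event.samples.size < 2:
        raise ValidationError("event: too short for a scalogram")
    freqs = cwt_frequencies(cfg)
    scales = pywt.frequency2scale(cfg.wavelet_kind, freqs / event.sample_rate)
    # scales derive from ascending freqs, so coefficient rows are already
    # ordered by ascending pseudo-frequency
    coef, _ = pywt.cwt(event.samples, scales, cfg.wavelet_kind,
                       sampling_period=1.0 / event.sample_rate, method="fft")
    values = np.abs(coef)
    times = np.arange(event.samples.size) / event.sample_rate
    return TimeFrequencyMatrix(values, freqs, times, "wavelet")


# ---------------------------------------------------------------------------
# rendering


#: Broadcast luma weights used for every grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _colormap_lut(tag: str) -> np.ndarray:
    """256x3 uint8 lookup table for a named colormap.

    ``gray`` (the default) is the identity ramp, which makes rendering
    exactly monotone in input power. Any matplotlib colormap name is also
    accepted for presentation-quality figures.
    """
    if tag == "gray":
        ramp = np.arange(256, dtype=np.uint8)
        return np.stack([ramp] * 3, axis=1)
    import matplotlib

    cmap = matplotlib.colormaps[tag]
    return (cmap(np.arange(256) / 255.0)[:, :3] * 255).round().astype(np.uint8)


def render(
    tf: TimeFrequencyMatrix,
    dynamic_range_db: float = 80.0,
    colormap_tag: str = "gray",
    clip_bounds: tuple | None = None,
) -> RenderedImage:
    """Render a time-frequency matrix to a 227x227x3 8-bit image.

    Power is converted to dB and clipped to ``[max - dynamic_range_db, max]``
    (or to explicit ``clip_bounds`` in dB), normalized, bilinearly resized to
    227x227 (aspect ratio not preserved), and mapped through the colormap.
    The frequency axis points up: row 0 of the image is the highest
    frequency. An all-zero matrix renders at the colormap minimum.
    """
    if tf.values.size == 0:
        raise ValidationError("values: empty matrix")
    if dynamic_range_db <= 0:
        raise ValidationError("dynamic_range_db: must be positive")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(tf.values)
    if clip_bounds is not None:
        vmin, vmax = clip_bounds
    else:
        vmax = float(np.max(db)) if np.isfinite(db).any() else 0.0
        vmin = vmax - dynamic_range_db
    if vmax <= vmin:
        raise ValidationError("clip_bounds: vmax must exceed vmin")
    norm = np.clip((db - vmin) / (vmax - vmin), 0.0, 1.0)
    norm[~np.isfinite(db)] = 0.0  # zero power sits at the floor
    levels = np.round(norm * 255.0).astype(np.uint8)[::-1]  # high freq on top
    img = Image.fromarray(levels, mode="L").resize(
        (IMAGE_SIDE, IMAGE_SIDE), Image.Resampling.BILINEAR
    )
    gray = np.asarray(img, dtype=np.uint8)
    pixels = _colormap_lut(colormap_tag)[gray]
    return RenderedImage(pixels=pixels, method_tag=tf.scale_tag, provenance="")


def to_grayscale(img: RenderedImage) -> np.ndarray:
    """Single 8-bit channel via the fixed luma weights (0.299, 0.587, 0.114)."""
    w = np.asarray(LUMA_WEIGHTS)
    gray = img.pixels.astype(np.float64) @ w
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def compose_aggregate(
    linear_img: RenderedImage,
    mel_img: RenderedImage,
    wavelet_img: RenderedImage,
) -> RenderedImage:
    """Stack grayscale linear/mel/wavelet renderings as R/G/B channels.

    The three inputs must come from the same source event; mixing events
    would fabricate an observation, so mismatched provenance is rejected.
    Channel order is fixed: red = linear spectrogram, green =
    mel-spectrogram, blue = wavelet scalogram.
    """
    ids = {linear_img.provenance, mel_img.provenance, wavelet_img.provenance}
    if len(ids) != 1:
        raise ValidationError(
            f"provenance: images come from different events {sorted(ids)!r}"
        )
    pixels = np.stack(
        [to_grayscale(linear_img), to_grayscale(mel_img), to_grayscale(wavelet_img)],
        axis=-1,
    )
    return RenderedImage(pixels=pixels, method_tag="aggregate",
                         provenance=linear_img.provenance)


# ---------------------------------------------------------------------------
# per-event image production

METHODS = ("linear", "log", "mel", "wavelet", "aggregate")


def images_for_event(
    event: AudioEvent,
    methods=METHODS,
    stft_cfg: StftConfig | None = None,
    mel_cfg: MelConfig | None = None,
    log_cfg: LogAxisConfig | None = None,
    cwt_cfg: CwtConfig | None = None,
    dynamic_range_db: float = 80.0,
    colormap_tag: str = "gray",
) -> dict:
    """Render the requested visualizations of one standardized event.

    Returns ``{method_tag: RenderedImage}``; the aggregate image reuses the
    linear, mel and wavelet renderings when those are also requested.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"methods: unknown {sorted(unknown)!r}")
    need = set(methods)
    if "aggregate" in need:
        need |= {"linear", "mel", "wavelet"}
    made = {}
    if "linear" in need:
        made["linear"] = render(linear_spectrogram(event, stft_cfg),
                                dynamic_range_db, colormap_tag)
    if "log" in need:
        made["log"] = render(log_spectrogram(event, stft_cfg, log_cfg),
                             dynamic_range_db, colormap_tag)
    if "mel" in need:
        made["mel"] = render(mel_spectrogram(event, mel_cfg, stft_cfg),
                             dynamic_range_db, colormap_tag)
    if "wavelet" in need:
        made["wavelet"] = render(cwt_scalogram(event, cwt_cfg),
                                 dynamic_range_db, colormap_tag)
    for img in made.values():
        img.provenance = event.source_id
    if "aggregate" in methods:
        made["aggregate"] = compose_aggregate(made["linear"], made["mel"],
                                              made["wavelet"])
    return {m: made[m] for m in methods}
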