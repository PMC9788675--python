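"""Standardization of audio events to the common analysis representation.

Every event, whatever its original rate, is brought to 20 kHz and lowpass
filtered at f_c = 4 kHz — the typical frequency range of cough sounds; the
band above carries little respiratory information and mostly noise.

Resampling is polyphase rational resampling with built-in anti-aliasing;
the explicit lowpass is an order-8 Butterworth applied forward-backward
(zero phase), so spectrogram features are attenuated in place rather than
smeared in time. Filtering this way can only remove energy: the Butterworth
magnitude response never exceeds one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .types import AudioEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Target rate and lowpass settings.

    ``cutoff_hz`` must sit strictly inside (0, target_rate/2). The filter
    family and order are configurable because only the cutoff is a fixed
    design point of the pipeline.
    """

    target_rate: int = 20000
    cutoff_hz: float = 4000.0
    filter_kind: str = "butter"
    filter_order: int = 8

    def validate(self) -> None:
        if self.target_rate <= 0:
            raise ValidationError("target_rate: must be positive")
        if not 0 < self.cutoff_hz < self.target_rate / 2:
            raise ValidationError(
                "cutoff_hz: must lie in (0, target_rate/2) = (0, %g)"
                % (self.target_rate / 2)
            )
        if self.filter_kind not in ("butter", "cheby2", "ellip"):
            raise ValidationError(f"filter_kind: unsupported {self.filter_kind!r}")
        if self.filter_order < 1:
            raise ValidationError("filter_order: must be >= 1")


def design_lowpass(cfg: PreprocessConfig) -> np.ndarray:
    """Second-order-sections of the configured lowpass at the target rate."""
    cfg.validate()
    kwargs = {"fs": cfg.target_rate, "output": "sos", "btype": "lowpass"}
    if cfg.filter_kind == "butter":
        return signal.butter(cfg.filter_order, cfg.cutoff_hz, **kwargs)
    if cfg.filter_kind == "cheby2":
        return signal.cheby2(cfg.filter_order, 60.0, cfg.cutoff_hz, **kwargs)
    return signal.ellip(cfg.filter_order, 0.1, 60.0, cfg.cutoff_hz, **kwargs)


def lowpass_gain(cfg: PreprocessConfig, freq_hz: float) -> float:
    """Designed magnitude response at ``freq_hz`` for the zero-phase application.

    Forward-backward filtering applies the magnitude response twice, so the
    effective gain is ``|H(f)|**2``.
    """
    sos = design_lowpass(cfg)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=cfg.target_rate)
    return float(np.abs(h[0]) ** 2)


class AudioStandardizer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping events onto the 20 kHz / 4 kHz standard.

    Scikit-learn transformer conventions are kept (``fit`` is a no-op) so the
    standardizer composes with pipelines; :func:`standardize` is the
    function-style entry point.
    """

    def __init__(self, target_rate: int = 20000, cutoff_hz: float = 4000.0,
                 filter_kind: str = "butter", filter_order: int = 8):
        self.target_rate = target_rate
        self.cutoff_hz = cutoff_hz
        self.filter_kind = filter_kind
        self.filter_order = filter_order

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            target_rate=self.target_rate,
            cutoff_hz=self.cutoff_hz,
            filter_kind=self.filter_kind,
            filter_order=self.filter_order,
        )

    def fit(self, X=None, y=None):
        self._config().validate()
        self.n_features_in_ = 0
        return self

    def transform_event(self, event: AudioEvent) -> AudioEvent:
        cfg = self._config()
        cfg.validate()
        if event.samples.size == 0:
            raise ValidationError("samples: empty waveform")
        # AudioEvent already rejects NaN/Inf; re-check to keep the contract local
        if not np.all(np.isfinite(event.samples)):
            raise ValidationError("samples: contains NaN or Inf values")

        x = event.samples
        if event.sample_rate != cfg.target_rate:
            if event.sample_rate < cfg.target_rate:
                logger.info(
                    "upsampling %s from %d Hz to %d Hz",
                    event.source_id, event.sample_rate, cfg.target_rate,
                )
            ratio = Fraction(cfg.target_rate, event.sample_rate)
            x = signal.resample_poly(x, ratio.numerator, ratio.denominator)

        sos = design_lowpass(cfg)
        if x.size > 3 * (2 * cfg.filter_order + 1):
            x = signal.sosfiltfilt(sos, x)
        else:  # too short for filtfilt edge padding; single-pass fallback
            x = signal.sosfilt(sos, x)
        x = np.clip(x, -1.0, 1.0)
        return AudioEvent(samples=x, sample_rate=cfg.target_rate,
                          label=event.label, source_id=event.source_id)

    def transform(self, X):
        """Standardize a sequence of events; returns a list."""
        return [self.transform_event(ev) for ev in X]


def standardize(event: AudioEvent, cfg: PreprocessConfig | None = None) -> AudioEvent:
    """Resample ``event`` to the target rate and lowpass it at the cutoff."""
    cfg = cfg or PreprocessConfig()
    return AudioStandardizer(
        target_rate=cfg.target_rate, cutoff_hz=cfg.cutoff_hz,
        filter_kind=cfg.filter_kind, filter_order=cfg.filter_order,
    ).transform_event(event)
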