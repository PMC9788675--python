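"""Synthetic respiratory-sound generator.

Real wet/dry/whooping-cough and wheeze recordings with clinical labels are
scarce and rarely redistributable, so this module synthesizes events that
carry the *class-distinguishing* temporal and spectral structure of each
phenotype without claiming acoustic realism:

- wet cough (``wC``): one sustained broadband burst spanning most of the event;
- dry cough (``dC``): two short broadband bursts separated by a silent gap;
- whooping cough (``whC``): a burst sequence followed by a long tonal
  inspiratory "whoop" (rising chirp);
- restricted breathing (``RB``): a continuous narrowband wheeze, slowly
  amplitude-modulated at the breathing-cycle rate.

Bursts are white noise band-limited to 50–4000 Hz under an attack/decay
envelope; the whoop is an 800–1500 Hz chirp held for most of a second; the
wheeze is a few-hundred-Hz tone with 0.2–0.4 Hz amplitude modulation.
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import ValidationError
from .types import CLASS_LABELS, AudioEvent

#: Generation sample rate. Deliberately higher than the pipeline's 20 kHz
#: target so the downsampling path is always exercised.
GENERATION_SAMPLE_RATE = 44100

#: Bursts are band-limited to the typical cough band.
BURST_BAND_HZ = (50.0, 4000.0)

#: Peak amplitude after normalization; leaves headroom for later filtering.
PEAK_AMPLITUDE = 0.9


@dataclass(frozen=True)
class SyntheticEventSpec:
    """Recipe for one synthetic respiratory event.

    ``burst_times`` holds (onset_s, length_s) pairs of broadband bursts;
    ``tonal_components`` holds (freq_hz, amplitude, onset_s, length_s)
    fixed-frequency tones; ``chirp_components`` holds
    (f0_hz, f1_hz, amplitude, onset_s, length_s) linear chirps (the whoop).
    ``tone_am_hz`` > 0 amplitude-modulates the tones at the breathing-cycle
    rate (the wheeze). ``broadband_level`` scales every burst and
    ``noise_floor`` the background noise, both relative to full scale.
    """

    class_label: str
    duration: float
    burst_times: tuple = ()
    tonal_components: tuple = ()
    chirp_components: tuple = ()
    broadband_level: float = 1.0
    noise_floor: float = 0.0
    tone_am_hz: float = 0.0
    seed: int = 0
    #: Burst decay time constant as a fraction of burst length; larger values
    #: sound sustained (wet cough), smaller values percussive (dry cough).
    burst_decay_fraction: float = 0.33

    def validate(self, sample_rate: int) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"class_label: {self.class_label!r} not in {CLASS_LABELS}"
            )
        if not self.duration > 0:
            raise ValidationError("duration: must be > 0")
        for name in ("broadband_level", "noise_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: must lie in [0, 1]")
        for onset, length in self.burst_times:
            if onset < 0 or length <= 0 or onset + length > self.duration + 1e-9:
                raise ValidationError(
                    "burst_times: onset+length must fit inside duration"
                )
        for freq, _amp, onset, length in self.tonal_components:
            if onset < 0 or length <= 0 or onset + length > self.duration + 1e-9:
                raise ValidationError(
                    "tonal_components: onset+length must fit inside duration"
                )
            if not 0 < freq < sample_rate / 2:
                raise ValidationError(
                    "tonal_components: frequency must be below Nyquist"
                )
        for f0, f1, _amp, onset, length in self.chirp_components:
            if onset < 0 or length <= 0 or onset + length > self.duration + 1e-9:
                raise ValidationError(
                    "chirp_components: onset+length must fit inside duration"
                )
            if not (0 < f0 < sample_rate / 2 and 0 < f1 < sample_rate / 2):
                raise ValidationError(
                    "chirp_components: frequencies must be below Nyquist"
                )


def _envelope(n: int, sr: int, length: float, decay_fraction: float) -> np.ndarray:
    """Attack/decay burst envelope: 10 ms linear attack, exponential decay."""
    t = np.arange(n) / sr
    attack = np.clip(t / 0.010, 0.0, 1.0)
    decay = np.exp(-t / max(length * decay_fraction, 1e-4))
    return attack * decay


def _fade(n: int, sr: int, fade_s: float = 0.010) -> np.ndarray:
    """Raised-cosine fade-in/out window to avoid clicks at tone edges."""
    env = np.ones(n)
    k = min(int(round(fade_s * sr)), n // 2)
    if k > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(k) / k)
        env[:k] = ramp
        env[-k:] = ramp[::-1]
    return env


def generate_event(
    spec: SyntheticEventSpec, sample_rate: int = GENERATION_SAMPLE_RATE
) -> AudioEvent:
    """Synthesize one event from its spec; deterministic given ``spec.seed``."""
    spec.validate(sample_rate)
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * sample_rate))
    x = np.zeros(n)

    if spec.noise_floor > 0:
        x += spec.noise_floor * 0.05 * rng.standard_normal(n)

    if spec.burst_times and spec.broadband_level > 0:
        sos = signal.butter(
            4, BURST_BAND_HZ, btype="bandpass", fs=sample_rate, output="sos"
        )
        for onset, length in spec.burst_times:
            i0 = int(round(onset * sample_rate))
            m = min(int(round(length * sample_rate)), n - i0)
            noise = signal.sosfilt(sos, rng.standard_normal(m))
            x[i0 : i0 + m] += (
                spec.broadband_level
                * _envelope(m, sample_rate, length, spec.burst_decay_fraction)
                * noise
            )

    for freq, amp, onset, length in spec.tonal_components:
        i0 = int(round(onset * sample_rate))
        m = min(int(round(length * sample_rate)), n - i0)
        t = np.arange(m) / sample_rate
        tone = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        if spec.tone_am_hz > 0:
            tone *= 0.55 + 0.45 * np.sin(
                2 * np.pi * spec.tone_am_hz * t + rng.uniform(0, 2 * np.pi)
            )
        x[i0 : i0 + m] += _fade(m, sample_rate) * tone

    for f0, f1, amp, onset, length in spec.chirp_components:
        i0 = int(round(onset * sample_rate))
        m = min(int(round(length * sample_rate)), n - i0)
        t = np.arange(m) / sample_rate
        sweep = amp * signal.chirp(t, f0=f0, t1=length, f1=f1, phi=rng.uniform(0, 360))
        x[i0 : i0 + m] += _fade(m, sample_rate) * sweep

    peak = np.max(np.abs(x)) if n else 0.0
    if peak > 0:
        x *= PEAK_AMPLITUDE / peak
    return AudioEvent(
        samples=x,
        sample_rate=sample_rate,
        label=spec.class_label,
        source_id=f"{spec.class_label}-{spec.seed}",
    )


def default_spec(class_label: str, seed: int = 0) -> SyntheticEventSpec:
    """Default phenotype recipe for one class."""
    if class_label == "wC":
        return SyntheticEventSpec(
            class_label="wC",
            duration=0.7,
            burst_times=((0.05, 0.55),),
            broadband_level=1.0,
            noise_floor=0.02,
            burst_decay_fraction=0.8,  # sustained response over the event
            seed=seed,
        )
    if class_label == "dC":
        return SyntheticEventSpec(
            class_label="dC",
            duration=0.8,
            burst_times=((0.10, 0.15), (0.50, 0.15)),
            broadband_level=1.0,
            noise_floor=0.02,
            burst_decay_fraction=0.25,  # percussive bursts, silent gap between
            seed=seed,
        )
    if class_label == "whC":
        return SyntheticEventSpec(
            class_label="whC",
            duration=1.8,
            burst_times=((0.05, 0.12), (0.30, 0.12), (0.55, 0.12)),
            chirp_components=((800.0, 1500.0, 0.8, 0.85, 0.75),),
            broadband_level=0.9,
            noise_floor=0.02,
            burst_decay_fraction=0.3,
            seed=seed,
        )
    if class_label == "RB":
        return SyntheticEventSpec(
            class_label="RB",
            duration=2.0,
            tonal_components=((400.0, 0.9, 0.05, 1.9),),
            tone_am_hz=0.3,
            broadband_level=0.0,
            noise_floor=0.02,
            seed=seed,
        )
    raise ValidationError(f"class_label: {class_label!r} not in {CLASS_LABELS}")


def _jittered_spec(class_label: str, seed: int, rng: np.random.Generator) -> SyntheticEventSpec:
    """Per-event variation: timing +/-20%, lengths and frequencies +/-10%."""
    base = default_spec(class_label, seed=seed)

    def j(v, frac):
        return float(v * rng.uniform(1 - frac, 1 + frac))

    bursts = tuple((j(o, 0.2), j(l, 0.1)) for o, l in base.burst_times)
    tones = tuple(
        (j(f, 0.1), a, j(o, 0.2), j(l, 0.1)) for f, a, o, l in base.tonal_components
    )
    chirps = tuple(
        (j(f0, 0.1), j(f1, 0.1), a, j(o, 0.1), j(l, 0.1))
        for f0, f1, a, o, l in base.chirp_components
    )
    # keep components inside the event
    end = max(
        [o + l for o, l in bursts]
        + [o + l for _, _, o, l in tones]
        + [o + l for _, _, _, o, l in chirps]
        + [base.duration]
    )
    return replace(
        base,
        duration=float(end) + 0.01,
        burst_times=bursts,
        tonal_components=tones,
        chirp_components=chirps,
    )


def generate_corpus(
    class_counts: dict,
    seed: int,
    sample_rate: int = GENERATION_SAMPLE_RATE,
) -> tuple[list, pd.DataFrame]:
    """Generate a labelled corpus of synthetic events.

    Returns the events plus a manifest with columns (path, label, seed);
    ``path`` is filled in by :func:`save_corpus`. Reproducible given
    ``seed``: event order and per-event seeds derive only from it.
    """
    for label, count in class_counts.items():
        if label not in CLASS_LABELS:
            raise ValidationError(f"class_counts: unknown class {label!r}")
        if count < 0:
            raise ValidationError(f"class_counts[{label}]: must be >= 0")
    master = np.random.default_rng(seed)
    events, rows = [], []
    for label in CLASS_LABELS:
        for i in range(int(class_counts.get(label, 0))):
            event_seed = int(master.integers(0, 2**31))
            spec = _jittered_spec(label, event_seed, master)
            ev = generate_event(spec, sample_rate)
            ev.source_id = f"{label}-{i:03d}-{event_seed}"
            events.append(ev)
            rows.append({"path": "", "label": label, "seed": event_seed,
                         "source_id": ev.source_id})
    manifest = pd.DataFrame(rows, columns=["path", "label", "seed", "source_id"])
    return events, manifest


def save_corpus(events: list, manifest: pd.DataFrame, out_dir: str) -> pd.DataFrame:
    """Write events as 16-bit PCM WAV plus a CSV manifest; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = manifest.copy()
    for i, ev in enumerate(events):
        path = os.path.join(out_dir, f"{ev.source_id}.wav")
        wavfile.write(path, ev.sample_rate, np.round(ev.samples * 32767).astype(np.int16))
        manifest.loc[i, "path"] = path
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def load_corpus(manifest_path: str) -> tuple[list, pd.DataFrame]:
    """Read a corpus back from its CSV manifest and WAV files."""
    manifest = pd.read_csv(manifest_path)
    events = []
    for _, row in manifest.iterrows():
        sr, data = wavfile.read(row["path"])
        samples = data.astype(np.float64) / 32768.0
        events.append(
            AudioEvent(samples=samples, sample_rate=sr, label=row["label"],
                       source_id=str(row.get("source_id", row["path"])))
        )
    return events, manifest
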