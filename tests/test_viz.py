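"""Time-frequency transforms, rendering, and the aggregate composition."""

import numpy as np
import pytest
from scipy.signal import get_window

from respviz import (
    AudioEvent,
    CwtConfig,
    LogAxisConfig,
    MelConfig,
    RenderedImage,
    StftConfig,
    TimeFrequencyMatrix,
    ValidationError,
    compose_aggregate,
    cwt_scalogram,
    images_for_event,
    linear_spectrogram,
    log_spectrogram,
    mel_spectrogram,
    render,
    to_grayscale,
)
from respviz.viz import cwt_frequencies, hz_to_mel, mel_band_centers, mel_filterbank, mel_to_hz

from conftest import make_tone


def brute_dft_power(frame, nfft):
    """Quadratic-cost one-sided |DFT|^2, the STFT oracle."""
    n = np.arange(frame.size)
    out = []
    for k in range(nfft // 2 + 1):
        out.append(abs(np.sum(frame * np.exp(-2j * np.pi * k * n / nfft))) ** 2)
    return np.array(out)


class TestStft:
    def test_power_matches_brute_force_dft(self):
        """Pinned normalization: entries are |DFT(window*frame)|^2 exactly."""
        cfg = StftConfig(window_length=64, fft_length=64, overlap_fraction=0.5)
        rng = np.random.default_rng(0)
        x = rng.uniform(-0.5, 0.5, 200)
        ev = AudioEvent(samples=x, sample_rate=20000, source_id="rand")
        tf = linear_spectrogram(ev, cfg)
        win = get_window("hamming", 64, fftbins=True)
        hop = cfg.hop
        for col in range(tf.time_axis.size):
            frame = x[col * hop : col * hop + 64] * win
            expected = brute_dft_power(frame, 64)
            assert np.allclose(tf.values[:, col], expected, atol=1e-8)

    def test_parseval_per_window(self):
        """Full-spectrum power sums to nfft times the windowed-frame energy."""
        cfg = StftConfig(window_length=128, fft_length=128, overlap_fraction=0.0)
        rng = np.random.default_rng(1)
        x = rng.uniform(-0.5, 0.5, 512)
        ev = AudioEvent(samples=x, sample_rate=20000)
        tf = linear_spectrogram(ev, cfg)
        win = get_window("hamming", 128, fftbins=True)
        for col in range(tf.time_axis.size):
            frame = x[col * 128 : (col + 1) * 128] * win
            onesided = tf.values[:, col]
            full = onesided[0] + onesided[-1] + 2 * onesided[1:-1].sum()
            assert full == pytest.approx(128 * np.sum(frame**2), rel=1e-10)

    def test_tone_peaks_in_correct_bin(self, tone_1khz):
        tf = linear_spectrogram(tone_1khz)
        mean_power = tf.values.mean(axis=1)
        peak_freq = tf.freq_axis[np.argmax(mean_power)]
        df = tf.freq_axis[1] - tf.freq_axis[0]
        assert abs(peak_freq - 1000.0) <= df

    def test_zero_event_gives_zero_matrix(self, zero_event):
        assert np.all(linear_spectrogram(zero_event).values == 0.0)

    def test_overlap_90_vs_50_column_ratio_near_5(self, tone_1khz):
        n90 = linear_spectrogram(tone_1khz, StftConfig(overlap_fraction=0.90)).time_axis.size
        n50 = linear_spectrogram(tone_1khz, StftConfig(overlap_fraction=0.50)).time_axis.size
        assert n90 / n50 == pytest.approx(5.0, rel=0.05)

    def test_event_shorter_than_window_rejected(self):
        ev = AudioEvent(samples=np.zeros(100), sample_rate=20000)
        with pytest.raises(ValidationError, match="window"):
            linear_spectrogram(ev, StftConfig(window_length=500))

    def test_frequency_axis_spans_zero_to_nyquist(self, tone_1khz):
        tf = linear_spectrogram(tone_1khz)
        assert tf.freq_axis[0] == 0.0
        assert tf.freq_axis[-1] == pytest.approx(10000.0)


class TestLogSpectrogram:
    def test_low_frequencies_expanded(self):
        """On the log axis, 100 Hz and 1 kHz rows are farther apart than
        1 kHz and 1.9 kHz rows."""
        sr = 20000
        t = np.arange(sr) / sr
        x = 0.3 * (np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 1000 * t)
                   + np.sin(2 * np.pi * 1900 * t))
        ev = AudioEvent(samples=x, sample_rate=sr)
        tf = log_spectrogram(ev)
        mean = tf.values.mean(axis=1)

        def peak_row(freq):
            window = np.abs(tf.freq_axis - freq) < freq * 0.25
            rows = np.flatnonzero(window)
            return rows[np.argmax(mean[rows])]

        assert (peak_row(1000) - peak_row(100)) > (peak_row(1900) - peak_row(1000))

    def test_zero_event_gives_zero_matrix(self, zero_event):
        assert np.all(log_spectrogram(zero_event).values == 0.0)

    def test_axis_starts_at_f_min_and_is_monotone(self, tone_1khz):
        cfg = LogAxisConfig(n_bins=48, f_min=25.0, f_max=4000.0)
        tf = log_spectrogram(tone_1khz, axis_cfg=cfg)
        assert tf.freq_axis[0] == pytest.approx(25.0)
        assert tf.freq_axis.size == 48
        assert np.all(np.diff(tf.freq_axis) > 0)


class TestMelSpectrogram:
    def test_matches_explicit_filterbank_multiplication(self, tone_1khz):
        """Dual route: projection equals an independently built triangular
        filterbank (loop construction from the mel formula) times the power."""
        mel_cfg = MelConfig(n_mel_bands=40)
        lin = linear_spectrogram(tone_1khz)
        tf = mel_spectrogram(tone_1khz, mel_cfg)

        # independent construction
        mels = np.linspace(hz_to_mel(mel_cfg.f_min), hz_to_mel(mel_cfg.f_max), 42)
        edges = mel_to_hz(mels)
        expected = np.zeros((40, lin.time_axis.size))
        for b in range(40):
            lo, c, hi = edges[b], edges[b + 1], edges[b + 2]
            w = np.zeros(lin.freq_axis.size)
            for i, f in enumerate(lin.freq_axis):
                if lo <= f <= c:
                    w[i] = (f - lo) / (c - lo)
                elif c < f <= hi:
                    w[i] = (hi - f) / (hi - c)
            if w.sum() == 0:
                w[np.argmin(np.abs(lin.freq_axis - c))] = 1.0
            expected[b] = w @ lin.values
        assert np.allclose(tf.values, expected, rtol=1e-10, atol=1e-12)

    def test_tone_maximizes_band_nearest_its_frequency(self):
        ev = make_tone(500.0)
        tf = mel_spectrogram(ev)
        band = int(np.argmax(tf.values.mean(axis=1)))
        nearest = int(np.argmin(np.abs(mel_band_centers(MelConfig()) - 500.0)))
        assert abs(band - nearest) <= 1

    def test_zero_event_gives_zero_matrix(self, zero_event):
        assert np.all(mel_spectrogram(zero_event).values == 0.0)

    def test_every_filter_sums_positive_and_projects_ones_positive(self):
        freqs = np.fft.rfftfreq(512, 1 / 20000)
        fb = mel_filterbank(MelConfig(), freqs)
        assert fb.shape == (64, freqs.size)
        assert np.all(fb.sum(axis=1) > 0)
        assert np.all(fb @ np.ones(freqs.size) > 0)

    def test_band_centers_monotone(self):
        centers = mel_band_centers(MelConfig())
        assert np.all(np.diff(centers) > 0)


def oracle_ridge_frequency(x, sr, freqs):
    """Matched-filter oracle: dominant frequency by direct convolution with
    explicitly constructed analytic Morlet atoms (6-cycle Gaussian window)."""
    best, best_val = None, -1.0
    for f in freqs:
        sigma = 6.0 / (2 * np.pi * f)
        t = np.arange(-4 * sigma, 4 * sigma, 1.0 / sr)
        atom = np.exp(-(t**2) / (2 * sigma**2)) * np.exp(2j * np.pi * f * t)
        atom /= np.linalg.norm(atom)
        val = np.max(np.abs(np.convolve(x, atom, mode="valid")))
        if val > best_val:
            best, best_val = f, val
    return best


class TestCwtScalogram:
    def test_zero_event_gives_zero_matrix(self, zero_event):
        assert np.all(cwt_scalogram(zero_event).values == 0.0)

    def test_tone_ridge_within_one_voice(self):
        ev = make_tone(1000.0, duration=0.3)
        cfg = CwtConfig()
        tf = cwt_scalogram(ev, cfg)
        mid = tf.values[:, tf.time_axis.size // 4 : -tf.time_axis.size // 4]
        ridge_freq = tf.freq_axis[int(np.argmax(mid.mean(axis=1)))]
        one_voice = 2.0 ** (1.0 / cfg.voices_per_octave)
        assert 1000.0 / one_voice <= ridge_freq <= 1000.0 * one_voice
        # agreement with the independent matched-filter oracle
        oracle = oracle_ridge_frequency(ev.samples, ev.sample_rate, tf.freq_axis)
        assert abs(np.log2(ridge_freq / oracle)) <= 1.0 / cfg.voices_per_octave

    def test_sequential_tones_ridge_rises(self):
        sr = 20000
        t = np.arange(sr // 4) / sr
        x = np.concatenate([0.5 * np.sin(2 * np.pi * 500 * t),
                            0.5 * np.sin(2 * np.pi * 2000 * t)])
        ev = AudioEvent(samples=x, sample_rate=sr)
        tf = cwt_scalogram(ev)
        half = tf.time_axis.size // 2
        margin = half // 4
        first = tf.freq_axis[int(np.argmax(tf.values[:, margin : half - margin].mean(axis=1)))]
        second = tf.freq_axis[int(np.argmax(tf.values[:, half + margin : -margin].mean(axis=1)))]
        assert second > first * 2

    def test_rows_ordered_by_pseudo_frequency(self):
        freqs = cwt_frequencies(CwtConfig())
        assert np.all(np.diff(freqs) > 0)
        assert freqs[0] == pytest.approx(20.0)
        assert freqs[-1] <= 4000.0


def const_matrix(value, shape=(32, 40)):
    return TimeFrequencyMatrix(
        values=np.full(shape, value), freq_axis=np.arange(shape[0], dtype=float),
        time_axis=np.arange(shape[1], dtype=float), scale_tag="linear",
    )


class TestRender:
    def test_output_geometry(self, tone_1khz):
        img = render(linear_spectrogram(tone_1khz))
        assert img.pixels.shape == (227, 227, 3)
        assert img.pixels.dtype == np.uint8

    def test_constant_matrix_renders_spatially_constant(self):
        img = render(const_matrix(3.7))
        assert np.all(img.pixels == img.pixels[0, 0])

    def test_triplication_channels_identical(self, tone_1khz):
        img = render(linear_spectrogram(tone_1khz))
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 1])
        assert np.array_equal(img.pixels[..., 0], img.pixels[..., 2])

    def test_all_zero_matrix_renders_at_floor(self):
        img = render(const_matrix(0.0))
        assert np.all(img.pixels == 0)

    def test_monotone_under_shared_clip_bounds(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(1e-6, 1.0, (30, 50))
        b = a * rng.uniform(0.1, 1.0, a.shape)  # b <= a elementwise
        bounds = (-60.0, 0.0)
        axes = (np.arange(30.0), np.arange(50.0))
        ga = to_grayscale(render(TimeFrequencyMatrix(a, *axes, "linear"),
                                 clip_bounds=bounds))
        gb = to_grayscale(render(TimeFrequencyMatrix(b, *axes, "linear"),
                                 clip_bounds=bounds))
        assert np.all(ga.astype(int) >= gb.astype(int))

    def test_named_colormap_accepted(self, tone_1khz):
        img = render(linear_spectrogram(tone_1khz), colormap_tag="viridis")
        assert img.pixels.shape == (227, 227, 3)


class TestGrayscaleAndAggregate:
    @pytest.mark.parametrize("v", [0, 17, 128, 255])
    def test_gray_image_maps_to_itself(self, v):
        img = RenderedImage(pixels=np.full((227, 227, 3), v, dtype=np.uint8),
                            method_tag="linear")
        assert np.all(to_grayscale(img) == v)

    def test_pure_red_uses_luma_weight(self):
        pixels = np.zeros((227, 227, 3), dtype=np.uint8)
        pixels[..., 0] = 255
        img = RenderedImage(pixels=pixels, method_tag="linear")
        assert np.all(to_grayscale(img) == round(255 * 0.299))

    def test_compose_round_trip_recovers_inputs(self, standardized_dc):
        imgs = images_for_event(standardized_dc,
                                methods=("linear", "mel", "wavelet", "aggregate"))
        agg = imgs["aggregate"]
        assert agg.method_tag == "aggregate"
        # channel order fixed: R=linear, G=mel, B=wavelet
        assert np.array_equal(agg.pixels[..., 0], to_grayscale(imgs["linear"]))
        assert np.array_equal(agg.pixels[..., 1], to_grayscale(imgs["mel"]))
        assert np.array_equal(agg.pixels[..., 2], to_grayscale(imgs["wavelet"]))

    def test_identical_inputs_give_equal_channels(self):
        pix = np.random.default_rng(2).integers(0, 256, (227, 227, 3)).astype(np.uint8)
        img = RenderedImage(pixels=pix, method_tag="linear", provenance="e1")
        agg = compose_aggregate(img, img, img)
        assert np.array_equal(agg.pixels[..., 0], agg.pixels[..., 1])
        assert np.array_equal(agg.pixels[..., 1], agg.pixels[..., 2])

    def test_mismatched_provenance_rejected(self):
        pix = np.zeros((227, 227, 3), dtype=np.uint8)
        a = RenderedImage(pixels=pix, method_tag="linear", provenance="e1")
        b = RenderedImage(pixels=pix, method_tag="mel", provenance="e2")
        c = RenderedImage(pixels=pix, method_tag="wavelet", provenance="e1")
        with pytest.raises(ValidationError, match="provenance"):
            compose_aggregate(a, b, c)
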