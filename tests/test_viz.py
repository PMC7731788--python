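"""Polarity projections, kymograph sampling and beat-frequency readout."""

import matplotlib
import numpy as np
import pytest

from csfflow.errors import InvalidParameterError
from csfflow.movie import Movie
from csfflow.viz import beat_frequency, compute_kymograph, temporal_color_projection

FPS = 30.0


def static_structured_movie(n_frames=40):
    rng = np.random.default_rng(0)
    frame = rng.uniform(20, 200, (24, 24)).astype(np.float32)
    return Movie(np.repeat(frame[None], n_frames, axis=0), 2.0, 1 / FPS)


def moving_dot_movie(n_frames=30, amplitude=150.0):
    data = np.full((n_frames, 16, 40), 20.0, np.float32)
    jj, ii = np.meshgrid(np.arange(40), np.arange(16))
    for t in range(n_frames):
        x = 4.0 + t  # one px per frame, left to right
        data[t] += amplitude * np.exp(-((jj - x) ** 2 + (ii - 8.0) ** 2) / 2.0)
    return Movie(data, 2.0, 1 / FPS)


class TestTemporalColorProjection:
    def test_static_movie_reduces_to_grayscale_first_frame(self):
        mv = static_structured_movie()
        rgb = temporal_color_projection(mv)
        f0 = mv.data[0]
        gray = (f0 - f0.min()) / (f0.max() - f0.min())
        assert np.allclose(rgb[:, :, 0], gray, atol=1e-6)
        assert np.allclose(rgb[:, :, 1], gray, atol=1e-6)
        assert np.allclose(rgb[:, :, 2], gray, atol=1e-6)

    def test_trail_hue_order_follows_motion(self):
        mv = moving_dot_movie()
        rgb = temporal_color_projection(mv, colormap="viridis")
        # viridis runs blue -> yellow: late (right-hand) trail pixels have a
        # larger red-minus-blue difference than early ones
        row = rgb[8]
        signal = row[:, 0] - row[:, 2]
        lit = np.nonzero(np.abs(signal) > 0.05)[0]
        assert len(lit) > 10
        early = signal[lit[:3]].mean()
        late = signal[lit[-3:]].mean()
        assert late > early

    def test_reversed_frames_reverse_hue_order(self):
        mv = moving_dot_movie()
        rev = Movie(mv.data[::-1].copy(), mv.pixel_size_um, mv.frame_interval_s)
        fwd = temporal_color_projection(mv)
        bwd = temporal_color_projection(rev)
        sig_f = fwd[8, :, 0] - fwd[8, :, 2]
        sig_b = bwd[8, :, 0] - bwd[8, :, 2]
        lit = np.nonzero(np.abs(sig_f) > 0.05)[0]
        assert (sig_f[lit[-3:]].mean() - sig_f[lit[:3]].mean()) * (
            sig_b[lit[-3:]].mean() - sig_b[lit[:3]].mean()
        ) < 0

    def test_single_frame_range_single_tint(self):
        mv = moving_dot_movie()
        rgb = temporal_color_projection(mv, frame_range=(5, 6), fg_threshold=10.0)
        # all foreground pixels carry the same colormap colour (t=0 of range)
        tint = np.asarray(matplotlib.colormaps["viridis"](0.0)[:3])
        fg = rgb.reshape(-1, 3)
        bright = fg[fg[:, 2] > 0.2]  # the tint is blue-dominant
        assert len(bright) > 0
        ratios = bright / np.linalg.norm(bright, axis=1, keepdims=True)
        expected = tint / np.linalg.norm(tint)
        assert np.allclose(ratios, expected, atol=0.05)

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            temporal_color_projection(static_structured_movie(), (5, 5))


class TestKymograph:
    def test_static_movie_columns_identical(self):
        mv = static_structured_movie()
        k = compute_kymograph(mv, [(2, 3), (20, 18)], width=1)
        assert np.allclose(k.image, k.image[:, :1])

    def test_width_one_equals_no_transverse_averaging(self):
        mv = static_structured_movie()
        a = compute_kymograph(mv, [(2, 5), (20, 5)], width=1)
        b = compute_kymograph(mv, [(2, 5), (20, 5)])
        assert np.array_equal(a.image, b.image)

    def test_travelling_wave_stripe_slope(self):
        # pattern moving at s px/frame tilts stripes by 1/s frames per px
        T, H, W = 64, 12, 80
        s = 2.0
        t = np.arange(T)[:, None, None]
        x = np.arange(W)[None, None, :]
        data = 100 + 50 * np.sin(2 * np.pi * (x - s * t) / 16.0)
        mv = Movie(np.broadcast_to(data, (T, H, W)).astype(np.float32), 2.0, 1 / FPS)
        k = compute_kymograph(mv, [(4, 6), (74, 6)])
        # cross-correlate consecutive columns: spatial shift per frame = s px
        shifts = []
        for tt in range(20):
            c0 = k.image[:, tt] - k.image[:, tt].mean()
            c1 = k.image[:, tt + 1] - k.image[:, tt + 1].mean()
            xc = np.correlate(c1, c0, mode="full")
            shifts.append(np.argmax(xc) - (len(c0) - 1))
        assert np.median(shifts) == pytest.approx(s, abs=0.5)

    def test_zero_length_line_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_kymograph(static_structured_movie(), [(5, 5), (5, 5)])

    def test_line_outside_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_kymograph(static_structured_movie(), [(0, 0), (100, 0)])


class TestBeatFrequency:
    def beating_movie(self, freq_hz, amplitude, n_frames=128):
        t = np.arange(n_frames)[:, None, None] / FPS
        base = np.full((12, 30), 50.0)
        mod = amplitude * np.sin(2 * np.pi * freq_hz * t)
        data = (base[None] + mod).astype(np.float32)
        return Movie(data, 2.0, 1 / FPS)

    def test_five_hz_recovered_within_one_bin(self):
        mv = self.beating_movie(5.0, 20.0)
        k = compute_kymograph(mv, [(2, 6), (27, 6)])
        assert beat_frequency(k) == pytest.approx(5.0, abs=FPS / mv.n_frames)

    def test_zero_amplitude_returns_zero(self):
        mv = self.beating_movie(5.0, 0.0)
        k = compute_kymograph(mv, [(2, 6), (27, 6)])
        assert beat_frequency(k) == 0.0

    def test_noise_only_returns_zero(self):
        rng = np.random.default_rng(3)
        data = rng.normal(50, 5, (128, 12, 30)).astype(np.float32)
        k = compute_kymograph(Movie(data, 2.0, 1 / FPS), [(2, 6), (27, 6)])
        assert beat_frequency(k) == 0.0

    def test_intensity_scaling_invariance(self):
        mv = self.beating_movie(7.0, 20.0)
        k = compute_kymograph(mv, [(2, 6), (27, 6)])
        k2 = compute_kymograph(
            Movie(mv.data * 3.7, mv.pixel_size_um, mv.frame_interval_s),
            [(2, 6), (27, 6)],
        )
        assert beat_frequency(k) == beat_frequency(k2)

    def test_too_few_frames_rejected(self):
        mv = self.beating_movie(5.0, 20.0, n_frames=16)
        k = compute_kymograph(mv, [(2, 6), (27, 6)])
        with pytest.raises(InvalidParameterError):
            beat_frequency(k)


def test_save_field_maps_writes_three_pngs(tmp_path):
    from csfflow.gpr import DenseField
    from csfflow.viz import save_field_maps

    mask = np.zeros((12, 12), bool)
    mask[3:9, 3:9] = True
    g = np.where(mask, 2.0, np.nan)
    fld = DenseField(mask, g, g / 2, g / 10, g / 10, pixel_size_um=2.0)
    paths = save_field_maps(fld, str(tmp_path / "f"))
    assert len(paths) == 3
    import os
    assert all(os.path.exists(p) for p in paths)
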