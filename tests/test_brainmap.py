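"""Band power, azimuthal projection, interpolation, map construction."""

import numpy as np
import pytest

import topogru as tg
from topogru.brainmap import DEFAULT_BANDS, hull_mask
from topogru.io import Montage

THETA, ALPHA, BETA = DEFAULT_BANDS


class TestBandPower:
    def test_pure_alpha_tone_power_is_half_amplitude_squared(self, sinusoid_segment):
        seg = sinusoid_segment  # 10 Hz, amplitude 1
        a = tg.band_power(seg, ALPHA)
        th = tg.band_power(seg, THETA)
        be = tg.band_power(seg, BETA)
        assert np.allclose(a, 0.5, rtol=0.03)
        assert (th <= 0.01 * a).all() and (be <= 0.01 * a).all()

    def test_zero_segment_has_zero_power(self, montage16):
        seg = tg.Segment(np.zeros((16, 250)), 250.0, "z", 0,
                         list(montage16.channel_names))
        for band in DEFAULT_BANDS:
            assert np.allclose(tg.band_power(seg, band), 0.0)

    def test_white_noise_band_fraction_matches_flat_spectrum(self):
        rng = np.random.default_rng(8)
        fs = 250.0
        x = rng.normal(size=(64, int(fs)))
        total = tg.total_power(x)
        summed = sum(tg.band_power(x, b, fs=fs) for b in DEFAULT_BANDS)
        frac = (summed / total).mean()
        assert abs(frac - (30 - 4) / (fs / 2)) < 0.1 * ((30 - 4) / (fs / 2)) + 0.02

    def test_band_partition_never_exceeds_total_power(self):
        rng = np.random.default_rng(5)
        fs = 250.0
        for _ in range(100):
            x = rng.normal(size=(1, int(fs)))
            summed = sum(tg.band_power(x, b, fs=fs) for b in DEFAULT_BANDS)
            assert summed[0] <= tg.total_power(x)[0] * (1 + 1e-9)

    def test_bandlimited_signal_reaches_parseval_equality(self):
        rng = np.random.default_rng(6)
        fs = 250.0
        t = np.arange(int(fs)) / fs
        # bin-aligned tones: at 1 s the periodogram bins sit on integers,
        # so integer frequencies avoid rectangular-window leakage
        freqs = rng.choice(np.arange(5, 29), size=8, replace=False)
        x = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 6)) for f in freqs)
        x = x[None, :] - x.mean()
        summed = sum(tg.band_power(x, b, fs=fs) for b in DEFAULT_BANDS)
        assert np.allclose(summed, tg.total_power(x), rtol=0.02)

    def test_band_above_nyquist_is_an_error(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tg.band_power(np.zeros((1, 100)), tg.BandDefinition("hi", 60, 80),
                          fs=100.0)


class TestProjection:
    def test_vertex_maps_to_the_origin(self):
        m = Montage("t", ["Cz", "a", "b", "c"], np.array(
            [[0, 0, 1], [1, 0, 0], [0, 1, 0], [-1, 0, 0]], dtype=float))
        lay = tg.aep_project(m)
        assert np.allclose(lay.uv[0], [0, 0], atol=1e-12)

    def test_equatorial_electrode_radius_is_half_pi(self):
        m = Montage("t", ["Cz", "eq", "b", "c"], np.array(
            [[0, 0, 1], [1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float))
        lay = tg.aep_project(m)
        assert np.allclose(np.linalg.norm(lay.uv[1]), np.pi / 2, atol=1e-12)

    @pytest.mark.parametrize("name", ["standard-1020-16", "dense-sim-128"])
    def test_planar_radius_equals_arc_distance_from_vertex(self, name):
        m = tg.load_montage(name)
        lay = tg.aep_project(m)
        radii = np.linalg.norm(lay.uv, axis=1)
        arcs = np.arccos(np.clip(m.coords[:, 2], -1, 1))
        assert np.abs(radii - arcs).max() <= 1e-9

    def test_antipodal_electrode_is_singular(self):
        m = Montage("t", ["a", "b", "c", "d"], np.array(
            [[0, 0, 1], [1, 0, 0], [0, 1, 0], [0, 0, -1]], dtype=float))
        with pytest.raises(ValueError, match="antipode"):
            tg.aep_project(m)

    def test_anterior_electrodes_sit_in_the_upper_half_plane(self, montage16, layout16):
        fp1 = montage16.channel_names.index("Fp1")
        o1 = montage16.channel_names.index("O1")
        assert layout16.uv[fp1, 1] > 0 > layout16.uv[o1, 1]


class TestInterpolation:
    def test_constant_field_fills_the_hull(self, layout16):
        grid = tg.interpolate_topomap(np.full(16, 3.25), layout16)
        mask = hull_mask(layout16)
        assert np.allclose(grid[mask], 3.25, atol=1e-6)
        assert np.allclose(grid[~mask], 0.0)

    def test_interpolant_is_node_exact(self, layout16):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=16)
        from scipy.interpolate import CloughTocher2DInterpolator
        interp = CloughTocher2DInterpolator(layout16.uv, vals)
        back = interp(layout16.uv)
        assert np.allclose(back, vals, rtol=1e-6, atol=1e-9)

    def test_linear_fields_are_reproduced(self, layout16):
        a, b, c = 1.3, -0.7, 0.2
        vals = a * layout16.uv[:, 0] + b * layout16.uv[:, 1] + c
        grid = tg.interpolate_topomap(vals, layout16, 28, fill=np.nan)
        r = 1.05 * layout16.r_max
        u = np.linspace(-r, r, 28)
        v = np.linspace(r, -r, 28)
        uu, vv = np.meshgrid(u, v)
        expected = a * uu + b * vv + c
        m = ~np.isnan(grid)
        scale = np.abs(expected[m]).max()
        assert np.abs(grid[m] - expected[m]).max() <= 1e-3 * scale

    def test_too_few_or_collinear_electrodes_are_errors(self):
        lay3 = tg.Layout2D(["a", "b", "c"], np.array(
            [[0, 0], [1, 0], [0, 1]], dtype=float), 1.0)
        with pytest.raises(ValueError, match="4 electrodes"):
            tg.interpolate_topomap(np.zeros(3), lay3)
        col = tg.Layout2D(list("abcd"), np.array(
            [[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float), 3.0)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            tg.interpolate_topomap(np.zeros(4), col)


class TestBrainMap:
    def test_shape_is_always_28_28_3(self, sinusoid_segment, layout16):
        bmap = tg.make_brainmap(sinusoid_segment, layout16)
        assert bmap.grid.shape == (28, 28, 3)
        assert np.isfinite(bmap.grid).all()

    def test_zero_segment_gives_an_all_zero_map(self, montage16, layout16):
        seg = tg.Segment(np.zeros((16, 250)), 250.0, "z", 0,
                         list(montage16.channel_names))
        assert np.allclose(tg.make_brainmap(seg, layout16).grid, 0.0)

    def test_occipital_alpha_source_peaks_in_the_posterior_half(
            self, montage16, layout16):
        fs = 250.0
        t = np.arange(int(fs)) / fs
        data = np.zeros((16, int(fs)))
        for ch in ("O1", "O2"):
            data[montage16.channel_names.index(ch)] = np.sin(2 * np.pi * 10 * t)
        seg = tg.Segment(data, fs, "s", 0, list(montage16.channel_names))
        bmap = tg.make_brainmap(seg, layout16)
        alpha_plane = bmap.grid[:, :, 1]
        i, _ = np.unravel_index(np.argmax(alpha_plane), alpha_plane.shape)
        assert i >= 14  # rows are anterior→posterior; the peak is posterior

    def test_channel_mismatch_is_an_error(self, layout16):
        seg = tg.Segment(np.zeros((16, 250)), 250.0, "s", 0,
                         ["x"] * 16)
        with pytest.raises(ValueError, match="match the layout"):
            tg.make_brainmap(seg, layout16)

    def test_maps_are_bit_deterministic(self, sinusoid_segment, layout16):
        g1 = tg.make_brainmap(sinusoid_segment, layout16).grid
        g2 = tg.make_brainmap(sinusoid_segment, layout16).grid
        assert np.array_equal(g1, g2)

    def test_rotating_the_montage_rotates_the_image(self):
        az = np.deg2rad(np.arange(0, 360, 45))
        outer = np.column_stack([np.sin(1.0) * np.sin(az),
                                 np.sin(1.0) * np.cos(az),
                                 np.cos(1.0) * np.ones(8)])
        az2 = np.deg2rad(np.arange(0, 360, 90) + 22.5)
        inner = np.column_stack([np.sin(0.4) * np.sin(az2),
                                 np.sin(0.4) * np.cos(az2),
                                 np.cos(0.4) * np.ones(4)])
        coords = np.vstack([outer, inner])
        names = [f"ch{i}" for i in range(len(coords))]
        vals = np.random.default_rng(0).normal(size=len(coords))
        rho = np.pi / 2
        R = np.array([[np.cos(rho), -np.sin(rho), 0],
                      [np.sin(rho), np.cos(rho), 0], [0, 0, 1]])
        g1 = tg.interpolate_topomap(
            vals, tg.aep_project(Montage("a", names, coords)))
        g2 = tg.interpolate_topomap(
            vals, tg.aep_project(Montage("b", names, coords @ R.T)))
        assert np.abs(np.rot90(g1, 1) - g2).max() <= 1e-6


class TestSequence:
    def test_default_framing_gives_three_frames_per_second(
            self, sinusoid_segment, layout16):
        seq = tg.make_sequence(sinusoid_segment, layout16)
        assert seq.frames.shape == (3, 28, 28, 3)

    def test_full_length_frame_equals_the_plain_map(self, sinusoid_segment,
                                                    layout16):
        seq = tg.make_sequence(sinusoid_segment, layout16, frame_len=1.0,
                               frame_step=1.0)
        bmap = tg.make_brainmap(sinusoid_segment, layout16)
        assert seq.frames.shape[0] == 1
        assert np.array_equal(seq.frames[0], bmap.grid)

    def test_stationary_tone_gives_nearly_identical_frames(
            self, sinusoid_segment, layout16):
        seq = tg.make_sequence(sinusoid_segment, layout16)
        ref = np.linalg.norm(seq.frames[0])
        for i in range(1, seq.n_frames):
            d = np.linalg.norm(seq.frames[i] - seq.frames[0])
            assert d <= 0.10 * ref

    def test_too_short_frames_are_rejected(self, sinusoid_segment, layout16):
        with pytest.raises(ValueError, match="2 cycles"):
            tg.make_sequence(sinusoid_segment, layout16, frame_len=0.2)
        with pytest.raises(ValueError, match="exceeds"):
            tg.make_sequence(sinusoid_segment, layout16, frame_len=2.0)


class TestNormalization:
    def test_none_mode_is_identity(self, layout16):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(5, 28, 28, 3))
        out, stats = tg.normalize_maps(maps, hull_mask(layout16), "none")
        assert np.array_equal(out, maps)
        assert stats == {"mode": "none"}

    def test_per_band_z_standardises_in_hull_training_pixels(self, layout16):
        rng = np.random.default_rng(1)
        mask = hull_mask(layout16)
        maps = rng.normal(3.0, 2.0, size=(20, 28, 28, 3))
        out, stats = tg.normalize_maps(maps, mask, "per_band_z")
        pix = out[:, mask, :]
        assert np.allclose(pix.mean(axis=(0, 1)), 0.0, atol=1e-9)
        assert np.allclose(pix.std(axis=(0, 1)), 1.0, atol=1e-9)

    def test_test_set_reuses_training_statistics(self, layout16):
        rng = np.random.default_rng(2)
        mask = hull_mask(layout16)
        train = rng.normal(size=(20, 28, 28, 3))
        _, stats = tg.normalize_maps(train, mask, "per_band_z")
        shifted = train + 5.0
        out, stats2 = tg.normalize_maps(shifted, mask, "per_band_z", stats=stats)
        assert stats2 is stats
        # a shifted test set keeps its shift: no recomputation happened
        mean_shift = out[:, mask, :].mean()
        expected = 5.0 / np.asarray(stats["sd"]).mean()
        assert abs(mean_shift) > 1.0  # clearly non-centred
        assert np.isclose(mean_shift, (5.0 / np.asarray(stats["sd"])).mean(),
                          rtol=0.05)

    def test_unknown_mode_is_an_error(self, layout16):
        with pytest.raises(ValueError, match="unknown"):
            tg.normalize_maps(np.zeros((1, 28, 28, 3)), hull_mask(layout16),
                              "weird")
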