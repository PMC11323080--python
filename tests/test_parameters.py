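import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodpool import (
    AcquisitionMeta,
    GatedCine,
    PhantomConfig,
    SeedPoint,
    approx_entropy,
    apen_spatial,
    beat_statistics,
    bounded_apen,
    compute_all,
    compute_lvef,
    detect_ed_es,
    ejection_rate,
    first_harmonic,
    fractional_shortening,
    generate_phantom,
    lung_heart_ratio,
    phase_lvef,
    phase_statistics,
    shape_metrics,
)

T = 16


def maps_from_phases(phases, amps, a0=100.0):
    t = np.arange(T)[:, None, None]
    phases = np.asarray(phases, dtype=float)[None, None, :]
    amps = np.asarray(amps, dtype=float)[None, None, :]
    frames = a0 + amps * np.cos(2 * np.pi * t / T - np.radians(phases))
    return first_harmonic(GatedCine(frames, AcquisitionMeta(n_frames=T)))


class TestLvef:
    @pytest.mark.parametrize(
        "edc,esc,expected", [(10000, 4000, 60.0), (5000, 5000, 0.0), (1000, 500, 50.0)]
    )
    def test_count_formula(self, edc, esc, expected):
        tac = np.array([edc, 8000, 6000, esc, 6000, 8000, 9000, 9500])
        assert compute_lvef(tac, 0, 3) == pytest.approx(expected)

    def test_zero_edc_rejected(self):
        with pytest.raises(ValueError):
            compute_lvef(np.zeros(8), 0, 3)


class TestPhaseLvef:
    def test_uniform_maps_formula(self):
        maps = maps_from_phases([30.0] * 8, [25.0] * 8, a0=100.0)
        mask = np.ones((1, 8), dtype=bool)
        assert phase_lvef(maps, mask) == pytest.approx(40.0, abs=1e-6)

    def test_zero_amplitude_gives_zero(self):
        frames = np.full((T, 1, 4), 50.0)
        maps = first_harmonic(GatedCine(frames, AcquisitionMeta(n_frames=T)))
        assert phase_lvef(maps, np.ones((1, 4), bool)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_count_lvef_on_pure_harmonic_cine(self):
        rng = np.random.default_rng(6)
        a0 = rng.uniform(80, 120, size=(6, 6))
        a1 = a0 * 0.3
        t = np.arange(T)[:, None, None]
        frames = a0 + a1 * np.cos(2 * np.pi * t / T)
        cine = GatedCine(frames, AcquisitionMeta(n_frames=T))
        mask = np.ones((6, 6), dtype=bool)
        tac = frames.sum(axis=(1, 2))
        ed, es = detect_ed_es(tac)
        assert phase_lvef(first_harmonic(cine), mask) == pytest.approx(
            compute_lvef(tac, ed, es), abs=2.0
        )


class TestEjectionRate:
    def test_peak_drop_normalised(self):
        tac = [100.0, 60.0, 40.0, 50.0, 70.0, 85.0, 95.0, 100.0]
        # biggest drop 100 -> 60 over one 50 ms frame
        assert ejection_rate(np.array(tac), 0, 50.0) == pytest.approx(8.0)

    def test_constant_curve_rate_zero(self):
        assert ejection_rate(np.full(8, 5.0), 0, 50.0) == 0.0

    def test_matches_analytic_peak_emptying_rate(self, sync_phantom, sync_params):
        cine, truth = sync_phantom
        v = truth.volume_curve
        dt = cine.meta.frame_time / 1000.0
        analytic = max(np.maximum(v - np.roll(v, -1), 0.0) / (v.max() * dt))
        assert sync_params.ejection_rate == pytest.approx(analytic, rel=0.10)


class TestApproxEntropy:
    def test_constant_sequence_is_zero(self):
        assert approx_entropy(np.full(20, 3.0), m=2, r=0.5) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "x,m,r",
        [
            (np.tile([1.0, 2.0, 3.0], 10), 2, 0.5),
            (np.tile([0.0, 1.0], 10), 1, 0.1),
        ],
    )
    def test_fast_matches_slow_oracle(self, x, m, r):
        fast = approx_entropy(x, m, r, mode="fast")
        slow = approx_entropy(x, m, r, mode="slow")
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            approx_entropy(np.arange(3.0), m=2)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            approx_entropy(np.arange(10.0), m=1, r=-0.1)


class TestBoundedApen:
    @settings(max_examples=20, derandomize=True)
    @given(a=st.floats(0.1, 50.0), c=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, c):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=40)
        assert bounded_apen(a * x + c) == pytest.approx(bounded_apen(x), abs=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="range"):
            bounded_apen(np.full(30, 2.0))

    def test_identity_with_explicit_tolerance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=100)
        r = 0.2 * (x.max() - x.min())
        assert bounded_apen(x, m=2, r_frac=0.2) == pytest.approx(
            approx_entropy(x, m=2, r=r), abs=1e-12
        )


class TestPhaseStatistics:
    def test_perfect_synchrony(self):
        maps = maps_from_phases([120.0] * 10, np.linspace(5, 30, 10))
        e_raw, e_norm, syn, mean_phase, psd = phase_statistics(
            maps, np.ones((1, 10), bool)
        )
        assert e_norm == pytest.approx(0.0, abs=1e-12)
        assert syn == pytest.approx(1.0, abs=1e-9)
        assert psd == pytest.approx(0.0, abs=1e-6)
        assert mean_phase == pytest.approx(120.0, abs=1e-6)

    def test_opposite_phases_cancel(self):
        maps = maps_from_phases([0.0, 180.0], [10.0, 10.0])
        e_raw, e_norm, syn, _, _ = phase_statistics(maps, np.ones((1, 2), bool), 64)
        assert syn == pytest.approx(0.0, abs=1e-9)
        assert e_norm == pytest.approx(1.0 / np.log2(64), abs=1e-9)

    def test_amplitude_scale_invariance(self):
        phases = [10.0, 40.0, 200.0, 355.0]
        amps = np.array([5.0, 10.0, 3.0, 8.0])
        m1 = maps_from_phases(phases, amps)
        m2 = maps_from_phases(phases, 2 * amps)
        mask = np.ones((1, 4), bool)
        np.testing.assert_allclose(
            phase_statistics(m1, mask), phase_statistics(m2, mask), atol=1e-9
        )


class TestApenSpatial:
    def test_uniform_phase_scores_zero_with_warning(self):
        maps = maps_from_phases([90.0] * 12, [10.0] * 12)
        mask = np.ones((1, 12), bool)
        with pytest.warns(UserWarning, match="uniform phase"):
            d, s, ds = apen_spatial(maps, mask, mask)
        assert d == s == ds == 0.0

    def test_identical_masks_identical_values(self):
        rng = np.random.default_rng(7)
        phases = rng.uniform(0, 360, 30)
        maps = maps_from_phases(phases, rng.uniform(5, 15, 30))
        mask = np.ones((1, 30), bool)
        d, s, ds = apen_spatial(maps, mask, mask)
        assert d == s
        assert ds == pytest.approx((d + s) / 2)

    def test_mean_composition_against_oracle(self):
        rng = np.random.default_rng(7)
        phases = rng.uniform(0, 360, 40)
        maps = maps_from_phases(phases, rng.uniform(5, 15, 40))
        ed = np.zeros((1, 40), bool)
        es = np.zeros((1, 40), bool)
        ed[0, :25] = True
        es[0, 25:] = True
        d, s, ds = apen_spatial(maps, ed, es)
        oracle_d = bounded_apen(maps.phase[ed], m=2, r_frac=0.2, mode="slow")
        oracle_s = bounded_apen(maps.phase[es], m=2, r_frac=0.2, mode="slow")
        assert d == pytest.approx(oracle_d, abs=1e-9)
        assert ds == pytest.approx((oracle_d + oracle_s) / 2, abs=1e-9)

    def test_tiny_mask_rejected(self):
        maps = maps_from_phases([0.0, 10.0, 20.0], [5.0, 5.0, 5.0])
        small = np.zeros((1, 3), bool)
        small[0, 0] = True
        with pytest.raises(ValueError, match="m\\+2"):
            apen_spatial(maps, small, small)


class TestShapeMetrics:
    def test_disc_is_round(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        area, _, circ, elong, L, S = shape_metrics(disc)
        assert elong == pytest.approx(1.0, abs=0.02)
        assert 0.95 <= circ <= 1.05

    def test_two_to_one_ellipse_elongation(self):
        rr, cc = np.mgrid[0:64, 0:64]
        ell = ((rr - 32) / 20.0) ** 2 + ((cc - 32) / 10.0) ** 2 <= 1.0
        area, mm2, circ, elong, L, S = shape_metrics(ell)
        assert elong == pytest.approx(2.0, rel=0.05)

    def test_area_scaled_by_pixel_spacing(self):
        rr, cc = np.mgrid[0:16, 0:16]
        disc = (rr - 8) ** 2 + (cc - 8) ** 2 <= 9
        area, mm2, *_ = shape_metrics(disc, pixel_spacing=(3.0, 3.0))
        assert mm2 == pytest.approx(area * 9.0)

    def test_degenerate_masks_rejected(self):
        tiny = np.zeros((8, 8), bool)
        tiny[2, 2] = tiny[2, 3] = True
        with pytest.raises(ValueError):
            shape_metrics(tiny)
        line = np.zeros((8, 8), bool)
        line[2, 1:7] = True
        with pytest.raises(ValueError):
            shape_metrics(line)


class TestFractionalShortening:
    def test_quarter_shortening(self):
        fs_long, fs_short = fractional_shortening((40.0, 20.0), (30.0, 15.0))
        assert fs_long == pytest.approx(25.0)
        assert fs_short == pytest.approx(25.0)

    def test_identical_axes_zero(self):
        assert fractional_shortening((40.0, 20.0), (40.0, 20.0)) == (0.0, 0.0)

    def test_negative_fs_returned_not_raised(self):
        fs_long, _ = fractional_shortening((40.0, 20.0), (44.0, 20.0))
        assert fs_long == pytest.approx(-10.0)

    def test_nonpositive_ed_axis_rejected(self):
        with pytest.raises(ValueError):
            fractional_shortening((0.0, 20.0), (30.0, 15.0))


class TestLungHeartRatio:
    def _scene(self):
        frame = np.zeros((10, 10))
        lung = np.zeros((10, 10), bool)
        lv = np.zeros((10, 10), bool)
        lung[1:3, 1:3] = True
        lv[6:9, 6:9] = True
        frame[lung] = 2.0
        frame[lv] = 8.0
        return frame, lung, lv

    def test_ratio(self):
        frame, lung, lv = self._scene()
        assert lung_heart_ratio(frame, lung, lv) == pytest.approx(0.25)

    def test_scale_invariance(self):
        frame, lung, lv = self._scene()
        assert lung_heart_ratio(7.3 * frame, lung, lv) == pytest.approx(0.25)

    def test_overlap_rejected(self):
        frame, lung, lv = self._scene()
        with pytest.raises(ValueError, match="overlap"):
            lung_heart_ratio(frame, lv, lv)


class TestBeatStatistics:
    def test_heart_rate_from_beat_duration(self):
        meta = AcquisitionMeta(n_frames=16, mean_beat_duration=1000.0)
        hr, beat, rej, _ = beat_statistics(meta)
        assert hr == pytest.approx(60.0)

    def test_rejected_fraction(self):
        meta = AcquisitionMeta(
            n_frames=16, heart_rate=60.0, accepted_beats=90, rejected_beats=10
        )
        assert beat_statistics(meta)[2] == pytest.approx(0.10)

    def test_both_absent_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            beat_statistics(AcquisitionMeta(n_frames=16))


class TestTimeActivityCurve:
    def test_linearity_under_count_scaling(self, sync_phantom, default_config):
        from bloodpool import time_activity_curve
        from test_segmentation import run_pipeline_to_segmentation

        cine, truth = sync_phantom
        corr, _, seg = run_pipeline_to_segmentation(cine, truth)
        tac = time_activity_curve(corr, seg)
        scaled = corr.with_frames(corr.frames * 3.0)
        np.testing.assert_allclose(time_activity_curve(scaled, seg), 3.0 * tac)


class TestComputeAll:
    def test_noise_free_ef_recovery(self, sync_params):
        assert 58.0 <= sync_params.lvef <= 62.0

    def test_synchronous_phantom_is_synchronous(self, sync_params):
        assert sync_params.synchrony >= 0.99
        assert sync_params.phase_sd <= 2.0

    def test_invariant_ranges(self, sync_params):
        ps = sync_params
        assert ps.lvef <= 100.0
        assert 0.0 <= ps.synchrony <= 1.0
        assert 0.0 <= ps.e_norm <= 1.0
        assert ps.elong_ed >= 1.0 and ps.elong_es >= 1.0
        assert ps.fs_long <= 100.0 and ps.fs_short <= 100.0
        assert ps.counts_es <= ps.counts_ed
        assert ps.lhr is not None and ps.lhr > 0

    def test_deterministic(self, sync_phantom, sync_params):
        cine, truth = sync_phantom
        again = compute_all(cine, SeedPoint(*truth.lv_center))
        for col in type(sync_params).csv_columns():
            assert getattr(again, col) == getattr(sync_params, col), col

    def test_dyssynchrony_degrades_indices(self):
        results = []
        for delay in (0.0, 45.0, 90.0):
            cfg = PhantomConfig(dyssync_sectors=1, dyssync_delay=delay)
            cine, truth = generate_phantom(cfg)
            results.append(compute_all(cine, SeedPoint(*truth.lv_center)))
        psd = [r.phase_sd for r in results]
        en = [r.e_norm for r in results]
        syn = [r.synchrony for r in results]
        # circular-moment indices are strictly ordered by the delay
        assert psd[0] < psd[1] < psd[2]
        assert syn[0] > syn[1] > syn[2]
        # histogram entropy separates dyssynchrony from synchrony but
        # saturates once the delayed cluster is more than a bin away
        assert en[0] < en[1]
        assert en[0] < en[2]
        assert en[1] > 0.1 and en[2] > 0.1

    def test_provenance_recorded(self, sync_params):
        prov = sync_params.provenance
        assert prov["filter"] == "mmwf" and prov["kernel"] == 5
        assert prov["background_location"] == 1
        assert "tool_version" in prov
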