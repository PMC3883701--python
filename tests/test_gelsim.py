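"""Synthetic generator: forward-model correctness and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from teloquant import gelsim
from teloquant.gelsim import (
    FragmentSizeDistribution,
    MigrationModel,
    TrapLaneSpec,
    make_distribution,
    render_lane,
    render_marker_lane,
    signal_weighted_median_kb,
    simulate_dose_response,
    simulate_growth,
    simulate_trap_lane,
)
from teloquant.trap import quantify_lane


class TestMakeDistribution:
    def test_point_mass_signal_median_is_its_size(self, point_mass_grid):
        dist = point_mass_grid(2200)
        assert signal_weighted_median_kb(dist) == pytest.approx(2.2)

    @pytest.mark.parametrize("target_kb", [2.2, 3.7, 1.8])
    def test_tuned_lognormal_hits_target_median(self, target_kb):
        dist = make_distribution(target_kb)
        assert signal_weighted_median_kb(dist) == pytest.approx(
            target_kb, rel=0.01
        )

    def test_biphasic_tail_places_signal_above_5kb(self):
        dist = make_distribution(2.5, long_fraction=0.1, long_mode_kb=6.0)
        sizes_kb = dist.sizes_bp / 1000.0
        frac_above = dist.signal[sizes_kb > 5.0].sum() / dist.signal.sum()
        assert frac_above > 0.05
        # direct integration of the mixture: the monophasic counterpart has
        # essentially nothing above 5 kb
        mono = make_distribution(2.5, long_fraction=0.0)
        mono_above = mono.signal[mono.sizes_bp / 1000.0 > 5.0].sum() / mono.signal.sum()
        assert frac_above > 10 * mono_above

    def test_unreachable_target_raises_with_bound(self):
        grid = np.arange(1000, 2001, 10)
        with pytest.raises(ValueError, match="outside grid"):
            make_distribution(5.0, grid=grid)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            FragmentSizeDistribution(np.array([200, 150]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="100 bp"):
            FragmentSizeDistribution(np.array([50, 150]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="positive finite"):
            FragmentSizeDistribution(np.array([150, 250]), np.array([0.0, 0.0]))


class TestRenderLane:
    def test_point_mass_peaks_at_model_distance(self, mig, point_mass_grid):
        # d(2 kb) = 60 - 40*log10(2) = 47.9588 mm
        lane = render_lane(point_mass_grid(2000), mig, band_sd_mm=1.0)
        peak = lane.distance_mm[np.argmax(lane.intensity)]
        assert peak == pytest.approx(60 - 40 * np.log10(2.0), abs=0.06)

    def test_baseline_floor_far_from_bands(self, mig, point_mass_grid):
        lane = render_lane(point_mass_grid(2000), mig, band_sd_mm=1.0, baseline=5.0)
        assert lane.intensity[0] == pytest.approx(5.0)
        assert lane.intensity[-1] == pytest.approx(5.0)

    def test_signal_proportional_to_fragment_length(self, mig):
        # equal abundance at 1 kb and 4 kb: integrated signal near the 4 kb
        # band must be 4x that near the 1 kb band (probe binds repeat content)
        dist = FragmentSizeDistribution(
            sizes_bp=np.array([1000, 4000]), abundance=np.array([1.0, 1.0])
        )
        lane = render_lane(dist, mig, band_sd_mm=1.0)
        d, y = lane.distance_mm, lane.intensity
        d1, d4 = mig.distance_mm(1000), mig.distance_mm(4000)
        near = lambda c: np.trapezoid(y[np.abs(d - c) < 6], d[np.abs(d - c) < 6])
        assert near(d4) / near(d1) == pytest.approx(4.0, rel=1e-6)

    def test_noiseless_lane_conserves_total_signal(self, mig):
        dist = make_distribution(2.5)
        lane = render_lane(dist, mig, band_sd_mm=1.5, baseline=2.0)
        integral = np.trapezoid(lane.intensity - 2.0, lane.distance_mm)
        assert integral == pytest.approx(dist.signal.sum(), rel=1e-6)

    def test_seed_reproducibility(self, mig, point_mass_grid):
        a = render_lane(point_mass_grid(2000), mig, noise_sd=3.0, seed=11)
        b = render_lane(point_mass_grid(2000), mig, noise_sd=3.0, seed=11)
        c = render_lane(point_mass_grid(2000), mig, noise_sd=3.0, seed=12)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)


class TestMarkerLane:
    def test_two_point_marker_distances(self, mig):
        _, table = render_marker_lane([10_000, 1_000], mig)
        assert table["distance_mm"].tolist() == pytest.approx([20.0, 60.0])

    def test_single_marker_rejected(self, mig):
        with pytest.raises(ValueError, match="at least 2"):
            render_marker_lane([5_000], mig)

    def test_distances_increase_as_sizes_decrease(self, mig):
        _, table = render_marker_lane(gelsim.DEFAULT_MARKER_SIZES_BP, mig)
        assert (np.diff(table["size_bp"]) < 0).all()
        assert (np.diff(table["distance_mm"]) > 0).all()


class TestTrapLane:
    def test_zero_activity_gives_itas_only(self):
        lane, reg = simulate_trap_lane(TrapLaneSpec(activity=0.0, n_cells=100))
        q = quantify_lane(lane, reg["ladder_mm"], reg["itas_mm"])
        # only the far ITAS Gaussian tail can reach the ladder region
        assert q.activity_ratio < 1e-6
        assert q.itas_signal > 0

    def test_ratio_linear_in_activity(self):
        def ratio(act):
            lane, reg = simulate_trap_lane(TrapLaneSpec(activity=act, n_cells=100))
            return quantify_lane(lane, reg["ladder_mm"], reg["itas_mm"]).activity_ratio

        assert ratio(0.5) / ratio(0.25) == pytest.approx(2.0, rel=1e-9)
        assert ratio(0.23) / ratio(1.0) == pytest.approx(0.23, rel=1e-9)

    def test_itas_independent_of_activity(self):
        lanes = [
            simulate_trap_lane(TrapLaneSpec(activity=a, n_cells=100))
            for a in (0.1, 1.0)
        ]
        qs = [quantify_lane(l, r["ladder_mm"], r["itas_mm"]) for l, r in lanes]
        assert qs[0].itas_signal == pytest.approx(qs[1].itas_signal, rel=1e-9)

    def test_itas_must_sit_below_ladder(self):
        with pytest.raises(ValueError, match="ITAS"):
            TrapLaneSpec(activity=1.0, n_cells=100, itas_size_bp=60)


class TestDoseResponse:
    def test_midpoint_of_sigmoid(self):
        tbl = simulate_dose_response(100.0, floor_D=0.0, doses_nM=[0.0, 100.0])
        pct = 100.0 * tbl.loc[tbl.dose_nM == 100.0, "raw_ratio"].mean() / \
            tbl.loc[tbl.dose_nM == 0.0, "raw_ratio"].mean()
        assert pct == pytest.approx(50.0)

    def test_midpoint_with_floor(self):
        tbl = simulate_dose_response(100.0, floor_D=10.0, doses_nM=[0.0, 100.0])
        pct = 100.0 * tbl.loc[tbl.dose_nM == 100.0, "raw_ratio"].mean() / \
            tbl.loc[tbl.dose_nM == 0.0, "raw_ratio"].mean()
        assert pct == pytest.approx(55.0)

    def test_floor_is_high_dose_asymptote(self):
        tbl = simulate_dose_response(100.0, floor_D=20.0, doses_nM=[0.0, 1e9])
        pct = 100.0 * tbl.loc[tbl.dose_nM == 1e9, "raw_ratio"].mean() / \
            tbl.loc[tbl.dose_nM == 0.0, "raw_ratio"].mean()
        assert pct == pytest.approx(20.0, abs=0.01)

    def test_noiseless_table_lies_on_sigmoid(self):
        tbl = simulate_dose_response(204.0, floor_D=20.0)
        pos = tbl[tbl.dose_nM > 0]
        expected = gelsim.inhibition_sigmoid(pos["dose_nM"], 204.0, 20.0)
        observed = 100.0 * pos["raw_ratio"] / gelsim.UNTREATED_RAW_RATIO
        np.testing.assert_allclose(observed, expected, rtol=1e-12)

    def test_requires_zero_dose_anchor(self):
        with pytest.raises(ValueError, match="include 0"):
            simulate_dose_response(100.0, doses_nM=[50.0, 100.0])

    def test_rejects_nonpositive_ic50(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_dose_response(-5.0)


class TestGrowth:
    def test_no_crisis_constant_doubling(self):
        recs = simulate_growth(3.0, crisis_start_week=99, weeks=10)
        assert sum(r.pd_week for r in recs) == pytest.approx(30.0)

    def test_noiseless_harvest_count(self):
        recs = simulate_growth(3.0, crisis_start_week=99, weeks=1, seeded=300_000)
        assert recs[0].harvested == 2_400_000

    def test_crisis_pd_goes_negative(self):
        recs = simulate_growth(2.0, crisis_start_week=3, decline_per_week=2.0,
                               weeks=6)
        pds = [r.pd_week for r in recs]
        assert pds[0] == pytest.approx(2.0)
        assert pds[-1] < 0

    def test_seed_reproducibility(self):
        a = simulate_growth(3.0, 5, 1.0, 10, seed=3, noise_cv=0.1)
        b = simulate_growth(3.0, 5, 1.0, 10, seed=3, noise_cv=0.1)
        assert [r.harvested for r in a] == [r.harvested for r in b]
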