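"""Replicate averaging, 0-10 scaling, paired t-test, subtraction heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ttest_rel

from thromboflow.stats import (
    PARAM_COLS,
    AlignmentError,
    MissingCellError,
    assemble_report,
    average_replicates,
    benjamini_hochberg,
    null_type_i_fraction,
    paired_t_test,
    records_to_frame,
    scale_parameters,
    subtraction_heatmap,
    univariate_scale,
)


def make_frame(n_donors=3, replicates=2, presets=(("vehicle", "none"),),
               surfaces=("collagen_TF",), timepoints=(2.0, 10.0), seed=0):
    """Synthetic tidy parameter table (no imaging, direct values)."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_donors):
        donor_effect = rng.lognormal(0, 0.1)
        for preset, switch in presets:
            effect = 0.5 if preset != "vehicle" else 1.0
            for s in surfaces:
                for t in timepoints:
                    for r in range(replicates):
                        base = donor_effect * effect * (5 + t)
                        rows.append({
                            "donor": f"D{d}", "replicate": f"r{r}",
                            "surface": s, "preset": preset,
                            "switch_time": switch, "timepoint": t,
                            **{p: base * (i + 1) + rng.normal(0, 0.2)
                               for i, p in enumerate(PARAM_COLS)},
                        })
    return pd.DataFrame(rows)


class TestAverageReplicates:
    @pytest.mark.parametrize("values, expected", [
        ((10.0, 20.0), 15.0),
        ((7.0,), 7.0),
        ((1.0, 2.0, 6.0), 3.0),
    ])
    def test_arithmetic_mean(self, values, expected):
        rows = [{"donor": "D1", "replicate": f"r{i}", "surface": "collagen",
                 "preset": "vehicle", "switch_time": "none", "timepoint": 2.0,
                 **{p: v for p in PARAM_COLS}}
                for i, v in enumerate(values)]
        out = average_replicates(pd.DataFrame(rows))
        assert len(out) == 1
        assert out["P1"].iloc[0] == pytest.approx(expected)

    def test_missing_required_cell(self):
        df = make_frame()
        required = df[df.columns].copy()
        required.loc[len(required)] = {
            "donor": "D99", "replicate": "r0", "surface": "collagen_TF",
            "preset": "vehicle", "switch_time": "none", "timepoint": 2.0,
            **{p: 0.0 for p in PARAM_COLS}}
        with pytest.raises(MissingCellError, match="D99"):
            average_replicates(df, required_cells=required)


class TestUnivariateScale:
    def test_affine_endpoints(self):
        np.testing.assert_allclose(univariate_scale([2, 4, 6]), [0, 5, 10])

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out = univariate_scale([7, 7, 7])
        np.testing.assert_array_equal(out, [0, 0, 0])

    def test_empty_series(self):
        with pytest.raises(ValueError):
            univariate_scale([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
    def test_matches_direct_formula(self, values):
        x = np.array(values)
        if x.max() == x.min():
            return
        expected = (x - x.min()) * 10.0 / (x.max() - x.min())
        np.testing.assert_allclose(univariate_scale(x), expected, atol=1e-12)

    def test_idempotent(self):
        x = np.array([3.0, 1.0, 8.0, 5.0])
        once = univariate_scale(x)
        np.testing.assert_allclose(univariate_scale(once), once, atol=1e-12)

    def test_strictly_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        out = univariate_scale(x)
        assert np.all(np.diff(out) > 0)

    def test_scale_parameters_covers_full_range(self):
        scaled, bounds = scale_parameters(
            average_replicates(make_frame(timepoints=(2.0, 6.0, 10.0))))
        for p in PARAM_COLS:
            assert scaled[p].min() == 0.0
            assert scaled[p].max() == 10.0
        assert set(bounds["parameter"]) == set(PARAM_COLS)


class TestPairedTTest:
    def test_identical_samples(self):
        t, df, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_unit_differences(self):
        """d = [1..5]: t = 3/(sqrt(2.5)/sqrt(5)) = 4.2426..., p ~ 0.0132."""
        control = np.zeros(5)
        treated = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, df, p = paired_t_test(control, treated)
        assert t == pytest.approx(4.242640687, abs=1e-8)
        assert df == 4
        assert p == pytest.approx(0.0132, abs=2e-4)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            paired_t_test([1.0], [2.0])

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, _, p = paired_t_test([0.0, 0.0], [1.0, 1.0])
        assert p == 0.0 and np.isinf(t)

    def test_matches_scipy_reference(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 11))
            c, tr = rng.normal(size=n), rng.normal(size=n)
            t, _, p = paired_t_test(c, tr)
            ref = ttest_rel(tr, c)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_vectorised_axis(self, rng):
        c = rng.normal(size=(4, 7, 6))
        tr = rng.normal(size=(4, 7, 6))
        t, df, p = paired_t_test(c, tr, axis=1)
        assert t.shape == p.shape == (4, 6)
        ref = ttest_rel(tr, c, axis=1)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-10)


class TestSubtractionHeatmap:
    def grid(self, values):
        cols = pd.MultiIndex.from_product(
            [["collagen_TF"], [2.0, 10.0]], names=["surface", "timepoint"])
        return pd.DataFrame(values, index=PARAM_COLS[:2], columns=cols)

    def test_self_subtraction_is_zero(self):
        g = self.grid([[1.0, 2.0], [3.0, 4.0]])
        p = self.grid([[0.01, 0.5], [0.9, 0.001]])
        hm = subtraction_heatmap(g, g, p, filtered=False)
        assert (hm.display == 0).all().all()
        hm_f = subtraction_heatmap(g, g, p, filtered=True)
        assert (hm_f.display == 0).all().all()

    def test_filter_zeroes_non_significant(self):
        treated = self.grid([[0.0, 0.0], [0.0, 0.0]])
        ref = self.grid([[4.2, 4.2], [0.0, 0.0]])
        p = self.grid([[0.20, 0.01], [0.5, 0.5]])
        hm = subtraction_heatmap(treated, ref, p, alpha=0.05, filtered=True)
        assert hm.display.iloc[0, 0] == 0.0         # p = 0.20: filtered out
        assert hm.display.iloc[0, 1] == pytest.approx(-4.2)  # p = 0.01: kept
        assert hm.delta.iloc[0, 0] == pytest.approx(-4.2)    # raw retained

    def test_misaligned_grids_rejected(self):
        g = self.grid([[1.0, 2.0], [3.0, 4.0]])
        other = g.copy()
        other.index = ["P6", "P7"]
        with pytest.raises(AlignmentError):
            subtraction_heatmap(g, other, g)

    def test_benjamini_hochberg_monotone(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= 0)


class TestAssembleReport:
    def test_vehicle_only_has_no_subtraction_maps(self, tmp_path):
        report = assemble_report(make_frame(), tmp_path, make_figures=False)
        assert report.heatmaps == []
        assert (tmp_path / "scaled.csv").exists()

    def test_one_map_per_treated_condition(self, tmp_path):
        presets = [("vehicle", "none")] + \
            [(p, s) for p in ("iFVIIa", "PAR1_4", "tirofiban")
             for s in ("0", "2")]
        df = make_frame(presets=presets)
        report = assemble_report(df, tmp_path, make_figures=False)
        assert len(report.heatmaps) == 6
        names = {(h.preset, h.switch_time) for h in report.heatmaps}
        assert ("vehicle", "none") not in names

    def test_filtered_cells_respect_alpha(self, tmp_path):
        df = make_frame(n_donors=4,
                        presets=[("vehicle", "none"), ("tirofiban", "0")])
        report = assemble_report(df, tmp_path, alpha=0.05, make_figures=False)
        hm = report.heatmaps[0]
        disp = hm.display.to_numpy()
        pv = hm.p_values.to_numpy()
        assert np.all(disp[pv >= 0.05] == 0.0)
        assert np.all(np.abs(disp) <= 10.0 + 1e-12)

    def test_missing_reference_condition(self, tmp_path):
        df = make_frame(presets=[("tirofiban", "0")])
        with pytest.raises(AlignmentError, match="reference"):
            assemble_report(df, tmp_path, make_figures=False)

    def test_csv_round_trip_is_stable(self, tmp_path):
        df = make_frame(presets=[("vehicle", "none"), ("PAR1_4", "2")])
        assemble_report(df, tmp_path / "a", make_figures=False)
        assemble_report(df, tmp_path / "b", make_figures=False)
        for name in ("scaled.csv", "delta_PAR1_4_2.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()


class TestRecordsToFrame:
    def test_round_trip(self):
        from thromboflow.params import ParameterRecord
        rec = ParameterRecord(
            donor="D1", replicate="r1", surface="collagen",
            preset="vehicle", switch_time="none", timepoint=4.0,
            p1_platelet_sac=12.0, p2_thrombus_sac=8.0, p3_morphology=3,
            p4_contraction=1, p5_multilayer=2, p6_ps_sac=1.5,
            p7_fibrin_sac=0.0)
        frame = records_to_frame([rec])
        assert frame.loc[0, "P3"] == 3.0
        assert frame.loc[0, "timepoint"] == 4.0


class TestNullCalibration:
    def test_type_i_error_near_alpha(self):
        frac = null_type_i_fraction(n_cohorts=300, n_donors=5, seed=42)
        assert 0.02 <= frac <= 0.08  # quick check; the full one runs 2000
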