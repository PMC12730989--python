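"""Network construction: residualization, group covariance, the
ESD -> R -> W -> individual-SCN chain, and functional networks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import pearson_hand, tanh_exponential_form
from scnkit import (
    build_functional_network,
    build_group_covariance,
    build_individual_scn,
    binarize_proportional,
    compute_esd,
    residualize_morphometry,
    weight_from_esd,
)
from scnkit.netbuild import FISHER_R_CAP
from scnkit.types import BaselineReference, MorphometryRecord, TimeSeriesRecord


def _records(gmv_matrix, tivs, timepoint=0.0):
    return [
        MorphometryRecord(
            subject_id=f"M{i:02d}", group="sci_only", timepoint=timepoint,
            gmv=np.asarray(row, dtype=float), tiv=float(t),
        )
        for i, (row, t) in enumerate(zip(gmv_matrix, tivs))
    ]


def _reference(n_roi=3, mean=0.0, sd=1.0, scn=None):
    if scn is None:
        scn = np.eye(n_roi)
    return BaselineReference(
        mean=np.full(n_roi, float(mean)), sd=np.full(n_roi, float(sd)), scn_hc=scn
    )


class TestResidualize:
    def test_residual_means_are_exactly_zero(self):
        rng = np.random.default_rng(0)
        gmv = np.tile(rng.normal(100, 5, 4), (6, 1))  # identical GMV across subjects
        recs = _records(gmv, tivs=rng.normal(90, 5, 6))
        resid, _ = residualize_morphometry(recs)
        assert np.allclose(resid.to_numpy().mean(axis=0), 0.0, atol=1e-10)

    def test_null_tiv_slope_estimated_near_zero(self):
        """GMV independent of TIV: fitted slope within 3 SE of zero."""
        rng = np.random.default_rng(1)
        n = 200
        tiv = rng.normal(90, 8, n)
        gmv = rng.normal(100, 5, (n, 3))  # no TIV dependence planted
        _, model = residualize_morphometry(_records(gmv, tiv))
        se = 5.0 / (np.sqrt(n) * tiv.std(ddof=1))
        assert np.all(np.abs(model.slopes) < 3 * se)

    def test_planted_tiv_slope_recovered(self):
        rng = np.random.default_rng(2)
        tiv = rng.normal(90, 8, 300)
        gmv = 50 + 0.7 * tiv[:, None] + rng.normal(0, 0.5, (300, 2))
        _, model = residualize_morphometry(_records(gmv, tiv))
        assert np.allclose(model.slopes, 0.7, atol=0.05)

    def test_too_few_subjects_rejected(self):
        recs = _records(np.ones((2, 3)) * 100, [90.0, 95.0])
        with pytest.raises(ValueError, match=">= 3"):
            residualize_morphometry(recs)

    def test_constant_tiv_rejected(self):
        recs = _records(np.random.default_rng(3).normal(100, 5, (5, 3)), [90.0] * 5)
        with pytest.raises(ValueError, match="constant"):
            residualize_morphometry(recs)


class TestGroupCovariance:
    def test_matches_hand_computed_pearson(self):
        rng = np.random.default_rng(4)
        gmv = rng.normal(100, 5, (3, 2))
        tiv = rng.normal(90, 5, 3)
        recs = _records(gmv, tiv)
        resid, _ = residualize_morphometry(recs)
        conn, ref = build_group_covariance(resid, recs)
        r_hand = pearson_hand(resid.iloc[:, 0], resid.iloc[:, 1])
        assert abs(ref.scn_hc[0, 1] - r_hand) < 1e-12

    def test_identical_residual_columns_give_unit_correlation(self):
        rng = np.random.default_rng(5)
        tiv = rng.normal(90, 5, 5)
        base = rng.normal(0, 3, 5)
        gmv = np.column_stack([100 + base, 200 + base, rng.normal(100, 5, 5)])
        recs = _records(gmv, tiv)
        resid, _ = residualize_morphometry(recs)
        _, ref = build_group_covariance(resid, recs)
        assert ref.scn_hc[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_residuals_give_small_correlations(self):
        rng = np.random.default_rng(6)
        gmv = rng.normal(100, 5, (500, 4))
        recs = _records(gmv, rng.normal(90, 5, 500))
        resid, _ = residualize_morphometry(recs)
        _, ref = build_group_covariance(resid, recs)
        off = ref.scn_hc[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_zero_variance_roi_named_in_error(self):
        import pandas as pd

        resid = pd.DataFrame({"roi_1": [1.0, -1.0, 0.0], "roi_2": [0.0, 0.0, 0.0]})
        recs = _records(np.random.default_rng(7).normal(100, 5, (3, 2)),
                        [90.0, 92.0, 95.0])
        with pytest.raises(ValueError, match="roi_2"):
            build_group_covariance(resid, recs)


class TestEsdChain:
    def test_subject_at_healthy_mean_gives_zero_esd(self):
        ref = _reference(4, mean=100.0, sd=10.0)
        rec = MorphometryRecord("M00", "sci_only", 0.0, np.full(4, 100.0), 90.0)
        assert np.all(compute_esd(rec, ref) == 0.0)

    def test_equal_deviations_cancel(self):
        ref = _reference(4, mean=100.0, sd=10.0)
        rec = MorphometryRecord("M00", "sci_only", 0.0, np.full(4, 107.0), 90.0)
        assert np.all(compute_esd(rec, ref) == 0.0)

    def test_unit_deviation_with_unit_sds(self):
        ref = _reference(2, mean=0.0, sd=1.0)
        rec = MorphometryRecord("M00", "sci_only", 0.0, np.array([1.0, 0.0]), 90.0)
        esd = compute_esd(rec, ref)
        assert esd[0, 1] == pytest.approx(1.0, abs=1e-15)
        assert esd[1, 0] == esd[0, 1]
        assert np.all(np.diag(esd) == 0.0)

    def test_length_mismatch_rejected(self):
        ref = _reference(3)
        rec = MorphometryRecord("M00", "sci_only", 0.0, np.zeros(4), 90.0)
        with pytest.raises(ValueError, match="match"):
            compute_esd(rec, ref)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=30.0))
    def test_r_equals_exponential_form(self, esd_val):
        """R must agree with (e^{2x}-1)/(e^{2x}+1) to 1e-12."""
        esd = np.array([[0.0, esd_val], [esd_val, 0.0]])
        w = weight_from_esd(esd)
        assert abs(w.r[0, 1] - tanh_exponential_form(esd_val)) < 1e-12

    def test_known_values(self):
        esd = np.array([[0.0, 1.0], [1.0, 0.0]])
        w = weight_from_esd(esd)
        assert w.r[0, 1] == pytest.approx(0.7615941559557649, abs=1e-12)
        assert w.w[0, 1] == pytest.approx(1.0 - 0.7615941559557649, abs=1e-12)

    def test_zero_esd_gives_unit_weight(self):
        w = weight_from_esd(np.zeros((3, 3)))
        assert np.all(w.r == 0.0)
        assert np.all(w.w == 1.0)

    def test_saturation_keeps_weight_positive(self):
        esd = np.array([[0.0, 20.0], [20.0, 0.0]])
        w = weight_from_esd(esd)
        assert 0.0 < w.w[0, 1] < 1e-8

    def test_negative_esd_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            weight_from_esd(np.array([[0.0, -0.1], [-0.1, 0.0]]))

    def test_growing_deviation_never_increases_row_weights(self):
        """Monotonicity: with the other regions at their healthy means,
        pushing one region further from its mean cannot strengthen that
        region's weights (its pairwise effect sizes only grow)."""
        ref = _reference(5, mean=100.0, sd=10.0)
        prev = None
        for bump in np.linspace(0.0, 50.0, 11):
            gmv = np.full(5, 100.0)
            gmv[2] += bump
            rec = MorphometryRecord("M00", "sci_only", 0.0, gmv, 90.0)
            w = weight_from_esd(compute_esd(rec, ref)).w
            if prev is not None:
                assert np.all(w[2] <= prev[2] + 1e-12)
            prev = w


class TestIndividualScn:
    def test_healthy_mean_recovers_group_network(self):
        rng = np.random.default_rng(9)
        scn = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-0.8, 0.8, (4, 4))), -1, 1)
        np.fill_diagonal(scn, 1.0)
        ref = _reference(4, mean=100.0, sd=10.0, scn=scn)
        rec = MorphometryRecord("M00", "sci_only", 0.0, np.full(4, 100.0), 90.0)
        m = build_individual_scn(weight_from_esd(compute_esd(rec, ref)), ref)
        expected = scn.copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(m.values, expected)

    def test_two_roi_product(self):
        scn = np.array([[1.0, 0.8], [0.8, 1.0]])
        ref = _reference(2, scn=scn)
        w = weight_from_esd(np.array([[0.0, np.arctanh(0.5)], [np.arctanh(0.5), 0.0]]))
        assert w.w[0, 1] == pytest.approx(0.5, abs=1e-12)
        m = build_individual_scn(w, ref)
        assert m.values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_bound_by_group_network(self):
        rng = np.random.default_rng(10)
        scn = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (5, 5))), -1, 1)
        np.fill_diagonal(scn, 1.0)
        ref = _reference(5, mean=100.0, sd=10.0, scn=scn)
        rec = MorphometryRecord("M00", "sci_only", 0.0, rng.normal(100, 15, 5), 90.0)
        m = build_individual_scn(weight_from_esd(compute_esd(rec, ref)), ref)
        off = ~np.eye(5, dtype=bool)
        assert np.all(np.abs(m.values[off]) <= np.abs(scn[off]) + 1e-15)

    def test_shape_mismatch_rejected(self):
        ref = _reference(3)
        w = weight_from_esd(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            build_individual_scn(w, ref)


class TestFunctionalNetwork:
    def _record(self, series):
        return TimeSeriesRecord("M00", 0.0, np.asarray(series, dtype=float))

    def test_perfect_correlation_capped(self, rng):
        x = rng.standard_normal(60)
        series = np.column_stack([x, x, rng.standard_normal(60)])
        net = build_functional_network(self._record(series))
        assert net.values[0, 1] == pytest.approx(np.arctanh(FISHER_R_CAP))

    def test_negative_correlation_masked(self, rng):
        x = rng.standard_normal(60)
        series = np.column_stack([x, -x, rng.standard_normal(60)])
        net = build_functional_network(self._record(series))
        assert net.values[0, 1] == 0.0

    def test_independent_columns_stay_weak(self, rng):
        series = rng.standard_normal((5000, 6))
        net = build_functional_network(self._record(series))
        off = net.values[~np.eye(6, dtype=bool)]
        assert np.mean(off < np.arctanh(0.05)) >= 0.95

    def test_zero_variance_column_named(self, rng):
        series = rng.standard_normal((60, 3))
        series[:, 1] = 5.0
        with pytest.raises(ValueError, match="roi_2"):
            build_functional_network(self._record(series))

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 30"):
            build_functional_network(self._record(rng.standard_normal((20, 3))))

    def test_threshold_invariant_to_fisher_transform(self, rng):
        """Fisher z is monotone on (0,1): binary graphs from r and from z
        are identical at any proportional threshold."""
        series = rng.standard_normal((80, 10)) + 0.5 * rng.standard_normal((80, 1))
        r = np.corrcoef(series, rowvar=False)
        r_pos = np.where(r > 0, r, 0.0)
        np.fill_diagonal(r_pos, 0.0)
        net = build_functional_network(self._record(series))
        for s in (0.1, 0.25, 0.5):
            g_r = binarize_proportional(r_pos, s)
            g_z = binarize_proportional(net.values, s)
            assert np.array_equal(g_r.adjacency, g_z.adjacency)
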