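import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from latemix.preprocess import (SdClassBinner, TrainingScaler, apply_scaler,
                                assign_sd_classes, filter_transcripts,
                                fit_scaler, residualize_targets,
                                select_features_by_list, verify_provenance)


def _cov(n, rng):
    return pd.DataFrame({"age": rng.normal(42, 5, n),
                         "sex": (rng.random(n) < 0.5).astype(float),
                         "bmi": rng.normal(26, 4, n)})


def _targets_frame(values: dict, n) -> pd.DataFrame:
    cols = ["sbp", "dbp", "e_over_eprime", "e_over_a", "lavi"]
    out = {c: values.get(c, np.zeros(n)) for c in cols}
    return pd.DataFrame(out)


class TestResidualize:
    def test_independent_target_nearly_unchanged(self):
        rng = np.random.default_rng(0)
        n = 1000
        cov = _cov(n, rng)
        y = rng.standard_normal(n)
        targets = _targets_frame({"sbp": y, "dbp": rng.standard_normal(n),
                                  "e_over_eprime": rng.standard_normal(n),
                                  "e_over_a": rng.standard_normal(n),
                                  "lavi": rng.standard_normal(n)}, n)
        adj = residualize_targets(targets, cov, np.ones(n, dtype=bool))
        assert np.corrcoef(adj.values["sbp"], y)[0, 1] > 0.99

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(1)
        n = 200
        cov = _cov(n, rng)
        targets = _targets_frame(
            {c: 2 * cov.age + rng.standard_normal(n) * 3
             for c in ("sbp", "dbp", "e_over_eprime", "e_over_a", "lavi")}, n)
        train = np.zeros(n, dtype=bool)
        train[:120] = True
        adj = residualize_targets(targets, cov, train)
        tr = adj.values[train]
        assert np.abs(tr.mean()).max() < 1e-8
        assert np.abs(tr.std(ddof=1) - 1).max() < 1e-8

    def test_exactly_collinear_target_raises(self):
        rng = np.random.default_rng(2)
        n = 50
        cov = _cov(n, rng)
        targets = _targets_frame({"sbp": 2 * cov.age.to_numpy()}, n)
        targets["dbp"] = rng.standard_normal(n)
        with pytest.raises(ValueError, match="degenerate"):
            residualize_targets(targets, cov, np.ones(n, dtype=bool))

    def test_matches_normal_equations_oracle(self):
        # tiny fit checked against the closed-form OLS solution
        age = np.linspace(30.0, 75.0, 10)
        y = np.arange(1.0, 11.0)
        y[-1] += 1.0   # last point off the line
        cov = pd.DataFrame({"age": age, "sex": np.zeros(10), "bmi": np.zeros(10)})
        targets = _targets_frame({"sbp": y, "dbp": y + 1, "e_over_eprime": y,
                                  "e_over_a": y, "lavi": y}, 10)
        X = np.column_stack([np.ones(10), age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        expected = (resid - resid.mean()) / resid.std(ddof=1)
        # sex and bmi are constant zeros, so their lstsq coefficients vanish
        # and the residuals equal the age-only normal-equation solution
        adj = residualize_targets(targets, cov, np.ones(10, dtype=bool))
        np.testing.assert_allclose(adj.values["sbp"], expected, atol=1e-10)

    def test_provenance_audit(self):
        rng = np.random.default_rng(3)
        n = 60
        cov = _cov(n, rng)
        targets = _targets_frame(
            {c: rng.standard_normal(n)
             for c in ("sbp", "dbp", "e_over_eprime", "e_over_a", "lavi")}, n)
        train = np.arange(n) < 40
        adj = residualize_targets(targets, cov, train)
        assert verify_provenance(adj, targets.index, train)
        with pytest.raises(AssertionError, match="provenance"):
            verify_provenance(adj, targets.index, ~train)


class TestFilterTranscripts:
    def _adjusted(self, n, rng):
        cov = _cov(n, rng)
        targets = _targets_frame(
            {c: rng.standard_normal(n)
             for c in ("sbp", "dbp", "e_over_eprime", "e_over_a", "lavi")}, n)
        return residualize_targets(targets, cov, np.ones(n, dtype=bool))

    def test_perfect_bp_correlate_retained(self):
        rng = np.random.default_rng(4)
        n = 200
        adj = self._adjusted(n, rng)
        block = pd.DataFrame({
            "hit": adj.values["sbp"].to_numpy() + 1e-6 * rng.standard_normal(n),
            "flat": np.ones(n),
            "noise": rng.standard_normal(n)})
        mask = filter_transcripts(block, adj, np.ones(n, dtype=bool))
        assert bool(mask.retained[0]) and mask.reasons[0] == "bp_corr"
        assert not mask.retained[1] and mask.reasons[1] == "zero_variance"

    def test_planted_effects_recovered_and_null_rate_matches_oracle(self):
        rng = np.random.default_rng(5)
        n = 1000
        adj = self._adjusted(n, rng)
        sbp = adj.values["sbp"].to_numpy()
        n_feat, n_hit = 100, 10
        X = rng.standard_normal((n, n_feat))
        # plant r ~ 0.3 on the first 10 features
        X[:, :n_hit] = 0.31 * sbp[:, None] + np.sqrt(1 - 0.31 ** 2) * X[:, :n_hit]
        block = pd.DataFrame(X, columns=[f"f{j}" for j in range(n_feat)])
        mask = filter_transcripts(block, adj, np.ones(n, dtype=bool))
        assert mask.retained[:n_hit].all()
        # null false-retention rate vs scipy.stats.pearsonr oracle
        oracle = np.zeros(n_feat, dtype=bool)
        A = adj.values
        for j in range(n_feat):
            ps = [stats.pearsonr(X[:, j], A[t]).pvalue
                  for t in ("sbp", "dbp")]
            lv = [stats.pearsonr(X[:, j], A[t]).pvalue
                  for t in ("e_over_eprime", "e_over_a", "lavi")]
            oracle[j] = (min(ps) < 0.05) or (min(lv) < 0.05
                                             and X[:, j].var(ddof=1) > 0.01)
        np.testing.assert_array_equal(mask.retained, oracle)

    def test_mask_invariant_to_affine_feature_maps(self):
        rng = np.random.default_rng(6)
        n = 300
        adj = self._adjusted(n, rng)
        X = rng.standard_normal((n, 20))
        block = pd.DataFrame(X, columns=[f"f{j}" for j in range(20)])
        # variance threshold applies to the LVDD route, so scale up only
        scaled = pd.DataFrame(5.0 * X + 3.0, columns=block.columns)
        m1 = filter_transcripts(block, adj, np.ones(n, dtype=bool), var_thresh=0)
        m2 = filter_transcripts(scaled, adj, np.ones(n, dtype=bool), var_thresh=0)
        np.testing.assert_array_equal(m1.retained, m2.retained)


class TestSelectByList:
    def _block(self, ids):
        rng = np.random.default_rng(7)
        return pd.DataFrame(rng.standard_normal((5, len(ids))), columns=ids)

    def test_full_panel_retained(self):
        ids = [f"cg{i:03d}" for i in range(75)]
        mask = select_features_by_list(self._block(ids), ids)
        assert mask.n_retained == 75

    def test_partial_overlap_warns(self):
        block = self._block(["a", "b", "c"])
        with pytest.warns(UserWarning, match="not in block"):
            mask = select_features_by_list(block, ["a", "b", "zzz"])
        assert mask.n_retained == 2

    def test_disjoint_list_raises(self):
        with pytest.raises(ValueError, match="none of the supplied"):
            select_features_by_list(self._block(["a", "b"]), ["x", "y"])


class TestScaling:
    def test_minmax_maps_training_to_unit_interval(self):
        block = pd.DataFrame({"u": [2.0, 4.0, 6.0]})
        stats_ = fit_scaler(block, np.ones(3, dtype=bool), "minmax")
        np.testing.assert_allclose(apply_scaler(block, stats_)["u"],
                                   [0.0, 0.5, 1.0])

    def test_test_values_extrapolate_unclipped(self):
        train = pd.DataFrame({"u": [2.0, 4.0, 6.0]})
        stats_ = fit_scaler(train, np.ones(3, dtype=bool), "minmax")
        out = apply_scaler(pd.DataFrame({"u": [8.0]}), stats_)
        assert out["u"].iloc[0] == pytest.approx(1.5)

    def test_zscore_uses_sample_sd(self):
        block = pd.DataFrame({"u": [1.0, 2.0, 3.0]})
        stats_ = fit_scaler(block, np.ones(3, dtype=bool), "zscore")
        np.testing.assert_allclose(apply_scaler(block, stats_)["u"], [-1, 0, 1])

    def test_degenerate_feature_named_in_error(self):
        block = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            TrainingScaler("minmax").fit(block)
        with pytest.raises(ValueError, match="flat"):
            TrainingScaler("zscore").fit(block)


class TestSdClasses:
    def test_label_rule_and_boundaries(self):
        binner = SdClassBinner().fit(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
        mu, sd = binner.mean_, binner.sd_
        y = np.array([mu, mu + 1.5 * sd, mu - 1.5 * sd, mu + sd, mu - sd])
        np.testing.assert_array_equal(binner.transform(y), [0, 1, -1, 0, 0])

    def test_normal_mid_class_fraction(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(50_000)
        binner = SdClassBinner().fit(y)
        frac = np.mean(binner.transform(y) == 0)
        assert abs(frac - 0.6827) < 0.01

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(200)
        base = SdClassBinner().fit(y).transform(y)
        mapped = SdClassBinner().fit(a * y + b).transform(a * y + b)
        np.testing.assert_array_equal(base, mapped)

    def test_assign_sd_classes_uses_training_stats_only(self, small_cohort,
                                                        train_mask):
        classes = assign_sd_classes(small_cohort.targets, train_mask)
        y = small_cohort.targets["sbp"].to_numpy()[train_mask]
        assert classes.train_mean["sbp"] == pytest.approx(y.mean())
        assert classes.train_sd["sbp"] == pytest.approx(y.std(ddof=1))
        assert verify_provenance(classes, small_cohort.sample_ids, train_mask)
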