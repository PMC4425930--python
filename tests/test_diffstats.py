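"""Differential statistics: PCA, two-way ANOVA, fold-changes, shift pairs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wcms.diffstats import (
    PTM_DELTA_DA,
    condition_contrast_sets,
    find_shift_pairs,
    fold_change,
    pca_correlation,
    select_biomarkers,
    two_way_anova_per_feature,
)
from wcms.evaluate import match_within, pc1_separation
from wcms.peakmatrix import FeatureMatrix


def _design_samples(n_donors=4, populations=("pan", "cd16"), conditions=("resting", "lps", "ppd")):
    rows = [
        (f"d{d}", p, c)
        for d in range(n_donors)
        for p in populations
        for c in conditions
    ]
    return pd.DataFrame(rows, columns=["donor", "population", "condition"])


def _matrix(values, samples=None, mz=None):
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = _design_samples()
    if mz is None:
        mz = 3000.0 + 100.0 * np.arange(values.shape[1])
    return FeatureMatrix(mz, samples, values, np.ones_like(values, dtype=int))


class TestPCA:
    def test_variance_fractions_sorted_and_bounded(self, rng):
        m = _matrix(np.abs(rng.random((24, 10))))
        pca = pca_correlation(m)
        v = pca.variance_explained
        assert np.all(v[:-1] >= v[1:] - 1e-12)
        assert np.all((v >= 0) & (v <= 1))
        assert v.sum() <= 1 + 1e-9

    def test_two_perfectly_correlated_features(self, rng):
        base = np.abs(rng.random(24)) + 0.1
        m = _matrix(np.c_[base, 2 * base])
        pca = pca_correlation(m)
        assert pca.variance_explained[0] == pytest.approx(1.0)

    def test_matches_correlation_eigendecomposition_oracle(self, rng):
        X = np.abs(rng.random((6, 5))) + 0.05
        samples = _design_samples(1)[:6]
        pca = pca_correlation(_matrix(X, samples))
        corr = np.corrcoef(X, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(pca.variance_explained * 5, eigvals[: pca.scores.shape[1]],
                           atol=1e-8)
        # scores reproduce projections of the standardized data
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        G = pca.scores.T @ pca.scores
        assert np.allclose(G, np.diag(np.diag(G)), atol=1e-8)  # orthogonal scores
        assert np.allclose(np.diag(G), eigvals[: G.shape[0]] * 5, atol=1e-8)

    def test_zero_variance_features_dropped(self, rng):
        X = np.abs(rng.random((24, 4)))
        X[:, 2] = 3.14
        pca = pca_correlation(_matrix(X))
        assert pca.feature_mz.size == 3

    def test_deterministic_sign_convention(self, rng):
        X = np.abs(rng.random((24, 6)))
        p1 = pca_correlation(_matrix(X))
        p2 = pca_correlation(_matrix(X))
        assert np.array_equal(p1.scores, p2.scores)
        for j in range(p1.loadings.shape[1]):
            assert p1.loadings[np.argmax(np.abs(p1.loadings[:, j])), j] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_correlation(_matrix(np.ones((1, 3)), _design_samples(1)[:1]))


class TestAnova:
    def _toy(self):
        """2x2 with two replicates: A1B1={1,2} A1B2={3,4} A2B1={5,6} A2B2={7,8}."""
        samples = pd.DataFrame(
            {
                "donor": [f"r{i}" for i in range(8)],
                "population": ["A1"] * 4 + ["A2"] * 4,
                "condition": ["B1", "B1", "B2", "B2"] * 2,
            }
        )
        values = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0], [7.0], [8.0]])
        return _matrix(values, samples)

    def test_hand_computed_sums_of_squares(self):
        """Closed forms: SS_A=32, SS_B=8, SS_AB=0, SS_E=2 -> F=64, 16, 0."""
        res = two_way_anova_per_feature(self._toy())
        row = res.effects.iloc[0]
        assert row["F_population"] == pytest.approx(64.0)
        assert row["F_condition"] == pytest.approx(16.0)
        assert row["F_interaction"] == pytest.approx(0.0, abs=1e-9)
        assert res.df_resid == 4
        # post-test: diff -4 with SE sqrt(0.5 * 2/2) -> t = -5.657, k = 2
        c = res.contrasts
        assert np.allclose(c["estimate"], -4.0)
        assert np.allclose(c["t"], -4.0 / np.sqrt(0.5))
        assert np.allclose(c["p_adj"], np.minimum(1.0, 2 * c["p_raw"]))

    def test_all_equal_observations_degenerate_convention(self):
        m = self._toy()
        m.values[:] = 3.0
        res = two_way_anova_per_feature(m)
        assert res.effects["F_population"].iloc[0] == 0.0
        assert res.effects["p_population"].iloc[0] == 1.0
        assert (res.contrasts["p_adj"] == 1.0).all()

    def test_bonferroni_adjustment_definition(self, rng):
        m = _matrix(np.abs(rng.random((24, 7))) + 0.1)
        res = two_way_anova_per_feature(m, contrast_family="a_within_b")
        k = res.contrasts["contrast"].nunique()
        assert k == 3  # one population pair within each of 3 conditions
        assert np.allclose(
            res.contrasts["p_adj"],
            np.minimum(1.0, k * res.contrasts["p_raw"]),
        )
        assert (res.contrasts["p_adj"] >= res.contrasts["p_raw"] - 1e-15).all()

    def test_unbalanced_design_falls_back_to_least_squares(self, rng):
        samples = _design_samples(2)
        X = np.abs(rng.random((len(samples), 2))) + 0.1
        m = _matrix(X, samples)
        sub = m.subset_samples(np.arange(len(samples)) != 0)  # drop one obs
        res = two_way_anova_per_feature(sub)
        # oracle: statsmodels type-II ANOVA per feature
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        for j in range(2):
            df = pd.DataFrame(
                {
                    "y": sub.values[:, j],
                    "A": sub.samples["population"],
                    "B": sub.samples["condition"],
                }
            )
            tbl = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", df).fit(), typ=2)
            assert res.effects[f"F_population"].iloc[j] == pytest.approx(
                tbl.loc["C(A)", "F"], rel=1e-8
            )
            assert res.effects[f"F_condition"].iloc[j] == pytest.approx(
                tbl.loc["C(B)", "F"], rel=1e-8
            )

    def test_single_level_factor_rejected(self):
        samples = _design_samples(2, populations=("pan",))
        with pytest.raises(ValueError):
            two_way_anova_per_feature(_matrix(np.ones((len(samples), 1)), samples))

    def test_null_type_one_error_calibrated(self, rng):
        """No planted effects: factor-level rejection rate stays near nominal."""
        samples = _design_samples(8)
        X = np.exp(0.2 * rng.standard_normal((len(samples), 1000)))
        res = two_way_anova_per_feature(_matrix(X, samples), alpha=0.05)
        rate = (res.effects["p_population"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestFoldChange:
    def test_simple_ratio(self):
        samples = _design_samples(2)
        X = np.where((samples["population"] == "pan").to_numpy()[:, None], 2.0, 1.0)
        fc = fold_change(_matrix(X, samples), {"population": "pan"}, {"population": "cd16"})
        assert fc["ratio_ab"].iloc[0] == pytest.approx(2.0, rel=1e-6)
        assert fc["direction"].iloc[0] == "pan"

    def test_equal_means_give_unity(self):
        fc = fold_change(
            _matrix(np.ones((24, 3))), {"population": "pan"}, {"population": "cd16"}
        )
        assert np.allclose(fc["fold_change"], 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change(
                _matrix(np.ones((24, 2))), {"population": "pan"}, {"population": "nk"}
            )


class TestBiomarkers:
    def test_empty_inputs_give_empty_output(self):
        m = _matrix(np.ones((24, 0)), mz=np.array([]))
        anova_like = two_way_anova_per_feature(_matrix(np.abs(np.random.default_rng(0).random((24, 1))) + 1))
        fc = fold_change(_matrix(np.ones((24, 1))), {"population": "pan"}, {"population": "cd16"})
        hits = select_biomarkers(anova_like, fc)
        assert len(hits) == 0

    def test_default_thresholds(self):
        import inspect

        sig = inspect.signature(select_biomarkers)
        assert sig.parameters["alpha"].default == 0.001
        assert sig.parameters["fc_threshold"].default == 2.0

    def test_requires_both_significance_and_fold_change(self, rng):
        samples = _design_samples(8)
        pan = (samples["population"] == "pan").to_numpy()
        noise = 1 + 0.01 * rng.standard_normal((len(samples), 3))
        X = noise.copy()
        X[pan, 0] *= 4.0  # significant and large FC -> hit
        X[pan, 1] *= 1.2  # significant but small FC -> no hit
        m = _matrix(X, samples)
        anova = two_way_anova_per_feature(m)
        fc = fold_change(m, {"population": "pan"}, {"population": "cd16"})
        hits = select_biomarkers(anova, fc)
        assert list(hits["feature_mz"]) == [m.feature_mz[0]]
        assert hits["direction"].iloc[0] == "pan"

    def test_sorted_by_fold_change_descending(self, study):
        truth, _, matrix = study
        anova = two_way_anova_per_feature(matrix)
        fc = fold_change(matrix, {"population": "pan"}, {"population": "cd16"})
        hits = select_biomarkers(anova, fc)
        assert len(hits) > 0
        assert (np.diff(hits["fold_change"]) <= 1e-12).all()


class TestConditionContrasts:
    def test_no_signal_gives_empty_sets(self, rng):
        X = np.exp(0.05 * rng.standard_normal((48, 20)))
        sets, inter, _ = condition_contrast_sets(_matrix(X, _design_samples(8)))
        assert all(len(v) == 0 for v in sets.values())
        assert all(len(v) == 0 for v in inter.values())

    def test_shared_responder_lands_in_intersection(self, rng):
        samples = _design_samples(8)
        X = np.exp(0.03 * rng.standard_normal((len(samples), 5)))
        lps = (samples["condition"] == "lps").to_numpy()
        X[lps, 2] *= 3.0  # responds in both populations
        sets, inter, _ = condition_contrast_sets(_matrix(X, samples))
        mz = np.round(3000.0 + 100.0 * 2, 4)
        assert mz in sets["pan"] and mz in sets["cd16"]
        assert mz in inter[("pan", "cd16")]

    def test_planted_condition_markers_recovered(self, study):
        truth, _, matrix = study
        sets, _, _ = condition_contrast_sets(matrix)
        responders = [
            p.mz_true for p in truth.peak_specs
            if p.group_multipliers and len({k[0] for k in p.group_multipliers}) >= 1
            and any(k[1] != "resting" for k in p.group_multipliers)
            and all(k[1] != "resting" for k in p.group_multipliers)
        ]
        found = np.asarray(sorted(set().union(*sets.values())))
        assert responders
        hits = match_within(np.asarray(responders), found, 0.002)
        assert hits.mean() >= 0.8


class TestShiftPairs:
    def test_empty_matrix_gives_empty_table(self):
        m = _matrix(np.ones((24, 0)), mz=np.array([]))
        pairs = find_shift_pairs(m)
        assert len(pairs) == 0

    def test_default_delta_is_eighty(self):
        import inspect

        assert PTM_DELTA_DA == 80.0
        sig = inspect.signature(find_shift_pairs)
        assert sig.parameters["delta"].default == 80.0

    def test_each_unordered_pair_reported_once(self):
        mz = np.array([5000.0, 5080.0, 9000.0])
        m = _matrix(np.abs(np.random.default_rng(1).random((48, 3))) + 0.1,
                    _design_samples(8), mz=mz)
        pairs = find_shift_pairs(m)
        assert len(pairs) == 1
        assert pairs["mz_low"].iloc[0] == 5000.0
        assert pairs["mz_high"].iloc[0] == 5080.0

    def test_planted_pair_uniquely_flagged(self, study):
        truth, _, matrix = study
        pairs = find_shift_pairs(matrix)
        flagged = pairs[pairs["anticorrelated"]]
        prec = truth.shift_pairs[0].precursor.mz_true
        assert len(flagged) == 1
        assert abs(flagged["mz_low"].iloc[0] - prec) <= 0.002 * prec
        assert flagged["population"].iloc[0] == "cd16"
        assert flagged["condition_to"].iloc[0] == "lps"

    def test_pc1_separates_populations(self, study):
        truth, _, matrix = study
        pca = pca_correlation(matrix)
        separable, margin = pc1_separation(
            pca, matrix.samples["population"].to_numpy()
        )
        assert separable and margin > 0
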