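"""Differential statistics on the feature matrix.

Correlation-matrix PCA for sample separation, per-feature two-way fixed
effects ANOVA with Bonferroni-adjusted post-tests, fold-change biomarker
selection, per-population condition-contrast sets, and detection of
precursor/+80 Da peak pairs with the anti-correlated intensity pattern
expected of a stimulation-induced modification such as phosphorylation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .peakmatrix import FeatureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "AnovaResult",
    "pca_correlation",
    "two_way_anova_per_feature",
    "fold_change",
    "select_biomarkers",
    "condition_contrast_sets",
    "find_shift_pairs",
    "PTM_DELTA_DA",
]

PTM_DELTA_DA = 80.0  # nominal phosphorylation / sulfation mass shift


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """PCA on standardized features (eigendecomposition of the correlation matrix)."""

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # kept features x components
    variance_explained: np.ndarray  # fraction of total variance per component
    feature_mz: np.ndarray  # features actually used (zero-variance dropped)


def pca_correlation(m: FeatureMatrix, n_components: int | None = None) -> PCAResult:
    """Principal components of the feature correlation matrix.

    Columns are standardized with the n-1 sample standard deviation;
    zero-variance features are dropped (logged).  Deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """
    X = m.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.info("pca_correlation: dropped %d zero-variance features", (~keep).sum())
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = S**2 / (n - 1)
    p = int(keep.sum())
    k = min(n_components or eig.size, eig.size)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(scores, loadings, eig[:k] / p, m.feature_mz[keep])


# ---------------------------------------------------------------------------
# two-way ANOVA


@dataclass
class AnovaResult:
    """Per-feature two-way ANOVA tables.

    ``effects`` has one row per feature (F and p for both factors and, with
    replication, their interaction).  ``contrasts`` is long-format: one row
    per (feature, contrast), with raw and Bonferroni-adjusted p-values.
    ``group_means`` holds the cell means used by the post-tests.
    """

    factor_a: str
    factor_b: str
    effects: pd.DataFrame
    contrasts: pd.DataFrame
    group_means: pd.DataFrame
    df_resid: int

    def min_adjusted_p(self) -> np.ndarray:
        """Per feature, the smallest Bonferroni-adjusted contrast p-value."""
        return (
            self.contrasts.groupby("feature_index")["p_adj"].min()
            .reindex(range(len(self.effects)), fill_value=1.0)
            .to_numpy()
        )

    def significant_features(self, alpha: float) -> np.ndarray:
        return self.effects["feature_mz"].to_numpy()[self.min_adjusted_p() < alpha]


def _f_p(ss: np.ndarray, df: int, mse: np.ndarray, df_e: int) -> tuple[np.ndarray, np.ndarray]:
    ms = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(mse > 0, ms / np.where(mse > 0, mse, 1.0), np.where(ms > 0, np.inf, 0.0))
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isfinite(F), F, 0.0), df, df_e))
    return F, p


def two_way_anova_per_feature(
    m: FeatureMatrix,
    factor_a: str = "population",
    factor_b: str = "condition",
    contrast_family: str = "a_within_b",
    alpha: float = 0.001,
) -> AnovaResult:
    """Classical fixed-effects two-way ANOVA for every feature.

    Balanced designs use the closed-form sums of squares, vectorized across
    features.  With one observation per cell the additive model is fitted and
    the interaction serves as the residual.  Unbalanced designs fall back to
    per-feature least squares on cell means (type-II sums of squares via
    statsmodels), with a logged warning.

    Post-tests (``contrast_family``):
      * ``a_within_b`` — pairwise levels of factor A within each level of B
        (e.g. population contrasts per condition);
      * ``a_marginal`` — pairwise marginal means of factor A (e.g. condition
        contrasts averaged over donors).
    Both use the pooled residual variance and Bonferroni adjustment by the
    family size.  Zero-variance features get F = 0, p = 1 by convention and
    can never be significant.
    """
    a_lab = m.samples[factor_a].astype(str).to_numpy()
    b_lab = m.samples[factor_b].astype(str).to_numpy()
    a_levels = list(dict.fromkeys(a_lab))
    b_levels = list(dict.fromkeys(b_lab))
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least 2 levels")
    Y = m.values
    N, P = Y.shape

    cell_n = np.zeros((a, b), dtype=int)
    cell_sum = np.zeros((a, b, P))
    ai = np.asarray([a_levels.index(x) for x in a_lab])
    bi = np.asarray([b_levels.index(x) for x in b_lab])
    np.add.at(cell_n, (ai, bi), 1)
    np.add.at(cell_sum, (ai, bi), Y)
    if np.any(cell_n == 0):
        raise ValueError("every factor-level cell needs at least one observation")

    balanced = np.all(cell_n == cell_n[0, 0])
    if not balanced:
        log.warning(
            "unbalanced %s x %s design (cell sizes %s); using least-squares fallback",
            factor_a, factor_b, sorted(set(cell_n.ravel())),
        )
        return _anova_unbalanced(
            m, factor_a, factor_b, a_levels, b_levels, ai, bi, contrast_family, alpha
        )

    n = int(cell_n[0, 0])
    cell_mean = cell_sum / n
    grand = Y.mean(axis=0)
    a_mean = cell_mean.mean(axis=1)  # a x P
    b_mean = cell_mean.mean(axis=0)  # b x P

    ss_a = n * b * ((a_mean - grand) ** 2).sum(axis=0)
    ss_b = n * a * ((b_mean - grand) ** 2).sum(axis=0)
    ss_cells = n * ((cell_mean - grand) ** 2).sum(axis=(0, 1))
    ss_ab = np.clip(ss_cells - ss_a - ss_b, 0.0, None)
    ss_t = ((Y - grand) ** 2).sum(axis=0)

    if n > 1:
        ss_e = np.clip(ss_t - ss_cells, 0.0, None)
        df_e = N - a * b
        df_ab = (a - 1) * (b - 1)
    else:
        # additive model: interaction is the residual
        ss_e = ss_ab
        df_e = (a - 1) * (b - 1)
        df_ab = 0
    if df_e <= 0:
        raise ValueError("zero residual degrees of freedom")
    mse = ss_e / df_e

    degenerate = ss_t <= 1e-300
    F_a, p_a = _f_p(ss_a, a - 1, mse, df_e)
    F_b, p_b = _f_p(ss_b, b - 1, mse, df_e)
    effects = pd.DataFrame(
        {
            "feature_mz": m.feature_mz,
            f"F_{factor_a}": np.where(degenerate, 0.0, F_a),
            f"p_{factor_a}": np.where(degenerate, 1.0, p_a),
            f"F_{factor_b}": np.where(degenerate, 0.0, F_b),
            f"p_{factor_b}": np.where(degenerate, 1.0, p_b),
        }
    )
    if df_ab > 0:
        F_ab, p_ab = _f_p(ss_ab, df_ab, mse, df_e)
        effects["F_interaction"] = np.where(degenerate, 0.0, F_ab)
        effects["p_interaction"] = np.where(degenerate, 1.0, p_ab)

    contrasts = _contrast_table(
        m.feature_mz, cell_mean, a_levels, b_levels, n, mse, df_e,
        contrast_family, degenerate,
    )
    gm = pd.DataFrame(
        {f"{al}:{bl}": cell_mean[i, j]
         for i, al in enumerate(a_levels) for j, bl in enumerate(b_levels)}
    )
    gm.insert(0, "feature_mz", m.feature_mz)
    return AnovaResult(factor_a, factor_b, effects, contrasts, gm, df_e)


def _contrast_table(
    feature_mz, cell_mean, a_levels, b_levels, n, mse, df_e, family, degenerate
) -> pd.DataFrame:
    """Pooled-variance pairwise t contrasts, Bonferroni-adjusted by family size."""
    a, b, P = cell_mean.shape
    rows = []
    if family == "a_within_b":
        pairs = list(itertools.combinations(range(a), 2))
        specs = [(i1, i2, j) for j in range(b) for (i1, i2) in pairs]
        k = len(specs)
        for i1, i2, j in specs:
            est = cell_mean[i1, j] - cell_mean[i2, j]
            se = np.sqrt(mse * 2.0 / n)
            rows.append((f"{a_levels[i1]}-{a_levels[i2]}@{b_levels[j]}",
                         a_levels[i1], a_levels[i2], b_levels[j], est, se))
    elif family == "a_marginal":
        pairs = list(itertools.combinations(range(a), 2))
        k = len(pairs)
        marg = cell_mean.mean(axis=1)
        for i1, i2 in pairs:
            est = marg[i1] - marg[i2]
            se = np.sqrt(mse * 2.0 / (n * b))
            rows.append((f"{a_levels[i1]}-{a_levels[i2]}",
                         a_levels[i1], a_levels[i2], "", est, se))
    else:
        raise ValueError(f"unknown contrast family {family!r}")

    frames = []
    for label, l1, l2, within, est, se in rows:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0),
                         np.sign(est) * np.inf)
        p = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df_e))
        p = np.where(est == 0, 1.0, p)
        p = np.where(degenerate, 1.0, p)
        frames.append(
            pd.DataFrame(
                {
                    "feature_index": np.arange(P),
                    "feature_mz": feature_mz,
                    "contrast": label,
                    "level_1": l1,
                    "level_2": l2,
                    "within": within,
                    "estimate": est,
                    "t": np.where(degenerate, 0.0, t),
                    "p_raw": p,
                    "p_adj": np.minimum(1.0, k * p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _anova_unbalanced(
    m, factor_a, factor_b, a_levels, b_levels, ai, bi, contrast_family, alpha
) -> AnovaResult:
    """Per-feature type-II least squares for unbalanced designs (statsmodels)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    a, b = len(a_levels), len(b_levels)
    base = pd.DataFrame({"A": pd.Categorical([a_levels[i] for i in ai], a_levels),
                         "B": pd.Categorical([b_levels[i] for i in bi], b_levels)})
    cell_n = np.zeros((a, b), dtype=int)
    np.add.at(cell_n, (ai, bi), 1)
    with_rep = len(ai) - a * b > 0  # residual df left after the full model
    formula = "y ~ C(A) * C(B)" if with_rep else "y ~ C(A) + C(B)"
    eff_rows, cm_list, mse_list, dfe = [], [], [], None
    for j in range(m.values.shape[1]):
        df = base.assign(y=m.values[:, j])
        if np.ptp(m.values[:, j]) == 0:
            eff_rows.append([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
            cm_list.append(np.zeros((a, b)) + m.values[0, j])
            mse_list.append(0.0)
            fit = ols(formula, df).fit()
            dfe = int(fit.df_resid)
            continue
        fit = ols(formula, df).fit()
        tbl = sm.stats.anova_lm(fit, typ=2)
        Fa, pa = tbl.loc["C(A)", ["F", "PR(>F)"]]
        Fb, pb = tbl.loc["C(B)", ["F", "PR(>F)"]]
        if with_rep:
            Fab, pab = tbl.loc["C(A):C(B)", ["F", "PR(>F)"]]
        else:
            Fab, pab = np.nan, np.nan
        eff_rows.append([Fa, pa, Fb, pb, Fab, pab])
        cm = np.array(
            [[df.loc[(base["A"] == al) & (base["B"] == bl), "y"].mean()
              for bl in b_levels] for al in a_levels]
        )
        cm_list.append(cm)
        mse_list.append(float(fit.mse_resid))
        dfe = int(fit.df_resid)
    effects = pd.DataFrame(
        eff_rows,
        columns=[f"F_{factor_a}", f"p_{factor_a}", f"F_{factor_b}", f"p_{factor_b}",
                 "F_interaction", "p_interaction"],
    )
    effects.insert(0, "feature_mz", m.feature_mz)
    cell_mean = np.stack(cm_list, axis=-1)  # a x b x P
    mse = np.asarray(mse_list)
    n_h = sps.hmean(cell_n.ravel())  # harmonic mean cell size for contrast SE
    degenerate = np.asarray([np.ptp(m.values[:, j]) == 0 for j in range(m.values.shape[1])])
    contrasts = _contrast_table(
        m.feature_mz, cell_mean, a_levels, b_levels, n_h, mse, dfe,
        contrast_family, degenerate,
    )
    gm = pd.DataFrame(
        {f"{al}:{bl}": cell_mean[i, j]
         for i, al in enumerate(a_levels) for j, bl in enumerate(b_levels)}
    )
    gm.insert(0, "feature_mz", m.feature_mz)
    return AnovaResult(factor_a, factor_b, effects, contrasts, gm, dfe)


# ---------------------------------------------------------------------------
# fold-change and biomarker selection


def fold_change(
    m: FeatureMatrix,
    group_a: dict,
    group_b: dict,
    eps_rel: float = 1e-6,
) -> pd.DataFrame:
    """Per-feature ratio of group mean intensities.

    Groups are given as factor filters, e.g. ``{"population": "pan"}``.  The
    ratio is epsilon-stabilized with ``eps = eps_rel x`` the median positive
    matrix value.  ``fold_change`` is the larger of the two orientations and
    ``direction`` names the higher group.
    """
    mask_a = m.sample_mask(**group_a)
    mask_b = m.sample_mask(**group_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be non-empty")
    mean_a = m.values[mask_a].mean(axis=0)
    mean_b = m.values[mask_b].mean(axis=0)
    pos = m.values[m.values > 0]
    eps = eps_rel * (float(np.median(pos)) if pos.size else 1.0)
    ratio = (mean_a + eps) / (mean_b + eps)
    fc = np.maximum(ratio, 1.0 / ratio)
    label_a = "/".join(str(v) for v in group_a.values())
    label_b = "/".join(str(v) for v in group_b.values())
    return pd.DataFrame(
        {
            "feature_mz": m.feature_mz,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "ratio_ab": ratio,
            "fold_change": fc,
            "direction": np.where(ratio >= 1.0, label_a, label_b),
        }
    )


def select_biomarkers(
    anova: AnovaResult,
    fold_changes: pd.DataFrame,
    alpha: float = 0.001,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Features with adjusted p < alpha and fold-change > threshold.

    Defaults implement the discriminatory-peak rule: Bonferroni-adjusted
    post-test p < 0.001 and expression fold-change > 2, sorted by
    fold-change descending.
    """
    if len(anova.effects) != len(fold_changes):
        raise ValueError("ANOVA and fold-change tables must align on features")
    p_adj = anova.min_adjusted_p()
    fc = fold_changes["fold_change"].to_numpy()
    hit = (p_adj < alpha) & (fc > fc_threshold)
    out = pd.DataFrame(
        {
            "feature_mz": fold_changes["feature_mz"].to_numpy()[hit],
            "direction": fold_changes["direction"].to_numpy()[hit],
            "fold_change": fc[hit],
            "p_adj": p_adj[hit],
        }
    )
    return out.sort_values("fold_change", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# condition contrasts and shift pairs


def condition_contrast_sets(
    m: FeatureMatrix,
    alpha: float = 0.001,
    donor_factor: str = "donor",
) -> tuple[dict[str, set[float]], dict[tuple[str, str], set[float]], dict[str, AnovaResult]]:
    """Per population: features responding to any condition contrast.

    Within each population the donor-averaged values are analysed as a
    condition x donor block design (residual = interaction); a feature enters
    the population's set when any pairwise condition contrast has Bonferroni
    adjusted p < alpha.  Pairwise intersections between populations are
    returned alongside the full ANOVA tables.
    """
    sets: dict[str, set[float]] = {}
    tables: dict[str, AnovaResult] = {}
    pops = list(dict.fromkeys(m.samples["population"]))
    for pop in pops:
        sub = m.subset_samples(m.sample_mask(population=pop))
        res = two_way_anova_per_feature(
            sub, factor_a="condition", factor_b=donor_factor,
            contrast_family="a_marginal", alpha=alpha,
        )
        sets[pop] = set(np.round(res.significant_features(alpha), 4))
        tables[pop] = res
    inter = {
        (p1, p2): sets[p1] & sets[p2]
        for p1, p2 in itertools.combinations(pops, 2)
    }
    return sets, inter, tables


def find_shift_pairs(
    m: FeatureMatrix,
    delta: float = PTM_DELTA_DA,
    pair_tolerance: float = 1.0,
    alpha: float = 0.001,
    contrast: tuple[str, str, str] | None = None,
) -> pd.DataFrame:
    """Feature pairs separated by ~delta Da, flagged when anti-correlated.

    All unordered pairs with ``|mz_high - mz_low - delta| <= pair_tolerance``
    are reported with their per-group mean intensities.  The anticorrelation
    flag is set when, under a (population, condition_from, condition_to)
    contrast, the low-mass feature significantly decreases while the
    high-mass feature significantly increases (both Bonferroni-adjusted
    p < alpha) — the signature of a modification consuming its precursor.
    With ``contrast=None`` every population x (reference -> stimulated)
    contrast is screened and the matching one is reported.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    mz = m.feature_mz
    pairs = [
        (i, j)
        for i in range(mz.size)
        for j in range(i + 1, mz.size)
        if abs(mz[j] - mz[i] - delta) <= pair_tolerance
    ]
    cols = [
        "mz_low", "mz_high", "delta_observed", "anticorrelated",
        "population", "condition_from", "condition_to", "p_low", "p_high",
    ]
    groups = [
        (p, c)
        for p in dict.fromkeys(m.samples["population"])
        for c in dict.fromkeys(m.samples["condition"])
    ]
    if not pairs:
        return pd.DataFrame(columns=cols)

    _, _, tables = condition_contrast_sets(m, alpha=alpha)
    conditions = list(dict.fromkeys(m.samples["condition"]))
    ref = conditions[0]
    if contrast is not None:
        candidates = [contrast]
    else:
        candidates = [
            (pop, ref, cond)
            for pop in tables
            for cond in conditions[1:]
        ]

    def signed_p(pop: str, c_from: str, c_to: str, feat: int) -> tuple[float, float]:
        """(mean_to - mean_from, adjusted p) for one feature and contrast."""
        tab = tables[pop].contrasts
        rows = tab[
            (tab["feature_index"] == feat)
            & (
                ((tab["level_1"] == c_from) & (tab["level_2"] == c_to))
                | ((tab["level_1"] == c_to) & (tab["level_2"] == c_from))
            )
        ]
        r = rows.iloc[0]
        est = -r["estimate"] if r["level_1"] == c_from else r["estimate"]
        return float(est), float(r["p_adj"])

    records = []
    for i, j in pairs:
        flagged = False
        best = (candidates[0], 1.0, 1.0)
        for pop, c_from, c_to in candidates:
            est_lo, p_lo = signed_p(pop, c_from, c_to, i)
            est_hi, p_hi = signed_p(pop, c_from, c_to, j)
            if est_lo < 0 and est_hi > 0 and p_lo < alpha and p_hi < alpha:
                flagged = True
                best = ((pop, c_from, c_to), p_lo, p_hi)
                break
        (pop, c_from, c_to), p_lo, p_hi = best
        rec = {
            "mz_low": mz[i],
            "mz_high": mz[j],
            "delta_observed": mz[j] - mz[i],
            "anticorrelated": flagged,
            "population": pop if flagged else "",
            "condition_from": c_from if flagged else "",
            "condition_to": c_to if flagged else "",
            "p_low": p_lo,
            "p_high": p_hi,
        }
        for pop_g, cond_g in groups:
            mask = m.sample_mask(population=pop_g, condition=cond_g)
            rec[f"mean_low_{pop_g}_{cond_g}"] = float(m.values[mask, i].mean())
            rec[f"mean_high_{pop_g}_{cond_g}"] = float(m.values[mask, j].mean())
        records.append(rec)
    return pd.DataFrame(records)
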