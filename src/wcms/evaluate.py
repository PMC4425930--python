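"""Score pipeline results against a simulation's ground truth.

Used by the test-suite and the reproduction script to measure, on synthetic
experiments, how well the chain recovers what was planted: peak recovery and
false-discovery proportions, fold-change estimation error, marker and
shift-pair flagging, and PCA class separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import (
    PCAResult,
    find_shift_pairs,
    fold_change,
    pca_correlation,
    select_biomarkers,
    two_way_anova_per_feature,
)
from .peakmatrix import FeatureMatrix
from .simulate import SimTruth
from .spectrum import PeakList

__all__ = [
    "RecoveryReport",
    "match_within",
    "evaluate_experiment",
    "pc1_separation",
    "run_synthetic_to_matrix",
]


def run_synthetic_to_matrix(
    seed: int,
    design_overrides: dict | None = None,
    params=None,
    tol_rel: float = 0.002,
    min_frequency: float = 0.9,
):
    """Simulate a default experiment and process it to the feature matrix.

    Returns ``(truth, peaklists, matrix)`` — the standard entry point for
    truth-based scoring.
    """
    from .peakmatrix import bin_peaks, build_matrix, filter_features
    from .preprocess import PreprocessParams, preprocess_experiment
    from .simulate import SimDesign, simulate_experiment

    design = SimDesign(seed=seed, **(design_overrides or {}))
    spectra, truth = simulate_experiment(design)
    _states, peaklists = preprocess_experiment(
        spectra, params or PreprocessParams()
    )
    sheet = pd.DataFrame(
        [
            {
                "file": s.meta.sample_id,
                "donor": s.meta.donor,
                "population": s.meta.population,
                "condition": s.meta.condition,
                "replicate": s.meta.replicate,
            }
            for s in spectra
        ]
    )
    bins = bin_peaks(peaklists, tol_rel)
    matrix = filter_features(
        build_matrix(bins, peaklists, sheet), min_frequency
    )
    return truth, peaklists, matrix


def match_within(query: np.ndarray, targets: np.ndarray, tol_rel: float) -> np.ndarray:
    """Boolean per query mass: any target within tol_rel * m/z."""
    query = np.atleast_1d(np.asarray(query, dtype=float))
    if targets.size == 0:
        return np.zeros(query.size, dtype=bool)
    return np.asarray(
        [np.min(np.abs(targets - q)) <= tol_rel * q for q in query]
    )


def pc1_separation(pca: PCAResult, labels: np.ndarray) -> tuple[bool, float]:
    """Is PC1 linearly separable by class?  Returns (separable, margin).

    The margin is the smallest gap between the two class score ranges along
    component 1; positive means perfectly separable by one threshold.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("pc1_separation expects exactly two classes")
    s = pca.scores[:, 0]
    a, b = s[labels == classes[0]], s[labels == classes[1]]
    margin = max(b.min() - a.max(), a.min() - b.max())
    return bool(margin > 0), float(margin)


@dataclass
class RecoveryReport:
    """Truth-based scores of one simulated experiment."""

    recovery_snr5: float  # planted peaks (min group SNR >= 5) found as features
    per_spectrum_fdr: float  # detected peaks not matching any planted mass
    feature_fdr: float  # retained features not matching any planted mass
    fc_rel_errors: list[float]  # per estimable marker, relative FC error
    n_markers: int
    n_markers_flagged: int  # planted multiplier >= 2.5 markers in biomarker list
    n_markers_eligible: int
    pair_flagged: bool  # the planted shift pair is flagged anticorrelated
    n_extra_pairs_flagged: int
    pc1_separable: bool
    pc1_margin: float
    pc1_variance: float
    n_features: int
    n_biomarkers: int


def evaluate_experiment(
    truth: SimTruth,
    peaklists: list[PeakList],
    matrix: FeatureMatrix,
    tol_rel: float = 0.002,
    alpha: float = 0.001,
    fc_threshold: float = 2.0,
) -> RecoveryReport:
    """Run the standard statistics on ``matrix`` and score them against truth.

    Fold-change error is evaluated only for markers whose feature was
    detected in at least half of each population's samples: a ratio with an
    (almost) unobserved denominator group is not an estimate.
    """
    design = truth.design
    pops = list(design.populations)
    masses = truth.true_masses()
    _, min_snr = truth.min_planted_snr()

    rec = match_within(matrix.feature_mz, masses, tol_rel)
    recovered_mask = match_within(masses, matrix.feature_mz, tol_rel)
    recovery = float(recovered_mask[min_snr >= 5].mean())
    feature_fdr = float(1.0 - rec.mean())

    fdrs = []
    for pk in peaklists:
        if len(pk):
            fdrs.append(1.0 - match_within(pk.mz, masses, tol_rel).mean())
    per_spectrum_fdr = float(np.mean(fdrs)) if fdrs else 0.0

    # fold changes vs planted ratios (marker peaks)
    fc = fold_change(matrix, {"population": pops[0]}, {"population": pops[-1]})
    mz_true, true_fc = truth.true_fold_change(pops[0], pops[-1])
    markers = [
        (p.mz_true, max(p.group_multipliers.values()))
        for p in truth.peak_specs
        if p.group_multipliers
        and len({k[0] for k in p.group_multipliers}) == 1
        and len(p.group_multipliers) == len(design.conditions)
    ]
    detected = matrix.n_detected > 0
    fc_errors: list[float] = []
    for mzt, _mult in markers:
        i = int(np.argmin(np.abs(matrix.feature_mz - mzt)))
        if abs(matrix.feature_mz[i] - mzt) > tol_rel * mzt:
            continue
        estimable = all(
            detected[matrix.sample_mask(population=p), i].mean() >= 0.5
            for p in pops
        )
        if not estimable:
            continue
        k = int(np.argmin(np.abs(mz_true - mzt)))
        fc_errors.append(
            float((fc["ratio_ab"].iloc[i] - true_fc[k]) / true_fc[k])
        )

    anova = two_way_anova_per_feature(matrix, alpha=alpha)
    hits = select_biomarkers(anova, fc, alpha=alpha, fc_threshold=fc_threshold)
    eligible = [(mzt, m) for mzt, m in markers if m >= 2.5]
    flagged = sum(
        bool(match_within(np.asarray([mzt]), hits["feature_mz"].to_numpy(), tol_rel)[0])
        for mzt, _ in eligible
    )

    pairs = find_shift_pairs(matrix, alpha=alpha)
    flagged_pairs = pairs[pairs["anticorrelated"]] if len(pairs) else pairs
    pair_ok = False
    n_extra = 0
    if truth.shift_pairs:
        prec = truth.shift_pairs[0].precursor.mz_true
        for r in flagged_pairs.itertuples():
            if abs(r.mz_low - prec) <= tol_rel * prec:
                pair_ok = True
            else:
                n_extra += 1
    else:
        n_extra = len(flagged_pairs)

    pca = pca_correlation(matrix)
    separable, margin = pc1_separation(
        pca, matrix.samples["population"].to_numpy()
    )

    return RecoveryReport(
        recovery_snr5=recovery,
        per_spectrum_fdr=per_spectrum_fdr,
        feature_fdr=feature_fdr,
        fc_rel_errors=fc_errors,
        n_markers=len(markers),
        n_markers_flagged=int(flagged),
        n_markers_eligible=len(eligible),
        pair_flagged=pair_ok,
        n_extra_pairs_flagged=int(n_extra),
        pc1_separable=separable,
        pc1_margin=margin,
        pc1_variance=float(pca.variance_explained[0]),
        n_features=matrix.n_features,
        n_biomarkers=int(len(hits)),
    )
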