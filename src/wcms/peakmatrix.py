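"""From per-spectrum peak lists to the replicate-averaged feature matrix.

Peaks from all aligned spectra are pooled into consensus m/z bins; per
biological sample (donor x population x condition) the intensities of its
technical replicates are averaged into one row, yielding the features x
samples matrix consumed by every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._binning import Bin, greedy_bin
from .spectrum import PeakList

log = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "bin_peaks", "build_matrix", "filter_features"]


@dataclass
class FeatureMatrix:
    """Consensus features x biological samples.

    ``values`` is samples x features (replicate-averaged normalized
    intensities, >= 0); ``n_detected`` counts, per cell, the technical
    replicates in which the feature was detected.  ``samples`` carries the
    design factors (donor, population, condition) row-aligned with
    ``values``.
    """

    feature_mz: np.ndarray
    samples: pd.DataFrame
    values: np.ndarray
    n_detected: np.ndarray

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_detected = np.asarray(self.n_detected, dtype=int)
        if np.any(np.diff(self.feature_mz) <= 0):
            raise ValueError("feature_mz must be strictly ascending")
        if self.values.shape != (len(self.samples), self.feature_mz.size):
            raise ValueError("values shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("matrix values must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return int(self.feature_mz.size)

    def sample_mask(self, population: str | None = None, condition: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            mask &= (self.samples["population"] == population).to_numpy()
        if condition is not None:
            mask &= (self.samples["condition"] == condition).to_numpy()
        return mask

    def subset_samples(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.feature_mz,
            self.samples.loc[mask].reset_index(drop=True),
            self.values[mask],
            self.n_detected[mask],
        )

    def subset_features(self, keep: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.feature_mz[keep],
            self.samples.copy(),
            self.values[:, keep],
            self.n_detected[:, keep],
        )

    # -- CSV round trip -----------------------------------------------------
    def to_csv(self, matrix_path: str | Path, factors_path: str | Path) -> None:
        """Matrix CSV: first column feature m/z (1 decimal), one column per sample."""
        ids = [
            f"{r.donor}_{r.population}_{r.condition}"
            for r in self.samples.itertuples(index=False)
        ]
        df = pd.DataFrame(self.values.T, columns=ids)
        df.insert(0, "feature_mz", np.round(self.feature_mz, 1))
        df.to_csv(matrix_path, index=False, float_format="%.10g")
        self.samples.assign(sample=ids).to_csv(factors_path, index=False)

    @classmethod
    def from_csv(cls, matrix_path: str | Path, factors_path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(matrix_path)
        samples = pd.read_csv(factors_path, dtype={"donor": str}).drop(columns=["sample"])
        values = df.drop(columns=["feature_mz"]).to_numpy().T
        return cls(
            df["feature_mz"].to_numpy(),
            samples,
            values,
            np.zeros_like(values, dtype=int),
        )


def bin_peaks(
    peaklists: Sequence[PeakList], tolerance_rel: float = 0.002
) -> list[Bin]:
    """Pool peaks of all spectra into consensus m/z bins.

    Greedy agglomerative: sort pooled peaks, cut where a consecutive gap
    exceeds ``tolerance_rel`` x m/z, split any bin holding two peaks of one
    spectrum at its widest internal gap.  Consensus m/z is the
    intensity-weighted mean of member m/z.
    """
    if not peaklists:
        return []
    mzs = np.concatenate([p.mz for p in peaklists])
    ints = np.concatenate([p.intensity for p in peaklists])
    sids = np.concatenate([np.full(len(p), i) for i, p in enumerate(peaklists)])
    return greedy_bin(mzs, ints, sids, tolerance_rel)


def build_matrix(
    bins: Sequence[Bin],
    peaklists: Sequence[PeakList],
    sheet: pd.DataFrame,
    average: str = "detected",
) -> FeatureMatrix:
    """Replicate-average binned peak intensities into the feature matrix.

    ``average='detected'`` (default) averages over the replicates in which
    the peak was actually detected; ``'all'`` divides by the full replicate
    count (missing replicates count as zero).  Cells with no detection are 0.
    """
    if average not in ("detected", "all"):
        raise ValueError("average must be 'detected' or 'all'")
    if len(peaklists) != len(sheet):
        raise ValueError(
            f"{len(peaklists)} peak lists but {len(sheet)} sample-sheet rows"
        )
    keys = list(
        dict.fromkeys(
            (str(r.donor), r.population, r.condition)
            for r in sheet.itertuples(index=False)
        )
    )
    key_index = {k: i for i, k in enumerate(keys)}
    spec_sample = np.asarray(
        [
            key_index[(str(r.donor), r.population, r.condition)]
            for r in sheet.itertuples(index=False)
        ]
    )
    n_reps = sheet.groupby(["donor", "population", "condition"], sort=False).size()

    n_s, n_f = len(keys), len(bins)
    total = np.zeros((n_s, n_f))
    count = np.zeros((n_s, n_f), dtype=int)
    for j, b in enumerate(bins):
        for sid, inten in zip(b.spectrum_ids, b.member_intensity):
            i = spec_sample[int(sid)]
            total[i, j] += inten
            count[i, j] += 1
    if average == "detected":
        with np.errstate(invalid="ignore"):
            values = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    else:
        reps = np.asarray([n_reps[k] for k in keys])[:, None]
        values = total / reps
    samples = pd.DataFrame(keys, columns=["donor", "population", "condition"])
    return FeatureMatrix(
        np.asarray([b.mz for b in bins]), samples, values, count
    )


def filter_features(m: FeatureMatrix, min_frequency: float = 0.9) -> FeatureMatrix:
    """Keep features detected in >= min_frequency of samples of some group.

    A group is one (population, condition) cell of the design; a feature
    survives if its detection frequency reaches the threshold in at least one
    group.
    """
    if not 0 <= min_frequency <= 1:
        raise ValueError("min_frequency must be in [0, 1]")
    if min_frequency == 0:
        return m
    detected = m.n_detected > 0
    keep = np.zeros(m.n_features, dtype=bool)
    for (pop, cond), grp in m.samples.groupby(["population", "condition"]):
        rows = grp.index.to_numpy()
        freq = detected[rows].mean(axis=0)
        keep |= freq >= min_frequency
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_features: dropped %d/%d features", dropped, m.n_features)
    return m.subset_features(keep)
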