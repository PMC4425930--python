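"""Greedy agglomerative m/z binning shared by alignment and matrix building."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Bin", "greedy_bin"]


@dataclass
class Bin:
    """A consensus feature: member peaks pooled across spectra."""

    mz: float  # intensity-weighted mean of member m/z
    member_mz: np.ndarray
    member_intensity: np.ndarray
    spectrum_ids: np.ndarray

    def __len__(self) -> int:
        return int(self.member_mz.size)


def _make_bin(mz: np.ndarray, inten: np.ndarray, sids: np.ndarray) -> Bin:
    w = inten.sum()
    center = float(np.average(mz, weights=inten)) if w > 0 else float(np.mean(mz))
    return Bin(center, mz, inten, sids)


def _split(mz: np.ndarray, inten: np.ndarray, sids: np.ndarray, out: list[Bin]) -> None:
    """Recursively split runs until no spectrum contributes two peaks."""
    if mz.size <= 1 or np.unique(sids).size == sids.size:
        out.append(_make_bin(mz, inten, sids))
        return
    gaps = np.diff(mz)
    cut = int(np.argmax(gaps)) + 1
    _split(mz[:cut], inten[:cut], sids[:cut], out)
    _split(mz[cut:], inten[cut:], sids[cut:], out)


def greedy_bin(
    mz: np.ndarray,
    intensity: np.ndarray,
    spectrum_ids: np.ndarray,
    tolerance_rel: float,
) -> list[Bin]:
    """Pool peaks of many spectra into consensus bins.

    Peaks are sorted by m/z and cut wherever a consecutive gap exceeds
    ``tolerance_rel`` times the local m/z; any run still containing two peaks
    of one spectrum is split at its widest internal gap, recursively, so each
    spectrum contributes at most one peak per bin.  The result is invariant
    to input order (ties broken by spectrum id then intensity).
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    spectrum_ids = np.asarray(spectrum_ids)
    if mz.size == 0:
        return []
    order = np.lexsort((intensity, spectrum_ids, mz))
    mz, intensity, spectrum_ids = mz[order], intensity[order], spectrum_ids[order]
    gaps = np.diff(mz)
    mids = 0.5 * (mz[1:] + mz[:-1])
    cut_points = np.flatnonzero(gaps > tolerance_rel * mids) + 1
    bins: list[Bin] = []
    for lo, hi in zip(np.r_[0, cut_points], np.r_[cut_points, mz.size]):
        _split(mz[lo:hi], intensity[lo:hi], spectrum_ids[lo:hi], bins)
    bins.sort(key=lambda b: b.mz)
    return bins
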