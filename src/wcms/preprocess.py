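"""Per-spectrum processing chain and cross-spectrum alignment.

The chain mirrors the standard quantitative workflow for whole-cell profile
spectra: square-root variance stabilisation, Savitzky-Golay smoothing, TopHat
(morphological opening) baseline removal, median-to-one normalization of peak
intensities, affine pre-alignment to conserved anchor peaks, LOWESS warping
alignment across spectra, and SNR-thresholded peak detection.

Peak amplitudes are reported on the acquisition (linear) scale by inverting
the square-root transform above the estimated baseline:
``amplitude = (height + baseline)**2 - baseline**2``, which makes group
intensity ratios comparable to fold-changes on the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import grey_dilation, grey_erosion
from scipy.signal import argrelmax, savgol_filter
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from ._binning import greedy_bin
from .spectrum import PeakList, RawSpectrum, SpectrumMeta

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessParams",
    "ProcessedSpectrum",
    "sqrt_transform",
    "smooth_savitzky_golay",
    "baseline_tophat",
    "estimate_noise",
    "detect_peaks",
    "normalize_median_to_one",
    "anchor_prealign",
    "warp_align",
    "preprocess_experiment",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the processing chain.

    Defaults suit ~1 Da grids over m/z 3,000-30,000.  ``snr_threshold`` and
    the anchor masses follow the workflow this package reproduces (SNR >= 3;
    conserved peaks at 4078.8 and 14019.1); the window sizes are package
    choices, exposed here.
    """

    mass_range: tuple[float, float] = (3000.0, 30000.0)
    sg_window: int = 21
    sg_polyorder: int = 3
    tophat_half_window: float = 75.0  # Da
    noise_window: float = 500.0  # Da
    snr_threshold: float = 3.0
    anchor_masses: tuple[float, ...] = (4078.8, 14019.1)
    anchor_tolerance: float | None = None  # Da; None -> match_tolerance_rel * m/z
    match_tolerance_rel: float = 0.002  # 2000 ppm, linear-mode accuracy scale
    lowess_span: float = 0.67
    lowess_iterations: int = 3
    align_min_frequency: float = 0.9
    align_min_peaks: int = 5
    local_max_half_window: int = 5  # grid points

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if not self.sg_polyorder < self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be > 0")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess_span must be in (0, 1]")
        if not 0 < self.align_min_frequency <= 1:
            raise ValueError("align_min_frequency must be in (0, 1]")
        lo, hi = self.mass_range
        for a in self.anchor_masses:
            if not lo <= a <= hi:
                raise ValueError(f"anchor {a} outside mass range")

    def tolerance_da(self, mz: float) -> float:
        if self.anchor_tolerance is not None:
            return self.anchor_tolerance
        return self.match_tolerance_rel * mz


@dataclass
class ProcessedSpectrum:
    """A fully processed spectrum with provenance.

    ``intensity`` is the baseline-corrected, normalized signal on the
    square-root scale; ``baseline`` and ``noise`` are on the same scale.
    ``mz`` is the aligned axis (strictly increasing).  ``provenance`` lists
    each applied step with its parameters, in order.
    """

    mz: np.ndarray
    intensity: np.ndarray
    baseline: np.ndarray
    noise: np.ndarray
    meta: SpectrumMeta
    norm_factor: float = 1.0
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.provenance.append((step, params))


# ---------------------------------------------------------------------------
# elementary steps


def sqrt_transform(s: RawSpectrum) -> RawSpectrum:
    """Square-root variance stabilisation; m/z unchanged."""
    if np.any(s.intensity < 0):
        raise ValueError("negative intensities cannot be sqrt-transformed")
    return s.with_intensity(np.sqrt(s.intensity))


def smooth_savitzky_golay(s: RawSpectrum, sg_window: int = 21, sg_polyorder: int = 3) -> RawSpectrum:
    """Savitzky-Golay smoothing (local polynomial least squares).

    Edges are handled by fitting a degree-``sg_polyorder`` polynomial over the
    first/last window and evaluating it there, so no padding is invented.
    """
    if sg_window % 2 == 0 or sg_polyorder >= sg_window:
        raise ValueError("need odd sg_window and sg_polyorder < sg_window")
    if len(s) < sg_window:
        raise ValueError("spectrum shorter than the smoothing window")
    return s.with_intensity(savgol_filter(s.intensity, sg_window, sg_polyorder, mode="interp"))


def _grid_step(mz: np.ndarray) -> float:
    return float(np.median(np.diff(mz)))


def baseline_tophat(s: RawSpectrum, tophat_half_window: float = 75.0) -> tuple[np.ndarray, RawSpectrum]:
    """TopHat baseline: morphological opening with a flat structuring element.

    The element half-width is given in Da and converted to grid points; the
    opening (erosion then dilation) is a lower envelope, so ``baseline <=
    signal`` pointwise and the corrected signal is clipped at zero.  Edge
    windows are truncated (edge replication is equivalent for flat elements).
    """
    if tophat_half_window <= 0:
        raise ValueError("tophat_half_window must be > 0")
    step = _grid_step(s.mz)
    half = int(round(tophat_half_window / step))
    if half < 1:
        raise ValueError("tophat_half_window smaller than the grid step")
    size = 2 * half + 1
    baseline = grey_dilation(grey_erosion(s.intensity, size=size, mode="nearest"),
                             size=size, mode="nearest")
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return baseline, s.with_intensity(corrected)


def estimate_noise(s: RawSpectrum, noise_window: float = 500.0) -> np.ndarray:
    """Per-point noise level: 1.4826 x sliding-window MAD of the signal.

    The MAD is evaluated at window centers spaced window/8 apart and linearly
    interpolated to every grid point; a strictly positive floor is applied
    (relative to the signal maximum, so scaling intensities by k scales the
    estimate by k).
    """
    x = s.intensity
    n = x.size
    if n == 0:
        return np.zeros(0)
    step = _grid_step(s.mz) if n > 1 else 1.0
    w = max(3, int(round(noise_window / step)))
    stride = max(1, w // 8)
    centers = np.arange(0, n, stride)
    mad = np.empty(centers.size)
    for k, c in enumerate(centers):
        lo = max(0, c - w // 2)
        win = x[lo : min(n, c + w // 2 + 1)]
        mad[k] = np.median(np.abs(win - np.median(win)))
    noise = np.interp(np.arange(n), centers, 1.4826 * mad)
    floor = max(1e-12, 1e-9 * float(np.max(x, initial=0.0)))
    return np.maximum(noise, floor)


def _raw_scale_amplitude(height: np.ndarray, baseline_at: np.ndarray) -> np.ndarray:
    # inverse of the sqrt transform above the baseline:
    # (h + b)^2 - b^2 on the sqrt scale == linear-scale amplitude
    return (height + baseline_at) ** 2 - baseline_at**2


def detect_peaks(
    s: RawSpectrum,
    params: PreprocessParams = PreprocessParams(),
    noise: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
) -> PeakList:
    """SNR-thresholded local-maximum peak picking on a corrected spectrum.

    A peak is a point strictly greater than all neighbours within
    ``local_max_half_window`` grid points whose apex is at least
    ``snr_threshold`` times the local noise.  Maxima closer together than
    the matching tolerance (two candidates on one broad peak top) are merged,
    keeping the higher apex.  When ``baseline`` is given the reported
    intensity is back-transformed to the linear scale; otherwise it is the
    apex height.
    """
    x = s.intensity
    if noise is None:
        noise = estimate_noise(s, params.noise_window)
    order = max(1, int(params.local_max_half_window))
    (idx,) = argrelmax(x, order=order)
    if idx.size:
        keep = x[idx] >= params.snr_threshold * noise[idx]
        idx = idx[keep]
    if idx.size > 1:
        # merge candidates within the m/z matching tolerance (broad peaks at
        # high mass span many grid points and can carry several noise maxima)
        by_height = idx[np.argsort(x[idx])[::-1]]
        kept: list[int] = []
        for i in by_height:
            mzi = s.mz[i]
            if all(abs(mzi - s.mz[j]) > params.tolerance_da(mzi) for j in kept):
                kept.append(i)
        idx = np.sort(np.asarray(kept))
    height = x[idx]
    snr = height / noise[idx]
    if baseline is not None:
        intensity = _raw_scale_amplitude(height, baseline[idx])
    else:
        intensity = height.copy()
    # centroid refinement: on broad high-mass peaks the grid argmax wanders
    # by several Da on the noisy flat top; the intensity-weighted centroid
    # over +/- half the matching tolerance localises the apex far better
    mz_peaks = s.mz[idx].copy()
    for k, i in enumerate(idx):
        half = 0.5 * params.tolerance_da(s.mz[i])
        lo = np.searchsorted(s.mz, s.mz[i] - half)
        hi = np.searchsorted(s.mz, s.mz[i] + half, side="right")
        w = np.clip(x[lo:hi], 0.0, None)
        if w.sum() > 0:
            mz_peaks[k] = float(np.average(s.mz[lo:hi], weights=w))
    return PeakList(mz_peaks, intensity, snr, height=height, meta=s.meta)


def normalize_median_to_one(s: RawSpectrum, peaks: PeakList) -> tuple[RawSpectrum, PeakList]:
    """Divide spectrum and peak intensities by the median peak intensity.

    After the call the median of the returned peak intensities is exactly 1.
    """
    if len(peaks) == 0:
        raise ValueError("cannot normalize: no detected peaks")
    m = float(np.median(peaks.intensity))
    if m <= 0:
        raise ValueError("cannot normalize: median peak intensity is zero")
    return s.with_intensity(s.intensity / m), peaks.scaled(m)


def anchor_prealign(
    s: RawSpectrum,
    peaks: PeakList,
    anchor_masses: Sequence[float] = (4078.8, 14019.1),
    params: PreprocessParams = PreprocessParams(),
) -> tuple[RawSpectrum, PeakList, dict]:
    """Affine m/z correction fitted to conserved anchor peaks.

    The nearest detected peak within tolerance is matched to each anchor; one
    match gives a shift, two or more a least-squares shift+scale.  With no
    match the mapping is the identity (recorded, with a warning).
    """
    matched_obs, matched_ref = [], []
    for a in anchor_masses:
        if len(peaks) == 0:
            break
        j = int(np.argmin(np.abs(peaks.mz - a)))
        if abs(peaks.mz[j] - a) <= params.tolerance_da(a):
            matched_obs.append(peaks.mz[j])
            matched_ref.append(a)
    info = {"anchors": list(anchor_masses), "matched": matched_obs}
    if not matched_obs:
        log.warning("%s: no anchor peak matched; identity pre-alignment",
                    s.meta.sample_id or "<spectrum>")
        info.update(slope=1.0, offset=0.0)
        return s, peaks, info
    obs = np.asarray(matched_obs)
    ref = np.asarray(matched_ref)
    if obs.size == 1:
        slope, offset = 1.0, float(ref[0] - obs[0])
    else:
        slope, offset = np.polyfit(obs, ref, 1)
        slope = float(slope)
        offset = float(offset)
    info.update(slope=slope, offset=offset)
    return (
        s.with_mz(slope * s.mz + offset),
        peaks.with_mz(slope * peaks.mz + offset),
        info,
    )


# ---------------------------------------------------------------------------
# LOWESS warping alignment


def _reference_peaks(
    peaklists: Sequence[PeakList], params: PreprocessParams
) -> np.ndarray:
    """Consensus masses of peaks present in >= align_min_frequency of spectra."""
    mzs = np.concatenate([p.mz for p in peaklists])
    ints = np.concatenate([p.intensity for p in peaklists])
    sids = np.concatenate(
        [np.full(len(p), i) for i, p in enumerate(peaklists)]
    )
    bins = greedy_bin(mzs, ints, sids, params.match_tolerance_rel)
    need = params.align_min_frequency * len(peaklists)
    return np.asarray(
        [b.mz for b in bins if np.unique(b.spectrum_ids).size >= need]
    )


def _fit_warp(
    obs: np.ndarray, ref: np.ndarray, mz_axis: np.ndarray, params: PreprocessParams
) -> np.ndarray:
    """Fit shift = f(observed m/z) by robust LOWESS; return per-point shift."""
    shift = ref - obs
    fitted = _lowess(
        shift,
        obs,
        frac=params.lowess_span,
        it=params.lowess_iterations,
        return_sorted=True,
    )
    return np.interp(mz_axis, fitted[:, 0], fitted[:, 1])


def _ensure_strictly_increasing(mz: np.ndarray) -> np.ndarray:
    """Isotonic repair: cumulative max plus a vanishing ramp on flat runs."""
    if np.all(np.diff(mz) > 0):
        return mz
    out = np.maximum.accumulate(mz)
    flat = np.diff(out) <= 0
    if np.any(flat):
        eps = 1e-9 * max(1.0, float(out[-1]))
        out = out + eps * np.arange(out.size)
        out = np.maximum.accumulate(out)
    return out


def warp_align(
    spectra: Sequence[RawSpectrum],
    peaklists: Sequence[PeakList],
    params: PreprocessParams = PreprocessParams(),
) -> tuple[list[RawSpectrum], list[PeakList], list[dict]]:
    """LOWESS warping alignment of a batch of spectra.

    A reference peak set is built from peaks recurring in at least
    ``align_min_frequency`` of the spectra; per spectrum, a LOWESS curve of
    (observed m/z, reference - observed) over matched reference peaks defines
    a smooth monotone warp applied to the m/z axis and peak positions.
    Spectra with fewer than ``align_min_peaks`` matches keep their current
    (anchor-corrected) axis, recorded in the returned info.
    """
    if len(spectra) != len(peaklists):
        raise ValueError("spectra and peak lists must be parallel")
    if len(spectra) < 2:
        return list(spectra), list(peaklists), [{"warp": "identity"} for _ in spectra]
    ref = _reference_peaks(peaklists, params)
    out_s: list[RawSpectrum] = []
    out_p: list[PeakList] = []
    infos: list[dict] = []
    for s, p in zip(spectra, peaklists):
        obs_list, ref_list = [], []
        for r in ref:
            if len(p) == 0:
                break
            j = int(np.argmin(np.abs(p.mz - r)))
            if abs(p.mz[j] - r) <= params.tolerance_da(r):
                obs_list.append(p.mz[j])
                ref_list.append(r)
        if len(obs_list) < params.align_min_peaks:
            log.warning(
                "%s: only %d reference peaks matched; keeping anchor mapping",
                s.meta.sample_id or "<spectrum>", len(obs_list),
            )
            out_s.append(s)
            out_p.append(p)
            infos.append({"warp": "fallback", "n_matched": len(obs_list)})
            continue
        shift = _fit_warp(np.asarray(obs_list), np.asarray(ref_list), s.mz, params)
        new_mz = _ensure_strictly_increasing(s.mz + shift)
        out_s.append(s.with_mz(new_mz))
        out_p.append(p.with_mz(np.interp(p.mz, s.mz, new_mz)))
        infos.append({"warp": "lowess", "n_matched": len(obs_list)})
    return out_s, out_p, infos


# ---------------------------------------------------------------------------
# full chain


def _preprocess_single(raw: RawSpectrum, params: PreprocessParams) -> ProcessedSpectrum:
    """sqrt -> smooth -> TopHat -> noise -> provisional peaks -> normalize -> anchors."""
    s = raw.crop(*params.mass_range)
    prov: list[tuple[str, dict]] = [("crop", {"mass_range": params.mass_range})]
    s = sqrt_transform(s)
    prov.append(("sqrt_transform", {}))
    unsmoothed = s.intensity
    s = smooth_savitzky_golay(s, params.sg_window, params.sg_polyorder)
    prov.append(("smooth_savitzky_golay",
                 {"window": params.sg_window, "polyorder": params.sg_polyorder}))
    baseline, s = baseline_tophat(s, params.tophat_half_window)
    prov.append(("baseline_tophat", {"half_window": params.tophat_half_window}))
    # noise level of the acquisition, not of the smoothed trace: the MAD is
    # taken on the unsmoothed baseline-corrected signal (unclipped), so an
    # SNR-3 cut refers to the physical noise and smoothing cannot inflate SNR
    noise = estimate_noise(
        s.with_intensity(unsmoothed - baseline), params.noise_window
    )
    prov.append(("estimate_noise", {"window": params.noise_window}))

    peaks = detect_peaks(s, params, noise=noise, baseline=baseline)
    prov.append(("detect_peaks_provisional",
                 {"snr_threshold": params.snr_threshold, "n": len(peaks)}))
    if len(peaks) == 0:
        raise ValueError(
            f"{raw.meta.sample_id or '<spectrum>'}: no peaks detected; "
            "cannot median-normalize"
        )
    m = float(np.median(peaks.intensity))
    if m <= 0:
        raise ValueError("median peak intensity is zero")
    # dividing linear-scale amplitudes by m == dividing sqrt-scale signal,
    # baseline and noise by sqrt(m)
    root = np.sqrt(m)
    s = s.with_intensity(s.intensity / root)
    baseline = baseline / root
    noise = noise / root
    peaks = peaks.scaled(m)
    prov.append(("normalize_median_to_one", {"median": m}))

    s, peaks, info = anchor_prealign(s, peaks, params.anchor_masses, params)
    prov.append(("anchor_prealign", info))

    ps = ProcessedSpectrum(
        mz=s.mz,
        intensity=s.intensity,
        baseline=baseline,
        noise=noise,
        meta=raw.meta,
        norm_factor=m,
        provenance=prov,
    )
    ps._provisional_peaks = peaks  # type: ignore[attr-defined]
    return ps


def preprocess_experiment(
    spectra: Sequence[RawSpectrum],
    params: PreprocessParams = PreprocessParams(),
) -> tuple[list[ProcessedSpectrum], list[PeakList]]:
    """Run the full chain on a batch and return aligned spectra + final peaks.

    Pipeline order: sqrt -> smooth -> baseline -> normalize -> (anchor,
    LOWESS) alignment -> final peak detection.  The provisional detection
    pass feeds normalization and alignment only; the returned peak lists come
    from a second pass on the aligned spectra, with intensities on the
    normalized linear scale.
    """
    states = [_preprocess_single(raw, params) for raw in spectra]
    carriers = [RawSpectrum(st.mz, st.intensity, st.meta) for st in states]
    prov_peaks = [st._provisional_peaks for st in states]  # type: ignore[attr-defined]
    aligned, _, infos = warp_align(carriers, prov_peaks, params)
    final_peaks: list[PeakList] = []
    for st, al, info in zip(states, aligned, infos):
        st.mz = al.mz
        st.record("warp_align", **info)
        pk = detect_peaks(
            RawSpectrum(st.mz, st.intensity, st.meta),
            params,
            noise=st.noise,
            baseline=st.baseline,
        )
        st.record("detect_peaks_final", snr_threshold=params.snr_threshold, n=len(pk))
        final_peaks.append(pk)
    return states, final_peaks
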