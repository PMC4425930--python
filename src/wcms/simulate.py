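"""Synthetic whole-cell MALDI-TOF experiments with full ground truth.

The generator emulates linear-mode profile acquisitions of crude monocyte
lysates over m/z 3,000-30,000: a smooth decaying chemical baseline, dozens to
hundreds of Gaussian protein peaks, shot-noise-like heteroscedastic noise, a
smooth per-spectrum mass-axis miscalibration, quadruplicate technical spots,
and planted group structure — population marker peaks, stimulation-responsive
peaks, and precursor/+80 Da pairs whose intensities trade off against each
other as a phosphorylation-like modification is induced.

Every spectrum is a pure function of ``(design.seed, donor, population,
condition, replicate)``; the accompanying :class:`SimTruth` records everything
needed to score a downstream analysis against the planted signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .spectrum import RawSpectrum, SpectrumMeta

__all__ = [
    "PeakSpec",
    "ShiftPairSpec",
    "SimDesign",
    "SimTruth",
    "make_default_panel",
    "default_design",
    "render_spectrum",
    "simulate_experiment",
    "PanelError",
]

GroupKey = tuple[str, str]  # (population, condition)


class PanelError(ValueError):
    """Raised when a peak panel cannot be packed into the mass range."""


@dataclass(frozen=True)
class PeakSpec:
    """One planted protein peak.

    ``group_multipliers`` maps (population, condition) to a positive intensity
    multiplier; missing groups default to 1 (no effect).
    """

    mz_true: float
    base_intensity: float
    width_sigma: float
    group_multipliers: Mapping[GroupKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if not 0 < self.width_sigma < 0.01 * self.mz_true:
            raise ValueError("width_sigma must be in (0, 0.01 * mz_true)")
        if any(v <= 0 for v in self.group_multipliers.values()):
            raise ValueError("group multipliers must be > 0")

    def multiplier(self, population: str, condition: str) -> float:
        return float(self.group_multipliers.get((population, condition), 1.0))


@dataclass(frozen=True)
class ShiftPairSpec:
    """A precursor peak plus its +delta modified form.

    ``transfer_fraction`` gives, per (population, condition), the fraction of
    the precursor's intensity moved to the shifted peak (phosphorylation-like
    conversion: precursor keeps ``1 - f``, the +delta form receives ``f``).
    """

    precursor: PeakSpec
    delta: float = 80.0
    transfer_fraction: Mapping[GroupKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if any(not 0 <= v <= 1 for v in self.transfer_fraction.values()):
            raise ValueError("transfer fractions must lie in [0, 1]")

    @property
    def mz_shifted(self) -> float:
        return self.precursor.mz_true + self.delta

    def fraction(self, population: str, condition: str) -> float:
        return float(self.transfer_fraction.get((population, condition), 0.0))


@dataclass(frozen=True)
class SimDesign:
    """Experimental layout and physical parameters of a simulated study.

    Defaults reproduce the study design emulated throughout the package:
    two monocyte preparations (pan vs CD16+), three conditions (resting, LPS,
    PPD), eight donors, quadruplicate spots, m/z 3,000-30,000 on a 1 Da grid.
    """

    populations: tuple[str, ...] = ("pan", "cd16")
    conditions: tuple[str, ...] = ("resting", "lps", "ppd")
    n_donors: int = 8
    n_replicates: int = 4
    mass_range: tuple[float, float] = (3000.0, 30000.0)
    sampling_step: float = 1.0
    # double-exponential chemical baseline: a1*exp(-mz/tau1) + a2*exp(-mz/tau2)
    baseline_amp: tuple[float, float] = (150.0, 12.0)
    baseline_tau: tuple[float, float] = (1200.0, 9000.0)
    noise_sigma_rel: float = 0.25
    noise_floor: float = 1.0
    warp_amplitude: float = 3.0
    population_effect_sd: float = 0.25  # broad fingerprint difference between cell types
    donor_sd: float = 0.15
    donor_peak_sd: float = 0.20  # per-(donor, protein) biological variability
    donor_peak_correlation: float = 0.5  # of that, share common to both cell types
    replicate_sd: float = 0.10
    peak_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError("mass_range must satisfy low < high")
        if min(self.n_donors, self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if len(self.populations) < 1 or len(self.conditions) < 1:
            raise ValueError("need at least one population and condition")
        for name in ("sampling_step",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "noise_sigma_rel",
            "noise_floor",
            "warp_amplitude",
            "population_effect_sd",
            "donor_sd",
            "donor_peak_sd",
            "replicate_sd",
            "peak_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.donor_peak_correlation <= 1:
            raise ValueError("donor_peak_correlation must be in [0, 1]")

    @property
    def n_spectra(self) -> int:
        return (
            self.n_donors
            * len(self.populations)
            * len(self.conditions)
            * self.n_replicates
        )

    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mass_range
        return np.arange(lo, hi + 0.5 * self.sampling_step, self.sampling_step)

    def baseline(self, mz: np.ndarray) -> np.ndarray:
        (a1, a2), (t1, t2) = self.baseline_amp, self.baseline_tau
        return a1 * np.exp(-mz / t1) + a2 * np.exp(-mz / t2)

    def groups(self) -> list[GroupKey]:
        return [(p, c) for p in self.populations for c in self.conditions]


def default_design(seed: int = 0, **overrides) -> SimDesign:
    """The package's default study layout with an explicit seed."""
    return SimDesign(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# deterministic RNG plumbing


def _rng(design: SimDesign, *key: int | str) -> np.random.Generator:
    ints = [design.seed]
    for k in key:
        if isinstance(k, str):
            ints.extend(k.encode())
        else:
            ints.append(int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


def _donor_gain(design: SimDesign, donor_index: int) -> float:
    if design.donor_sd == 0:
        return 1.0
    g = _rng(design, "donor", donor_index)
    return float(np.exp(design.donor_sd * g.standard_normal()))


def sample_id(donor_index: int, population: str, condition: str, replicate: int) -> str:
    return f"d{donor_index + 1:02d}_{population}_{condition}_r{replicate}"


# ---------------------------------------------------------------------------
# panel construction


DEFAULT_PANEL = dict(n_common=80, n_pop_markers=12, n_cond_markers=8, n_shift_pairs=1)
ANCHOR_MASSES = (4078.8, 14019.1)
_WIDTH_REL = 0.0008  # linear-mode width: sigma = 0.0008 * m/z


def _default_sigma(mz: float) -> float:
    return _WIDTH_REL * mz


def amplitude_for_snr(mz: float, snr: float, design: SimDesign) -> float:
    """Apex amplitude that yields the requested SNR at mass ``mz``.

    SNR is defined on the variance-stabilised (sqrt) scale, where the noise
    model sd = noise_sigma_rel * sqrt(x + floor) becomes approximately
    constant; the local chemical baseline raises the noise floor, so the same
    SNR needs a larger amplitude at low mass.  Solved by bisection.
    """
    if design.noise_sigma_rel == 0:
        return snr  # noise-free: any positive amplitude; return snr as scale

    b = float(design.baseline(np.asarray([mz]))[0])
    r, floor = design.noise_sigma_rel, design.noise_floor

    def measured(a: float) -> float:
        tot = b + a
        sd = r * np.sqrt(tot + floor) / (2.0 * np.sqrt(tot))
        return (np.sqrt(tot) - np.sqrt(b)) / sd

    from scipy.optimize import brentq

    hi = 10.0
    while measured(hi) < snr:
        hi *= 4.0
    return float(brentq(lambda a: measured(a) - snr, 1e-9, hi, xtol=1e-9))


def make_default_panel(
    n_common: int,
    n_pop_markers: int,
    n_cond_markers: int,
    n_shift_pairs: int,
    seed: int,
    populations: Sequence[str] = ("pan", "cd16"),
    conditions: Sequence[str] = ("resting", "lps", "ppd"),
    mass_range: tuple[float, float] = (3000.0, 30000.0),
    design: SimDesign | None = None,
    snr_range: tuple[float, float] = (5.0, 70.0),
) -> tuple[list[PeakSpec], list[ShiftPairSpec]]:
    """Build a deterministic peak panel with planted group effects.

    Base intensities are drawn so that planted apex SNR (at multiplier 1,
    under ``design``'s baseline and noise model) is log-uniform over
    ``snr_range`` — every planted peak is in principle detectable at an
    SNR-3 cut, with a tail near the limit.  Common peaks (including the two
    conserved calibrant peaks at 4078.8 and 14019.1 when they fit) carry no
    group effect.  Population markers get a multiplier drawn from U(2.5, 10)
    in one population across all conditions.  Condition markers respond to
    LPS and/or PPD (multiplier U(2.5, 6)) in one or both populations.  Shift
    pairs place a +80 Da partner whose intensity is fed by the precursor
    under one stimulated group (transfer fraction 0.5), the
    phosphorylation-like pattern.
    """
    if design is None:
        design = SimDesign(
            populations=tuple(populations),
            conditions=tuple(conditions),
            mass_range=mass_range,
        )
    for name, v in (
        ("n_common", n_common),
        ("n_pop_markers", n_pop_markers),
        ("n_cond_markers", n_cond_markers),
        ("n_shift_pairs", n_shift_pairs),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7E1]))
    lo, hi = mass_range
    margin = 300.0
    positions: list[float] = []  # occupied centers (incl. shifted partners)

    def fits(mz: float) -> bool:
        if not lo + margin <= mz <= hi - margin:
            return False
        s = 5.0 * _default_sigma(mz)
        return all(abs(mz - q) >= max(s, 5.0 * _default_sigma(q)) for q in positions)

    def place(extra_partner: float | None = None) -> float:
        for _ in range(20000):
            mz = float(np.exp(rng.uniform(np.log(lo + margin), np.log(hi - margin))))
            if fits(mz) and (extra_partner is None or fits(mz + extra_partner)):
                positions.append(mz)
                if extra_partner is not None:
                    positions.append(mz + extra_partner)
                return mz
        raise PanelError(
            "could not pack the requested number of peaks into the mass range"
        )

    def intensity(mz: float, lo_snr: float | None = None, hi_snr: float | None = None) -> float:
        snr = float(
            np.exp(rng.uniform(np.log(lo_snr or snr_range[0]),
                               np.log(hi_snr or snr_range[1])))
        )
        return amplitude_for_snr(mz, snr, design)

    peaks: list[PeakSpec] = []
    # conserved anchor peaks first, as bright common peaks
    n_anchors = 0
    if n_common >= 2:
        for a in ANCHOR_MASSES:
            if lo + margin <= a <= hi - margin and fits(a):
                positions.append(a)
                peaks.append(
                    PeakSpec(a, amplitude_for_snr(a, 40.0, design), _default_sigma(a))
                )
                n_anchors += 1
    for _ in range(n_common - n_anchors):
        mz = place()
        peaks.append(PeakSpec(mz, intensity(mz), _default_sigma(mz)))

    stimulated = [c for c in conditions if c != conditions[0]]
    for i in range(n_pop_markers):
        mz = place()
        pop = populations[i % len(populations)]
        mult = float(rng.uniform(2.5, 10.0))
        mults = {(pop, c): mult for c in conditions}
        peaks.append(PeakSpec(mz, intensity(mz), _default_sigma(mz), mults))

    for i in range(n_cond_markers):
        mz = place()
        mult = float(rng.uniform(2.5, 6.0))
        which_pops = [
            list(populations),
            [populations[0]],
            [populations[-1]],
        ][int(rng.integers(3))]
        which_conds = (
            [stimulated, stimulated[:1], stimulated[-1:]][int(rng.integers(3))]
            if stimulated
            else [conditions[0]]
        )
        mults = {(p, c): mult for p in which_pops for c in which_conds}
        peaks.append(PeakSpec(mz, intensity(mz), _default_sigma(mz), mults))

    pairs: list[ShiftPairSpec] = []
    combos: list[GroupKey] = [
        (p, c) for c in stimulated for p in reversed(list(populations))
    ] or [(populations[0], conditions[0])]
    for i in range(n_shift_pairs):
        mz = place(extra_partner=80.0)
        # precursor SNR >= 20 so both halves stay reliably detectable at
        # f = 0.5 even under donor-level abundance variability
        prec = PeakSpec(mz, intensity(mz, 20.0, 60.0), _default_sigma(mz))
        frac = {g: 0.0 for p in populations for g in [(p, c) for c in conditions]}
        frac[combos[i % len(combos)]] = 0.5
        pairs.append(ShiftPairSpec(prec, 80.0, frac))

    return peaks, pairs


def default_panel(seed: int = 0) -> tuple[list[PeakSpec], list[ShiftPairSpec]]:
    """The default panel at the package's standard composition."""
    return make_default_panel(seed=seed, **DEFAULT_PANEL)


# ---------------------------------------------------------------------------
# rendering


def _warp_coeffs(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """Quadratic mass-axis displacement coefficients, bounded by warp_amplitude."""
    c = rng.uniform(-1.0, 1.0, size=3)
    u = np.linspace(0.0, 1.0, 101)
    d = c[0] + c[1] * u + c[2] * u**2
    peak = np.max(np.abs(d))
    target = design.warp_amplitude * rng.uniform(0.3, 1.0)
    if design.warp_amplitude == 0 or peak == 0:
        return np.zeros(3)
    return c * (target / peak)


def _displacement(coeffs: np.ndarray, mz, mass_range: tuple[float, float]):
    lo, hi = mass_range
    u = (np.asarray(mz, dtype=float) - lo) / (hi - lo)
    return coeffs[0] + coeffs[1] * u + coeffs[2] * u**2


def _population_factors(
    design: SimDesign, population: str, common_mask: np.ndarray
) -> np.ndarray:
    """Cell-type fingerprint factors for the panel's common peaks.

    Whole-cell fingerprints of distinct cell types differ broadly and
    modestly across most proteins, not only at the strong marker peaks; each
    (population, common peak) gets a log-normal factor with sd
    ``population_effect_sd``, identical for all donors.  The factors are
    centred so their sample median is exactly 1: under per-spectrum median
    normalization a global level difference between populations is
    unidentifiable, so planted effects are level-neutral redistributions.
    """
    f = np.ones(common_mask.size)
    if design.population_effect_sd == 0 or not common_mask.any():
        return f
    g = _rng(design, "popfingerprint", design.populations.index(population))
    z = g.standard_normal(common_mask.size)
    raw = np.exp(design.population_effect_sd * z[common_mask])
    f[common_mask] = raw / np.median(raw)
    return f


def _effective_peaks(
    panel_peaks: Sequence[PeakSpec],
    panel_pairs: Sequence[ShiftPairSpec],
    design: SimDesign,
    population: str,
    condition: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand the panel into per-group (mz, amplitude, sigma) arrays.

    Common peaks (no explicit multipliers) carry the broad population
    fingerprint factor; marker peaks carry exactly their multipliers.  Shift
    pairs contribute two entries: the precursor at (1 - f) and the shifted
    form at f times the precursor's group amplitude.
    """
    common_mask = np.asarray([not p.group_multipliers for p in panel_peaks])
    pop_f = _population_factors(design, population, common_mask)
    mzs, amps, sigs = [], [], []
    for i, p in enumerate(panel_peaks):
        mzs.append(p.mz_true)
        amps.append(p.base_intensity * p.multiplier(population, condition) * pop_f[i])
        sigs.append(p.width_sigma)
    for pair in panel_pairs:
        f = pair.fraction(population, condition)
        a = pair.precursor.base_intensity * pair.precursor.multiplier(
            population, condition
        )
        mzs.extend([pair.precursor.mz_true, pair.mz_shifted])
        amps.extend([a * (1.0 - f), a * f])
        sigs.extend([pair.precursor.width_sigma] * 2)
    return np.asarray(mzs), np.asarray(amps), np.asarray(sigs)


def render_spectrum(
    panel_peaks: Sequence[PeakSpec],
    panel_pairs: Sequence[ShiftPairSpec],
    design: SimDesign,
    donor_index: int,
    population: str,
    condition: str,
    replicate: int,
) -> RawSpectrum:
    """Render one technical-replicate spot deterministically.

    intensity(m/z) = baseline + sum of Gaussians at warped centers, scaled by
    group multiplier and donor/replicate/per-peak log-normal gains, plus
    heteroscedastic Gaussian noise with sd = noise_sigma_rel *
    sqrt(signal + noise_floor), clipped at zero.
    """
    if population not in design.populations:
        raise ValueError(f"unknown population {population!r}")
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if not 0 <= donor_index < design.n_donors:
        raise ValueError("donor index out of range")
    if not 1 <= replicate <= design.n_replicates:
        raise ValueError("replicate index out of range")

    rng = _rng(
        design,
        "spectrum",
        donor_index,
        design.populations.index(population),
        design.conditions.index(condition),
        replicate,
    )
    mz = design.mz_axis()
    clean = design.baseline(mz)

    rep_gain = (
        float(np.exp(design.replicate_sd * rng.standard_normal()))
        if design.replicate_sd
        else 1.0
    )
    gain = _donor_gain(design, donor_index) * rep_gain
    coeffs = _warp_coeffs(design, rng)

    pk_mz, pk_amp, pk_sig = _effective_peaks(
        panel_peaks, panel_pairs, design, population, condition
    )
    jitter = (
        np.exp(design.peak_jitter_sd * rng.standard_normal(pk_mz.size))
        if design.peak_jitter_sd and pk_mz.size
        else np.ones(pk_mz.size)
    )
    if design.donor_peak_sd and pk_mz.size:
        # biological inter-individual abundance variation: partially shared
        # between a donor's two cell preparations (distinct cell types have
        # correlated but not identical per-protein deviations)
        rho = design.donor_peak_correlation
        z_shared = _rng(design, "donorpeak", donor_index).standard_normal(pk_mz.size)
        z_pop = _rng(
            design, "donorpeak", donor_index,
            design.populations.index(population),
        ).standard_normal(pk_mz.size)
        z = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_pop
        jitter = jitter * np.exp(design.donor_peak_sd * z)
    centers = pk_mz + _displacement(coeffs, pk_mz, design.mass_range)
    step = design.sampling_step
    for c, a, s, j in zip(centers, pk_amp, pk_sig, jitter):
        if a == 0:
            continue
        i0 = max(0, int((c - 6 * s - mz[0]) / step))
        i1 = min(mz.size, int((c + 6 * s - mz[0]) / step) + 2)
        win = mz[i0:i1]
        clean[i0:i1] += a * gain * j * np.exp(-0.5 * ((win - c) / s) ** 2)

    if design.noise_sigma_rel > 0:
        sd = design.noise_sigma_rel * np.sqrt(clean + design.noise_floor)
        clean = clean + sd * rng.standard_normal(mz.size)
    intensity = np.clip(clean, 0.0, None)
    meta = SpectrumMeta(
        sample_id=sample_id(donor_index, population, condition, replicate),
        donor=f"d{donor_index + 1:02d}",
        population=population,
        condition=condition,
        replicate=replicate,
    )
    return RawSpectrum(mz, intensity, meta)


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    design: SimDesign
    peak_specs: list[PeakSpec]
    shift_pairs: list[ShiftPairSpec]
    warp_coeffs: dict[str, tuple[float, float, float]]

    def displacement(self, sid: str, mz) -> np.ndarray:
        """Planted mass-axis displacement of spectrum ``sid`` at ``mz``."""
        return _displacement(
            np.asarray(self.warp_coeffs[sid]), mz, self.design.mass_range
        )

    def true_masses(self) -> np.ndarray:
        """All planted apex masses (pairs contribute precursor and +delta)."""
        mzs = [p.mz_true for p in self.peak_specs]
        for pair in self.shift_pairs:
            mzs.extend([pair.precursor.mz_true, pair.mz_shifted])
        return np.asarray(sorted(mzs))

    def group_amplitude(self, population: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """(mz, noise-free apex amplitude) for one group, gains at 1."""
        mz, amp, _ = _effective_peaks(
            self.peak_specs, self.shift_pairs, self.design, population, condition
        )
        order = np.argsort(mz)
        return mz[order], amp[order]

    def true_fold_change(
        self, pop_a: str, pop_b: str, condition: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(mz, planted amplitude ratio pop_a / pop_b) per planted mass.

        Averaged over conditions unless one is named; includes marker
        multipliers, population fingerprint factors and shift-pair transfer.
        """
        conds = [condition] if condition else list(self.design.conditions)
        num = den = None
        for c in conds:
            mz, a = self.group_amplitude(pop_a, c)
            _, b = self.group_amplitude(pop_b, c)
            num = a if num is None else num + a
            den = b if den is None else den + b
        with np.errstate(divide="ignore", invalid="ignore"):
            return mz, np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)

    def planted_snr(self, population: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Per planted peak, apex SNR on the variance-stabilised (sqrt) scale.

        With noise sd = r*sqrt(x + floor) on the linear scale, the sqrt-scale
        noise sd at level x is ~ r*sqrt(x + floor) / (2*sqrt(x)); the apex
        amplitude above baseline b is sqrt(b + a) - sqrt(b).
        """
        d = self.design
        mz, amp = self.group_amplitude(population, condition)
        b = d.baseline(mz)
        amp_sqrt = np.sqrt(b + amp) - np.sqrt(b)
        if d.noise_sigma_rel == 0:
            return mz, np.full(mz.size, np.inf)
        with np.errstate(divide="ignore"):
            sd = (
                d.noise_sigma_rel
                * np.sqrt(b + amp + d.noise_floor)
                / (2.0 * np.sqrt(b + amp))
            )
        return mz, np.where(amp > 0, amp_sqrt / sd, 0.0)

    def min_planted_snr(self) -> tuple[np.ndarray, np.ndarray]:
        """Per planted mass, the minimum SNR across all design groups."""
        masses = self.true_masses()
        snr = np.full(masses.size, np.inf)
        for pop, cond in self.design.groups():
            mz, s = self.planted_snr(pop, cond)
            order = np.argsort(mz)
            snr = np.minimum(snr, s[order][np.searchsorted(mz[order], masses)])
        return masses, snr

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        def peak(p: PeakSpec) -> dict:
            return {
                "mz_true": p.mz_true,
                "base_intensity": p.base_intensity,
                "width_sigma": p.width_sigma,
                "group_multipliers": [
                    [list(k), v] for k, v in p.group_multipliers.items()
                ],
            }

        payload = {
            "design": asdict(self.design),
            "peak_specs": [peak(p) for p in self.peak_specs],
            "shift_pairs": [
                {
                    "precursor": peak(pr.precursor),
                    "delta": pr.delta,
                    "transfer_fraction": [
                        [list(k), v] for k, v in pr.transfer_fraction.items()
                    ],
                }
                for pr in self.shift_pairs
            ],
            "warp_coeffs": {k: list(v) for k, v in self.warp_coeffs.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        raw = json.loads(text)

        def peak(d: dict) -> PeakSpec:
            return PeakSpec(
                d["mz_true"],
                d["base_intensity"],
                d["width_sigma"],
                {tuple(k): v for k, v in d["group_multipliers"]},
            )

        dd = raw["design"]
        for key in ("populations", "conditions", "mass_range", "baseline_amp", "baseline_tau"):
            dd[key] = tuple(dd[key])
        return cls(
            design=SimDesign(**dd),
            peak_specs=[peak(p) for p in raw["peak_specs"]],
            shift_pairs=[
                ShiftPairSpec(
                    peak(p["precursor"]),
                    p["delta"],
                    {tuple(k): v for k, v in p["transfer_fraction"]},
                )
                for p in raw["shift_pairs"]
            ],
            warp_coeffs={k: tuple(v) for k, v in raw["warp_coeffs"].items()},
        )


def simulate_experiment(
    design: SimDesign,
    panel: tuple[Sequence[PeakSpec], Sequence[ShiftPairSpec]] | None = None,
) -> tuple[list[RawSpectrum], SimTruth]:
    """Render the full donor x population x condition x replicate experiment."""
    if panel is None:
        panel = default_panel(design.seed)
    peaks, pairs = panel
    spectra: list[RawSpectrum] = []
    warps: dict[str, tuple[float, float, float]] = {}
    for donor in range(design.n_donors):
        for pop in design.populations:
            for cond in design.conditions:
                for rep in range(1, design.n_replicates + 1):
                    s = render_spectrum(peaks, pairs, design, donor, pop, cond, rep)
                    spectra.append(s)
                    # re-derive the warp coefficients from the same stream
                    rng = _rng(
                        design,
                        "spectrum",
                        donor,
                        design.populations.index(pop),
                        design.conditions.index(cond),
                        rep,
                    )
                    if design.replicate_sd:
                        rng.standard_normal()
                    warps[s.meta.sample_id] = tuple(_warp_coeffs(design, rng))
    truth = SimTruth(design, list(peaks), list(pairs), warps)
    return spectra, truth
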