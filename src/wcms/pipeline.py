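"""End-to-end orchestration: simulate -> preprocess -> matrix -> stats.

One :class:`RunConfig` drives the whole chain; every run writes its resolved
configuration, a manifest with a config hash, and all tabular outputs as CSV
into the run directory.  Re-running with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, simulate, spectra_io
from .diffstats import (
    condition_contrast_sets,
    find_shift_pairs,
    fold_change,
    pca_correlation,
    select_biomarkers,
    two_way_anova_per_feature,
)
from .peakmatrix import bin_peaks, build_matrix, filter_features
from .preprocess import PreprocessParams, preprocess_experiment

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report_summary", "PipelineError"]

RESULT_FILES = [
    "peaks.csv",
    "matrix.csv",
    "factors.csv",
    "anova.csv",
    "biomarkers.csv",
    "pairs.csv",
    "pca_scores.csv",
    "pca_variance.csv",
    "condition_sets.json",
    "manifest.json",
]


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``sim`` is set (synthetic experiment, rendered at run time) or
    ``input_dir`` points to a directory with mzXML spectra plus a sample
    sheet.  ``seed`` overrides the simulation seed so one config file can
    serve many replicated runs.
    """

    out_dir: str = "wcms_run"
    seed: int = 0
    sim: simulate.SimDesign | None = field(default_factory=simulate.SimDesign)
    input_dir: str | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    bin_tolerance_rel: float = 0.002
    min_frequency: float = 0.9
    average: str = "detected"
    alpha: float = 0.001
    fc_threshold: float = 2.0
    delta: float = 80.0
    pair_tolerance: float = 1.0
    write_spectra: bool = False

    def __post_init__(self) -> None:
        for name in ("bin_tolerance_rel", "alpha", "fc_threshold", "delta", "pair_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sim is None and self.input_dir is None:
            raise ValueError("either sim or input_dir must be given")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            for key in ("populations", "conditions", "mass_range", "baseline_amp", "baseline_tau"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["sim"] = simulate.SimDesign(**sim)
        if d.get("preprocess") is not None:
            pp = dict(d["preprocess"])
            for key in ("mass_range", "anchor_masses"):
                if key in pp:
                    pp[key] = tuple(pp[key])
            d["preprocess"] = PreprocessParams(**pp)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Run the full chain and write all outputs into ``config.out_dir``.

    Dataflow is strictly forward (simulate/load -> preprocess -> matrix ->
    stats); any stage error aborts the run with a stage-labelled message.
    Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- acquire spectra ---------------------------------------------------
    truth = None
    if config.input_dir is not None:
        spectra, sheet = _stage("load")(spectra_io.read_experiment)(config.input_dir)
        log.info("loaded %d spectra from %s", len(spectra), config.input_dir)
    else:
        design = dataclasses.replace(config.sim, seed=config.seed)

        @_stage("simulate")
        def _simulate():
            sp, tr = simulate.simulate_experiment(design)
            sh = pd.DataFrame(
                [
                    {
                        "file": f"{s.meta.sample_id}.mzXML",
                        "donor": s.meta.donor,
                        "population": s.meta.population,
                        "condition": s.meta.condition,
                        "replicate": s.meta.replicate,
                    }
                    for s in sp
                ]
            )
            return sp, sh, tr

        spectra, sheet, truth = _simulate()
        log.info("simulated %d spectra (seed %d)", len(spectra), design.seed)
        if config.write_spectra:
            _stage("simulate")(spectra_io.write_experiment)(
                spectra, truth, out / "spectra"
            )
        elif truth is not None:
            (out / "truth.json").write_text(truth.to_json())

    # --- preprocess --------------------------------------------------------
    states, peaklists = _stage("preprocess")(preprocess_experiment)(
        spectra, config.preprocess
    )
    peak_rows = []
    for st, pk in zip(states, peaklists):
        for mz, inten, snr in zip(pk.mz, pk.intensity, pk.snr):
            peak_rows.append((st.meta.sample_id, mz, inten, snr))
    _write_csv(
        pd.DataFrame(peak_rows, columns=["file", "mz", "intensity", "snr"]),
        out / "peaks.csv",
    )

    # --- matrix ------------------------------------------------------------
    @_stage("matrix")
    def _matrix():
        bins = bin_peaks(peaklists, config.bin_tolerance_rel)
        mat = build_matrix(bins, peaklists, sheet, average=config.average)
        return filter_features(mat, config.min_frequency)

    matrix = _matrix()
    matrix.to_csv(out / "matrix.csv", out / "factors.csv")
    log.info("feature matrix: %d samples x %d features", matrix.n_samples, matrix.n_features)

    # --- stats -------------------------------------------------------------
    @_stage("stats")
    def _stats():
        anova = two_way_anova_per_feature(matrix, alpha=config.alpha)
        pops = list(dict.fromkeys(matrix.samples["population"]))
        fc = fold_change(
            matrix, {"population": pops[0]}, {"population": pops[-1]}
        )
        hits = select_biomarkers(anova, fc, config.alpha, config.fc_threshold)
        sets, inter, _tables = condition_contrast_sets(matrix, alpha=config.alpha)
        pairs = find_shift_pairs(
            matrix, config.delta, config.pair_tolerance, alpha=config.alpha
        )
        pca = pca_correlation(matrix)
        return anova, fc, hits, sets, inter, pairs, pca

    anova, fc, hits, sets, inter, pairs, pca = _stats()
    _write_csv(
        anova.effects.merge(
            anova.contrasts.pivot_table(
                index="feature_index", columns="contrast", values="p_adj"
            ).add_prefix("p_adj_"),
            left_index=True,
            right_index=True,
            how="left",
        ),
        out / "anova.csv",
    )
    _write_csv(hits, out / "biomarkers.csv")
    _write_csv(pairs, out / "pairs.csv")
    scores = pd.DataFrame(
        pca.scores, columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
    )
    _write_csv(pd.concat([matrix.samples, scores], axis=1), out / "pca_scores.csv")
    _write_csv(
        pd.DataFrame(
            {
                "component": np.arange(1, pca.variance_explained.size + 1),
                "variance_fraction": pca.variance_explained,
            }
        ),
        out / "pca_variance.csv",
    )
    (out / "condition_sets.json").write_text(
        json.dumps(
            {
                "per_population": {k: sorted(v) for k, v in sets.items()},
                "intersections": {f"{a}&{b}": sorted(v) for (a, b), v in inter.items()},
            },
            indent=1,
            sort_keys=True,
        )
    )

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_spectra": len(spectra),
        "n_features": matrix.n_features,
        "n_biomarkers": int(len(hits)),
        "n_shift_pairs_flagged": int(pairs["anticorrelated"].sum()) if len(pairs) else 0,
        "stages": ["simulate" if config.input_dir is None else "load",
                   "preprocess", "matrix", "stats"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return out


def report_summary(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run; never alters results."""
    run = Path(run_dir)
    missing = [f for f in RESULT_FILES if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run}: missing {missing}")
    manifest = json.loads((run / "manifest.json").read_text())
    peaks = pd.read_csv(run / "peaks.csv")
    hits = pd.read_csv(run / "biomarkers.csv")
    pairs = pd.read_csv(run / "pairs.csv")
    variance = pd.read_csv(run / "pca_variance.csv")
    per_spectrum = peaks.groupby("file").size() if len(peaks) else pd.Series(dtype=int)
    lines = [
        f"run {run} (config {manifest['config_hash']}, seed {manifest['seed']})",
        f"spectra: {manifest['n_spectra']}",
        f"median peaks per spectrum: {per_spectrum.median():g}" if len(per_spectrum)
        else "median peaks per spectrum: 0",
        f"features retained: {manifest['n_features']}",
        f"biomarkers: {len(hits)}",
        f"shift pairs: {len(pairs)} ({int(pairs['anticorrelated'].sum()) if len(pairs) else 0} anticorrelated)",
        f"PC1 variance: {100 * variance['variance_fraction'].iloc[0]:.1f}%"
        if len(variance) else "PC1 variance: n/a",
    ]
    return "\n".join(lines)
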