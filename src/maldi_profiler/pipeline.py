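"""End-to-end orchestration of the synthetic study.

simulate -> preprocess -> pick -> matrix -> stats -> train (GA, SNN, QC)
-> validate -> report, per fluid.  Every stage writes its artifact to the
output directory and reads only the previous stage's artifact, so the run
can be restarted from any stage.  One global seed fans out into per-stage,
per-fluid seeds through ``numpy.random.SeedSequence`` spawning, so a run is
deterministic end to end while each model still sees its own stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, peak_analysis, preprocessing, reporting, stats
from .classification import GAParams, QCParams, SNNParams
from .core_io import Fluid, QuantityMode, SpectrumSet
from .synthetic_data import CohortConfig, generate_cohort
from .validation import CVScheme, results_table, validate_model

log = logging.getLogger("maldi_profiler")


@dataclass
class PipelineConfig:
    fluids: list = field(default_factory=lambda: ["saliva", "gcf"])
    cohort: dict = field(default_factory=dict)        # CohortConfig overrides
    preprocess: dict = field(default_factory=dict)    # PreprocessConfig overrides
    snr_threshold: float = 4.0
    resolution: float = 300.0
    quantity_mode: str = "area"
    ga: dict = field(default_factory=dict)
    snn: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)            # CVScheme overrides
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _stage_seeds(global_seed: int, fluid: str) -> dict:
    """Deterministic per-stage seeds below 2**31."""
    import zlib

    names = ["cohort", "ga", "snn", "qc", "cv"]
    ss = np.random.SeedSequence([global_seed, zlib.crc32(fluid.encode())])
    children = ss.generate_state(len(names))
    return {n: int(c & 0x7FFFFFFF) for n, c in zip(names, children)}


def _fluid_dir(outdir, fluid) -> Path:
    d = Path(outdir) / str(fluid)
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir, fluid: str) -> None:
    seeds = _stage_seeds(config.seed, fluid)
    cc = CohortConfig(fluid=fluid, seed=seeds["cohort"], **config.cohort)
    cohort, manifest = generate_cohort(cc)
    d = _fluid_dir(outdir, fluid)
    raw = d / "raw"
    raw.mkdir(exist_ok=True)
    for s in cohort:
        core_io.write_spectrum_csv(s, raw / f"{s.sample_id}.csv")
    manifest.to_csv(d / "manifest.csv", index=False)
    meta = {"fluid": fluid, "n_per_class": cc.n_per_class,
            "labels": cohort.labels, "sample_ids": cohort.sample_ids,
            "seed": cc.seed}
    (d / "cohort.json").write_text(json.dumps(meta, indent=1))
    log.info("simulate[%s]: %d spectra", fluid, len(cohort))


def _load_cohort(outdir, fluid: str, sub: str) -> SpectrumSet:
    d = _fluid_dir(outdir, fluid)
    meta = json.loads((d / "cohort.json").read_text())
    spectra = []
    for sid, lab in zip(meta["sample_ids"], meta["labels"]):
        spectra.append(core_io.read_spectrum_csv(
            d / sub / f"{sid}.csv", sample_id=sid, fluid=Fluid(fluid),
            label=core_io.Label(lab)))
    return SpectrumSet(spectra=spectra, fluid=Fluid(fluid),
                       class_names=["control", "foa", "in"])


def stage_preprocess(config: PipelineConfig, outdir, fluid: str) -> None:
    d = _fluid_dir(outdir, fluid)
    cohort = _load_cohort(outdir, fluid, "raw")
    cfg = preprocessing.PreprocessConfig(**config.preprocess)
    refs = None
    manifest_path = d / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        if len(manifest):
            refs = sorted(manifest["centroid_mz"].tolist())
    done = preprocessing.preprocess_set(cohort, cfg, reference_peaks=refs)
    out = d / "preprocessed"
    out.mkdir(exist_ok=True)
    for s in done:
        core_io.write_spectrum_csv(s, out / f"{s.sample_id}.csv")
    log.info("preprocess[%s]: done", fluid)


def stage_pick(config: PipelineConfig, outdir, fluid: str) -> None:
    d = _fluid_dir(outdir, fluid)
    cohort = _load_cohort(outdir, fluid, "preprocessed")
    avg = peak_analysis.total_average_spectrum(cohort)
    noise = peak_analysis.estimate_noise(avg)
    peaks = peak_analysis.pick_peaks(avg, noise, config.snr_threshold,
                                     config.resolution)
    core_io.write_spectrum_csv(avg, d / "average_spectrum.csv")
    core_io.write_peaks_csv(peaks, d / "peaks.csv")
    log.info("pick[%s]: %d peaks", fluid, len(peaks))


def stage_matrix(config: PipelineConfig, outdir, fluid: str) -> None:
    d = _fluid_dir(outdir, fluid)
    cohort = _load_cohort(outdir, fluid, "preprocessed")
    peaks = core_io.read_peaks_csv(d / "peaks.csv")
    matrix = peak_analysis.build_peak_matrix(
        cohort, peaks, QuantityMode(config.quantity_mode))
    core_io.write_peak_matrix_csv(matrix, d / "matrix.csv")
    log.info("matrix[%s]: %d x %d", fluid, matrix.n_samples, matrix.n_peaks)


def _load_matrix(outdir, fluid: str):
    d = _fluid_dir(outdir, fluid)
    peaks = core_io.read_peaks_csv(d / "peaks.csv")
    return core_io.read_peak_matrix_csv(d / "matrix.csv", peaks=peaks)


def stage_stats(config: PipelineConfig, outdir, fluid: str) -> None:
    d = _fluid_dir(outdir, fluid)
    matrix = _load_matrix(outdir, fluid)
    stats.stats_table(matrix).to_csv(d / "stats.csv", index=False)
    log.info("stats[%s]: done", fluid)


def _model_params(config: PipelineConfig, fluid: str):
    seeds = _stage_seeds(config.seed, fluid)
    return {
        "GA": GAParams(seed=seeds["ga"], **config.ga),
        "SNN": SNNParams(seed=seeds["snn"], **config.snn),
        "QC": QCParams(seed=seeds["qc"], **config.qc),
    }


def stage_train(config: PipelineConfig, outdir, fluid: str) -> None:
    from .classification import train_ga, train_qc, train_snn

    d = _fluid_dir(outdir, fluid)
    matrix = _load_matrix(outdir, fluid)
    params = _model_params(config, fluid)
    for name, trainer in (("GA", train_ga), ("SNN", train_snn),
                          ("QC", train_qc)):
        model = trainer(matrix, params[name])
        core_io.save_model(model, d / f"model_{name.lower()}.json")
        log.info("train[%s]: %s -> %d peaks", fluid, name,
                 len(model.peak_indices))


def stage_validate(config: PipelineConfig, outdir, fluid: str) -> list:
    d = _fluid_dir(outdir, fluid)
    matrix = _load_matrix(outdir, fluid)
    params = _model_params(config, fluid)
    seeds = _stage_seeds(config.seed, fluid)
    scheme = CVScheme(**config.cv)
    results = []
    for name in ("GA", "SNN", "QC"):
        r = validate_model(name, matrix, params=params[name], scheme=scheme,
                           seed=seeds["cv"])
        results.append(r)
        log.info("validate[%s]: %s RC=%.2f%% CV=%.2f%%", fluid, name,
                 r.recognition_capability, r.cross_validation)
    (d / "validation.json").write_text(
        json.dumps([r.to_dict() for r in results], indent=1))
    results_table(results, [fluid] * len(results)).to_csv(
        d / "validation.csv", index=False)
    return results


def stage_report(config: PipelineConfig, outdir, fluid: str) -> None:
    d = _fluid_dir(outdir, fluid)
    matrix = _load_matrix(outdir, fluid)
    cohort = _load_cohort(outdir, fluid, "preprocessed")
    st = pd.read_csv(d / "stats.csv")
    # 2D scatter of the two lowest-p peaks
    order = np.argsort(st["ptta"].to_numpy(), kind="stable")
    a, b = (int(order[0]), int(order[1])) if len(order) >= 2 else (0, 0)
    scatter = reporting.scatter_2d(matrix, a, b)
    rows = []
    for c, dd in scatter.items():
        for x, y in dd["points"]:
            rows.append({"class": c, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(d / "scatter_points.csv", index=False)
    # HNP window overlay + gel view
    window = (3300.0, 3550.0)
    overlay = reporting.class_average_overlay(cohort, window)
    overlay.to_csv(d / "hnp_overlay.csv", index=False)
    raster, ids, bins = reporting.gel_view(cohort, window)
    pd.DataFrame(raster, index=ids, columns=[f"{m:.2f}" for m in bins]).to_csv(
        d / "hnp_gel_view.csv")
    if config.make_plots:
        reporting.plot_scatter_2d(
            scatter, d / "scatter.png",
            xlabel=f"m/z {matrix.peaks[a].centroid_mz:.2f}",
            ylabel=f"m/z {matrix.peaks[b].centroid_mz:.2f}")
        reporting.plot_overlay(overlay, d / "hnp_overlay.png")
        reporting.plot_gel_view(raster, bins, d / "hnp_gel_view.png")
    log.info("report[%s]: done", fluid)


STAGES = ["simulate", "preprocess", "pick", "matrix", "stats", "train",
          "validate", "report"]


def run_pipeline(config: PipelineConfig, outdir) -> pd.DataFrame:
    """Run every stage for every configured fluid; returns the summary
    table of validation results (one row per model per fluid)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_results: list = []
    names: list = []
    for fluid in config.fluids:
        for stage in STAGES:
            fn = globals()[f"stage_{stage}"]
            try:
                out = fn(config, outdir, fluid)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {stage!r} failed for fluid "
                    f"{fluid!r}: {exc}") from exc
            if stage == "validate":
                all_results.extend(out)
                names.extend([fluid] * len(out))
    table = results_table(all_results, names)
    table.to_csv(outdir / "summary.csv", index=False)
    flags = {
        "normalization": (config.preprocess.get("normalize", "tic")),
        "tophat_width": "percent of mass-range width",
        "sn_threshold_inclusive": True,
        "integration": "+-1 FWHM truncated at inter-peak midpoints",
        "cv_scheme": CVScheme(**config.cv).describe(),
        "seed": config.seed,
    }
    (outdir / "run_flags.json").write_text(json.dumps(flags, indent=1))
    return table
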