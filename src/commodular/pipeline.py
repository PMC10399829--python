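"""End-to-end orchestration of the modularity analysis.

Stages mirror the study workflow: simulate (or load) a community, fit the
latent-variable ordination, generate the null universes (module-structured
and completely randomized), fit those, compare each null ordination against
the observed one, and report eigenvalue profiles, temporal centroids and the
farm random-effect test.  Every stage is a plain function over the library so
the numbered analysis drivers, the CLI and the tests all share one code path.

All outputs are deterministic given the config seed; every JSON artifact
echoes the seeds that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .datamodel import CommunityMatrix, SampleMeta, read_dataset, write_dataset
from .gllvm import GLLVMConfig, GLLVMFit, fit_gllvm, model_aic
from .nullmodels import (assign_modules, randomize_within_modules,
                         best_complete_randomization)
from .comparisons import compare_ordinations, eigen_profile
from .spatiotemporal import temporal_centroids, lmm_farm_lrt, mean_log_abundance
from .synthetic import StudyDesign, generate_study

__all__ = ["PipelineConfig", "run_simulate", "run_fit", "run_nulls", "run_compare",
           "run_report", "run_analyze", "load_config"]


@dataclass
class PipelineConfig:
    """One artifact describing a full reproducible run."""

    out_dir: str = "results/run"
    counts_path: str | None = None
    meta_path: str | None = None
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    gllvm: GLLVMConfig = field(default_factory=GLLVMConfig)
    module_k: list[int] = field(default_factory=lambda: [2])
    r_within: float = 0.25
    r_between: float = 0.02
    calibration_tol: float = 0.05
    n_trials: int = 2000
    df_mode: str = "per-sample"
    unique_pairs: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.design, dict):
            d = dict(self.design)
            if "mean_range" in d:
                d["mean_range"] = tuple(d["mean_range"])
            if "dispersion_range" in d:
                d["dispersion_range"] = tuple(d["dispersion_range"])
            self.design = StudyDesign(**d)
        if isinstance(self.gllvm, dict):
            self.gllvm = GLLVMConfig(**self.gllvm)
        if any(k < 2 for k in self.module_k):
            raise ValueError("module_k values must be >= 2")

    @property
    def out(self) -> Path:
        return Path(self.out_dir)

    def dataset_paths(self) -> tuple[Path, Path]:
        c = Path(self.counts_path) if self.counts_path else self.out / "counts.csv"
        m = Path(self.meta_path) if self.meta_path else self.out / "meta.csv"
        return c, m


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**raw)


def _dump_json(obj: dict, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path


def _log(out: Path, message: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run.log", "a") as fh:
        fh.write(message + "\n")


def run_simulate(config: PipelineConfig):
    """Generate a study-shaped dataset and write counts, metadata and truth."""
    design = dataclasses.replace(config.design, seed=config.seed)
    cm, meta, truth = generate_study(design)
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    counts_path, meta_path = config.dataset_paths()
    write_dataset(cm, meta, counts_path, meta_path)
    truth.to_json(out / "truth.json")
    _log(out, f"simulate: seed={config.seed} -> {counts_path} ({cm.n_samples}x{cm.n_taxa})")
    return cm, meta, truth


def _load_dataset(config: PipelineConfig) -> tuple[CommunityMatrix, SampleMeta]:
    counts_path, meta_path = config.dataset_paths()
    return read_dataset(counts_path, meta_path)


def _fit(cm: CommunityMatrix, meta: SampleMeta, config: PipelineConfig) -> GLLVMFit:
    t = meta.aligned_to(cm.sample_ids)
    groups = (t["farm"] + "_" + t["year"]).tolist()
    cfg = dataclasses.replace(config.gllvm, seed=config.seed)
    return fit_gllvm(cm, cfg, groups=groups)


def run_fit(config: PipelineConfig) -> GLLVMFit:
    """Fit the ordination to the dataset on disk; write fit.json."""
    cm, meta = _load_dataset(config)
    fit = _fit(cm, meta, config)
    fit.to_json(config.out / "fit.json")
    _dump_json({"loglik": fit.loglik, "aic": model_aic(fit), "converged": fit.converged,
                "n_iter": fit.n_iter, "seed": config.seed}, config.out / "fit_summary.json")
    _log(config.out, f"fit: loglik={fit.loglik:.2f} aic={model_aic(fit):.1f} "
                     f"converged={fit.converged}")
    return fit


def run_nulls(config: PipelineConfig) -> dict:
    """Generate the module-structured and completely randomized null datasets."""
    cm, meta = _load_dataset(config)
    out = config.out
    artifacts = {}
    for k in config.module_k:
        assignment = assign_modules(cm.counts.sum(axis=0), k)
        res = randomize_within_modules(cm, assignment, config.r_within, config.r_between,
                                       seed=config.seed + k, tol=config.calibration_tol)
        write_dataset(res.matrix, meta, out / f"null_module{k}_counts.csv",
                      out / f"null_module{k}_meta.csv")
        diag = res.diagnostics()
        diag["module_labels"] = assignment.labels.tolist()
        _dump_json(diag, out / f"null_module{k}_diagnostics.json")
        artifacts[f"module_{k}"] = res
        _log(out, f"nulls: k={k} realized r_within={res.realized_within:.3f} "
                  f"r_between={res.realized_between:.3f} converged={res.converged}")
    rand = best_complete_randomization(cm, n_trials=config.n_trials, seed=config.seed,
                                       unique_pairs=config.unique_pairs)
    write_dataset(rand.matrix, meta, out / "null_random_counts.csv",
                  out / "null_random_meta.csv")
    _dump_json(rand.diagnostics(), out / "null_random_diagnostics.json")
    artifacts["random"] = rand
    _log(out, f"nulls: complete randomization KS={rand.ks_statistic:.4f} "
              f"(trial {rand.trial_index}/{rand.n_trials})")
    return artifacts


def run_compare(config: PipelineConfig) -> dict:
    """Fit each null dataset and compare its ordination with the observed one."""
    cm, meta = _load_dataset(config)
    out = config.out
    fit_path = out / "fit.json"
    fit = GLLVMFit.from_json(fit_path) if fit_path.exists() else run_fit(config)

    comparisons = {}
    eig = {"data": eigen_profile(cm).tolist()}
    labels = [f"module_{k}" for k in config.module_k] + ["random"]
    for label in labels:
        stem = f"null_{label.replace('_', '')}" if label != "random" else "null_random"
        cpath, mpath = out / f"{stem}_counts.csv", out / f"{stem}_meta.csv"
        if not cpath.exists():
            raise FileNotFoundError(f"null dataset missing (run nulls first): {cpath}")
        null_cm, null_meta = read_dataset(cpath, mpath)
        null_fit = _fit(null_cm, null_meta, config)
        null_fit.to_json(out / f"{stem}_fit.json")
        # fits share the canonical axis convention (principal axes ordered by
        # loading variance), so marginals compare like-with-like directly;
        # Procrustes alignment is meaningless between structurally unrelated
        # fits (a null's modules are random with respect to the data's)
        report = compare_ordinations(fit.theta, null_fit.theta, df_mode=config.df_mode)
        report.to_json(out / f"compare_{label}.json")
        report.to_table().to_csv(out / f"compare_{label}.csv", index=False)
        eig[label] = eigen_profile(null_cm).tolist()
        comparisons[label] = report
        _log(out, f"compare: {label} combined_p={report.combined_p:.4f}")
    _dump_json(eig, out / "eigenvalues.json")
    return comparisons


def run_report(config: PipelineConfig) -> dict:
    """Temporal centroids, farm random-effect tests, and the run conclusion."""
    cm, meta = _load_dataset(config)
    out = config.out
    fit_path = out / "fit.json"
    fit = GLLVMFit.from_json(fit_path) if fit_path.exists() else run_fit(config)
    meta_aligned = SampleMeta(meta.aligned_to(cm.sample_ids))

    centroids = temporal_centroids(fit.u, meta_aligned)
    centroids.to_csv(out / "centroids.csv")

    lrt = {}
    responses = {"LV1": fit.u[:, 0] if fit.u.shape[1] > 0 else None,
                 "LV2": fit.u[:, 1] if fit.u.shape[1] > 1 else None,
                 "mean_ln_count": mean_log_abundance(cm.counts)}
    for name, resp in responses.items():
        if resp is None:
            continue
        res = lmm_farm_lrt(resp, meta_aligned)
        lrt[name] = {"chi2": res.chi2, "p": res.p, "singular": res.singular}
        res.to_json(out / f"lrt_{name}.json")
    _dump_json(lrt, out / "farm_lrt.json")

    conclusion = {}
    for path in sorted(out.glob("compare_*.json")):
        label = path.stem.removeprefix("compare_")
        rep = json.loads(path.read_text())
        conclusion[label] = {
            "combined_p": rep["combined_p"],
            "conclusion": "rejected" if rep["combined_p"] < 0.05 else "not rejected",
        }
    summary = {"seed": config.seed, "version": __version__,
               "hypotheses": conclusion, "farm_lrt": lrt}
    _dump_json(summary, out / "summary.json")
    _log(out, f"report: {json.dumps(conclusion)}")
    return summary


def run_analyze(config: PipelineConfig) -> dict:
    """The full chain: (simulate if no data), fit, nulls, compare, report."""
    counts_path, meta_path = config.dataset_paths()
    if not counts_path.exists():
        if config.counts_path is not None:
            raise FileNotFoundError(f"counts file not found: {counts_path}")
        run_simulate(config)
    run_fit(config)
    run_nulls(config)
    run_compare(config)
    return run_report(config)
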