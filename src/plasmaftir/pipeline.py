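"""End-to-end orchestration: generate -> QC/preprocess -> difference maps ->
PCA -> PLS-DA cross-validation, with a manifest and a human-readable report.

Two shipped presets mirror the clinical comparison structure:

* ``treatment-monitoring`` — five time-point groups; four baseline-referenced
  and three post-hormone-referenced difference maps, a global PCA, and four
  baseline-referenced PLS-DA cross-validation tables;
* ``toxicity`` — acute and late toxicity grade groups (grade 0-1 vs 2+),
  with a difference map, pair PCA and PLS-DA table per pair.

Every stochastic stage derives its seed from the run seed, so two runs with
the same configuration produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemometrics import CVResult, cross_validate, pca_fit
from .cohort import (
    CohortConfig,
    SpectralDataset,
    generate_cohort,
    toxicity_config,
    treatment_monitoring_config,
)
from .group_statistics import DifferenceResult, difference_spectrum, significant_regions
from .preprocess import PreprocessConfig, QualityThresholds, preprocess_dataset

__all__ = [
    "Comparison",
    "CVParams",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "write_report",
    "report_from_directory",
    "treatment_monitoring_run_config",
    "toxicity_run_config",
]

log = logging.getLogger("plasmaftir")


@dataclass
class Comparison:
    group_a: str
    group_b: str
    analysis: str  # "difference" | "pca" | "plsda"

    def __post_init__(self) -> None:
        if self.analysis not in ("difference", "pca", "plsda"):
            raise ValueError(f"unknown analysis {self.analysis!r}")

    @property
    def tag(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


@dataclass
class CVParams:
    m_max: int = 50
    rounds: int = 20
    train_fraction: float = 0.9


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=treatment_monitoring_config)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qc: QualityThresholds = field(default_factory=QualityThresholds)
    comparisons: list[Comparison] = field(default_factory=list)
    cv: CVParams = field(default_factory=CVParams)
    alpha: float = 0.001
    seed: int = 0
    output_dir: str = "plasmaftir_run"
    global_pca_components: int = 10
    write_raw_dataset: bool = True

    def __post_init__(self) -> None:
        groups = set(self.cohort.group_labels)
        for c in self.comparisons:
            if c.group_a not in groups or c.group_b not in groups:
                raise ValueError(f"comparison {c.tag} references undefined groups")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "preprocess": dataclasses.asdict(self.preprocess),
            "qc": dataclasses.asdict(self.qc),
            "comparisons": [dataclasses.asdict(c) for c in self.comparisons],
            "cv": dataclasses.asdict(self.cv),
            "alpha": self.alpha,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "global_pca_components": self.global_pca_components,
            "write_raw_dataset": self.write_raw_dataset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["cohort"] = CohortConfig.from_dict(d["cohort"])
        pp = dict(d.get("preprocess", {}))
        d["preprocess"] = PreprocessConfig(**pp)
        qc = dict(d.get("qc", {}))
        for key in ("signal_region", "noise_region", "water_vapor_region"):
            if key in qc:
                qc[key] = tuple(qc[key])
        d["qc"] = QualityThresholds(**qc)
        d["comparisons"] = [Comparison(**c) for c in d.get("comparisons", [])]
        d["cv"] = CVParams(**d.get("cv", {}))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.canonical_yaml())

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()


def _baseline_then(others: list[str]) -> list[Comparison]:
    return [Comparison("baseline", g, "difference") for g in others]


def treatment_monitoring_run_config(output_dir: str = "plasmaftir_run",
                                    seed: int = 0) -> RunConfig:
    """Five-group monitoring preset: 4 + 3 difference maps and 4 PLS-DA
    cross-validation tables, all baseline- or post-hormone-referenced."""
    later = ["post_hormone", "post_radiotherapy", "two_month", "eight_month"]
    comparisons = _baseline_then(later)
    comparisons += [Comparison("post_hormone", g, "difference")
                    for g in ["post_radiotherapy", "two_month", "eight_month"]]
    comparisons += [Comparison("baseline", g, "plsda") for g in later]
    return RunConfig(
        cohort=treatment_monitoring_config(seed=seed),
        comparisons=comparisons,
        seed=seed,
        output_dir=output_dir,
    )


def toxicity_run_config(output_dir: str = "plasmaftir_toxicity_run",
                        seed: int = 0) -> RunConfig:
    """Toxicity preset: acute and late grade 0-1 vs 2+ pairs."""
    pairs = [("acute_grade_0_1", "acute_grade_2plus"),
             ("late_grade_0_1", "late_grade_2plus")]
    comparisons = []
    for a, b in pairs:
        comparisons += [Comparison(a, b, "difference"), Comparison(a, b, "pca"),
                        Comparison(a, b, "plsda")]
    return RunConfig(
        cohort=toxicity_config(seed=seed),
        comparisons=comparisons,
        seed=seed,
        output_dir=output_dir,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunReport:
    output_dir: Path
    config: RunConfig
    qc_counts: dict
    differences: dict[str, DifferenceResult]
    cv_results: dict[str, CVResult]
    report_text: str
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    log.info("stage %s: start", name)
    return time.perf_counter()


def _stage_done(name: str, t0: float) -> None:
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _cv_seed(run_seed: int, index: int) -> int:
    return int((run_seed * 1_000_003 + 7919 * (index + 1)) % (2**31))


def run_pipeline(config: RunConfig, figures: bool = False) -> RunReport:
    """Execute all configured stages and write every artefact under
    ``config.output_dir``.  Deterministic: identical config and seed give
    byte-identical CSV outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    try:
        t0 = _stage("generate")
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        raw = generate_cohort(cohort_cfg)
        if config.write_raw_dataset:
            raw.to_csv(out / "raw_data.csv", out / "metadata.csv")
            written += [out / "raw_data.csv", out / "metadata.csv"]
        else:
            save_csv("metadata.csv",
                     lambda p: raw.metadata.to_csv(p, index=False))
        _stage_done("generate", t0)

        t0 = _stage("preprocess")
        mv, ab, qc_log = preprocess_dataset(raw, config.preprocess, config.qc)
        save_csv("qc_log.csv", lambda p: qc_log.to_csv(p, index=False))
        qc_counts = {"input": len(raw), "passed": len(mv), "rejected": len(qc_log)}
        _stage_done("preprocess", t0)

        differences: dict[str, DifferenceResult] = {}
        cv_results: dict[str, CVResult] = {}
        for i, comp in enumerate(config.comparisons):
            t0 = _stage(f"{comp.analysis}:{comp.tag}")
            if comp.analysis == "difference":
                r = difference_spectrum(ab, comp.group_a, comp.group_b,
                                        alpha=config.alpha)
                save_csv(f"diff_{comp.tag}.csv", r.to_csv)
                differences[comp.tag] = r
                if figures:
                    from .plot import plot_difference
                    plot_difference(r, out / f"diff_{comp.tag}.png")
            elif comp.analysis == "pca":
                pair = mv.subset_groups([comp.group_a, comp.group_b])
                n_comp = min(config.global_pca_components,
                             len(pair.metadata["patient_id"].unique()) - 1)
                res = pca_fit(pair, n_components=n_comp)
                save_csv(f"pca_{comp.tag}_scores.csv",
                         lambda p, res=res: res.scores_frame().to_csv(p, index=False))
                save_csv(f"pca_{comp.tag}_variance.csv",
                         lambda p, res=res: pd.DataFrame(
                             {"component": np.arange(1, res.n_components + 1),
                              "explained_variance_pct": res.explained_variance_pct}
                         ).to_csv(p, index=False))
                if figures:
                    from .plot import plot_pca_scores
                    plot_pca_scores(res, out / f"pca_{comp.tag}.png")
            else:  # plsda
                r = cross_validate(
                    mv, comp.group_a, comp.group_b,
                    m_max=config.cv.m_max, rounds=config.cv.rounds,
                    train_fraction=config.cv.train_fraction,
                    seed=_cv_seed(config.seed, i),
                )
                save_csv(f"cv_{comp.tag}.csv", r.to_csv)
                cv_results[comp.tag] = r
                if figures:
                    from .plot import plot_lv_sweep
                    plot_lv_sweep(r, out / f"cv_{comp.tag}.png")
            _stage_done(f"{comp.analysis}:{comp.tag}", t0)

        t0 = _stage("global_pca")
        res = pca_fit(mv, n_components=config.global_pca_components)
        save_csv("pca_scores.csv",
                 lambda p: res.scores_frame().to_csv(p, index=False))
        save_csv("pca_variance.csv",
                 lambda p: pd.DataFrame(
                     {"component": np.arange(1, res.n_components + 1),
                      "explained_variance_pct": res.explained_variance_pct}
                 ).to_csv(p, index=False))
        save_csv("pca_loadings.csv",
                 lambda p: pd.DataFrame(
                     res.loadings.T,
                     columns=[f"PC{i+1}" for i in range(res.n_components)],
                     index=pd.Index(res.grid, name="wavenumber"),
                 ).to_csv(p))
        if figures:
            from .plot import plot_pca_scores
            plot_pca_scores(res, out / "pca_scores.png")
        _stage_done("global_pca", t0)

        config.to_yaml(out / "config.yaml")
        written.append(out / "config.yaml")

        report_text = report_from_directory(out)
        (out / "report.md").write_text(report_text)
        written.append(out / "report.md")

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise

    return RunReport(out, config, qc_counts, differences, cv_results,
                     report_text, manifest)


# ---------------------------------------------------------------------------
# reporting


def _diff_section(path: Path, alpha: float, band_library) -> list[str]:
    df = pd.read_csv(path)
    tag = path.stem.removeprefix("diff_")
    r = DifferenceResult(
        grid=df["wavenumber"].to_numpy(),
        mean_a=df["mean_a"].to_numpy(),
        mean_b=df["mean_b"].to_numpy(),
        difference=df["difference"].to_numpy(),
        t_stat=df["t_stat"].to_numpy(),
        p_value=df["p_value"].to_numpy(),
        significant_mask=df["significant"].to_numpy(dtype=bool),
        alpha=alpha, n_a=0, n_b=0,
    )
    regions = significant_regions(r, band_library)
    lines = [f"### {tag.replace('_vs_', ' vs ')}", ""]
    if not regions:
        lines.append("no significant regions")
    else:
        for reg in regions:
            lines.append(
                f"- {reg['lo']:.0f}-{reg['hi']:.0f} cm^-1 ({reg.get('assignment', '?')})"
            )
    lines.append("")
    return lines


def report_from_directory(output_dir: str | Path) -> str:
    """Rebuild the run report purely from the saved CSV/YAML artefacts."""
    out = Path(output_dir)
    config = RunConfig.from_yaml(out / "config.yaml")
    lines = ["# Plasma FTIR pipeline report", ""]

    qc_log = pd.read_csv(out / "qc_log.csv")
    n_rejected = len(qc_log)
    meta = pd.read_csv(out / "metadata.csv")
    lines += ["## Quality control", "",
              f"- spectra generated: {len(meta)}",
              f"- rejected by QC: {n_rejected}",
              f"- retained: {len(meta) - n_rejected}", ""]

    diff_paths = sorted(out.glob("diff_*.csv"))
    if diff_paths:
        lines += ["## Difference spectra "
                  f"(two-tailed t-test, p < {config.alpha:g})", ""]
        for path in diff_paths:
            lines += _diff_section(path, config.alpha, config.cohort.band_library)

    if (out / "pca_variance.csv").exists():
        pv = pd.read_csv(out / "pca_variance.csv")
        lines += ["## PCA explained variance", ""]
        for _, row in pv.iterrows():
            lines.append(f"- PC-{int(row['component'])}: "
                         f"{row['explained_variance_pct']:.1f}%")
        lines.append("")

    cv_paths = sorted(out.glob("cv_*.csv"))
    if cv_paths:
        lines += ["## PLS-DA cross-validation", ""]
        for path in cv_paths:
            t = pd.read_csv(path)
            ba = (t["sensitivity_mean"] + t["specificity_mean"]) / 2.0
            best = t.iloc[int(np.argmax(ba.to_numpy()))]
            tag = path.stem.removeprefix("cv_").replace("_vs_", " vs ")
            lines += [f"### {tag}", "",
                      f"- selected LVs: {int(best['lv'])}",
                      f"- sensitivity: {best['sensitivity_mean']:.1f}%",
                      f"- specificity: {best['specificity_mean']:.1f}%", ""]
    return "\n".join(lines)


def write_report(output_dir: str | Path, path: str | Path | None = None) -> str:
    """Write (or rewrite) ``report.md`` for a completed run directory."""
    text = report_from_directory(output_dir)
    target = Path(path) if path is not None else Path(output_dir) / "report.md"
    target.write_text(text)
    return text
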