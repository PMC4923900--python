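"""End-to-end orchestration: simulate (or load) -> regress -> filter ->
cluster -> per-day DE -> report, with a serializable configuration and a
deterministic, provenance-logged output directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterConfig, cluster_contrast, cluster_report
from .core import InputError, read_design, read_expression
from .de import per_time_de, top_n_cluster_overlap, venn_summary
from .regression import RegressionConfig, fit_contrast
from .simulate import (SimulationConfig, TemplateAssignment, TemplateSpec,
                       ba_mimic_config, generate_study, gh_mimic_config, write_study)

logger = logging.getLogger(__name__)

#: default R^2 stringency tier per contrast (strict for the high-amplitude
#: arm, relaxed for the low-amplitude arm) and both tiers reported per run
R2_TIERS = (0.5, 0.2)
DEFAULT_CONTRAST_R2 = {"ba": 0.5, "gh": 0.2}


class ConfigError(InputError):
    """Raised when a pipeline configuration fails validation."""


@dataclasses.dataclass
class PipelineConfig:
    """Fully-resolved run configuration; serializable and re-runnable."""

    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    degree: int = 2
    alpha_global: float = 0.05
    alpha_step: float = 0.05
    p_adjust: str = "none"
    contrast_r2: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CONTRAST_R2))
    cluster: ClusterConfig = dataclasses.field(default_factory=ClusterConfig)
    de_alpha: float = 0.05
    top_n: int = 50
    log_level: str = "INFO"
    overwrite: bool = False

    def regression_config(self, contrast: str) -> RegressionConfig:
        return RegressionConfig(contrast=contrast, degree=self.degree,
                                alpha_global=self.alpha_global, alpha_step=self.alpha_step,
                                r2_threshold=self.contrast_r2[contrast],
                                p_adjust=self.p_adjust)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


_TOP_KEYS = {"outdir", "seed", "simulation", "expression_path", "design_path",
             "annotation_path", "degree", "alpha_global", "alpha_step", "p_adjust",
             "contrast_r2", "cluster", "de_alpha", "top_n", "log_level", "overwrite"}
_SIM_KEYS = {"preset", "n_probes", "assignments", "noise_sd", "group_sizes", "n_batches",
             "batch_sd", "baseline_mean", "baseline_sd", "heavy_tail_fraction",
             "heavy_tail_scale", "seed", "n_null"}
_CLUSTER_KEYS = {f.name for f in dataclasses.fields(ClusterConfig)}


def _build_simulation(block: dict, seed: int) -> SimulationConfig:
    unknown = set(block) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"simulation: unknown keys {sorted(unknown)}")
    block = dict(block)
    block.setdefault("seed", seed)
    preset = block.pop("preset", None)
    if preset is None and "n_null" in block:
        raise ConfigError("simulation: 'n_null' is only valid with a preset")
    if preset is not None:
        extra = {k: v for k, v in block.items() if k not in ("seed",)}
        if preset == "ba_mimic":
            return ba_mimic_config(block["seed"], **{k: v for k, v in extra.items()
                                                     if k in ("n_null", "noise_sd")})
        if preset == "gh_mimic":
            return gh_mimic_config(block["seed"], **{k: v for k, v in extra.items()
                                                     if k in ("n_null", "noise_sd")})
        raise ConfigError(f"simulation.preset: unknown preset {preset!r}")
    assignments = []
    for i, a in enumerate(block.pop("assignments", [])):
        try:
            tpl = TemplateSpec(template_id=a["template_id"], shape=a.get("shape", "custom"),
                               amplitude=float(a["amplitude"]),
                               multipliers=tuple(a["multipliers"]))
            assignments.append(TemplateAssignment(tpl, int(a["n_probes"]),
                                                  a.get("treatment", "ba"), a.get("gene")))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"simulation.assignments[{i}]: {exc}") from exc
    if "group_sizes" in block:
        block["group_sizes"] = {float(k): int(v) for k, v in block["group_sizes"].items()}
    try:
        return SimulationConfig(assignments=assignments, **block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc


def validate_config(path_or_dict: str | Path | dict) -> PipelineConfig:
    """Load, validate and normalize a YAML pipeline configuration.

    Unknown keys are rejected with their key path; value errors are
    reported with the offending key.  Returns the fully-resolved config
    with every default filled in.
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "outdir" not in raw:
        raise ConfigError("missing required key 'outdir'")
    seed = int(raw.get("seed", 0))

    sim = None
    if raw.get("simulation") is not None:
        sim = _build_simulation(raw["simulation"], seed)
    has_paths = raw.get("expression_path") and raw.get("design_path")
    if sim is None and not has_paths:
        raise ConfigError("provide either a 'simulation' block or both "
                          "'expression_path' and 'design_path'")

    cluster_block = raw.get("cluster", {}) or {}
    unknown = set(cluster_block) - _CLUSTER_KEYS
    if unknown:
        raise ConfigError(f"cluster: unknown keys {sorted(unknown)}")
    cluster_block = dict(cluster_block)
    cluster_block.setdefault("seed", seed)
    try:
        cluster = ClusterConfig(**cluster_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"cluster: {exc}") from exc

    contrast_r2 = dict(DEFAULT_CONTRAST_R2)
    contrast_r2.update({str(k).lower(): float(v)
                        for k, v in (raw.get("contrast_r2") or {}).items()})
    for k, v in contrast_r2.items():
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"contrast_r2.{k}: threshold {v} outside [0, 1]")

    cfg = PipelineConfig(
        outdir=str(raw["outdir"]), seed=seed, simulation=sim,
        expression_path=raw.get("expression_path"), design_path=raw.get("design_path"),
        annotation_path=raw.get("annotation_path"),
        degree=int(raw.get("degree", 2)),
        alpha_global=float(raw.get("alpha_global", 0.05)),
        alpha_step=float(raw.get("alpha_step", 0.05)),
        p_adjust=str(raw.get("p_adjust", "none")),
        contrast_r2=contrast_r2, cluster=cluster,
        de_alpha=float(raw.get("de_alpha", 0.05)),
        top_n=int(raw.get("top_n", 50)),
        log_level=str(raw.get("log_level", "INFO")),
        overwrite=bool(raw.get("overwrite", False)),
    )
    # construct one RegressionConfig per contrast now so bad values fail
    # before any computation
    for contrast in cfg.contrast_r2:
        try:
            cfg.regression_config(contrast)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    return cfg


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_full(config: PipelineConfig) -> Path:
    """Execute the whole pipeline; returns the output directory.

    Writes: simulated study TSVs (when simulating), per-contrast fit
    tables, survivor lists at both stringency tiers, cluster tables /
    profiles / selection scores, per-day DE + Venn + top-N summaries, a
    machine-readable summary.json (k per contrast and all counts), the
    echoed configuration, and a run log.  An existing non-empty output
    directory is refused unless overwrite is set.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise InputError(f"output directory {outdir} is not empty; "
                         "pass overwrite to replace its contents")
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("timeclust")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run_full_inner(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_full_inner(config: PipelineConfig, outdir: Path) -> Path:
    summary: dict = {"version": __version__, "seed": config.seed, "contrasts": {}}

    if config.simulation is not None:
        logger.info("simulating study: %d probes, %d planted assignments",
                    config.simulation.n_probes, len(config.simulation.assignments))
        em, design, truth = generate_study(config.simulation)
        write_study(outdir / "data", em, design, truth, config.simulation)
    else:
        em = read_expression(config.expression_path, config.annotation_path)
        design = read_design(config.design_path)
        missing = [s for s in em.sample_ids if s not in set(design.sample_ids)]
        if missing:
            raise InputError(f"samples in expression but not in design: {missing[:5]}")

    cluster_results = {}
    for contrast in sorted(config.contrast_r2):
        rcfg = config.regression_config(contrast)
        logger.info("fitting contrast %s: degree %d, alpha %g, stepwise alpha %g",
                    contrast, rcfg.degree, rcfg.alpha_global, rcfg.alpha_step)
        fit = fit_contrast(em, design, rcfg)
        fit_table = fit.table.copy()
        fit_table.index.name = "probe_id"
        fit_table.to_csv(outdir / f"fit_{contrast}.tsv", sep="\t")

        tier_counts = {}
        for tier in sorted(set(R2_TIERS) | {rcfg.r2_threshold}):
            surv = fit.survivors(tier)
            tier_counts[f"{tier:g}"] = len(surv)
            pd.Series(surv, name="probe_id").to_csv(
                outdir / f"survivors_{contrast}_r2_{tier:g}.tsv", sep="\t", index=False)
            logger.info("contrast %s: %d survivors at R2 >= %g", contrast, len(surv), tier)

        res = cluster_contrast(fit, config.cluster, rcfg.r2_threshold)
        cluster_results[contrast] = (fit, res)
        logger.info("contrast %s: k = %d at R2 >= %g", contrast, res.k, rcfg.r2_threshold)
        res.cluster_profiles.to_csv(outdir / f"cluster_profiles_{contrast}.tsv",
                                    sep="\t", index=False)
        scores = pd.DataFrame(sorted(res.selection_scores.items()),
                              columns=["k", "score"])
        scores.to_csv(outdir / f"cluster_scores_{contrast}.tsv", sep="\t", index=False)

        summary["contrasts"][contrast] = {
            "k": res.k,
            "n_significant": int(len(fit.significant())),
            "survivors_by_r2": tier_counts,
            "r2_threshold": rcfg.r2_threshold,
        }

    # combined cluster tables with shared-across-contrasts flags
    if set(cluster_results) >= {"ba", "gh"}:
        report = cluster_report(cluster_results["ba"][1], cluster_results["gh"][1],
                                em.annotation)
    else:  # single-contrast run: no equivalent analysis to share with
        from .clustering import ClusterResult
        only = next(iter(cluster_results))
        empty = ClusterResult(contrast="none", k=0, labels=None,
                              cluster_profiles=pd.DataFrame(), selection_scores={})
        report = {only: cluster_report(cluster_results[only][1], empty,
                                       em.annotation)[only]}
    for contrast, tbl in report.items():
        tbl.to_csv(outdir / f"clusters_{contrast}.tsv", sep="\t", index=False)
        summary["contrasts"][contrast]["n_clustered"] = int(len(tbl))
        summary["contrasts"][contrast]["n_shared"] = int(tbl["shared_flag"].sum()) if len(tbl) else 0

    # per-day DE, Venn overlaps and top-N cluster overlap
    de_counts, top_overlaps = {}, {}
    for contrast in sorted(config.contrast_r2):
        _, res = cluster_results[contrast]
        clustered = list(res.probe_ids())
        de_counts[contrast], top_overlaps[contrast] = {}, {}
        for day in design.days():
            de = per_time_de(em, design, day, contrast, config.de_alpha)
            de.to_csv(outdir / f"de_{contrast}_d{day:g}.tsv", sep="\t")
            de_counts[contrast][f"{day:g}"] = int(de["significant"].sum())
            if clustered:
                top_overlaps[contrast][f"{day:g}"] = top_n_cluster_overlap(
                    de, clustered, config.top_n)
    venn = venn_summary(em, design, config.de_alpha)
    venn.to_csv(outdir / "venn_summary.tsv", sep="\t", index=False)
    summary["de_significant_counts"] = de_counts
    summary["venn"] = {f"{r.day:g}": [int(r.only_ba), int(r.only_gh), int(r.shared)]
                       for r in venn.itertuples()}
    summary[f"top{config.top_n}_overlap_pct"] = top_overlaps

    (outdir / "config_echo.json").write_text(
        json.dumps(_round_floats(config.to_dict()), indent=2, sort_keys=True) + "\n")
    (outdir / "summary.json").write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", outdir)
    return outdir
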