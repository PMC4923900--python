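"""Synthetic time-course expression studies with planted temporal templates.

The generator emulates a 3-arm (control / beta-agonist / growth-hormone)
porcine feeding trial sampled at days 1, 3, 7, 13 and 27 with 10 animals
per arm per day (15 at day 27), measured on a log-intensity microarray
scale.  Blocks of probes are assigned ground-truth temporal response
templates in one treatment arm; the rest are null.  The emitted truth
table allows recovery scoring of the downstream regression + clustering
pipeline.

Amplitude convention: preset template multipliers are normalized to unit
root-mean-square over the day grid, so ``amplitude`` is the RMS planted
effect in log-intensity units (the effect size the regression F statistic
responds to); the named canonical shapes in :func:`template_library` are
instead peak-normalized, with ``amplitude`` the effect at the
most-affected day.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_DAY_GRID, ExpressionMatrix, StudyDesign, transform_times

DEFAULT_GROUP_SIZES = {1.0: 10, 3.0: 10, 7.0: 10, 13.0: 10, 27.0: 15}


@dataclasses.dataclass(frozen=True)
class TemplateSpec:
    """A ground-truth temporal response shape over the day grid.

    multipliers are per-day effect weights; non-null templates are
    peak-normalized so the planted ``amplitude`` is the peak effect.
    """

    template_id: str
    shape: str
    amplitude: float
    multipliers: tuple

    def __post_init__(self):
        if self.shape == "null" and (self.amplitude != 0 or any(self.multipliers)):
            raise ValueError("null template must have amplitude 0 and zero multipliers")

    def effect(self) -> np.ndarray:
        """Planted effect (log-intensity units) at each grid day."""
        return self.amplitude * np.asarray(self.multipliers, dtype=float)


def template_library(day_grid: Sequence[float] = DEFAULT_DAY_GRID,
                     amplitude: float = 1.0) -> list[TemplateSpec]:
    """The canonical response shapes seen in anabolic-agent time courses.

    early_peak_decay : expression peaks at day 3 and decays back toward
        control by day 27 (the dominant beta-agonist response).
    transient_day1 : peaks on day 1, back to control from day 7 (the
        typical growth-hormone response).
    sustained : constant elevation at every sampled day.
    late_rise : maximal at day 27, rising sharply after day 13.
    singleton_extreme : early-peak shape intended for a very large
        amplitude, so the probe clusters on its own.
    null : no treatment effect.
    """
    if tuple(day_grid) != tuple(DEFAULT_DAY_GRID):
        raise ValueError("canonical templates are defined on the default day grid")
    shapes = {
        "early_peak_decay": (0.35, 1.0, 0.70, 0.40, 0.10),
        "transient_day1": (1.0, 0.60, 0.05, 0.0, 0.0),
        "sustained": (1.0, 1.0, 1.0, 1.0, 1.0),
        "late_rise": (0.05, 0.10, 0.20, 0.50, 1.0),
        "singleton_extreme": (0.50, 1.0, 0.80, 0.60, 0.30),
        "null": (0.0, 0.0, 0.0, 0.0, 0.0),
    }
    out = []
    for name, mult in shapes.items():
        amp = 0.0 if name == "null" else (5.0 * amplitude if name == "singleton_extreme" else amplitude)
        out.append(TemplateSpec(template_id=name, shape=name, amplitude=amp, multipliers=mult))
    return out


def _quadratic_plane(day_grid: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal bases of the centered span of {T, T^2} and its complement.

    Returns (e, f): e is 2 x n_days spanning the shapes a degree-2
    polynomial in log-time can take (after centering); f spans the centered
    directions orthogonal to it — temporal patterns a quadratic cannot fit.
    """
    T = transform_times(day_grid)
    n = len(T)
    basis = []
    for v in (T, T ** 2):
        v = v - v.mean()
        for u in basis:
            v = v - (v @ u) * u
        basis.append(v / np.linalg.norm(v))
    e = np.vstack(basis)
    # complement within the centered space: start from day-indicator spikes
    comp = []
    for j in range(n):
        v = np.zeros(n)
        v[j] = 1.0
        v = v - v.mean()
        for u in [*e, *comp]:
            v = v - (v @ u) * u
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            comp.append(v / norm)
    return e, np.vstack(comp)


def circle_templates(n: int, amplitude: float, day_grid: Sequence[float] = DEFAULT_DAY_GRID,
                     phase_deg: float = 0.0, prefix: str = "tpl",
                     lack_of_fit: float = 0.0) -> list[TemplateSpec]:
    """n maximally-distinguishable temporal templates for a degree-2 analysis.

    Degree-2 fitted difference profiles, after per-probe standardization,
    lie on a circle (the centered quadratic span is two-dimensional), so
    the most distinguishable set of n templates places their quadratic
    components at evenly spaced angles on that circle.

    lack_of_fit adds, per template, a sharp transient component orthogonal
    to the quadratic span (single-day excursions a degree-2 curve cannot
    capture), with norm ``lack_of_fit`` times the quadratic component's.
    This emulates poorly-fitted transient responses: it lowers the
    selected-model R^2 without moving the template's position on the
    profile circle.

    Multipliers are normalized to unit RMS over the grid, so the planted
    ``amplitude`` is the RMS effect across the time course.
    """
    e, f = _quadratic_plane(day_grid)
    n_days = len(tuple(day_grid))
    out = []
    for i in range(n):
        th = np.radians(phase_deg) + 2 * np.pi * i / n
        u = np.cos(th) * e[0] + np.sin(th) * e[1]
        if lack_of_fit > 0:
            ph = np.radians(phase_deg) + 2 * np.pi * (2 * i + 1) / (2 * n)
            w = np.cos(ph) * f[0] + np.sin(ph) * f[1]
            u = u + lack_of_fit * w
        m = u * np.sqrt(n_days) / np.linalg.norm(u)
        peak_day = day_grid[int(np.argmax(np.abs(m)))]
        direction = "up" if m[int(np.argmax(np.abs(m)))] > 0 else "down"
        kind = "transient" if lack_of_fit > 0 else "quadratic"
        out.append(TemplateSpec(
            template_id=f"{prefix}{i + 1:02d}",
            shape=f"{kind}_peak_d{peak_day:g}_{direction}",
            amplitude=amplitude,
            multipliers=tuple(np.round(m, 6)),
        ))
    return out


def day3_peak_phase(day_grid: Sequence[float] = DEFAULT_DAY_GRID) -> float:
    """Circle angle (degrees) of the early-peak-decay shape; used to phase presets."""
    e, _ = _quadratic_plane(day_grid)
    v = np.array(template_library(day_grid)[0].multipliers, dtype=float)
    v = v - v.mean()
    return float(np.degrees(np.arctan2(v @ e[1], v @ e[0])))


@dataclasses.dataclass
class TemplateAssignment:
    """Assign ``n_probes`` probes to one template in one treatment arm.

    gene: if given, all probes of this assignment share the gene symbol
    (multi-probe gene); otherwise each probe gets its own gene id.
    """

    template: TemplateSpec
    n_probes: int
    treatment: str = "ba"
    gene: str | None = None


@dataclasses.dataclass
class SimulationConfig:
    n_probes: int
    assignments: list = dataclasses.field(default_factory=list)
    noise_sd: float = 0.25
    group_sizes: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_batches: int = 3
    batch_sd: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    heavy_tail_fraction: float = 0.0
    heavy_tail_scale: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be at least 2")
        n_planted = sum(a.n_probes for a in self.assignments)
        if n_planted > self.n_probes:
            raise ValueError(f"template probe counts ({n_planted}) exceed n_probes ({self.n_probes})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assignments"] = [
            {"template_id": a.template.template_id, "shape": a.template.shape,
             "amplitude": a.template.amplitude, "multipliers": list(a.template.multipliers),
             "n_probes": a.n_probes, "treatment": a.treatment, "gene": a.gene}
            for a in self.assignments
        ]
        return d


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth per probe, for recovery scoring."""

    frame: pd.DataFrame  # probe_id, gene, template_id, affected_treatment, amplitude, noise_sd
    seed: int

    def gene_multiplicity(self) -> pd.Series:
        return self.frame.groupby("gene").size()

    def planted_probes(self) -> pd.Index:
        return pd.Index(self.frame.loc[self.frame["template_id"] != "null", "probe_id"])

    def labels(self) -> pd.Series:
        """template_id per probe (the planted clustering)."""
        return self.frame.set_index("probe_id")["template_id"]

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_design(group_sizes: dict = None, n_batches: int = 3,
                 treatments: Sequence[str] = ("control", "ba", "gh")) -> StudyDesign:
    """The cross-sectional 3-arm design: each animal sampled at one day only."""
    group_sizes = dict(DEFAULT_GROUP_SIZES) if group_sizes is None else group_sizes
    rows = []
    i = 0
    for day in sorted(group_sizes):
        for treat in treatments:
            for rep in range(group_sizes[day]):
                rows.append({
                    "sample_id": f"{treat}_d{int(day):02d}_r{rep + 1:02d}",
                    "treatment": treat,
                    "day": float(day),
                    "batch": i % n_batches + 1,
                })
                i += 1
    return StudyDesign.from_frame(pd.DataFrame(rows), day_grid=tuple(sorted(group_sizes)))


def generate_study(config: SimulationConfig) -> tuple[ExpressionMatrix, StudyDesign, SyntheticTruth]:
    """Generate (expression, design, truth) for one synthetic study.

    value(probe, sample) = baseline(probe)
                         + amplitude * multiplier(template, day) * 1[arm == affected]
                         + batch offset + Gaussian noise.

    Identical config + seed gives a bit-identical matrix.
    """
    rng = np.random.default_rng(config.seed)
    design = build_design(config.group_sizes, config.n_batches)
    days = np.array(sorted(config.group_sizes))
    day_index = {d: j for j, d in enumerate(days)}
    n_samples = len(design.frame)
    n_probes = config.n_probes

    probe_ids = [f"P{i + 1:05d}" for i in range(n_probes)]
    genes = [f"G{i + 1:05d}" for i in range(n_probes)]
    template_of = ["null"] * n_probes
    affected = [""] * n_probes
    amplitude = np.zeros(n_probes)
    effect_rows = np.zeros((n_probes, n_samples))

    sample_day_idx = np.array([day_index[d] for d in design.frame["day"]])
    sample_treat = design.frame["treatment"].to_numpy()
    sample_batch = design.frame["batch"].to_numpy()

    i = 0
    for a in config.assignments:
        eff = a.template.effect()  # per grid day
        arm_mask = (sample_treat == a.treatment).astype(float)
        row = eff[sample_day_idx] * arm_mask
        for _ in range(a.n_probes):
            template_of[i] = a.template.template_id
            affected[i] = a.treatment
            amplitude[i] = a.template.amplitude
            if a.gene is not None:
                genes[i] = a.gene
            effect_rows[i] = row
            i += 1

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches) if config.batch_sd > 0 \
        else np.zeros(config.n_batches)
    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    if config.heavy_tail_fraction > 0:
        mask = rng.random((n_probes, n_samples)) < config.heavy_tail_fraction
        heavy = rng.standard_t(3, size=(n_probes, n_samples)) * config.noise_sd * config.heavy_tail_scale
        noise = np.where(mask, heavy, noise)

    values = baseline[:, None] + effect_rows + batch_offsets[sample_batch - 1][None, :] + noise
    em = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=design.sample_ids),
        pd.Series(genes, index=probe_ids),
    )
    truth = SyntheticTruth(
        frame=pd.DataFrame({
            "probe_id": probe_ids, "gene": genes, "template_id": template_of,
            "affected_treatment": affected, "amplitude": amplitude,
            "noise_sd": config.noise_sd,
        }),
        seed=config.seed,
    )
    return em, design, truth


# ---------------------------------------------------------------------------
# Study-mimicking presets
# ---------------------------------------------------------------------------

def ba_mimic_config(seed: int, n_null: int = 1000, probes_per_template: int = 50,
                    noise_sd: float = 0.25, multi_probe_gene: str = "Psat1",
                    multi_probe_count: int = 7) -> SimulationConfig:
    """Beta-agonist-like preset: 9 well-separated high-amplitude templates.

    RMS amplitude is 5x the replicate noise sd, mirroring the large,
    tightly regulated, smoothly-varying responses of the beta-agonist arm.
    One early-peak template carries a 7-probe gene (several array probes
    reporting one transcript).
    """
    templates = circle_templates(9, amplitude=5.0 * noise_sd, phase_deg=day3_peak_phase(),
                                 prefix="ba")
    assignments = []
    for j, t in enumerate(templates):
        if j == 0 and multi_probe_count > 0:
            assignments.append(TemplateAssignment(t, multi_probe_count, "ba", gene=multi_probe_gene))
            assignments.append(TemplateAssignment(t, probes_per_template - multi_probe_count, "ba"))
        else:
            assignments.append(TemplateAssignment(t, probes_per_template, "ba"))
    n_probes = 9 * probes_per_template + n_null
    return SimulationConfig(n_probes=n_probes, assignments=assignments,
                            noise_sd=noise_sd, seed=seed)


def gh_mimic_config(seed: int, n_null: int = 1000, probes_per_template: int = 40,
                    noise_sd: float = 0.5) -> SimulationConfig:
    """Growth-hormone-like preset: 12 low-amplitude transient templates in
    elevated noise.

    RMS amplitude is 2x the replicate noise sd, and each template combines
    a weak smooth trend with a sharp single-day transient that a degree-2
    curve cannot capture (lack_of_fit).  Responses are therefore real but
    weak and poorly fitted: selected models pass an R^2 filter of 0.2 but
    essentially never 0.5, reproducing the qualitative contrast between
    the two treatment arms.
    """
    templates = circle_templates(12, amplitude=2.0 * noise_sd, phase_deg=day3_peak_phase(),
                                 prefix="gh", lack_of_fit=1.1)
    assignments = [TemplateAssignment(t, probes_per_template, "gh") for t in templates]
    n_probes = 12 * probes_per_template + n_null
    return SimulationConfig(n_probes=n_probes, assignments=assignments,
                            noise_sd=noise_sd, seed=seed)


def null_config(seed: int, n_probes: int = 10000, noise_sd: float = 0.25) -> SimulationConfig:
    """All-null preset for type-I-error calibration."""
    return SimulationConfig(n_probes=n_probes, assignments=[], noise_sd=noise_sd, seed=seed)


def generate_phenotypes(seed: int, group_sizes: dict = None, n_batches: int = 3,
                        baseline: float = 70.0, treatment_effects: dict = None,
                        day_slope: float = 0.35, batch_sd: float = 1.0,
                        noise_sd: float = 3.0, response: str = "carcass_kg") -> pd.DataFrame:
    """Synthetic animal-level phenotype table (one response column).

    response = baseline + day_slope*day + treatment effect (scaling with day)
             + batch offset + noise; emulates carcass-weight-like growth data
    for exercising the blocked two-way ANOVA / Dunnett layer.
    """
    rng = np.random.default_rng(seed)
    group_sizes = dict(DEFAULT_GROUP_SIZES) if group_sizes is None else group_sizes
    treatment_effects = {"control": 0.0, "ba": 4.0, "gh": 3.0} if treatment_effects is None \
        else treatment_effects
    design = build_design(group_sizes, n_batches)
    batch_off = rng.normal(0.0, batch_sd, size=n_batches)
    rows = []
    for _, r in design.frame.iterrows():
        eff = treatment_effects[r["treatment"]] * r["day"] / max(group_sizes)
        val = baseline + day_slope * r["day"] + eff + batch_off[int(r["batch"]) - 1] \
            + rng.normal(0.0, noise_sd)
        rows.append({"animal_id": r["sample_id"], "batch": int(r["batch"]),
                     "treatment": r["treatment"], "day": r["day"], response: val})
    return pd.DataFrame(rows)


def write_study(outdir: str | Path, em: ExpressionMatrix, design: StudyDesign,
                truth: SyntheticTruth, config: SimulationConfig) -> dict:
    """Write the TSV/JSON artifacts of one simulated study; returns the paths."""
    from .core import write_design, write_expression
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "simulation_config.json",
    }
    write_expression(em, paths["expression"], annotation_path=paths["annotation"])
    write_design(design, paths["design"])
    truth.write(paths["truth"])
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
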