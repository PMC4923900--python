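"""Animal-level statistics: blocked two-way ANOVA, SED, and Dunnett tests.

Growth and protein phenotypes from the three-arm trial are analysed by a
two-way ANOVA (treatment, time, treatment x time) with an additive block
term for pig batch, fitted sequentially so the block is removed first.
The standard error of difference (SED) between two group means uses the
pooled residual mean square.  Many-to-one comparisons of each treatment
against the control use Dunnett's procedure, with the critical values of
the correlated max-|t| null obtained by seeded Monte-Carlo so unbalanced
group sizes (n = 15 at day 27 vs 10 elsewhere) are handled exactly.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError


@dataclasses.dataclass
class AnovaResult:
    """Decomposition table plus the quantities downstream reporting needs.

    table : per-term sum_sq, df, F, p (last row 'residual').
    mse : residual mean square; df_resid its degrees of freedom.
    group_means : cell or group means of the response.
    sed : standard error of difference per group pair (when computed).
    """

    table: pd.DataFrame
    mse: float
    df_resid: int
    group_means: pd.Series
    sed: pd.Series | None = None


def _anova_from_formula(frame: pd.DataFrame, formula: str) -> pd.DataFrame:
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols(formula, data=frame).fit()
    # sequential (Type I) sums of squares: the block enters first and is
    # removed before treatment/time effects are assessed
    tbl = anova_lm(model, typ=1)
    tbl = tbl.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    tbl.index = [i.replace("C(", "").replace(")", "").replace(":", " x ") for i in tbl.index]
    tbl.index = [i.strip().lower() for i in tbl.index]
    tbl = tbl.rename(index={"residual": "residual"})
    return tbl[["df", "sum_sq", "F", "p"]]


def two_way_anova_blocked(values: Sequence[float], treatment: Sequence[str],
                          time: Sequence[float], batch: Sequence[int] | None = None
                          ) -> AnovaResult:
    """Two-way ANOVA with treatment, time and interaction, optionally batch-blocked.

    Every treatment x time cell must contain at least 2 observations so the
    interaction is testable against the residual.  All F tests use the
    residual mean square of the full sequential decomposition.
    """
    frame = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "treatment": pd.Categorical(treatment),
        "time": pd.Categorical(time),
    })
    if not np.all(np.isfinite(frame["y"])):
        raise InputError("non-finite response values")
    cells = frame.groupby(["treatment", "time"], observed=True).size()
    full = pd.MultiIndex.from_product([frame["treatment"].cat.categories,
                                       frame["time"].cat.categories])
    missing = [c for c in full if c not in cells.index or cells.get(c, 0) < 2]
    if missing:
        raise InputError(f"treatment x time cells with < 2 observations: {missing}")
    if batch is not None:
        frame["batch"] = pd.Categorical(batch)
        formula = "y ~ C(batch) + C(treatment) + C(time) + C(treatment):C(time)"
    else:
        formula = "y ~ C(treatment) + C(time) + C(treatment):C(time)"
    tbl = _anova_from_formula(frame, formula)
    mse = float(tbl.loc["residual", "sum_sq"] / tbl.loc["residual", "df"])
    means = frame.groupby(["treatment", "time"], observed=True)["y"].mean()
    ns = frame.groupby("treatment", observed=True).size()
    pairs = {}
    cats = list(frame["treatment"].cat.categories)
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            pairs[f"{a}-{b}"] = sed(mse, int(ns[a]), int(ns[b]))
    return AnovaResult(table=tbl, mse=mse, df_resid=int(tbl.loc["residual", "df"]),
                       group_means=means, sed=pd.Series(pairs))


def one_way_anova(values: Sequence[float], group: Sequence[str]) -> AnovaResult:
    """Standard one-way between/within decomposition."""
    frame = pd.DataFrame({"y": np.asarray(values, dtype=float),
                          "g": pd.Categorical(group)})
    counts = frame.groupby("g", observed=True).size()
    if len(counts) < 2:
        raise InputError("one-way ANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise InputError(f"groups with < 2 observations: {small}")
    grand = frame["y"].mean()
    means = frame.groupby("g", observed=True)["y"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((frame["y"] - means.loc[frame["g"]].to_numpy()) ** 2).sum())
    df_b, df_w = len(counts) - 1, len(frame) - len(counts)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else np.inf
    p = float(stats.f.sf(f, df_b, df_w))
    tbl = pd.DataFrame(
        {"df": [df_b, df_w], "sum_sq": [ss_between, ss_within],
         "F": [f, np.nan], "p": [p, np.nan]},
        index=["group", "residual"])
    ns = {f"{a}-{b}": sed(ms_w, int(counts[a]), int(counts[b]))
          for i, a in enumerate(counts.index) for b in counts.index[i + 1:]}
    return AnovaResult(table=tbl, mse=ms_w, df_resid=df_w, group_means=means,
                       sed=pd.Series(ns))


def sed(mse: float, n1: int, n2: int) -> float:
    """Standard error of the difference of two group means, pooled variance.

    sed = sqrt(mse * (1/n1 + 1/n2)); symmetric in (n1, n2).
    """
    if mse < 0:
        raise InputError(f"mse must be non-negative, got {mse}")
    if n1 < 1 or n2 < 1:
        raise InputError("group sizes must be >= 1")
    return float(np.sqrt(mse * (1.0 / n1 + 1.0 / n2)))


@dataclasses.dataclass
class DunnettResult:
    comparisons: pd.DataFrame  # treatment, diff, t, p_adjusted, significant
    alpha: float
    df_resid: int
    mse: float


def dunnett_test(group_values: Mapping[str, Sequence[float]], control_label: str,
                 alpha: float = 0.05, n_mc: int = 100_000, seed: int = 0) -> DunnettResult:
    """Dunnett many-to-one comparisons against a control group.

    For each treatment i, t_i = (mean_i - mean_0) / sqrt(MSE (1/n_i + 1/n_0))
    with the pooled within-group MSE.  Adjusted p-values are tail
    probabilities of max_i |T_i| under the joint null, estimated by seeded
    Monte-Carlo of the correlated t statistics (exact for unbalanced n).
    """
    if control_label not in group_values:
        raise InputError(f"control label {control_label!r} missing from groups "
                         f"{sorted(group_values)}")
    groups = {g: np.asarray(v, dtype=float) for g, v in group_values.items()}
    if len(groups) < 2:
        raise InputError("need at least one treatment group besides the control")
    for g, v in groups.items():
        if len(v) < 2:
            raise InputError(f"group {g!r} has fewer than 2 observations")
    ctrl = groups[control_label]
    treats = [g for g in groups if g != control_label]
    n_tot = sum(len(v) for v in groups.values())
    df = n_tot - len(groups)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df

    tstats = {}
    for g in treats:
        v = groups[g]
        tstats[g] = (v.mean() - ctrl.mean()) / np.sqrt(mse * (1 / len(v) + 1 / len(ctrl)))

    # Monte-Carlo of the null max-|t|: group means ~ N(0, 1/n), shared
    # chi-square variance estimate with df degrees of freedom
    rng = np.random.default_rng(seed)
    n0 = len(ctrl)
    m0 = rng.normal(0.0, 1.0 / np.sqrt(n0), size=n_mc)
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    maxabs = np.zeros(n_mc)
    for g in treats:
        ni = len(groups[g])
        mi = rng.normal(0.0, 1.0 / np.sqrt(ni), size=n_mc)
        ti = (mi - m0) / (s * np.sqrt(1 / ni + 1 / n0))
        maxabs = np.maximum(maxabs, np.abs(ti))

    rows = []
    for g in treats:
        padj = float((maxabs >= abs(tstats[g])).mean())
        rows.append({"treatment": g, "diff": groups[g].mean() - ctrl.mean(),
                     "t": tstats[g], "p_adjusted": padj, "significant": padj < alpha})
    comparisons = pd.DataFrame(rows)
    return DunnettResult(comparisons=comparisons, alpha=alpha, df_resid=df, mse=float(mse))


def phenotype_anova(frame: pd.DataFrame, response: str, block: bool = True,
                    dunnett: str = "auto", alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Study-style analysis of one phenotype column.

    Two-way blocked ANOVA (treatment, day, interaction); Dunnett vs control
    is run per the gate: 'auto' only when the interaction is not significant
    (the convention of reporting main treatment effects only when they are
    interpretable), 'always', or 'never'.
    """
    if dunnett not in ("auto", "always", "never"):
        raise InputError(f"dunnett gate must be auto/always/never, got {dunnett!r}")
    res = two_way_anova_blocked(frame[response], frame["treatment"], frame["day"],
                                frame["batch"] if block else None)
    inter_rows = [i for i in res.table.index if " x " in i]
    inter_p = float(res.table.loc[inter_rows[0], "p"]) if inter_rows else np.nan
    run_dunnett = dunnett == "always" or (dunnett == "auto" and not inter_p < alpha)
    dn = None
    if run_dunnett:
        groups = {g: sub[response].to_numpy() for g, sub in frame.groupby("treatment")}
        dn = dunnett_test(groups, "control", alpha=alpha, seed=seed)
    return {"anova": res, "interaction_p": inter_p, "dunnett": dn}
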