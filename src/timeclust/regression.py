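"""Two-stage time-course regression: global F filter, backward-stepwise term
selection, and R-squared stringency filtering.

Each probe is modelled per treatment contrast (treated arm vs control) by a
polynomial in log-transformed time with group-specific terms:

    y = b0 + b1*T + ... + bd*T^d + g*(c0 + c1*T + ... + cd*T^d) + e

where g indicates the treated arm.  Stage 1 keeps probes whose full model
is significant against the intercept-only model (ANOVA F-test, p < alpha).
Stage 2 reduces each kept model by backward elimination at alpha_step and
recomputes R^2; probes whose reduced model reaches the R^2 stringency
threshold enter clustering.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEFAULT_DAY_GRID, ExpressionMatrix, InputError, StudyDesign, transform_times


@dataclasses.dataclass
class RegressionConfig:
    """Tuning knobs of the two-stage engine.

    degree : polynomial degree in transformed time (at most n_times - 1).
    alpha_global : stage-1 probe filter level applied to the full-model F p.
    alpha_step : stage-2 backward-elimination retention level.
    r2_threshold : R^2 stringency for cluster entry (0.5 strict, 0.2 relaxed).
    contrast : treated arm compared against control ('ba' or 'gh').
    p_adjust : 'none' (raw p, the default) or 'fdr_bh'.
    """

    contrast: str = "ba"
    degree: int = 2
    alpha_global: float = 0.05
    alpha_step: float = 0.05
    r2_threshold: float = 0.5
    p_adjust: str = "none"

    def __post_init__(self):
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        for name in ("alpha_global", "alpha_step", "r2_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_adjust not in ("none", "fdr_bh"):
            raise ValueError(f"unknown p_adjust mode {self.p_adjust!r}")


@dataclasses.dataclass
class ProbeFit:
    """Per-probe regression result."""

    probe_id: str
    coefficients: pd.Series  # named terms of the (possibly reduced) model
    global_p: float
    selected_terms: tuple
    r_squared: float
    fitted_profiles: dict  # group -> fitted values over the day grid
    day_grid: tuple = DEFAULT_DAY_GRID


def build_design_matrix(design: StudyDesign, config: RegressionConfig) -> pd.DataFrame:
    """Model matrix for one contrast: shared polynomial + group polynomial.

    Terms: intercept, t, t2, ..., group, group_x_t, ...; control rows carry
    zeros in all group terms.  Raises if the design mixes in a third arm or
    if the matrix is rank-deficient (naming the collinear terms).
    """
    treatments = set(design.frame["treatment"])
    allowed = {"control", config.contrast}
    if not treatments <= allowed:
        raise InputError(f"design contains arms {sorted(treatments - allowed)}; "
                         f"expected only control + {config.contrast}")
    n_times = design.frame["day"].nunique()
    if config.degree > n_times - 1:
        raise InputError(f"degree {config.degree} too high for {n_times} distinct times")
    T = design.frame["transformed_time"].to_numpy()
    g = (design.frame["treatment"] == config.contrast).to_numpy(dtype=float)
    cols = {"intercept": np.ones_like(T)}
    for m in range(1, config.degree + 1):
        cols["t" if m == 1 else f"t{m}"] = T ** m
    cols[config.contrast] = g
    for m in range(1, config.degree + 1):
        suffix = "t" if m == 1 else f"t{m}"
        cols[f"{config.contrast}_x_{suffix}"] = g * T ** m
    X = pd.DataFrame(cols, index=design.frame["sample_id"].to_numpy())
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    rank = np.linalg.matrix_rank(A)
    if rank < X.shape[1]:
        # small R-diagonal entries localize the dependent columns
        _, rmat = np.linalg.qr(A)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < tol]
        raise InputError(f"model matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                         f"collinear terms: {bad or 'unresolved'}")


def _ols(y: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares: coefficients, RSS, TSS (about the mean)."""
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return beta, rss, tss


def _global_f_p(rss: float, tss: float, n: int, p_full: int) -> float:
    """F-test of the full model against intercept-only."""
    df1, df2 = p_full - 1, n - p_full
    if df2 <= 0 or tss <= 0:
        return 1.0
    num = (tss - rss) / df1
    den = rss / df2
    if den <= 0:
        return 0.0 if num > 0 else 1.0
    return float(stats.f.sf(num / den, df1, df2))


def _profile_rows(term_names: Sequence[str], day_grid: Sequence[float],
                  contrast: str) -> dict:
    """Prediction matrices (n_days x terms) for the control and treated groups."""
    T = transform_times(day_grid)
    rows = {}
    for group, gval in (("control", 0.0), (contrast, 1.0)):
        cols = []
        for name in term_names:
            if name == "intercept":
                cols.append(np.ones_like(T))
            elif name == contrast:
                cols.append(np.full_like(T, gval))
            elif name.startswith(f"{contrast}_x_"):
                suffix = name[len(contrast) + 3:]
                m = 1 if suffix == "t" else int(suffix[1:])
                cols.append(gval * T ** m)
            else:
                m = 1 if name == "t" else int(name[1:])
                cols.append(T ** m)
        rows[group] = np.column_stack(cols)
    return rows


def _contrast_of(X: pd.DataFrame) -> str:
    group_cols = [c for c in X.columns if c != "intercept" and not c.startswith("t")]
    mains = [c for c in group_cols if "_x_" not in c]
    if len(mains) != 1:
        raise InputError(f"cannot identify the group term among {list(X.columns)}")
    return mains[0]


def fit_probe(y: Sequence[float] | np.ndarray, X: pd.DataFrame, probe_id: str = "probe",
              day_grid: Sequence[float] = DEFAULT_DAY_GRID) -> ProbeFit:
    """Full-model least-squares fit of one probe.

    Returns coefficients, the global F-test p-value against intercept-only,
    R^2 of the full model, and fitted per-group profiles over the day grid.
    A response with zero variance yields R^2 = 0 and p = 1.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise InputError(f"y has {y.shape[0]} values but X has {X.shape[0]} rows")
    if not np.all(np.isfinite(y)):
        raise InputError(f"probe {probe_id}: non-finite response values")
    A = X.to_numpy()
    beta, rss, tss = _ols(y, A)
    r2 = 0.0 if tss <= 0 else max(0.0, 1.0 - rss / tss)
    global_p = _global_f_p(rss, tss, len(y), X.shape[1])
    contrast = _contrast_of(X)
    prof = _profile_rows(list(X.columns), day_grid, contrast)
    fitted = {grp: mat @ beta for grp, mat in prof.items()}
    return ProbeFit(probe_id=probe_id, coefficients=pd.Series(beta, index=X.columns),
                    global_p=global_p, selected_terms=tuple(X.columns),
                    r_squared=float(r2), fitted_profiles=fitted, day_grid=tuple(day_grid))


def fit_probes(Y: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
    """Vectorized full-model fit of every probe (rows of Y) against X.

    Returns a frame indexed by probe with columns global_p, r_squared and
    one column per coefficient (prefixed 'coef_').
    """
    if list(Y.columns) != list(X.index):
        Y = Y.loc[:, list(X.index)]
    A = X.to_numpy()
    Ymat = Y.to_numpy().T  # samples x probes
    beta, *_ = np.linalg.lstsq(A, Ymat, rcond=None)
    resid = Ymat - A @ beta
    rss = (resid ** 2).sum(axis=0)
    tss = ((Ymat - Ymat.mean(axis=0)) ** 2).sum(axis=0)
    n, p = A.shape
    df1, df2 = p - 1, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df1) / (rss / df2)
        r2 = np.where(tss > 0, 1.0 - rss / np.where(tss > 0, tss, 1.0), 0.0)
    pvals = np.where(tss > 0, stats.f.sf(f, df1, df2), 1.0)
    out = pd.DataFrame({"global_p": pvals, "r_squared": np.clip(r2, 0.0, 1.0)}, index=Y.index)
    for j, c in enumerate(X.columns):
        out[f"coef_{c}"] = beta[j]
    return out


def stepwise_select(fit: ProbeFit, y: Sequence[float] | np.ndarray, X: pd.DataFrame,
                    alpha_step: float = 0.05) -> ProbeFit:
    """Backward elimination of non-intercept terms at level alpha_step.

    Iteratively refits after dropping the non-intercept term with the
    largest t-test p-value above alpha_step, until every remaining term is
    retained.  R^2 and the fitted profiles are those of the final reduced
    model; the stage-1 global p is carried over unchanged.  Intercept-only
    is a valid terminal state.
    """
    y = np.asarray(y, dtype=float)
    contrast = _contrast_of(X)
    terms = list(X.columns)
    while True:
        A = X[terms].to_numpy()
        beta, rss, tss = _ols(y, A)
        n, p = A.shape
        df = n - p
        if len(terms) == 1 or df <= 0:
            break
        sigma2 = rss / df
        XtXi = np.linalg.pinv(A.T @ A)
        se = np.sqrt(np.maximum(np.diag(XtXi) * sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        candidates = [(pvals[i], terms[i]) for i in range(len(terms)) if terms[i] != "intercept"]
        worst_p, worst_term = max(candidates, key=lambda t: (t[0], t[1]))
        if worst_p <= alpha_step:
            break
        terms.remove(worst_term)
    r2 = 0.0 if tss <= 0 else max(0.0, 1.0 - rss / tss)
    prof = _profile_rows(terms, fit.day_grid, contrast)
    fitted = {grp: mat @ beta for grp, mat in prof.items()}
    return ProbeFit(probe_id=fit.probe_id, coefficients=pd.Series(beta, index=terms),
                    global_p=fit.global_p, selected_terms=tuple(terms),
                    r_squared=float(r2), fitted_profiles=fitted, day_grid=fit.day_grid)


def _adjusted_p(pvals: pd.Series, mode: str) -> pd.Series:
    if mode == "none":
        return pvals
    from statsmodels.stats.multitest import multipletests
    return pd.Series(multipletests(pvals.to_numpy(), method="fdr_bh")[1], index=pvals.index)


def significant_probes(fits: pd.DataFrame, alpha_global: float,
                       p_adjust: str = "none") -> pd.Index:
    """Stage-1 filter: probes with (optionally BH-adjusted) global p strictly below alpha."""
    if len(fits) == 0:
        return pd.Index([])
    p = _adjusted_p(fits["global_p"], p_adjust)
    return fits.index[p < alpha_global]


def r2_filter(fits: pd.DataFrame, r2_threshold: float) -> pd.Index:
    """Stage-2 stringency filter: probes with R^2 >= threshold (inclusive)."""
    if len(fits) == 0:
        return pd.Index([])
    return fits.index[fits["r_squared"] >= r2_threshold]


@dataclasses.dataclass
class ContrastFit:
    """All per-probe results for one treatment contrast.

    table columns: gene, global_p, r2_full, selected_terms, r_squared
    (reduced model; NaN when stepwise was not run for that probe), and
    fitted profile columns fit_control_d{day} / fit_<contrast>_d{day}.
    """

    contrast: str
    config: RegressionConfig
    table: pd.DataFrame
    day_grid: tuple

    def significant(self, alpha: float | None = None) -> pd.Index:
        alpha = self.config.alpha_global if alpha is None else alpha
        return significant_probes(self.table, alpha, self.config.p_adjust)

    def survivors(self, r2_threshold: float | None = None) -> pd.Index:
        """Probes passing both the significance and the R^2 filters."""
        thr = self.config.r2_threshold if r2_threshold is None else thr_check(r2_threshold)
        sig = self.significant()
        stepped = self.table.loc[sig].dropna(subset=["r_squared"])
        return r2_filter(stepped, thr)

    def profiles(self, probes: Iterable[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(treated, control) fitted profile frames over the day grid."""
        probes = pd.Index(probes)
        tcols = [f"fit_{self.contrast}_d{d:g}" for d in self.day_grid]
        ccols = [f"fit_control_d{d:g}" for d in self.day_grid]
        return self.table.loc[probes, tcols], self.table.loc[probes, ccols]


def thr_check(v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"r2_threshold must lie in [0, 1], got {v}")
    return v


def fit_contrast(em: ExpressionMatrix, design: StudyDesign, config: RegressionConfig,
                 stepwise: str = "significant") -> ContrastFit:
    """Run the full two-stage engine for one contrast over all probes.

    stepwise: 'significant' (default) runs backward elimination only on
    probes passing the stage-1 filter; 'all' on every probe; 'none' skips
    stage 2 (r_squared column stays NaN).
    """
    sub = design.subset(["control", config.contrast])
    X = build_design_matrix(sub, config)
    Y = em.values.loc[:, list(X.index)]
    full = fit_probes(Y, X)
    day_grid = tuple(sub.day_grid) if sub.day_grid else tuple(sub.days())

    table = pd.DataFrame(index=Y.index)
    table["gene"] = em.annotation.reindex(Y.index).fillna("")
    table["global_p"] = full["global_p"]
    table["r2_full"] = full["r_squared"]
    table["selected_terms"] = ""
    table["r_squared"] = np.nan
    for grp in ("control", config.contrast):
        for d in day_grid:
            table[f"fit_{grp}_d{d:g}"] = np.nan

    if stepwise == "all":
        todo = Y.index
    elif stepwise == "significant":
        todo = significant_probes(full, config.alpha_global, config.p_adjust)
    elif stepwise == "none":
        todo = pd.Index([])
    else:
        raise ValueError(f"unknown stepwise mode {stepwise!r}")

    for probe in todo:
        y = Y.loc[probe].to_numpy()
        base = ProbeFit(probe_id=probe, coefficients=pd.Series(dtype=float),
                        global_p=float(full.loc[probe, "global_p"]), selected_terms=(),
                        r_squared=float(full.loc[probe, "r_squared"]),
                        fitted_profiles={}, day_grid=day_grid)
        red = stepwise_select(base, y, X, config.alpha_step)
        table.loc[probe, "selected_terms"] = ",".join(red.selected_terms)
        table.loc[probe, "r_squared"] = red.r_squared
        for grp, vals in red.fitted_profiles.items():
            for d, v in zip(day_grid, vals):
                table.loc[probe, f"fit_{grp}_d{d:g}"] = v

    return ContrastFit(contrast=config.contrast, config=config, table=table, day_grid=day_grid)
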