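"""Per-time-point differential expression and overlap summaries.

At each sampling day, every probe is compared between one treated arm and
the control arm with a Welch two-sample t-test.  The module also provides
Venn-style overlap counts between the two treatments' significant sets and
the top-N-overlap statistic relating cluster membership to the per-day
significance ranking.
"""
from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, InputError, StudyDesign, normalize_treatment

logger = logging.getLogger(__name__)


def per_time_de(em: ExpressionMatrix, design: StudyDesign, day: float,
                contrast: str, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test of treated vs control for every probe at one day.

    Returns a frame with columns effect (treated minus control mean, log
    units), p, rank (ascending p, ties broken by probe id), significant
    (p < alpha).  Probes where both groups have zero variance get p = NaN
    and are reported non-significant with a logged warning.
    """
    contrast = normalize_treatment(contrast)
    treated_ids = design.samples_at(day, contrast)
    control_ids = design.samples_at(day, "control")
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise InputError(f"day {day}: need >= 2 samples per group "
                         f"(got {len(treated_ids)} treated, {len(control_ids)} control)")
    a = em.values[treated_ids].to_numpy()
    b = em.values[control_ids].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    effect = a.mean(axis=1) - b.mean(axis=1)
    n_undef = int(np.isnan(p).sum())
    if n_undef:
        logger.warning("day %s %s: %d probes with undefined Welch p (zero variance); "
                       "reported non-significant", day, contrast, n_undef)
    out = pd.DataFrame({"effect": effect, "p": p}, index=em.values.index)
    # rank by ascending p, ties (and NaNs last) broken lexicographically by probe id
    sort_key = pd.DataFrame({"p": np.where(np.isnan(p), np.inf, p),
                             "probe": out.index}, index=out.index)
    ranked = sort_key.sort_values(["p", "probe"]).index
    out["rank"] = pd.Series(np.arange(1, len(out) + 1), index=ranked)
    out["significant"] = (out["p"] < alpha).fillna(False)
    out.index.name = "probe_id"
    return out


def venn_counts(sig_a: Iterable[str], sig_b: Iterable[str]) -> tuple[int, int, int]:
    """(only_A, only_B, shared) counts for two significant sets."""
    a, b = set(sig_a), set(sig_b)
    shared = len(a & b)
    return len(a) - shared, len(b) - shared, shared


def top_n_cluster_overlap(de: pd.DataFrame, clustered_probes: Iterable[str],
                          n: int) -> float:
    """Percentage of clustered probes appearing in the top n by DE rank.

    Raises on an empty clustered set (the statistic is undefined there).
    """
    clustered = pd.Index(clustered_probes)
    if len(clustered) == 0:
        raise InputError("top-n overlap undefined for an empty clustered set")
    if n > len(de):
        raise InputError(f"n={n} exceeds the {len(de)} ranked probes")
    top = set(de.index[de["rank"] <= n])
    hits = sum(1 for p in clustered if p in top)
    return 100.0 * hits / len(clustered)


def venn_summary(em: ExpressionMatrix, design: StudyDesign,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-day Venn counts between the BA and GH significant sets."""
    rows = []
    for day in design.days():
        de_ba = per_time_de(em, design, day, "ba", alpha)
        de_gh = per_time_de(em, design, day, "gh", alpha)
        only_ba, only_gh, shared = venn_counts(de_ba.index[de_ba["significant"]],
                                               de_gh.index[de_gh["significant"]])
        rows.append({"day": day, "only_ba": only_ba, "only_gh": only_gh,
                     "shared": shared, "total_ba": only_ba + shared,
                     "total_gh": only_gh + shared})
    return pd.DataFrame(rows)
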