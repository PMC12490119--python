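"""Prevalence, odds-ratio, multimorbidity, trend, and score comparisons.

Group contrasts follow the two primary comparisons of a preterm-ASD cohort
design: preterm vs term within ASD, and ASD vs non-ASD within preterm.
Odds ratios use the Haldane-Anscombe 0.5 correction for zero cells and
Woolf (log-normal) confidence intervals; p-values come from the Pearson
chi-square on the 2x2 (Fisher's exact when any expected cell is below 5);
multiplicity is controlled with Benjamini-Hochberg FDR per analysis family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CATEGORIES, DiagnosticProfile

logger = logging.getLogger(__name__)

MULTIMORBIDITY_BUCKETS = ("0", "1", "2", "3", "4", "5+")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a exposed-case, b exposed-noncase, c unexposed-case,
    d unexposed-noncase."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float | None = None


def prevalence(
    profiles: Sequence[DiagnosticProfile],
    group_ids: set[str] | Sequence[str],
    category: str,
) -> float:
    """Fraction of group members with any specific diagnosis in a category.

    A person with several specific diagnoses inside one category counts
    once.
    """
    ids = set(group_ids)
    members = [p for p in profiles if p.person_id in ids]
    if not members:
        raise ValueError("empty group")
    return sum(p.categories[category] for p in members) / len(members)


def odds_ratio(table: ContingencyTable) -> ORResult:
    """Odds ratio with Woolf 95% CI and chi-square (or Fisher) p-value.

    The Haldane-Anscombe correction adds 0.5 to every cell when any cell is
    zero, for both the estimate and the CI.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("a margin of the table is empty")
    cells = [a, b, c, d]
    if min(cells) == 0:
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_) - 1.96 * se_log)
    ci_high = math.exp(math.log(or_) + 1.96 * se_log)
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    expected = stats.contingency.expected_freq(obs) if obs.sum() else obs
    if (expected < 5).any():
        p = stats.fisher_exact(obs)[1]
    else:
        p = stats.chi2_contingency(obs, correction=False)[1]
    return ORResult(odds_ratio=or_, ci_low=ci_low, ci_high=ci_high, p_raw=float(p))


def category_table(
    profiles: Sequence[DiagnosticProfile],
    exposed_ids: set[str],
    unexposed_ids: set[str],
    category: str,
) -> ContingencyTable:
    by_id = {p.person_id: p for p in profiles}
    a = sum(by_id[i].categories[category] for i in exposed_ids if i in by_id)
    c = sum(by_id[i].categories[category] for i in unexposed_ids if i in by_id)
    n_e = sum(i in by_id for i in exposed_ids)
    n_u = sum(i in by_id for i in unexposed_ids)
    return ContingencyTable(a=a, b=n_e - a, c=c, d=n_u - c)


def category_comparison(
    profiles: Sequence[DiagnosticProfile],
    exposed_ids: set[str],
    unexposed_ids: set[str],
) -> pd.DataFrame:
    """Prevalence and OR for all nine categories, FDR over the category family."""
    rows = []
    for cat in CATEGORIES:
        res = odds_ratio(category_table(profiles, exposed_ids, unexposed_ids, cat))
        rows.append(
            {
                "category": cat,
                "prev_exposed": prevalence(profiles, exposed_ids, cat),
                "prev_unexposed": prevalence(profiles, unexposed_ids, cat),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_raw": res.p_raw,
            }
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
    return df


def multimorbidity_bucket(n_categories: int) -> str:
    return "5+" if n_categories >= 5 else str(n_categories)


def multimorbidity_distribution(
    profiles: Sequence[DiagnosticProfile],
    groups: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, float, pd.DataFrame | None]:
    """Bucketed multimorbidity counts per group with an overall chi-square.

    Returns (bucket-count table, chi-square p over group x bucket, and per-
    bucket OR table between the first two groups when exactly two or more
    groups are supplied).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    by_id = {p.person_id: p for p in profiles}
    counts = pd.DataFrame(0, index=list(groups), columns=list(MULTIMORBIDITY_BUCKETS))
    for name, ids in groups.items():
        for pid in ids:
            if pid in by_id:
                counts.loc[name, multimorbidity_bucket(by_id[pid].multimorbidity)] += 1
    table = counts.to_numpy(dtype=float)
    keep = table.sum(axis=0) > 0
    chi_p = float(stats.chi2_contingency(table[:, keep])[1]) if keep.sum() > 1 else 1.0

    or_table = None
    names = list(groups)
    g1, g2 = names[0], names[1]
    rows = []
    for bucket in MULTIMORBIDITY_BUCKETS:
        a = int(counts.loc[g1, bucket])
        b = int(counts.loc[g1].sum() - a)
        c = int(counts.loc[g2, bucket])
        d = int(counts.loc[g2].sum() - c)
        try:
            res = odds_ratio(ContingencyTable(a=a, b=b, c=c, d=d))
        except ValueError:
            continue
        rows.append(
            {"bucket": bucket, "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p_raw": res.p_raw}
        )
    if rows:
        or_table = pd.DataFrame(rows)
        or_table["p_fdr"] = fdr_adjust(or_table["p_raw"].to_numpy())
    return counts, chi_p, or_table


def preterm_trend(prevalence_by_stratum: Mapping[str, float]) -> tuple[float, float]:
    """Kendall rank correlation of ordered gestational-age strata with
    prevalence.

    Strata are ranked from lowest gestational age upward (extremely=1 ...
    term last), so a negative tau means prevalence falls as gestational age
    rises toward term. Constant prevalences make tau undefined (NaN).
    """
    strata = list(prevalence_by_stratum)
    if len(strata) < 3:
        raise ValueError("need at least three ordered strata")
    ranks = np.arange(1, len(strata) + 1, dtype=float)
    prevs = np.array([prevalence_by_stratum[s] for s in strata], dtype=float)
    if np.allclose(prevs, prevs[0]):
        return math.nan, math.nan
    tau, p = stats.kendalltau(ranks, prevs)
    return float(tau), float(p)


def compare_scores(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum for two groups, Kruskal-Wallis for more.

    Missing values must be dropped by the caller; groups with fewer than
    two observations are rejected. Returns (statistic, p, test name).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    small = [k for k, v in groups.items() if len(v) < 2]
    if small or len(groups) < 2:
        logger.warning("comparison skipped: groups too small (%s)", small)
        return math.nan, math.nan, "missing"
    if len(groups) == 2:
        x, y = groups.values()
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(stat), float(p), "wilcoxon_rank_sum"
    stat, p = stats.kruskal(*groups.values())
    return float(stat), float(p), "kruskal_wallis"


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def posthoc_stratum_tests(
    profiles: Sequence[DiagnosticProfile],
    ids_by_stratum: Mapping[str, set[str]],
    category: str,
) -> pd.DataFrame:
    """All pairwise stratum 2x2 comparisons for one category, FDR over pairs."""
    strata = list(ids_by_stratum)
    rows = []
    for i, s1 in enumerate(strata):
        for s2 in strata[i + 1:]:
            res = odds_ratio(
                category_table(profiles, set(ids_by_stratum[s1]), set(ids_by_stratum[s2]), category)
            )
            rows.append({"stratum_a": s1, "stratum_b": s2, "odds_ratio": res.odds_ratio,
                         "p_raw": res.p_raw})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
    return df
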