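"""Spatio-temporal haplogroup frequency statistics.

Cross-tabulates classifications by region, birth period, area type or year;
tests per-haplogroup frequency differences with the two-sided Fisher exact
test (point-probability convention, matching standard exact-test routines)
or its Monte-Carlo permutation extension for r x c tables; applies Bonferroni
correction (default m = 14 simultaneously compared groups: 13 haplogroup bins
plus the unassignable column); and computes yearly proportion series with
Wilson confidence intervals plus a weighted least-squares trend slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom
from statsmodels.stats.proportion import proportion_confint

from . import danish_cohort as dk
from .classify import UNASSIGNED, HgCall

__all__ = [
    "FreqTestResult",
    "crosstab",
    "percentages",
    "paper_bin",
    "fisher_exact_2x2",
    "permutation_fisher",
    "bonferroni",
    "compare_groups",
    "yearly_trend",
    "trend_slope",
]

# Relative tolerance when comparing table probabilities to the observed
# table's probability (the convention of standard exact-test routines).
_REL_TOL = 1e-7


@dataclass
class FreqTestResult:
    """One focal-haplogroup comparison between two groups."""

    haplogroup: str
    table: tuple[int, int, int, int]  # (a, b, c, d): focal/other x group1/group2
    p_value: float
    method: str  # "exact" | "monte_carlo"
    significant: bool | None = None
    alpha: float | None = None
    m: int | None = None
    n_perm: int | None = None
    seed: int | None = None


def paper_bin(call: HgCall) -> str:
    """Collapse a classification onto the merged reporting bins of the
    published regional/temporal tables.

    L0-L6 and M report as the macro-haplogroups "L" and "M"; within N, the
    haplogroups I, W and X report separately and everything else as "N";
    within R, the haplogroup label (or "R" when unresolved). Samples without
    a macro assignment report as "NA".
    """
    if call.macro_hg == UNASSIGNED:
        return "NA"
    if call.macro_hg.startswith("L"):
        return "L"
    if call.macro_hg == "M":
        return "M"
    if call.macro_hg == "N":
        return call.hg if call.hg in ("I", "W", "X") else "N"
    return call.hg if call.hg != UNASSIGNED else "R"


def _label_for(call: HgCall, level: str, use_bins: bool) -> str:
    if level == "paper":
        return paper_bin(call)
    lab = call.label_at(level)
    if lab == UNASSIGNED:
        return "NA"
    if use_bins and level == "subhg":
        return dk.SUBHG_BINS.get(lab, lab)
    return lab


def crosstab(
    calls: list[HgCall],
    meta: pd.DataFrame,
    grouping: str = "region",
    level: str = "paper",
    bins: list[tuple[int, int]] | None = None,
    use_subhg_bins: bool = True,
) -> pd.DataFrame:
    """Group x haplogroup contingency table of counts.

    grouping: "region", "area" (metropolitan vs rural), "year", or "period"
    (requires ``bins``, a list of inclusive (start, end) year ranges; samples
    outside every bin are dropped). level: "macro", "hg", "subhg", or "paper"
    (the published tables' merged bins). Unassigned samples tally in an "NA"
    column. Percentages per group are available via :func:`percentages`.
    """
    if not calls:
        return pd.DataFrame()
    meta_idx = meta.set_index("sample_id")
    missing = [c.sample_id for c in calls if c.sample_id not in meta_idx.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    rows = []
    for call in calls:
        info = meta_idx.loc[call.sample_id]
        if grouping == "region":
            group = info["region"]
        elif grouping == "area":
            group = "metropolitan" if bool(info["metro"]) else "rural"
        elif grouping == "year":
            group = int(info["birth_year"])
        elif grouping == "period":
            if bins is None:
                raise ValueError("period grouping requires bins")
            year = int(info["birth_year"])
            group = next(
                (f"{lo}-{hi}" for lo, hi in bins if lo <= year <= hi), None
            )
            if group is None:
                continue
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        rows.append((group, _label_for(call, level, use_subhg_bins)))
    frame = pd.DataFrame(rows, columns=["group", "haplogroup"])
    table = pd.crosstab(frame["group"], frame["haplogroup"])
    return table


def percentages(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Per-group (row) percentages, rounded as in the published tables."""
    return (table.div(table.sum(axis=1), axis=0) * 100).round(decimals)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities not exceeding the observed
    table's probability (point-probability / minimum-likelihood convention).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    n = a + b + c + d
    if n == 0 or min(a + b, c + d) < 0 or (a + c) == n == 0:
        raise ValueError("degenerate table")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0  # a zero margin makes every table equally (un)informative
    K = a + b  # row-1 total
    nn = a + c  # column-1 total
    rv = hypergeom(n, K, nn)
    support = np.arange(max(0, nn - (n - K)), min(K, nn) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return min(p, 1.0)


def _log_table_prob(table: np.ndarray) -> float:
    """Log point probability of an r x c table under fixed margins."""
    table = np.asarray(table, dtype=np.int64)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def permutation_fisher(
    table: pd.DataFrame | np.ndarray, n_perm: int = 10000, seed: int = 0
) -> FreqTestResult:
    """Monte-Carlo Fisher exact test for r x c contingency tables.

    The test statistic is the table's point probability under fixed margins;
    permutation replicates are generated by shuffling column labels across
    samples, and the add-one estimator p = (1 + #{P_perm <= P_obs}) /
    (n_perm + 1) avoids zero p-values. 2x2 input delegates to the exact
    routine.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins")
    if arr.shape == (2, 2):
        p = fisher_exact_2x2(*arr.ravel().tolist())
        return FreqTestResult("", tuple(arr.ravel().tolist()), p, "exact")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(arr.shape[0]), arr.sum(axis=1))
    cols = np.repeat(np.arange(arr.shape[1]), arr.sum(axis=0))
    obs = _log_table_prob(arr)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        t = np.zeros_like(arr)
        np.add.at(t, (rows, perm), 1)
        if _log_table_prob(t) <= obs + 1e-9:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return FreqTestResult(
        "", (0, 0, 0, 0), p, "monte_carlo", n_perm=n_perm, seed=seed
    )


def bonferroni(
    results: list[FreqTestResult], alpha: float = 0.05, m: int | None = None
) -> list[FreqTestResult]:
    """Annotate results with Bonferroni decisions: significant iff
    p <= alpha / m. ``m`` defaults to the number of comparisons and may be
    overridden (the published tables use m = 14)."""
    if m is None:
        m = len(results)
    if m < len(results):
        raise ValueError(
            f"m={m} smaller than the {len(results)} comparisons; override explicitly"
        )
    for res in results:
        res.alpha = alpha
        res.m = m
        res.significant = res.p_value <= alpha / m
    return results


def compare_groups(
    table: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
    m: int | None = None,
) -> list[FreqTestResult]:
    """Per-haplogroup 2x2 Fisher tests between two rows of a crosstab.

    For each haplogroup column, collapses the table to focal-vs-others and
    tests group_a against group_b; Bonferroni-corrects across columns
    (``m`` defaults to the number of columns).
    """
    if group_a not in table.index or group_b not in table.index:
        raise ValueError("both groups must be rows of the table")
    tot_a = int(table.loc[group_a].sum())
    tot_b = int(table.loc[group_b].sum())
    results = []
    for hg in table.columns:
        a = int(table.loc[group_a, hg])
        c = int(table.loc[group_b, hg])
        p = fisher_exact_2x2(a, tot_a - a, c, tot_b - c)
        results.append(
            FreqTestResult(str(hg), (a, tot_a - a, c, tot_b - c), p, "exact")
        )
    return bonferroni(results, alpha=alpha, m=m if m is not None else len(results))


def yearly_trend(
    calls: list[HgCall],
    meta: pd.DataFrame,
    hg_set,
    level: str = "paper",
    restrict_macro: str | None = None,
) -> pd.DataFrame:
    """Per-year proportion of one or more haplogroup bins, with Wilson 95% CIs.

    ``hg_set`` is a label or collection of labels at the requested level
    (default: the published merged bins). ``restrict_macro`` restricts the
    denominator to samples of one macro-haplogroup (e.g. the share of U
    within the R macro-haplogroup).
    """
    if isinstance(hg_set, str):
        hg_set = {hg_set}
    hg_set = set(hg_set)
    meta_idx = meta.set_index("sample_id")
    rows = []
    for call in calls:
        info = meta_idx.loc[call.sample_id]
        if restrict_macro is not None and call.macro_hg != restrict_macro:
            continue
        rows.append((int(info["birth_year"]), _label_for(call, level, True)))
    frame = pd.DataFrame(rows, columns=["year", "label"])
    if frame.empty or frame["year"].nunique() < 2:
        raise ValueError("need samples spanning at least two years")
    out = []
    for year, grp in frame.groupby("year"):
        denom = len(grp)
        count = int(grp["label"].isin(hg_set).sum())
        lo, hi = proportion_confint(count, denom, alpha=0.05, method="wilson")
        out.append((year, count, denom, count / denom, lo, hi))
    return pd.DataFrame(
        out, columns=["year", "count", "denominator", "proportion", "ci_low", "ci_high"]
    ).sort_values("year", ignore_index=True)


def trend_slope(series: pd.DataFrame) -> tuple[float, float]:
    """Weighted least-squares slope (per year) of a yearly proportion series.

    Weights are the per-year denominators. Returns (slope, standard error).
    """
    import statsmodels.api as sm

    x = sm.add_constant(series["year"].to_numpy(dtype=float))
    y = series["proportion"].to_numpy(dtype=float)
    w = series["denominator"].to_numpy(dtype=float)
    fit = sm.WLS(y, x, weights=w).fit()
    return float(fit.params[1]), float(fit.bse[1])
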