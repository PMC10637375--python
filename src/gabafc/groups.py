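"""Nonparametric comparison of FC distributions across age groups.

Per subunit gene, per-cell FC1 values are compared between age groups
(fetal / pediatric / adolescent / adult) with the two-sided Wilcoxon
rank-sum test for each group pair and the Kruskal-Wallis test across all
groups.  Small samples (both groups <= 10) use exact enumeration of the
rank-sum null — which handles ties by midranks, so two identical tied
groups give p = 1 — larger samples use the tie-corrected normal (pairwise)
and chi-square (omnibus) approximations.  Significance is flagged at a raw
alpha; no correction across the 19 subunits is applied, and the result
records how many tests were run.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import scipy.stats

from .errors import EstimationError
from .fc import CellFCProfile, DatasetFCSummary, aggregate_fc

logger = logging.getLogger("gabafc.groups")

EXACT_MAX_N = 10


def exact_rank_sum_p(x, y) -> float:
    """Exact two-sided Wilcoxon rank-sum p by full enumeration.

    Pooled values are midranked (ties supported); the p-value is the
    fraction of all C(n1+n2, n1) assignments of ranks to the first group
    whose rank-sum deviates from its null mean at least as much as
    observed.  Intended for small samples (enumeration is exponential).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise EstimationError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)

    total = comb(n1 + n2, n1)
    idx = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(n1 + n2), n1)
        ),
        dtype=np.intp,
        count=total * n1,
    ).reshape(total, n1)
    w_all = ranks[idx].sum(axis=1)
    count = int((np.abs(w_all - mean_w) >= dev_obs - 1e-9).sum())
    return count / total


def rank_sum_test(x, y) -> tuple[float, str]:
    """Two-sided rank-sum p and the method used ("exact" or "normal").

    Exact enumeration when both samples have <= 10 observations; the
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return exact_rank_sum_p(x, y), "exact"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "normal"


def kruskal_wallis_p(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis p (chi-square approximation, tie-corrected).

    All pooled values identical is the no-evidence case: p = 1.
    """
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(scipy.stats.kruskal(*groups).pvalue)


@dataclass
class GroupComparisonResult:
    """Per-subunit group comparison over age groups.

    ``pairwise_p`` is a long-format frame (gene, group_a, group_b, p,
    method, significant); ``kruskal_p`` indexes omnibus p by gene.
    """

    group_sizes: dict[str, int]
    medians: pd.DataFrame            # groups x genes
    means: pd.DataFrame              # groups x genes
    pairwise_p: pd.DataFrame
    kruskal_p: pd.Series
    alpha: float
    n_tests: int
    dropped_groups: list[str] = field(default_factory=list)


def _profiles_to_frame(profiles) -> pd.DataFrame:
    """Accept a per-cell FC frame or a list of CellFCProfile objects."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    rows = [p.fc for p in profiles if isinstance(p, CellFCProfile) and p.defined]
    return pd.DataFrame(rows)


def compare_fc_groups(
    profiles_by_group: dict[str, "pd.DataFrame | list[CellFCProfile]"],
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Compare per-cell FC distributions between groups, per subunit gene.

    Groups contributing zero defined profiles are dropped with a warning;
    fewer than two usable groups is an estimation error.
    """
    frames: dict[str, pd.DataFrame] = {}
    dropped: list[str] = []
    for name, profiles in profiles_by_group.items():
        df = _profiles_to_frame(profiles)
        if df.empty:
            dropped.append(name)
            warnings.warn(f"group {name!r} has no defined FC profiles; dropped",
                          stacklevel=2)
            continue
        frames[name] = df
    if len(frames) < 2:
        raise EstimationError(
            f"need >= 2 groups with defined profiles, got {len(frames)}"
        )

    group_names = list(frames)
    genes = list(frames[group_names[0]].columns)
    for name, df in frames.items():
        if list(df.columns) != genes:
            raise EstimationError(f"group {name!r} covers a different panel")

    medians = pd.DataFrame({g: frames[g].median(axis=0) for g in group_names}).T
    means = pd.DataFrame({g: frames[g].mean(axis=0) for g in group_names}).T

    records = []
    kw = {}
    for gene in genes:
        samples = {g: frames[g][gene].to_numpy(dtype=float) for g in group_names}
        for a, b in itertools.combinations(group_names, 2):
            p, method = rank_sum_test(samples[a], samples[b])
            records.append(
                {
                    "gene": gene,
                    "group_a": a,
                    "group_b": b,
                    "p": p,
                    "method": method,
                    "significant": p < alpha,
                }
            )
        kw[gene] = kruskal_wallis_p([samples[g] for g in group_names])

    pairwise = pd.DataFrame.from_records(records)
    kruskal = pd.Series(kw, name="kruskal_p")
    n_tests = len(pairwise) + len(kruskal)
    return GroupComparisonResult(
        group_sizes={g: len(frames[g]) for g in group_names},
        medians=medians,
        means=means,
        pairwise_p=pairwise,
        kruskal_p=kruskal,
        alpha=alpha,
        n_tests=n_tests,
        dropped_groups=dropped,
    )


def fc_by_group_table(
    summaries_by_group: dict[str, list[DatasetFCSummary]],
    statistic: str = "fc1_mean",
) -> pd.DataFrame:
    """Groups (rows) by panel genes (columns): unweighted mean over each
    group's datasets."""
    if not summaries_by_group:
        raise EstimationError("at least one group required")
    rows = {}
    for group, summaries in summaries_by_group.items():
        agg = aggregate_fc(summaries, statistic=statistic)
        rows[group] = agg.grand_mean
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out
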