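"""Tertile grouping, rank-based group comparisons and correlations.

These link the per-gene statistics (RIT, conservation scores) to external
gene-level measurements (mRNA abundance, ribosome density). All tests are
nonparametric: between-group contrasts use the two-sided Mann-Whitney
rank-sum test (the groups contain different genes, so a paired signed-rank
form would be invalid), with Holm-Bonferroni adjustment over the three
pairwise comparisons; correlations are Spearman's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneValueTable

GROUP_LABELS = ("bottom", "middle", "top")
PAIRS = (("bottom", "middle"), ("bottom", "top"), ("middle", "top"))


@dataclass(frozen=True)
class GroupedComparison:
    grouping_metric: str
    response_metric: str
    groups: Mapping[str, frozenset]
    group_means: Mapping[str, float]
    group_medians: Mapping[str, float]
    pairwise_p: Mapping[tuple[str, str], float]
    method: str = "mann-whitney/holm"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        sets = [self.groups[g] for g in GROUP_LABELS]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("groups must be disjoint")
        for p in self.pairwise_p.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("adjusted p outside [0, 1]")


def tertile_split(
    values: GeneValueTable,
) -> tuple[frozenset, frozenset, frozenset]:
    """Rank genes ascending by value and split into bottom/middle/top thirds.

    Sizes are n//3 with the remainder assigned to the top-most groups
    (10 genes -> 3/3/4). Ties in value fall back to gene-id order, so the
    partition is deterministic across runs.
    """
    items = sorted(values.values.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 genes to split into tertiles")
    base, rem = divmod(n, 3)
    sizes = [base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0)]
    out = []
    start = 0
    for size in sizes:
        out.append(frozenset(g for g, _ in items[start : start + size]))
        start += size
    return tuple(out)  # type: ignore[return-value]


def compare_groups(
    groups: Sequence[frozenset],
    response: GeneValueTable,
    grouping_metric: str = "grouping",
    response_metric: str = "response",
) -> GroupedComparison:
    """Pairwise two-sided rank-sum tests between three gene groups.

    Genes without a response value are dropped (counted in ``n_dropped``);
    an empty group after dropping is an error. The three raw p-values are
    Holm-Bonferroni adjusted.
    """
    if len(groups) != 3:
        raise ValueError("expected exactly 3 groups (bottom, middle, top)")
    samples: dict[str, np.ndarray] = {}
    n_dropped = 0
    for label, genes in zip(GROUP_LABELS, groups):
        vals = [response.values[g] for g in genes if g in response.values]
        n_dropped += len(genes) - len(vals)
        if not vals:
            raise ValueError(f"group {label!r} empty after dropping missing genes")
        samples[label] = np.asarray(vals, dtype=float)
    raw = []
    for a, b in PAIRS:
        res = stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        raw.append(float(res.pvalue))
    adjusted = multipletests(raw, method="holm")[1]
    return GroupedComparison(
        grouping_metric=grouping_metric,
        response_metric=response_metric,
        groups=dict(zip(GROUP_LABELS, (frozenset(g) for g in groups))),
        group_means={k: float(v.mean()) for k, v in samples.items()},
        group_medians={k: float(np.median(v)) for k, v in samples.items()},
        pairwise_p=dict(zip(PAIRS, (float(p) for p in adjusted))),
        n_dropped=n_dropped,
    )


def spearman(
    x: GeneValueTable, y: GeneValueTable
) -> tuple[float, float, int]:
    """Spearman correlation over the gene-id intersection of two tables."""
    shared = sorted(x.gene_ids() & y.gene_ids())
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    xs = [x.values[g] for g in shared]
    ys = [y.values[g] for g in shared]
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), len(shared)


def ks_compare(
    dist_a: Sequence[float], dist_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test."""
    if len(dist_a) == 0 or len(dist_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(dist_a, dist_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def write_group_report(comparison: GroupedComparison, path) -> None:
    """TSV: group label, n, mean, median plus the adjusted pairwise p rows."""
    with open(path, "w") as fh:
        fh.write(f"# grouping={comparison.grouping_metric}\t"
                 f"response={comparison.response_metric}\t"
                 f"method={comparison.method}\tdropped={comparison.n_dropped}\n")
        fh.write("group\tn\tmean\tmedian\n")
        for label in GROUP_LABELS:
            genes = comparison.groups[label]
            fh.write(
                f"{label}\t{len(genes)}\t{comparison.group_means[label]:.6f}\t"
                f"{comparison.group_medians[label]:.6f}\n"
            )
        fh.write("pair\tadjusted_p\n")
        for pair, p in comparison.pairwise_p.items():
            fh.write(f"{pair[0]}-vs-{pair[1]}\t{p:.6g}\n")
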