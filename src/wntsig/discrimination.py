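"""Subtype discrimination: one-way ANOVA, Tukey–Kramer HSD and min-HSD ranking.

A signature's per-sample scores are compared across the four TNBC molecular
subtypes.  The omnibus test is a standard one-way ANOVA; pairwise subtype
contrasts use the studentized-range ("HSD") statistic in its Tukey–Kramer
unequal-n form

    q_ij = |ybar_i - ybar_j| / sqrt( (MSE/2) * (1/n_i + 1/n_j) )

referred to the studentized-range distribution with ``k`` groups and
``N - k`` degrees of freedom.  A gene set's discriminatory power for a focal
subtype (default MLIA) is summarized by the minimum q over the focal-vs-other
comparisons; gene sets are ranked by that minimum, largest first.

The sums of squares, the q statistic and the minimum-HSD summary are computed
directly from the formulas above rather than delegated to a post-hoc routine,
so every intermediate (group means, MSE, per-pair q) is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, UsageError

__all__ = [
    "ANOVAResult",
    "PairStat",
    "HSDSummary",
    "DiscriminationRanking",
    "RankEntry",
    "anova_oneway",
    "tukey_kramer",
    "min_hsd_summary",
    "rank_gene_sets",
    "all_focal_significant",
]

#: Significance threshold for subtype contrasts (inclusive: p <= alpha).
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class ANOVAResult:
    k: int
    N: int
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    F: float
    mse: float
    df_within: int
    p: float


@dataclass(frozen=True)
class PairStat:
    """One unordered pairwise contrast.

    ``mean_diff`` is signed (group_i minus group_j); ``q`` is the
    studentized-range statistic and ``p`` its adjusted tail probability
    (NaN when the summary was built from published statistics without
    degrees-of-freedom information).
    """

    group_i: str
    group_j: str
    q: float
    p: float = float("nan")
    mean_diff: float = float("nan")

    def involves(self, group: str) -> bool:
        return group in (self.group_i, self.group_j)


@dataclass(frozen=True)
class HSDSummary:
    """Pairwise HSD statistics, optionally with a focal-subtype minimum."""

    pairs: tuple[PairStat, ...]
    anova: ANOVAResult | None = None
    focal: str | None = None
    focal_min_q: float | None = None
    focal_min_pair: tuple[str, str] | None = None

    def focal_pairs(self, focal: str) -> list[PairStat]:
        return [p for p in self.pairs if p.involves(focal)]

    def sorted_focal_q(self, focal: str | None = None) -> list[float]:
        focal = focal if focal is not None else self.focal
        if focal is None:
            raise UsageError("no focal group set on this summary")
        return sorted(p.q for p in self.focal_pairs(focal))


@dataclass(frozen=True)
class RankEntry:
    name: str
    focal_min_q: float
    focal_min_pair: tuple[str, str]
    summary: HSDSummary = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class DiscriminationRanking:
    entries: tuple[RankEntry, ...]

    @property
    def best(self) -> RankEntry:
        return self.entries[0]


def _group_arrays(scores, labels) -> dict[str, np.ndarray]:
    scores = np.asarray(pd.Series(scores), dtype=float)
    labels = np.asarray(pd.Series(labels).astype(str))
    if scores.shape[0] != labels.shape[0]:
        raise UsageError(
            f"scores ({scores.shape[0]}) and labels ({labels.shape[0]}) differ in length"
        )
    if np.isnan(scores).any():
        raise UsageError("scores contain NaN")
    return {g: scores[labels == g] for g in sorted(set(labels))}


def anova_oneway(scores, labels) -> ANOVAResult:
    """One-way fixed-effects ANOVA from the standard sum-of-squares decomposition.

    Requires at least two groups with at least two samples each and nonzero
    pooled within-group variance.
    """
    groups = _group_arrays(scores, labels)
    k = len(groups)
    if k < 2:
        raise UsageError(f"ANOVA needs >= 2 groups, got {k}")
    small = [g for g, v in groups.items() if v.size < 2]
    if small:
        raise UsageError(f"group(s) with fewer than 2 samples: {small}")
    sizes = {g: int(v.size) for g, v in groups.items()}
    means = {g: float(v.mean()) for g, v in groups.items()}
    N = sum(sizes.values())
    grand = sum(v.sum() for v in groups.values()) / N
    ss_between = sum(n * (means[g] - grand) ** 2 for g, n in sizes.items())
    ss_within = sum(((v - means[g]) ** 2).sum() for g, v in groups.items())
    df_between, df_within = k - 1, N - k
    mse = ss_within / df_within
    if mse == 0:
        raise DegenerateDataError("zero within-group variance; F undefined")
    F = (ss_between / df_between) / mse
    p = float(stats.f.sf(F, df_between, df_within))
    return ANOVAResult(
        k=k, N=N, group_means=means, group_sizes=sizes,
        F=float(F), mse=float(mse), df_within=df_within, p=p,
    )


def tukey_kramer(scores, labels) -> HSDSummary:
    """All pairwise studentized-range statistics with Tukey–Kramer adjustment.

    For each unordered group pair the q statistic is computed from the group
    means, the pooled MSE and the (possibly unequal) group sizes; its adjusted
    p-value is the upper tail of the studentized-range distribution with
    ``k`` groups and ``N - k`` degrees of freedom.
    """
    an = anova_oneway(scores, labels)
    names = sorted(an.group_means)
    pairs = []
    for a_i, gi in enumerate(names):
        for gj in names[a_i + 1:]:
            diff = an.group_means[gi] - an.group_means[gj]
            se = np.sqrt(
                (an.mse / 2.0)
                * (1.0 / an.group_sizes[gi] + 1.0 / an.group_sizes[gj])
            )
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, an.k, an.df_within))
            pairs.append(
                PairStat(group_i=gi, group_j=gj, q=float(q), p=p, mean_diff=float(diff))
            )
    return HSDSummary(pairs=tuple(pairs), anova=an)


def min_hsd_summary(
    pairs: HSDSummary | list[PairStat] | tuple[PairStat, ...], focal: str
) -> HSDSummary:
    """Attach the focal-subtype minimum to a set of pairwise statistics.

    ``focal_min_q`` is the smallest q over the pairs involving the focal
    group — the gene set separates the focal subtype from every other at
    least this strongly.
    """
    if isinstance(pairs, HSDSummary):
        summary = pairs
    else:
        summary = HSDSummary(pairs=tuple(pairs))
    focal_pairs = summary.focal_pairs(focal)
    if not focal_pairs:
        raise UsageError(f"focal group {focal!r} appears in no pairwise comparison")
    best = min(focal_pairs, key=lambda p: (p.q, (p.group_i, p.group_j)))
    return replace(
        summary,
        focal=focal,
        focal_min_q=best.q,
        focal_min_pair=(best.group_i, best.group_j),
    )


def rank_gene_sets(
    summaries: list[tuple[str, HSDSummary]],
) -> DiscriminationRanking:
    """Order gene sets by decreasing focal-minimum q; the top entry is ``best``.

    Ties on the minimum are broken by the second-smallest focal q (larger
    first), then by name, so the ranking is deterministic.
    """
    if not summaries:
        raise UsageError("rank_gene_sets requires a non-empty list")
    entries = []
    for name, summ in summaries:
        if summ.focal is None or summ.focal_min_q is None:
            raise UsageError(
                f"summary for {name!r} has no focal minimum; run min_hsd_summary first"
            )
        entries.append(RankEntry(
            name=name,
            focal_min_q=summ.focal_min_q,
            focal_min_pair=summ.focal_min_pair,
            summary=summ,
        ))

    def key(e: RankEntry):
        qs = e.summary.sorted_focal_q()
        second = qs[1] if len(qs) > 1 else qs[0]
        return (-e.focal_min_q, -second, e.name)

    return DiscriminationRanking(entries=tuple(sorted(entries, key=key)))


def all_focal_significant(summary: HSDSummary, alpha: float = DEFAULT_ALPHA) -> bool:
    """True when every focal-vs-other contrast reaches ``p <= alpha``."""
    if summary.focal is None:
        raise UsageError("summary has no focal group")
    return all(p.p <= alpha for p in summary.focal_pairs(summary.focal))
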