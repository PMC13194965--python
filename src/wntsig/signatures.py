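"""Derive consensus gene signatures from differential-expression tables.

A differential-expression (DEG) table holds, per gene, a log2 fold change
(Wnt-positive over Wnt-negative) and a multiple-testing-adjusted p-value.
Genes are called differentially expressed when ``padj < 0.05`` (strict) and
``|log2fc| >= 1`` (inclusive).  Signed intersection of two filtered tables
splits the shared genes into consistently up-, consistently down-regulated
and oppositely regulated sets; intersecting all four cell-line x serum
comparisons yields the consensus Wnt-activity signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassificationError, SchemaError, UsageError

__all__ = [
    "DEGTable",
    "OverlapSummary",
    "GeneSignature",
    "filter_degs",
    "intersect_signed",
    "consensus_signature",
    "per_condition_signatures",
]

#: Canonical column order of a DEG table.
DEG_COLUMNS = ("gene", "log2fc", "padj")


@dataclass(frozen=True)
class DEGTable:
    """One differential-expression comparison.

    Parameters
    ----------
    name
        Comparison label, conventionally ``<cell line>_<serum condition>``.
    records
        DataFrame with columns ``gene`` (str), ``log2fc`` (float) and
        ``padj`` (float).  Gene identifiers are whitespace-trimmed and must
        be unique; duplicates are a hard error because they signal upstream
        corruption rather than something safely deduplicated.
    """

    name: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DEG_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(
                f"DEG table {self.name!r} lacks column(s) {missing}; "
                f"expected {list(DEG_COLUMNS)}"
            )
        recs = self.records.loc[:, list(DEG_COLUMNS)].copy()
        recs["gene"] = recs["gene"].astype(str).str.strip()
        if (recs["gene"] == "").any():
            raise SchemaError(f"DEG table {self.name!r} contains an empty gene identifier")
        dup = recs["gene"][recs["gene"].duplicated()]
        if len(dup):
            raise SchemaError(
                f"DEG table {self.name!r} has duplicated gene identifier(s): "
                f"{sorted(set(dup))[:5]}"
            )
        recs["log2fc"] = recs["log2fc"].astype(float)
        recs["padj"] = recs["padj"].astype(float)
        bad_p = recs["padj"].dropna()
        if ((bad_p < 0) | (bad_p > 1)).any():
            raise SchemaError(f"DEG table {self.name!r} has padj outside [0, 1]")
        if np.isinf(recs["log2fc"]).any():
            raise SchemaError(f"DEG table {self.name!r} has non-finite log2fc")
        recs = recs.reset_index(drop=True)
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.records["gene"])

    def log2fc_of(self, gene: str) -> float:
        row = self.records.loc[self.records["gene"] == gene, "log2fc"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])


@dataclass(frozen=True)
class OverlapSummary:
    """Signed overlap of two filtered DEG tables.

    ``shared`` partitions exactly into ``consistent_up``, ``consistent_down``
    and ``opposite``.
    """

    table_a: str
    table_b: str
    shared: frozenset[str]
    consistent_up: frozenset[str]
    consistent_down: frozenset[str]
    opposite: frozenset[str]

    def __post_init__(self) -> None:
        parts = (self.consistent_up, self.consistent_down, self.opposite)
        if len(self.shared) != sum(len(p) for p in parts):
            raise ValueError("overlap subsets do not partition the shared set")
        union = self.consistent_up | self.consistent_down | self.opposite
        if union != self.shared:
            raise ValueError("overlap subsets do not cover the shared set")

    @property
    def n_consistent(self) -> int:
        return len(self.consistent_up) + len(self.consistent_down)


@dataclass(frozen=True)
class GeneSignature:
    """A named signed gene set (up-regulated and down-regulated members)."""

    name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise UsageError("signature name must be non-empty")
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if self.up & self.down:
            raise UsageError(
                f"signature {self.name!r}: up and down sets overlap "
                f"({sorted(self.up & self.down)[:5]})"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def filter_degs(
    table: DEGTable, padj_max: float = 0.05, lfc_min: float = 1.0
) -> DEGTable:
    """Apply the DEG thresholds: ``padj < padj_max`` and ``|log2fc| >= lfc_min``.

    The p-value cut is strict and the fold-change cut inclusive.  Records with
    missing (NaN) ``padj`` are dropped with a warning: differential-expression
    tools emit NaN for independent-filtering casualties, which are by
    definition not called significant.  Row order is preserved, so the
    operation is idempotent.
    """
    if not (padj_max > 0 and lfc_min > 0):
        raise UsageError(
            f"thresholds must be positive (padj_max={padj_max}, lfc_min={lfc_min})"
        )
    recs = table.records
    nan_mask = recs["padj"].isna()
    if nan_mask.any():
        warnings.warn(
            f"DEG table {table.name!r}: dropping {int(nan_mask.sum())} record(s) "
            f"with missing padj: {sorted(recs.loc[nan_mask, 'gene'])[:5]}",
            stacklevel=2,
        )
        recs = recs.loc[~nan_mask]
    keep = (recs["padj"] < padj_max) & (recs["log2fc"].abs() >= lfc_min)
    return DEGTable(name=table.name, records=recs.loc[keep])


def intersect_signed(a: DEGTable, b: DEGTable) -> OverlapSummary:
    """Signed intersection of two (already filtered) DEG tables.

    Shared genes are split by the sign agreement of their fold changes:
    both positive -> ``consistent_up``; both negative -> ``consistent_down``;
    discordant -> ``opposite``.  Symmetric in its arguments.
    """
    fc_a = a.records.set_index("gene")["log2fc"]
    fc_b = b.records.set_index("gene")["log2fc"]
    shared = fc_a.index.intersection(fc_b.index)
    sa, sb = np.sign(fc_a.loc[shared]), np.sign(fc_b.loc[shared])
    zero = shared[(sa == 0) | (sb == 0)]
    if len(zero):
        # unreachable after filtering at lfc_min >= 1; guards misconfigured thresholds
        raise ClassificationError(
            f"log2fc == 0 for shared gene(s) {sorted(zero)[:5]}; "
            "direction undefined — check the fold-change threshold"
        )
    up = shared[(sa > 0) & (sb > 0)]
    down = shared[(sa < 0) & (sb < 0)]
    opposite = shared[sa != sb]
    return OverlapSummary(
        table_a=a.name,
        table_b=b.name,
        shared=frozenset(shared),
        consistent_up=frozenset(up),
        consistent_down=frozenset(down),
        opposite=frozenset(opposite),
    )


def consensus_signature(
    tables: list[DEGTable] | tuple[DEGTable, ...], name: str = "consensus"
) -> GeneSignature:
    """Genes significant with a consistent sign in all four comparisons.

    ``up`` collects genes with positive log2 fold change in every table,
    ``down`` those negative in every table; genes present in all four with
    mixed signs are excluded.
    """
    tables = list(tables)
    if len(tables) != 4:
        raise UsageError(
            f"consensus requires exactly the four comparison tables, got {len(tables)}"
        )
    sign_frames = [
        np.sign(t.records.set_index("gene")["log2fc"]) for t in tables
    ]
    common = sign_frames[0].index
    for s in sign_frames[1:]:
        common = common.intersection(s.index)
    signs = pd.concat([s.loc[common] for s in sign_frames], axis=1)
    up = common[(signs > 0).all(axis=1)]
    down = common[(signs < 0).all(axis=1)]
    return GeneSignature(
        name=name,
        up=frozenset(up),
        down=frozenset(down),
        provenance=tuple(t.name for t in tables),
    )


def per_condition_signatures(
    tables: list[DEGTable] | tuple[DEGTable, ...],
) -> list[GeneSignature]:
    """For each filtered comparison emit full, up-only and down-only signatures.

    The full signature (all DEGs of one comparison, both directions pooled)
    corresponds to a GES-style set; the direction-restricted splits are the
    gene sets ranked for subtype discrimination.
    """
    out: list[GeneSignature] = []
    for t in tables:
        fc = t.records.set_index("gene")["log2fc"]
        up = frozenset(fc.index[fc > 0])
        down = frozenset(fc.index[fc < 0])
        if not up and not down:
            warnings.warn(
                f"comparison {t.name!r} has no DEGs; emitting empty signatures",
                stacklevel=2,
            )
        prov = (t.name,)
        out.append(GeneSignature(name=t.name, up=up, down=down, provenance=prov))
        out.append(GeneSignature(name=f"{t.name}_up", up=up, provenance=prov))
        out.append(GeneSignature(name=f"{t.name}_down", down=down, provenance=prov))
    return out
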