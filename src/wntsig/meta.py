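"""Cross-condition meta-statistics.

Stouffer's method combines the adjusted p-values a term obtained under the
low- and standard-serum conditions into one z-score,

    Z = sum_j Phi^{-1}(1 - p_j) / sqrt(k),    p_comb = 1 - Phi(Z),

which ranks the enrichment terms shared by both conditions.  Note the
combination is applied to already-adjusted p-values — statistically
unconventional, but that is the quantity the upstream enrichment exports
carry.  Pearson correlation between two signature score vectors quantifies
how similar two signatures' cohort-wide behavior is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, SchemaError, UsageError

__all__ = ["EnrichmentTable", "stouffer_combine", "rank_shared_terms", "pearson_r"]

#: p-values are clamped into this open interval before the normal-quantile
#: transform; enrichment tools emit p == 0 for saturated terms, which would
#: otherwise map to an infinite z-score.
P_CLAMP = 1e-15


@dataclass(frozen=True)
class EnrichmentTable:
    """Enrichment results for one condition: rows of (term_id, description, padj)."""

    condition: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        needed = ["term_id", "description", "padj"]
        missing = [c for c in needed if c not in self.rows.columns]
        if missing:
            raise SchemaError(
                f"enrichment table {self.condition!r} lacks column(s) {missing}"
            )
        rows = self.rows.loc[:, needed].copy()
        rows["term_id"] = rows["term_id"].astype(str).str.strip()
        rows["padj"] = rows["padj"].astype(float)
        if rows["term_id"].duplicated().any():
            dup = rows["term_id"][rows["term_id"].duplicated()]
            raise SchemaError(
                f"enrichment table {self.condition!r} has duplicated term(s): "
                f"{sorted(set(dup))[:5]}"
            )
        if ((rows["padj"] < 0) | (rows["padj"] > 1)).any():
            raise SchemaError(
                f"enrichment table {self.condition!r} has padj outside [0, 1]"
            )
        object.__setattr__(self, "rows", rows.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.rows)


def stouffer_combine(p_values) -> tuple[float, float]:
    """Combine one-sided p-values by the unweighted Stouffer z-method.

    Returns ``(Z, combined p)``.  With a single input the combined p equals
    the input; concordant small p-values reinforce each other.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise UsageError("stouffer_combine requires a non-empty 1-d list of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise UsageError("p-values must lie in [0, 1] and be non-missing")
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    z = stats.norm.isf(p)  # Phi^{-1}(1 - p)
    Z = z.sum() / np.sqrt(p.size)
    return float(Z), float(stats.norm.sf(Z))


def rank_shared_terms(
    tables: list[EnrichmentTable], top_k: int | None = None
) -> pd.DataFrame:
    """Rank the terms shared by all conditions by Stouffer-combined p-value.

    Restricts to the intersection of term identifiers, combines each term's
    per-condition adjusted p-values, and sorts ascending by combined p
    (ties broken by term id).  Returns the full ranking or its ``top_k``
    head, as a DataFrame with one ``padj_<condition>`` column per input.
    """
    if len(tables) < 2:
        raise UsageError(f"rank_shared_terms needs >= 2 tables, got {len(tables)}")
    names = [t.condition for t in tables]
    if len(set(names)) != len(names):
        raise UsageError(f"condition labels must be distinct, got {names}")
    shared = set(tables[0].rows["term_id"])
    for t in tables[1:]:
        shared &= set(t.rows["term_id"])
    cols = ["term_id", "description"] + [f"padj_{n}" for n in names] + [
        "combined_z", "combined_p"
    ]
    if not shared:
        warnings.warn("no terms shared by all conditions; empty ranking", stacklevel=2)
        return pd.DataFrame(columns=cols)
    desc = tables[0].rows.set_index("term_id")["description"]
    per_cond = [t.rows.set_index("term_id")["padj"] for t in tables]
    records = []
    for term in sorted(shared):
        ps = [float(s.loc[term]) for s in per_cond]
        Z, p_comb = stouffer_combine(ps)
        records.append([term, desc.loc[term], *ps, Z, p_comb])
    out = pd.DataFrame(records, columns=cols)
    out = out.sort_values(["combined_p", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
    return out if top_k is None else out.head(top_k).reset_index(drop=True)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two paired score vectors.

    When both inputs are indexed Series the pairing is by sample identifier
    and the identifier sets must agree; plain arrays are paired positionally.
    Requires length >= 3 and two non-constant vectors.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if set(x.index) != set(y.index):
            only_x = sorted(set(x.index) - set(y.index))[:5]
            only_y = sorted(set(y.index) - set(x.index))[:5]
            raise UsageError(
                f"sample identifiers do not match (x-only: {only_x}, y-only: {only_y})"
            )
        y = y.loc[x.index]
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise UsageError("pearson_r requires two 1-d vectors of equal length")
    if xv.size < 3:
        raise UsageError(f"pearson_r requires length >= 3, got {xv.size}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(stats.pearsonr(xv, yv).statistic)
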