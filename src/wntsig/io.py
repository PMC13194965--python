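"""Readers and writers for the pipeline's plain-text formats.

TSV is the canonical tabular dialect (tab-separated, header row, UTF-8,
"." decimal); CSV is accepted on read via ``sep=","`` or a ``.csv``
extension.  Floating-point output uses six significant digits.  Gene sets
travel as GMT (``name<TAB>description<TAB>gene...``) and as two-column
(gene, direction) TSV; trees as Newick; configuration, manifests and
simulation truth as JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discrimination import HSDSummary, DiscriminationRanking
from .errors import SchemaError, UsageError
from .meta import EnrichmentTable
from .scoring import ExpressionCohort, GESResult
from .signatures import DEGTable, GeneSignature

__all__ = [
    "read_deg_table", "write_deg_table",
    "read_expression", "read_annotation", "read_cohort", "write_cohort",
    "read_gmt", "write_gmt", "read_signature_tsv", "write_signature_tsv",
    "read_enrichment_table", "write_combined_terms",
    "read_ges_tsv", "write_ges_results",
    "write_pairwise_tsv", "write_ranking_tsv",
    "write_json", "fmt",
]

FLOAT_FMT = "%.6g"


def fmt(v: float) -> str:
    return FLOAT_FMT % v


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------- DEG tables

def read_deg_table(
    path: str | Path,
    name: str | None = None,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
    sep: str | None = None,
) -> DEGTable:
    """Read one differential-expression comparison from TSV/CSV.

    Column names default to the common DE-tool export (``gene``,
    ``log2FoldChange``, ``padj``) and are configurable.  The table name
    defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in (gene_col, lfc_col, padj_col) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    df = df.rename(columns={gene_col: "gene", lfc_col: "log2fc", padj_col: "padj"})
    return DEGTable(name=name or path.stem, records=df[["gene", "log2fc", "padj"]])


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    out = table.records.rename(columns={"log2fc": "log2FoldChange"})
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ------------------------------------------------------------------- cohorts

def read_expression(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Genes x samples matrix: first column = gene identifier, header = samples."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.index.name = "gene"
    return df.astype(float)


def read_annotation(path: str | Path, sep: str | None = None) -> pd.Series:
    """Sample annotation: columns ``sample_id`` and ``subtype``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in ("sample_id", "subtype"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated sample_id entries")
    return df.set_index("sample_id")["subtype"].astype(str)


def read_cohort(
    expression_path: str | Path, annotation_path: str | Path, sep: str | None = None
) -> ExpressionCohort:
    return ExpressionCohort(
        values=read_expression(expression_path, sep=sep),
        subtype=read_annotation(annotation_path, sep=sep),
    )


def write_cohort(
    cohort: ExpressionCohort, expression_path: str | Path, annotation_path: str | Path
) -> None:
    cohort.values.to_csv(expression_path, sep="\t", float_format=FLOAT_FMT)
    ann = pd.DataFrame({
        "sample_id": cohort.samples, "subtype": cohort.subtype.loc[cohort.samples]
    })
    ann.to_csv(annotation_path, sep="\t", index=False)


# ----------------------------------------------------------------- gene sets

def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    """One GMT line per signature, genes sorted, both directions pooled.

    GMT carries no direction information; use :func:`write_signature_tsv`
    to preserve up/down membership.  Empty descriptions are written as "na".
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            desc = ",".join(sig.provenance) or "na"
            genes = sorted(sig.genes)
            fh.write("\t".join([sig.name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read GMT gene sets; direction is unknown, so genes load as ``up``."""
    sigs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, _desc, *genes = parts
            genes = [g.strip() for g in genes if g.strip()]
            sigs.append(GeneSignature(name=name, up=frozenset(genes)))
    return sigs


def write_signature_tsv(signature: GeneSignature, path: str | Path) -> None:
    rows = [(g, "up") for g in sorted(signature.up)]
    rows += [(g, "down") for g in sorted(signature.down)]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature_tsv(path: str | Path, name: str | None = None) -> GeneSignature:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "direction"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise SchemaError(f"{path}: unknown direction value(s) {sorted(bad)}")
    return GeneSignature(
        name=name or path.stem,
        up=frozenset(df.loc[df["direction"] == "up", "gene"].astype(str)),
        down=frozenset(df.loc[df["direction"] == "down", "gene"].astype(str)),
    )


# ---------------------------------------------------------- enrichment terms

def read_enrichment_table(
    path: str | Path,
    condition: str | None = None,
    term_col: str = "term_id",
    desc_col: str = "description",
    padj_col: str = "padj",
    sep: str | None = None,
) -> EnrichmentTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in (term_col, padj_col) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df.rename(columns={term_col: "term_id", padj_col: "padj"})
    if desc_col in df.columns:
        df = df.rename(columns={desc_col: "description"})
    else:
        df["description"] = "na"
    return EnrichmentTable(condition=condition or path.stem, rows=df)


def write_enrichment_table(table: EnrichmentTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_combined_terms(combined: pd.DataFrame, path: str | Path) -> None:
    combined.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------- GES scores

def write_ges_results(
    results: list[GESResult],
    cohort: ExpressionCohort,
    out_dir: str | Path,
    expression_unit: str = "unspecified",
) -> dict:
    """One (sample, subtype, score) TSV per signature plus a JSON coverage report.

    The caller's declared expression unit is recorded in the report; scores
    inherit whatever scale the cohort matrix was supplied in.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"expression_unit": expression_unit, "signatures": {}}
    for res in results:
        df = pd.DataFrame({
            "sample": res.scores.index,
            "subtype": cohort.subtype.loc[res.scores.index].to_numpy(),
            "score": res.scores.to_numpy(),
        })
        dest = out_dir / f"ges_{res.signature_name}.tsv"
        df.to_csv(dest, sep="\t", index=False, float_format=FLOAT_FMT)
        report["signatures"][res.signature_name] = {
            "file": dest.name,
            "n_used": res.n_used,
            "coverage": round(res.coverage, 6),
            "missing": list(res.missing),
        }
    write_json(report, out_dir / "ges_coverage.json")
    return report


def read_ges_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "subtype", "score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicated sample entries")
    return df


# ------------------------------------------------------------ discrimination

def write_pairwise_tsv(
    summary: HSDSummary, path: str | Path, alpha: float = 0.01
) -> None:
    """Pairwise contrasts with all three candidate discriminatory quantities.

    Columns expose the signed mean difference, the q statistic and (when the
    ANOVA context is available) q scaled by the alpha-level studentized-range
    critical value, so downstream users can pick their preferred scale.
    """
    from scipy import stats

    q_crit = np.nan
    if summary.anova is not None:
        q_crit = float(
            stats.studentized_range.isf(alpha, summary.anova.k, summary.anova.df_within)
        )
    rows = []
    for p in summary.pairs:
        rows.append({
            "group_i": p.group_i,
            "group_j": p.group_j,
            "mean_diff": p.mean_diff,
            "q": p.q,
            "p": p.p,
            "q_over_critical": p.q / q_crit if np.isfinite(q_crit) else np.nan,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_ranking_tsv(
    ranking: DiscriminationRanking, path: str | Path, alpha: float = 0.01
) -> None:
    rows = []
    for e in ranking.entries:
        focal_ps = [p.p for p in e.summary.focal_pairs(e.summary.focal)]
        significant = bool(focal_ps) and all(
            np.isfinite(p) and p <= alpha for p in focal_ps
        )
        rows.append({
            "signature": e.name,
            "focal_min_q": e.focal_min_q,
            "attaining_pair": "-".join(e.focal_min_pair),
            f"significant_at_{alpha:g}": significant,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ----------------------------------------------------------------------- JSON

def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
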