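"""Single-sample gene-expression-signature (GES) scoring.

The GES score of a sample is the unweighted mean of the normalized
(log-scale) expression values of the signature's genes in that sample:

    GES(s) = (1/n) * sum_i x_{i,s}

with ``n`` the number of signature genes found in the cohort.  Up- and
down-regulated members are pooled without sign weighting.  Scores are
computed on whatever scale the matrix is supplied in; log-scale input is
expected.  An optional per-gene z-scoring flag exists but is off by default
because the score is defined on raw expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ScoringError, SchemaError, UsageError
from .signatures import GeneSignature

__all__ = ["ExpressionCohort", "GESResult", "ges_score", "score_all"]


@dataclass(frozen=True)
class ExpressionCohort:
    """A genes x samples expression matrix with per-sample subtype labels.

    ``values`` is indexed by gene identifier with one column per sample;
    ``subtype`` maps every sample to its molecular subtype label.
    """

    values: pd.DataFrame
    subtype: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()]
            raise SchemaError(f"duplicated gene identifier(s): {sorted(set(dups))[:5]}")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicated sample identifiers in expression matrix")
        missing = self.values.columns.difference(self.subtype.index)
        if len(missing):
            raise SchemaError(
                f"{len(missing)} sample(s) lack a subtype label, e.g. {list(missing[:5])}"
            )
        # restrict labels to the samples actually present, in matrix order
        object.__setattr__(
            self, "subtype", self.subtype.loc[self.values.columns].astype(str)
        )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def subtypes(self) -> list[str]:
        """Distinct subtype labels, in first-appearance order."""
        return list(dict.fromkeys(self.subtype))

    def samples_of(self, subtype: str) -> pd.Index:
        return self.subtype.index[self.subtype == subtype]


@dataclass(frozen=True)
class GESResult:
    """Per-sample scores for one signature plus gene-coverage diagnostics."""

    signature_name: str
    scores: pd.Series
    n_used: int
    coverage: float
    missing: tuple[str, ...] = ()

    def group_means(self, subtype: pd.Series) -> pd.Series:
        """Mean score per subtype label."""
        return self.scores.groupby(subtype.loc[self.scores.index]).mean()


def ges_score(
    cohort: ExpressionCohort,
    signature: GeneSignature,
    standardize: bool = False,
) -> GESResult:
    """Score one signature over every sample of a cohort.

    Signature genes absent from the cohort are dropped with a warning and
    reported through ``n_used``/``coverage``; if no gene overlaps the cohort
    the signature cannot be scored.  With ``standardize=True`` each gene is
    z-scored across samples before averaging (off by default).
    """
    wanted = sorted(signature.genes)
    if not wanted:
        raise ScoringError(f"signature {signature.name!r} is empty")
    present = [g for g in wanted if g in cohort.values.index]
    missing = tuple(g for g in wanted if g not in cohort.values.index)
    if not present:
        raise ScoringError(
            f"signature {signature.name!r}: none of its {len(wanted)} genes "
            "are present in the cohort"
        )
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)}/{len(wanted)} gene(s) "
            f"absent from the cohort: {list(missing[:10])}",
            stacklevel=2,
        )
    sub = cohort.values.loc[present]
    if standardize:
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ScoringError(
                f"signature {signature.name!r}: constant gene(s) cannot be z-scored"
            )
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    scores = sub.mean(axis=0)
    scores.name = signature.name
    return GESResult(
        signature_name=signature.name,
        scores=scores,
        n_used=len(present),
        coverage=len(present) / len(wanted),
        missing=missing,
    )


def score_all(
    cohort: ExpressionCohort,
    signatures: list[GeneSignature],
    standardize: bool = False,
) -> tuple[list[GESResult], dict[str, ScoringError]]:
    """Score a batch of signatures; per-signature failures are collected.

    Returns the successful results and a name -> error mapping for the
    signatures that could not be scored.  Only if every signature fails is
    the batch itself an error.
    """
    if not signatures:
        raise UsageError("score_all requires a non-empty list of signatures")
    results: list[GESResult] = []
    failures: dict[str, ScoringError] = {}
    for sig in signatures:
        try:
            results.append(ges_score(cohort, sig, standardize=standardize))
        except ScoringError as err:
            failures[sig.name] = err
    if not results:
        raise ScoringError(
            f"all {len(signatures)} signature(s) failed to score: "
            f"{ {k: str(v) for k, v in failures.items()} }"
        )
    return results, failures
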