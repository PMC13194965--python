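"""Synthetic data with planted, recoverable ground truth.

Three generators emulate the pipeline's three input kinds:

* :func:`generate_deg_tables` — four differential-expression tables (two
  cell lines x two serum conditions) in which genes are planted as
  consensus (significant with a consistent sign in all four), condition-
  consistent (both cell lines within one serum condition), opposite-sign
  shared, or table-specific; everything else is null.  Adjusted p-values
  are drawn directly from category-specific intervals (significant:
  [1e-6, 0.049]; null: [0.06, 1]) rather than via a DE model, since only
  the tables' schema and threshold behavior need emulating.
* :func:`generate_cohort` — a four-subtype log-expression cohort with a
  planted mean shift of ``delta`` residual standard deviations in the focal
  subtype for signature genes (positive for up-members, negative for
  down-members), optional correlated gene blocks, and Gaussian residual
  noise.
* :func:`generate_enrichment_pair` — two enrichment-term tables sharing a
  known set of terms, a subset of which is planted "strong" in both.

Default planted counts reproduce the published study's overlap structure:
759/1407 (low serum) and 925/1543 (standard serum) DEGs per comparison,
pairwise overlaps of 216 (138 consistent: 105 up + 33 down; 78 opposite)
and 247 (133 consistent: 95 up + 38 down; 114 opposite), and a 55-gene
four-way consensus (42 up + 13 down).  Default subtype sizes are the
published cohort's: LAR 137, MLIA 121, BLIA 199, BLIS 242 (n = 699).

All randomness flows from one ``numpy`` Generator seeded from
``SimConfig.seed``; draws happen in a fixed documented order (tables in
``TABLE_NAMES`` order, then per-table fold changes before p-values; for
cohorts: gene baselines, block factors, then residual noise), so identical
configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scoring import ExpressionCohort
from .signatures import DEGTable, GeneSignature

__all__ = [
    "SimConfig",
    "SimTruth",
    "TABLE_NAMES",
    "CONDITIONS",
    "generate_deg_tables",
    "generate_cohort",
    "generate_enrichment_pair",
]

#: The four comparisons: cell line x serum condition.
TABLE_NAMES = ("231_low", "436_low", "231_standard", "436_standard")
CONDITIONS = ("low", "standard")

_SIG_P = (1e-6, 0.049)   # padj interval for planted-significant calls
_NULL_P = (0.06, 1.0)    # padj interval for null calls
_SIG_LFC = (1.0, 4.0)    # |log2fc| interval for planted-significant calls
_NULL_LFC = (-0.99, 0.99)


def _as_table_map(value, names, what: str) -> dict[str, int]:
    if isinstance(value, int):
        return {n: value for n in names}
    out = {str(k): int(v) for k, v in dict(value).items()}
    extra = set(out) - set(names)
    if extra:
        raise ConfigurationError(f"{what}: unknown key(s) {sorted(extra)}")
    return {n: out.get(n, 0) for n in names}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Counts describe planted gene categories; ``delta`` is the focal-subtype
    mean shift in units of the residual SD ``sigma`` of log-expression;
    ``n_blocks``/``block_rho`` add equicorrelated gene blocks for cluster-
    recovery tests.  Per-condition and per-table counts accept either a
    single int (applied to each) or an explicit mapping.
    """

    n_genes: int = 5000
    n_consensus_up: int = 42
    n_consensus_down: int = 13
    n_condition_up: dict[str, int] | int = field(
        default_factory=lambda: {"low": 63, "standard": 53}
    )
    n_condition_down: dict[str, int] | int = field(
        default_factory=lambda: {"low": 20, "standard": 25}
    )
    n_shared_opposite: dict[str, int] | int = field(
        default_factory=lambda: {"low": 78, "standard": 114}
    )
    n_cellline_specific: dict[str, int] | int = field(
        default_factory=lambda: {
            "231_low": 543,
            "436_low": 1191,
            "231_standard": 678,
            "436_standard": 1296,
        }
    )
    subtype_sizes: dict[str, int] = field(
        default_factory=lambda: {"LAR": 137, "MLIA": 121, "BLIA": 199, "BLIS": 242}
    )
    focal_subtype: str = "MLIA"
    delta: float = 0.5
    sigma: float = 1.0
    n_blocks: int = 1
    block_rho: float = 0.0
    n_background_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for fname in ("n_genes", "n_consensus_up", "n_consensus_down",
                      "n_background_genes"):
            if getattr(self, fname) < 0:
                raise ConfigurationError(f"{fname} must be >= 0")
        object.__setattr__(
            self, "n_condition_up",
            _as_table_map(self.n_condition_up, CONDITIONS, "n_condition_up"),
        )
        object.__setattr__(
            self, "n_condition_down",
            _as_table_map(self.n_condition_down, CONDITIONS, "n_condition_down"),
        )
        object.__setattr__(
            self, "n_shared_opposite",
            _as_table_map(self.n_shared_opposite, CONDITIONS, "n_shared_opposite"),
        )
        object.__setattr__(
            self, "n_cellline_specific",
            _as_table_map(self.n_cellline_specific, TABLE_NAMES, "n_cellline_specific"),
        )
        for m in (self.n_condition_up, self.n_condition_down,
                  self.n_shared_opposite, self.n_cellline_specific):
            if any(v < 0 for v in m.values()):
                raise ConfigurationError("planted counts must be >= 0")
        if self.total_planted > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} is smaller than the "
                f"{self.total_planted} planted genes"
            )
        if not self.subtype_sizes:
            raise ConfigurationError("subtype_sizes must be non-empty")
        if any(v < 2 for v in self.subtype_sizes.values()):
            raise ConfigurationError(
                "subtype_sizes: every subtype needs >= 2 samples "
                "(within-group variance for ANOVA)"
            )
        if self.focal_subtype not in self.subtype_sizes:
            raise ConfigurationError(
                f"focal_subtype {self.focal_subtype!r} not in subtype_sizes"
            )
        if not (0 <= self.block_rho < 1):
            raise ConfigurationError("block_rho must lie in [0, 1)")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")

    @property
    def total_planted(self) -> int:
        return (
            self.n_consensus_up + self.n_consensus_down
            + sum(self.n_condition_up.values())
            + sum(self.n_condition_down.values())
            + sum(self.n_shared_opposite.values())
            + sum(self.n_cellline_specific.values())
        )

    @property
    def n_samples(self) -> int:
        return sum(self.subtype_sizes.values())

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth carried alongside a synthetic dataset."""

    consensus_up: frozenset[str] = frozenset()
    consensus_down: frozenset[str] = frozenset()
    opposite: frozenset[str] = frozenset()
    per_table_deg: dict[str, frozenset[str]] = field(default_factory=dict)
    condition_up: dict[str, frozenset[str]] = field(default_factory=dict)
    condition_down: dict[str, frozenset[str]] = field(default_factory=dict)
    block_assignment: dict[str, int] = field(default_factory=dict)
    focal_effect: dict[str, float] = field(default_factory=dict)
    strong_terms: frozenset[str] = frozenset()
    shared_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.consensus_up & self.consensus_down:
            raise ConfigurationError("consensus up/down sets overlap")
        if (self.consensus_up | self.consensus_down) & self.opposite:
            raise ConfigurationError("consensus and opposite sets overlap")

    def to_dict(self) -> dict:
        return {
            "consensus_up": sorted(self.consensus_up),
            "consensus_down": sorted(self.consensus_down),
            "opposite": sorted(self.opposite),
            "per_table_deg": {k: sorted(v) for k, v in self.per_table_deg.items()},
            "condition_up": {k: sorted(v) for k, v in self.condition_up.items()},
            "condition_down": {k: sorted(v) for k, v in self.condition_down.items()},
            "block_assignment": dict(sorted(self.block_assignment.items())),
            "focal_effect": dict(sorted(self.focal_effect.items())),
            "strong_terms": sorted(self.strong_terms),
            "shared_terms": sorted(self.shared_terms),
        }


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_deg_tables(config: SimConfig) -> tuple[list[DEGTable], SimTruth]:
    """Emit the four comparison tables with planted threshold behavior.

    Every table lists all ``n_genes`` genes.  A gene's status in a table is
    one of significant-up, significant-down or null; the planted categories
    determine the per-table status pattern, and fold changes / adjusted
    p-values are then drawn from the corresponding intervals.  Null calls
    always fail the p-value threshold, so filtering at the default cuts
    recovers exactly the planted per-table DEG sets.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    # deterministic category layout: consecutive slices of the gene list
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = genes[cursor:cursor + n]
        cursor += n
        return out

    consensus_up = take(config.n_consensus_up)
    consensus_down = take(config.n_consensus_down)
    cond_up = {c: take(config.n_condition_up[c]) for c in CONDITIONS}
    cond_down = {c: take(config.n_condition_down[c]) for c in CONDITIONS}
    cond_opp = {c: take(config.n_shared_opposite[c]) for c in CONDITIONS}
    specific = {t: take(config.n_cellline_specific[t]) for t in TABLE_NAMES}

    # status per table: +1 significant up, -1 significant down, 0 null
    status = {t: pd.Series(0, index=genes, dtype=int) for t in TABLE_NAMES}
    for t in TABLE_NAMES:
        status[t].loc[consensus_up] = 1
        status[t].loc[consensus_down] = -1
    for c in CONDITIONS:
        in_cond = [t for t in TABLE_NAMES if t.endswith(f"_{c}")]
        for t in in_cond:
            status[t].loc[cond_up[c]] = 1
            status[t].loc[cond_down[c]] = -1
        # opposite-sign genes: first half up in the 231 line, second half up in 436
        opp = cond_opp[c]
        half = len(opp) // 2
        t231, t436 = in_cond
        status[t231].loc[opp[:half]] = 1
        status[t436].loc[opp[:half]] = -1
        status[t231].loc[opp[half:]] = -1
        status[t436].loc[opp[half:]] = 1
    for t in TABLE_NAMES:
        spec = specific[t]
        if spec:
            signs = rng.choice([-1, 1], size=len(spec))
            status[t].loc[spec] = signs

    tables = []
    per_table_deg = {}
    for t in TABLE_NAMES:
        st = status[t].to_numpy()
        sig = st != 0
        lfc = rng.uniform(*_NULL_LFC, size=config.n_genes)
        mag = rng.uniform(*_SIG_LFC, size=config.n_genes)
        lfc[sig] = st[sig] * mag[sig]
        padj = rng.uniform(*_NULL_P, size=config.n_genes)
        padj_sig = rng.uniform(*_SIG_P, size=config.n_genes)
        padj[sig] = padj_sig[sig]
        tables.append(DEGTable(
            name=t,
            records=pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj}),
        ))
        per_table_deg[t] = frozenset(np.asarray(genes)[sig])

    truth = SimTruth(
        consensus_up=frozenset(consensus_up),
        consensus_down=frozenset(consensus_down),
        opposite=frozenset(g for c in CONDITIONS for g in cond_opp[c]),
        per_table_deg=per_table_deg,
        condition_up={c: frozenset(cond_up[c]) for c in CONDITIONS},
        condition_down={c: frozenset(cond_down[c]) for c in CONDITIONS},
    )
    return tables, truth


def generate_cohort(
    config: SimConfig, signature: GeneSignature
) -> tuple[ExpressionCohort, SimTruth]:
    """Simulate a multi-subtype log-expression cohort around a signature.

    Expression follows

        x[g, s] = mu_g + delta * dir(g) * 1[subtype(s) = focal]
                  + sigma * (sqrt(rho_g) * z[block(g), s]
                             + sqrt(1 - rho_g) * eps[g, s])

    with ``dir(g)`` +1 / -1 / 0 for signature up / down / background genes,
    per-gene baselines ``mu_g ~ N(6, 2)`` (log2-expression-like), and
    ``rho_g = block_rho`` for signature genes assigned to a block (background
    genes carry independent noise).  Signature genes are dealt into
    ``n_blocks`` contiguous blocks; an empty signature yields a pure null
    cohort of background genes.
    """
    if config.n_samples == 0:
        raise ConfigurationError("subtype_sizes sum to zero samples")
    rng = np.random.default_rng(config.seed)

    sig_genes = sorted(signature.up) + sorted(signature.down)
    bg = [f"bg{i + 1:04d}" for i in range(config.n_background_genes)]
    clash = set(sig_genes) & set(bg)
    if clash:
        raise ConfigurationError(
            f"signature genes collide with background identifiers: {sorted(clash)[:5]}"
        )
    genes = sig_genes + bg
    if not genes:
        raise ConfigurationError("cohort would contain zero genes")

    samples, labels = [], []
    for subtype, n in config.subtype_sizes.items():
        for i in range(n):
            samples.append(f"{subtype}_{i + 1:04d}")
            labels.append(subtype)
    subtype = pd.Series(labels, index=samples, name="subtype")
    focal_mask = (subtype == config.focal_subtype).to_numpy(dtype=float)

    direction = np.zeros(len(genes))
    direction[:len(signature.up)] = 1.0
    direction[len(signature.up):len(sig_genes)] = -1.0

    # blocks: signature genes dealt into contiguous chunks; background -> -1
    block = np.full(len(genes), -1, dtype=int)
    if sig_genes and config.block_rho > 0:
        chunks = np.array_split(np.arange(len(sig_genes)), config.n_blocks)
        for b, idx in enumerate(chunks):
            block[idx] = b

    n_s = len(samples)
    mu = rng.normal(6.0, 2.0, size=len(genes))
    z = rng.standard_normal((config.n_blocks, n_s))
    eps = rng.standard_normal((len(genes), n_s))

    rho_g = np.where(block >= 0, config.block_rho, 0.0)[:, None]
    block_part = np.where(
        block[:, None] >= 0, z[np.clip(block, 0, None), :], 0.0
    )
    x = (
        mu[:, None]
        + config.delta * direction[:, None] * focal_mask[None, :]
        + config.sigma * (np.sqrt(rho_g) * block_part
                          + np.sqrt(1.0 - rho_g) * eps)
    )
    cohort = ExpressionCohort(
        values=pd.DataFrame(x, index=genes, columns=samples), subtype=subtype
    )
    truth = SimTruth(
        block_assignment={g: int(b) for g, b in zip(genes, block) if b >= 0},
        focal_effect={
            g: config.delta * d for g, d in zip(genes, direction) if d != 0
        },
    )
    return cohort, truth


def generate_enrichment_pair(
    n_terms: int,
    n_shared: int,
    seed: int,
    n_strong: int | None = None,
) -> tuple[list, SimTruth]:
    """Two condition-labeled enrichment tables sharing ``n_shared`` terms.

    ``n_strong`` of the shared terms (default: min(10, n_shared)) are planted
    with much smaller adjusted p-values in both tables, so they dominate the
    Stouffer-combined ranking.
    """
    from .meta import EnrichmentTable

    if n_shared > n_terms:
        raise ConfigurationError(
            f"n_shared={n_shared} exceeds n_terms={n_terms}"
        )
    if n_terms < 0 or n_shared < 0:
        raise ConfigurationError("n_terms and n_shared must be >= 0")
    n_strong = min(10, n_shared) if n_strong is None else n_strong
    if n_strong > n_shared:
        raise ConfigurationError(f"n_strong={n_strong} exceeds n_shared={n_shared}")
    rng = np.random.default_rng(seed)

    shared = [f"GO:S{i + 1:04d}" for i in range(n_shared)]
    strong = shared[:n_strong]
    n_unique = n_terms - n_shared
    tables = []
    for cond in CONDITIONS:
        unique = [f"GO:U{cond[0].upper()}{i + 1:04d}" for i in range(n_unique)]
        terms = shared + unique
        padj = np.empty(len(terms))
        padj[:n_strong] = rng.uniform(1e-10, 1e-6, size=n_strong)
        padj[n_strong:n_shared] = rng.uniform(1e-3, 0.04, size=n_shared - n_strong)
        padj[n_shared:] = rng.uniform(1e-5, 0.05, size=n_unique)
        tables.append(EnrichmentTable(
            condition=cond,
            rows=pd.DataFrame({
                "term_id": terms,
                "description": [f"synthetic process {t}" for t in terms],
                "padj": padj,
            }),
        ))
    truth = SimTruth(strong_terms=frozenset(strong), shared_terms=frozenset(shared))
    return tables, truth
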