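"""Expression-matrix I/O, QUBIC-style discretization and seed extraction.

The pipeline consumes a normalized genes x conditions expression matrix.  For
bi-clustering it is discretized row-wise into three regulation levels
(-1 = down, 0 = unchanged, +1 = up) with a two-sided rank rule: per gene, the
``ceil(q * n_conditions)`` largest values become +1 and the same number of
smallest values become -1.  The rule is rank-based and therefore invariant
under any strictly increasing per-row transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: The six functional stages of plant cell-wall synthesis used for seed labels
#: (Purdue Cell Wall Gene Families vocabulary).
STAGES: tuple[str, ...] = (
    "substrate generation",
    "polysaccharide synthases and glycosyl transferases",
    "assembly, architecture and growth",
    "differentiation and secondary wall formation",
    "signaling and response",
    "secretion and targeting",
)


class FormatError(ValueError):
    """Malformed expression / seed input."""


class UnsupportedParameterError(ValueError):
    """A parameter outside the supported range of this pipeline."""


@dataclass
class ExpressionMatrix:
    """Real-valued genes x conditions matrix with unique, ordered id axes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate condition id: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric cells in expression matrix")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"missing/non-finite value at gene {idx[i]!r}, condition {cols[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def condition_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class DiscreteMatrix:
    """{-1, 0, +1}-valued view of an expression matrix (same id axes)."""

    data: pd.DataFrame
    q: float
    K: int = 1

    def __post_init__(self) -> None:
        symbols = set(np.unique(self.data.to_numpy()))
        if not symbols <= {-1, 0, 1}:
            raise ValueError(f"symbols outside {{-1,0,1}}: {sorted(symbols)}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def condition_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]


@dataclass
class SeedSet:
    """Known pathway genes (seeds) with their synthesis-stage labels."""

    members: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.members.values() if s not in STAGES}
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x conditions TSV (header = condition ids, col 0 = gene ids).

    ``#`` comment lines are ignored.  Duplicate ids and missing / non-numeric
    cells are rejected with the offending id in the message.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id in {path}: {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from None
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        cond = values.columns[values.isna().any(axis=0)][0]
        raise FormatError(f"missing value at gene {gene!r}, condition {cond!r}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "gene_id"
    return ExpressionMatrix(values)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write canonical TSV (readable back byte-identically via read/write)."""
    out = m.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def write_discrete(d: DiscreteMatrix, path) -> None:
    out = d.data.astype(int).copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_seeds(path) -> SeedSet:
    """Read a seed TSV with columns (gene_id, stage)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "stage"]:
        raise FormatError("seed TSV must start with columns gene_id, stage")
    return SeedSet(dict(zip(df["gene_id"], df["stage"])))


def write_seeds(s: SeedSet, path) -> None:
    df = pd.DataFrame(
        sorted(s.members.items()), columns=["gene_id", "stage"]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def discretize(m: ExpressionMatrix, q: float = 0.15, K: int = 1) -> DiscreteMatrix:
    """Discretize each gene row into {-1, 0, +1} by a two-sided rank rule.

    Per row of ``n`` conditions, the ``ceil(q*n)`` largest values map to +1 and
    the ``ceil(q*n)`` smallest (among the remaining cells) map to -1.  Ties at
    the boundary are broken by condition order: the earlier condition takes the
    extreme label.  A constant row has no distinguishable extremes and maps to
    all zeros.  Only ``K = 1`` (three levels) is supported.
    """
    if K != 1:
        raise UnsupportedParameterError(f"only K=1 is supported, got K={K}")
    if not 0 < q < 0.5:
        raise ValueError(f"q must lie in (0, 0.5), got {q}")
    values = m.data.to_numpy(dtype=float)
    n_genes, n_cond = values.shape
    k = math.ceil(q * n_cond)
    out = np.zeros((n_genes, n_cond), dtype=np.int8)
    order = np.arange(n_cond)
    for i in range(n_genes):
        row = values[i]
        if row.max() == row.min():
            continue
        desc = np.lexsort((order, -row))  # value desc, earlier condition first
        out[i, desc[:k]] = 1
        asc = np.lexsort((order, row))
        down = [j for j in asc if out[i, j] != 1][:k]
        out[i, down] = -1
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return DiscreteMatrix(df, q=q, K=1)


def extract_seed_matrix(m: ExpressionMatrix, s: SeedSet) -> ExpressionMatrix:
    """Row-subset of ``m`` restricted to seed genes (all conditions kept).

    Seeds absent from the matrix are silently dropped (logged with a count);
    an empty intersection is an error.
    """
    present = [g for g in m.gene_ids if g in s]
    dropped = len(s) - len(present)
    if dropped:
        log.info("dropped %d seed gene(s) absent from the matrix", dropped)
    if not present:
        raise ValueError("no seed gene found in the expression matrix")
    return ExpressionMatrix(m.data.loc[present])
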