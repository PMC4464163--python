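"""Tabular on-disk formats for expression matrices, networks and result tables.

All formats are plain tab-separated text:

* expression matrix — header ``gene_id<TAB>sample1<TAB>...``, one gene per row;
* design — columns ``sample_id, genotype, treatment, replicate``;
* network — two columns ``tf_id<TAB>target_id``, ``#`` comment lines allowed;
* result tables — header plus one row per record, P-values in scientific
  notation.

Gene and sample identifiers are opaque case-sensitive strings; missing or
non-numeric expression values are rejected rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("sample_id", "genotype", "treatment", "replicate")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a per-sample design.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with one column per sample; intensities
        are assumed to be on a log2 scale.
    design:
        DataFrame indexed by sample id with columns ``genotype``,
        ``treatment`` and ``replicate`` (1-based within each group).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, genotype: str, treatment: str) -> list[str]:
        """Sample ids of one (genotype, treatment) group, ordered by replicate."""
        mask = (self.design["genotype"] == genotype) & (
            self.design["treatment"] == treatment
        )
        sub = self.design.loc[mask].sort_values("replicate")
        return list(sub.index)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.design.copy())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = int(np.size(arr) - np.isfinite(arr).sum())
            raise FormatError(f"{bad} non-finite expression value(s)")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ConsistencyError(
                f"samples absent from the design: {sorted(missing)}"
            )
        extra = set(self.design.index) - set(self.values.columns)
        if extra:
            raise ConsistencyError(
                f"design rows without a matrix column: {sorted(extra)}"
            )
        for col in ("genotype", "treatment", "replicate"):
            if col not in self.design.columns:
                raise FormatError(f"design is missing column {col!r}")
        # replicate indices must be 1..n with no gaps inside each group
        for (gt, tr), grp in self.design.groupby(["genotype", "treatment"]):
            reps = sorted(int(r) for r in grp["replicate"])
            if reps != list(range(1, len(reps) + 1)):
                raise ConsistencyError(
                    f"replicate indices of group ({gt}, {tr}) are {reps}, "
                    f"expected 1..{len(reps)}"
                )


@dataclass
class RegulatoryNetwork:
    """A directed TF -> target pair set plus the gene universe tested against."""

    pairs: set[tuple[str, str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)
        if not self.universe:
            self.universe = {g for pair in self.pairs for g in pair}
        if not self.universe:
            raise ConsistencyError("network universe is empty")

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {tg for _, tg in self.pairs}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression_table(matrix_path, design_path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix plus its design table.

    Every sample column must appear in the design; a sample missing from the
    design is an error, never silently dropped.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if raw.shape[1] < 2:
        raise FormatError(f"{matrix_path}: expected gene_id plus sample columns")
    gene_col = raw.columns[0]
    dup = raw[gene_col][raw[gene_col].duplicated()]
    if len(dup):
        raise FormatError(f"{matrix_path}: duplicate gene id {dup.iloc[0]!r}")
    values = raw.set_index(gene_col)
    values.index.name = "gene_id"
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any() or values[col].isna().any():
            gene = values.index[(coerced.isna())][0]
            raise FormatError(
                f"{matrix_path}: non-numeric or missing value for gene "
                f"{gene!r}, sample {col!r}"
            )
        values[col] = coerced.astype(float)

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    missing_cols = set(DESIGN_COLUMNS) - set(design.columns)
    if missing_cols:
        raise FormatError(f"{design_path}: missing columns {sorted(missing_cols)}")
    if design["sample_id"].duplicated().any():
        dup_id = design["sample_id"][design["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{design_path}: duplicate sample id {dup_id!r}")
    design = design.set_index("sample_id")
    design["replicate"] = design["replicate"].astype(int)
    return ExpressionMatrix(values, design)


def write_expression_table(em: ExpressionMatrix, matrix_path, design_path) -> None:
    """Write an :class:`ExpressionMatrix` in the paired TSV format."""
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.10g")
    design = em.design.copy()
    design.index.name = "sample_id"
    design.to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# network I/O


def read_network_pairs(path, universe: set[str] | None = None) -> RegulatoryNetwork:
    """Read a two-column TF->target edge list.

    Duplicate pairs are de-duplicated (count logged). When a ``universe`` is
    given, pairs whose *target* is outside it are dropped (count logged) and
    the universe is stored; otherwise the universe is every gene seen in the
    file.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"found {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    unique = set(pairs)
    n_dup = len(pairs) - len(unique)
    if n_dup:
        logger.info("read_network_pairs: de-duplicated %d pair(s)", n_dup)
    if universe is not None:
        kept = {p for p in unique if p[1] in universe}
        n_drop = len(unique) - len(kept)
        if n_drop:
            logger.info(
                "read_network_pairs: dropped %d pair(s) with target outside "
                "the universe",
                n_drop,
            )
        return RegulatoryNetwork(kept, set(universe))
    return RegulatoryNetwork(unique)


def write_network_pairs(network: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("#tf_id\ttarget_id\n")
        for tf, tg in sorted(network.pairs):
            fh.write(f"{tf}\t{tg}\n")


# ---------------------------------------------------------------------------
# result tables

_PVALUE_COLUMNS = {"p_value", "fdr", "p_adjusted"}


def _format_cell(column: str, value) -> str:
    if column in _PVALUE_COLUMNS and isinstance(value, float):
        return f"{value:.6e}"
    if isinstance(value, float):
        if math.isfinite(value) and value == int(value) and abs(value) < 1e15:
            return f"{value:.6g}"
        return f"{value:.6g}"
    return str(value)


def write_results_table(
    rows: Sequence[Mapping], path, columns: Sequence[str] | None = None
) -> None:
    """Write result records as TSV, preserving row order.

    P-value-like columns are rendered in scientific notation with 7
    significant digits; all records must share a schema.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ConsistencyError(
                "cannot infer a header from an empty sequence; pass `columns`"
            )
        columns = list(rows[0].keys())
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            if set(row.keys()) != set(columns):
                raise ConsistencyError("result records do not share a schema")
            fh.write("\t".join(_format_cell(c, row[c]) for c in columns) + "\n")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
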