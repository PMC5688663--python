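"""Reading and writing expression matrices, GMT gene-set collections and score tables.

Expression matrices are plain pandas DataFrames (genes as rows, samples as
columns) in linear-scale, length-normalised units (FPKM/TPM-like) or array
intensities. Gene identifiers are HGNC-style symbols matched
case-insensitively by uppercasing; duplicate rows are collapsed by the
arithmetic mean, mirroring the usual probe-collapsing convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xcellkit")

#: size bounds enforced for learned signatures (user-supplied sets are exempt)
MIN_SIGNATURE_GENES = 8
MAX_SIGNATURE_GENES = 200


class ExpressionValidationError(ValueError):
    """Raised when an expression matrix violates its invariants."""


class GmtParseError(ValueError):
    """Raised on malformed GMT input."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set, optionally tied to a cell type and data source.

    Learned signatures follow the naming convention ``celltype%source%index``,
    from which ``cell_type`` and ``source`` are parsed.
    """

    name: str
    genes: frozenset[str]
    cell_type: str = ""
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))
        if not self.cell_type and "%" in self.name:
            parts = self.name.split("%")
            object.__setattr__(self, "cell_type", parts[0])
            if len(parts) > 1:
                object.__setattr__(self, "source", parts[1])

    def __len__(self) -> int:
        return len(self.genes)


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce ExpressionMatrix invariants on a genes x samples DataFrame.

    Uppercases gene identifiers, collapses duplicates by mean, and rejects
    negative or all-missing data. NaNs are permitted (a missing value is
    treated downstream as a missing gene in that sample).
    """
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionValidationError("expression matrix is empty")
    df = df.copy()
    df.index = df.index.astype(str).str.upper()
    df = df.apply(pd.to_numeric, errors="coerce")
    neg = df.lt(0)
    if neg.any().any():
        gene = neg.any(axis=1).idxmax()
        sample = neg.loc[gene].idxmax()
        raise ExpressionValidationError(
            f"negative expression value at gene {gene!r}, sample {sample!r}"
        )
    if not np.isfinite(df.to_numpy(dtype=float)[~np.isnan(df.to_numpy(dtype=float))]).all():
        raise ExpressionValidationError("non-finite expression values")
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    all_missing = df.isna().all(axis=0)
    if all_missing.any():
        raise ExpressionValidationError(
            f"sample {all_missing.idxmax()!r} has no observed genes"
        )
    return df


def read_expression(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression table from TSV or CSV.

    The first column holds gene identifiers and the header row holds sample
    identifiers. Duplicate gene rows are averaged.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise GmtParseError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise ExpressionValidationError(f"{path}: no sample columns found")
    df = validate_expression(df)
    logger.info("read %d genes x %d samples from %s", df.shape[0], df.shape[1], path)
    return df


def write_expression(df: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    sep = "\t" if fmt == "tsv" else ","
    df.to_csv(path, sep=sep, index_label="gene")


def read_gmt(path: str | Path, validate_signature_sizes: bool = False) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``.

    With ``validate_signature_sizes`` the learned-signature size bounds
    (8-200 genes) are enforced.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected at least 3 tab-separated columns"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            gs = GeneSet(name=name, description=desc, genes=frozenset(genes))
            if validate_signature_sizes and not (
                MIN_SIGNATURE_GENES <= len(gs) <= MAX_SIGNATURE_GENES
            ):
                raise GmtParseError(
                    f"{path}:{lineno}: signature {name!r} has {len(gs)} genes; "
                    f"learned signatures must have between {MIN_SIGNATURE_GENES} "
                    f"and {MAX_SIGNATURE_GENES}"
                )
            sets.append(gs)
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description or 'na'}\t{genes}\n")


def write_scores(
    scores: pd.DataFrame,
    path: str | Path,
    pvalues: pd.DataFrame | None = None,
    pvalue_path: str | Path | None = None,
) -> None:
    """Write a cell type x sample score table (TSV), optionally with a
    companion p-value table."""
    if scores.shape[0] == 0:
        raise ValueError("score matrix has no cell-type rows")
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("score matrix contains non-finite values")
    scores.to_csv(path, sep="\t", index_label="cell_type")
    if pvalues is not None:
        if pvalue_path is None:
            p = Path(path)
            pvalue_path = p.with_name(p.stem + ".pvals" + (p.suffix or ".tsv"))
        pvalues.to_csv(pvalue_path, sep="\t", index_label="cell_type")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
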