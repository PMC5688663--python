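"""Single-sample gene-set enrichment (ssGSEA) and per-cell-type raw scores.

The statistic is the Barbie-style integrated difference between a weighted
empirical CDF of the in-set genes and the unweighted ECDF of the out-of-set
genes, walked down the sample's expression ranking. Genes are ranked by
expression descending; the in-set weight at rank position i (1 = bottom,
N = top) is ``rank_value**tau`` with ``tau = 0.25`` by default. The score
depends only on within-sample ranks, which is what makes it portable across
platforms and normalisation schemes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet

logger = logging.getLogger("xcellkit")

DEFAULT_TAU = 0.25
DEFAULT_MIN_SHARED_GENES = 5000


class EmptyIntersectionError(ValueError):
    """The gene set shares no genes with the expression profile."""


def ssgsea_score(
    sample_expression: pd.Series, gene_set: GeneSet | Iterable[str], tau: float = DEFAULT_TAU
) -> float:
    """ssGSEA enrichment of one gene set in one expression profile.

    Missing values are treated as missing genes; set genes absent from the
    profile are dropped from the set for this sample. Rank ties are broken
    by gene identifier for determinism.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(g.upper() for g in gene_set)
    expr = sample_expression.dropna()
    if len(expr) < 2:
        raise ValueError("profile must contain at least 2 observed genes")
    names = expr.index.astype(str).str.upper().to_numpy()
    values = expr.to_numpy(dtype=float)
    # sort names first, then stable-sort by value descending: ties end up in name order
    name_order = np.argsort(names, kind="stable")
    order = name_order[np.argsort(-values[name_order], kind="stable")]
    member = np.isin(names[order], list(genes))
    m = int(member.sum())
    n = len(values)
    if m == 0:
        raise EmptyIntersectionError("gene set has no genes in common with the profile")
    if m == n:
        raise ValueError("gene set covers the entire profile; out-of-set ECDF undefined")
    rank_values = np.arange(n, 0, -1, dtype=float)  # top gene has rank value n
    weights = np.where(member, rank_values**tau, 0.0)
    cum_in = np.cumsum(weights) / weights.sum()
    cum_out = np.cumsum(~member) / (n - m)
    return float(np.sum(cum_in - cum_out))


def _universe_of(signatures: Iterable[GeneSet]) -> set[str]:
    universe: set[str] = set()
    for gs in signatures:
        universe |= gs.genes
    return universe


def score_signatures(
    expr: pd.DataFrame,
    signatures: Sequence[GeneSet] | "object",
    tau: float = DEFAULT_TAU,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every signature in every sample; rows signatures, columns samples.

    ``signatures`` may be a sequence of :class:`GeneSet` or any object with a
    ``signatures`` attribute and optional ``universe`` (a SignatureSet). The
    intersection of the expression genes with the signature universe must
    reach ``min_shared_genes`` (the scores degrade gracefully with missing
    genes, but a thin intersection is not trustworthy).

    With ``normalize`` the final matrix is divided by its global max - min,
    an optional across-sample rescaling some ssGSEA implementations apply.
    """
    sets = list(getattr(signatures, "signatures", signatures))
    if not sets:
        raise ValueError("no signatures supplied")
    universe = getattr(signatures, "universe", None)
    universe = set(universe) if universe is not None else _universe_of(sets)
    expr_genes_upper = set(expr.index.astype(str).str.upper())
    shared = len(expr_genes_upper & {g.upper() for g in universe})
    if shared < min_shared_genes:
        raise ValueError(
            f"requires intersection of at least {min_shared_genes} genes with the "
            f"signature universe; found {shared}"
        )

    values = expr.to_numpy(dtype=float)
    names = expr.index.astype(str).str.upper().to_numpy()
    if np.isnan(values).any():
        # slow path: per-sample missing-gene handling
        out = np.empty((len(sets), expr.shape[1]))
        for j, col in enumerate(expr.columns):
            sample = expr[col]
            for i, gs in enumerate(sets):
                out[i, j] = ssgsea_score(sample, gs, tau=tau)
        result = pd.DataFrame(out, index=[gs.name for gs in sets], columns=expr.columns)
    else:
        result = _score_dense(values, names, sets, list(expr.columns), tau)
    if normalize:
        rng_span = float(result.to_numpy().max() - result.to_numpy().min())
        if rng_span > 0:
            result = result / rng_span
    return result


def _score_dense(
    values: np.ndarray,
    names: np.ndarray,
    sets: Sequence[GeneSet],
    columns: list[str],
    tau: float,
) -> pd.DataFrame:
    """Vectorised scoring for a complete (NaN-free) matrix."""
    n, n_samples = values.shape
    if n < 2:
        raise ValueError("profile must contain at least 2 observed genes")
    name_order = np.argsort(names, kind="stable")
    values = values[name_order]
    names = names[name_order]
    gene_pos = {g: i for i, g in enumerate(names)}
    membership = np.zeros((len(sets), n), dtype=bool)
    for i, gs in enumerate(sets):
        idx = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if not idx:
            raise EmptyIntersectionError(
                f"gene set {gs.name!r} has no genes in common with the expression matrix"
            )
        membership[i, idx] = True
    m = membership.sum(axis=1)
    if (m == n).any():
        raise ValueError("a gene set covers the entire profile; out-of-set ECDF undefined")

    rank_values = np.arange(n, 0, -1, dtype=float)
    wv = rank_values**tau
    out = np.empty((len(sets), n_samples))
    for j in range(n_samples):
        order = np.argsort(-values[:, j], kind="stable")
        member_sorted = membership[:, order]
        win = member_sorted * wv
        cum_in = np.cumsum(win, axis=1)
        cum_in /= cum_in[:, -1][:, None]
        cum_out = np.cumsum(~member_sorted, axis=1) / (n - m)[:, None]
        out[:, j] = (cum_in - cum_out).sum(axis=1)
    return pd.DataFrame(out, index=[gs.name for gs in sets], columns=columns)


def raw_cell_scores(
    sig_scores: pd.DataFrame, cell_types: Sequence[str] | None = None
) -> pd.DataFrame:
    """Aggregate signature scores into per-cell-type raw scores (stage A).

    Each signature row is shifted to a minimum of 0 across samples, then rows
    belonging to the same cell type are averaged. The cell type of a row is
    taken from ``cell_types`` (aligned with rows) or parsed from the
    ``celltype%source%index`` naming convention.
    """
    if cell_types is None:
        cell_types = [str(name).split("%")[0] for name in sig_scores.index]
    if len(cell_types) != sig_scores.shape[0]:
        raise ValueError("cell_types must align with signature rows")
    shifted = sig_scores.sub(sig_scores.min(axis=1), axis=0)
    shifted.index = pd.Index(cell_types, name="cell_type")
    raw = shifted.groupby(level=0, sort=True).mean()
    return raw
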