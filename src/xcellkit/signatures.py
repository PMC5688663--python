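"""Learning cell-type gene signatures from a multi-source reference atlas.

For each data source and cell type, candidate signatures are the genes whose
low quantile of expression in the cell type exceeds the (r-th largest) high
quantile across all other cell types by a threshold — swept over a grid of
quantile pairs, opposing-quantile ranks and thresholds. Candidates are
filtered against a carcinoma cell-line panel (genes that cancers tend to
overexpress are excluded, except for cell types that are themselves the cell
of origin of solid tumors) and the best candidates are selected by their
cross-source ability to separate the cell type's samples from all others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CellTypeHierarchy, ReferenceAtlas, SourceData
from .io import GeneSet, MAX_SIGNATURE_GENES, MIN_SIGNATURE_GENES
from .ssgsea import DEFAULT_TAU, score_signatures

logger = logging.getLogger("xcellkit")

#: (low quantile, high quantile) pairs swept during signature derivation
DEFAULT_Q_PAIRS: tuple[tuple[float, float], ...] = (
    (0.10, 0.90),
    (0.25, 0.75),
    (0.333, 0.666),
    (0.50, 0.50),
)
#: log2-scale difference thresholds swept during signature derivation
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0, 0.1, float(np.log2(1.5)), 1.0, 3.0, 4.0, 5.0)

#: cell types that may be the cell of origin of solid tumors; the cancer-gene
#: filter is skipped for these (their markers ARE cancer-overexpressed genes)
DEFAULT_EXEMPT_CELL_TYPES = frozenset(
    {
        "epithelial cells",
        "sebocytes",
        "keratinocytes",
        "hepatocytes",
        "melanocytes",
        "astrocytes",
        "neurons",
    }
)

OVEREXPRESSION_RATE_CUTOFF = 0.05


@dataclass
class SignatureCandidate:
    """A candidate signature with its derivation parameters and fitness."""

    gene_set: GeneSet
    q_low: float
    q_high: float
    rank: int  # which largest opposing quantile was used (1..3)
    threshold: float
    t_stat: float = float("nan")


@dataclass
class SignatureSet:
    """Selected signatures grouped by cell type, with the shared gene universe."""

    signatures: list[GeneSet]
    universe: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def cell_types(self) -> list[str]:
        return sorted({gs.cell_type for gs in self.signatures})

    def for_cell_type(self, cell_type: str) -> list[GeneSet]:
        return [gs for gs in self.signatures if gs.cell_type == cell_type]


def log_transform(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise log2(x + 3).

    The +3 offset damps fold-changes among barely expressed genes before the
    quantile comparisons.
    """
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("log_transform requires non-negative input")
    out = np.log2(arr + 3.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def compute_overexpression_rates(panel: pd.DataFrame, n_grid: int = 512) -> pd.Series:
    """Per-gene fraction of cell lines overexpressing the gene.

    A line overexpresses gene g when its value exceeds twice the peak (mode)
    of g's cross-line expression distribution. The peak is located with a
    Gaussian KDE (Silverman bandwidth) in log2(x+3) space on a 512-point
    grid, then mapped back to linear scale.
    """
    if panel.shape[1] < 10:
        raise ValueError("cell-line panel must have at least 10 lines")
    values = panel.to_numpy(dtype=float)
    log_values = np.log2(values + 3.0)
    rates = np.empty(panel.shape[0])
    for i in range(panel.shape[0]):
        y = log_values[i]
        if np.ptp(y) < 1e-12:
            mode_linear = values[i, 0]
        else:
            kde = stats.gaussian_kde(y, bw_method="silverman")
            grid = np.linspace(y.min(), y.max(), n_grid)
            mode_linear = max(float(np.exp2(grid[np.argmax(kde(grid))]) - 3.0), 0.0)
        rates[i] = float(np.mean(values[i] > 2.0 * mode_linear))
    return pd.Series(rates, index=panel.index, name="overexpression_rate")


def filter_cancer_genes(
    universe: list[str],
    rates: pd.Series,
    cell_type: str,
    exempt_cell_types: frozenset[str] = DEFAULT_EXEMPT_CELL_TYPES,
    cutoff: float = OVEREXPRESSION_RATE_CUTOFF,
) -> list[str]:
    """Keep genes whose cancer-line overexpression rate is strictly below the
    cutoff; cell types that can be a solid tumor's cell of origin are exempt
    and keep the whole universe."""
    if cell_type.lower() in {t.lower() for t in exempt_cell_types}:
        return list(universe)
    allowed = [g for g in universe if g in rates.index and rates[g] < cutoff]
    if not allowed:
        logger.warning("cancer-gene filter removed every gene for cell type %r", cell_type)
    return allowed


def derive_signatures(
    source: SourceData,
    allowed_genes: dict[str, list[str]] | list[str] | None = None,
    q_pairs: tuple[tuple[float, float], ...] = DEFAULT_Q_PAIRS,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    max_rank: int = 3,
    hierarchy: CellTypeHierarchy | None = None,
    universe: list[str] | None = None,
    min_genes: int = MIN_SIGNATURE_GENES,
    max_genes: int = MAX_SIGNATURE_GENES,
) -> list[SignatureCandidate]:
    """Derive candidate signatures for every cell type of one source.

    For cell type A, quantile pair (q, 1-q), opposing rank r and threshold t,
    the candidate holds every allowed gene g with

        Q1_q(A; g) - [r-th largest over other cell types of Q2_{1-q}(.; g)] >= t

    computed on log2(x+3) expression of the source's training samples.
    Parent/descendant cell types of A are excluded from "other cell types".
    Only candidates with ``min_genes``..``max_genes`` genes are kept. The grid
    is fully crossed: len(q_pairs) * max_rank * len(thresholds) configurations
    per cell type.
    """
    hierarchy = hierarchy or CellTypeHierarchy()
    cell_types = source.cell_types
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types to derive signatures")
    genes = list(universe) if universe is not None else list(source.expression.index)
    expr = log_transform(source.expression.loc[genes])

    # per (cell type, q-pair): low and high quantiles over training samples
    q1: dict[tuple[str, float], np.ndarray] = {}
    q2: dict[tuple[str, float], np.ndarray] = {}
    for t in cell_types:
        sub = expr[source.samples_of(t)].to_numpy()
        for q_low, q_high in q_pairs:
            key_l, key_h = (t, q_low), (t, q_high)
            if key_l not in q1:
                q1[key_l] = np.quantile(sub, q_low, axis=1)
            if key_h not in q2:
                q2[key_h] = np.quantile(sub, q_high, axis=1)

    if allowed_genes is None:
        allowed_genes = genes
    gene_index = {g: i for i, g in enumerate(genes)}
    genes_arr = np.array(genes)

    candidates: list[SignatureCandidate] = []
    for a in cell_types:
        allowed = allowed_genes.get(a, genes) if isinstance(allowed_genes, dict) else allowed_genes
        allowed_mask = np.zeros(len(genes), dtype=bool)
        allowed_mask[[gene_index[g] for g in allowed if g in gene_index]] = True
        others = [b for b in cell_types if b != a and not hierarchy.related(a, b)]
        if not others:
            continue
        for q_low, q_high in q_pairs:
            opposing = np.stack([q2[(b, q_high)] for b in others])
            order = np.sort(opposing, axis=0)  # ascending per gene
            for r in range(1, max_rank + 1):
                if r > len(others):
                    break
                rth_largest = order[-r]
                diff = q1[(a, q_low)] - rth_largest
                for t in thresholds:
                    mask = (diff >= t) & allowed_mask
                    n = int(mask.sum())
                    if not (min_genes <= n <= max_genes):
                        continue
                    name = f"{a}%{source.name}%q{int(q_low * 1000)}_r{r}_t{t:g}"
                    candidates.append(
                        SignatureCandidate(
                            gene_set=GeneSet(
                                name=name,
                                genes=frozenset(genes_arr[mask]),
                                cell_type=a,
                                source=source.name,
                            ),
                            q_low=q_low,
                            q_high=q_high,
                            rank=r,
                            threshold=t,
                        )
                    )
    logger.info("derived %d candidate signatures from source %s", len(candidates), source.name)
    return candidates


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.ttest_ind(x, y, equal_var=False)
    t = float(res.statistic)
    return t if np.isfinite(t) else float("-inf")


def select_best_signatures(
    candidates: list[SignatureCandidate],
    atlas: ReferenceAtlas,
    tau: float = DEFAULT_TAU,
    top_k: int = 3,
) -> SignatureSet:
    """Select the most reliable signatures per (cell type, source).

    Each candidate is scored by ssGSEA in every source that contains its cell
    type other than the source it was learned from (falling back to the
    training source when the type exists nowhere else — logged, since that
    self-evaluation risks circularity). Fitness is the Welch t-statistic of
    the cell type's samples vs all other samples (parents/descendants
    omitted), averaged across evaluation sources. The ``top_k`` candidates
    per (cell type, source) are kept, renamed ``celltype%source%k``; ties
    break by larger gene count, then name.
    """
    hierarchy = atlas.hierarchy
    # dedupe identical gene sets to score each only once per source
    unique_sets: dict[frozenset[str], int] = {}
    for cand in candidates:
        unique_sets.setdefault(cand.gene_set.genes, len(unique_sets))
    proxy_sets = [
        GeneSet(name=f"u{idx}", genes=genes) for genes, idx in unique_sets.items()
    ]

    # score matrices per source, lazily
    score_cache: dict[str, pd.DataFrame] = {}

    def scores_in(src: SourceData) -> pd.DataFrame:
        if src.name not in score_cache:
            train = [s for s in src.annotations.index if s not in src.test_samples]
            score_cache[src.name] = score_signatures(
                src.expression[train], proxy_sets, tau=tau, min_shared_genes=1
            )
        return score_cache[src.name]

    selected: list[GeneSet] = []
    by_group: dict[tuple[str, str], list[SignatureCandidate]] = {}
    for cand in candidates:
        by_group.setdefault((cand.gene_set.cell_type, cand.gene_set.source), []).append(cand)

    for (cell_type, source_name), group in sorted(by_group.items()):
        eval_sources = [
            s for s in atlas.sources_with(cell_type) if s.name != source_name
        ]
        if not eval_sources:
            logger.warning(
                "cell type %r only present in its training source %r; "
                "evaluating in-source (risk of circularity)",
                cell_type,
                source_name,
            )
            eval_sources = [atlas.get_source(source_name)]
        for cand in group:
            proxy = f"u{unique_sets[cand.gene_set.genes]}"
            t_values = []
            for src in eval_sources:
                row = scores_in(src).loc[proxy]
                ann = src.annotations[row.index]
                relatives = hierarchy.relatives(cell_type)
                own = row[ann == cell_type].to_numpy()
                other = row[~ann.isin(relatives)].to_numpy()
                if len(own) < 2 or len(other) < 2:
                    continue
                t_values.append(_welch_t(own, other))
            cand.t_stat = float(np.mean(t_values)) if t_values else float("-inf")
        group.sort(
            key=lambda c: (-c.t_stat, -len(c.gene_set), c.gene_set.name)
        )
        seen: set[frozenset[str]] = set()
        kept = 0
        for cand in group:
            if not np.isfinite(cand.t_stat) or cand.gene_set.genes in seen:
                continue
            seen.add(cand.gene_set.genes)
            kept += 1
            selected.append(
                GeneSet(
                    name=f"{cell_type}%{source_name}%{kept}",
                    genes=cand.gene_set.genes,
                    cell_type=cell_type,
                    source=source_name,
                )
            )
            if kept == top_k:
                break
        if kept == 0:
            logger.warning("no reliable signature for %r from %r", cell_type, source_name)

    universe = sorted(set(atlas.genes))
    return SignatureSet(signatures=selected, universe=universe)


def learn_signatures(
    atlas: ReferenceAtlas,
    cellline_panel: pd.DataFrame | None = None,
    overexpression_rates: pd.Series | None = None,
    exempt_cell_types: frozenset[str] = DEFAULT_EXEMPT_CELL_TYPES,
    tau: float = DEFAULT_TAU,
    top_k: int = 3,
    q_pairs: tuple[tuple[float, float], ...] = DEFAULT_Q_PAIRS,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    max_rank: int = 3,
) -> tuple[SignatureSet, pd.DataFrame]:
    """End-to-end signature learning over all atlas sources.

    Applies the cancer-gene filter (when a cell-line panel is given), derives
    the candidate grid per source on the shared gene universe, and selects
    the top signatures cross-source. Returns the selected SignatureSet and a
    derivation log table (one row per candidate configuration).
    """
    universe = atlas.genes
    if overexpression_rates is None and cellline_panel is not None:
        overexpression_rates = compute_overexpression_rates(cellline_panel)
    if overexpression_rates is not None:
        rates = overexpression_rates
        allowed = {
            t: filter_cancer_genes(universe, rates, t, exempt_cell_types)
            for t in atlas.cell_types
        }
    else:
        allowed = {t: list(universe) for t in atlas.cell_types}

    candidates: list[SignatureCandidate] = []
    for src in atlas.sources:
        candidates.extend(
            derive_signatures(
                src,
                allowed_genes=allowed,
                q_pairs=q_pairs,
                thresholds=thresholds,
                max_rank=max_rank,
                hierarchy=atlas.hierarchy,
                universe=universe,
            )
        )
    sig_set = select_best_signatures(candidates, atlas, tau=tau, top_k=top_k)
    log = pd.DataFrame(
        [
            {
                "cell_type": c.gene_set.cell_type,
                "source": c.gene_set.source,
                "q_pair": f"{c.q_low:g}/{c.q_high:g}",
                "rank": c.rank,
                "threshold": c.threshold,
                "n_genes": len(c.gene_set),
                "t_stat": c.t_stat,
            }
            for c in candidates
        ]
    )
    return sig_set, log
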