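"""The user-facing scoring pipeline.

Given an expression matrix, a signature set and learned parameters, produce
adjusted cell-type enrichment scores:

1. ssGSEA-score every signature in every sample;
2. min-shift and average signature rows into per-cell-type raw scores A;
3. transform each element: T_ij = ((A_ij - min(A_i)) / 5000)^P_i / (V1_i V2_i);
4. compensate spillover per sample by non-negative least squares against the
   spillover matrix K (off-diagonal scaled by alpha, default 0.5).

The resulting scores are arbitrary units resembling proportions — they
support comparisons across samples and across cell types, but cannot be
interpreted as proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .calibration import DEFAULT_ALPHA, ParamBundle, SCORE_DIVISOR
from .signatures import SignatureSet
from .ssgsea import DEFAULT_MIN_SHARED_GENES, DEFAULT_TAU, raw_cell_scores, score_signatures

logger = logging.getLogger("xcellkit")


@dataclass
class AdjustedScores:
    """Final adjusted cell type x sample scores with compensation diagnostics."""

    scores: pd.DataFrame  # cell types x samples, all >= 0
    residual_norms: pd.Series  # per-sample NNLS residual
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.scores.to_numpy() < 0).any():
            raise ValueError("adjusted scores must be non-negative")


def transform_scores(A: pd.DataFrame, params: ParamBundle) -> pd.DataFrame:
    """Linearize and calibrate raw scores row-wise.

    T_ij = ((A_ij - min(A_i)) / 5000)^{P_i} / (V1_i * V2_i), with min(A_i)
    taken across the samples of the input matrix itself.
    """
    missing = [t for t in A.index if t not in params.P.index]
    if missing:
        raise ValueError(
            f"no learned parameters for cell types {missing[:5]} "
            f"(platform family {params.platform_family!r})"
        )
    vals = A.to_numpy(dtype=float)
    shifted = (vals - vals.min(axis=1, keepdims=True)) / SCORE_DIVISOR
    P = params.P[A.index].to_numpy()[:, None]
    denom = (params.V1[A.index] * params.V2[A.index]).to_numpy()[:, None]
    T = np.power(shifted, P) / denom
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def spillover_compensate(
    T: pd.DataFrame, K: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> AdjustedScores:
    """Remove cross-cell-type spillover from transformed scores.

    Solves, per sample column T_i, the non-negative least-squares problem
    min ||K' x - T_i|| with x >= 0, where K' is K with off-diagonal entries
    multiplied by ``alpha`` (Lawson-Hanson active set; deterministic). With
    alpha = 0 or K = I the solution is the input column itself.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    types = list(T.index)
    if set(types) - set(K.index) or set(types) - set(K.columns):
        raise ValueError("spillover matrix does not cover all scored cell types")
    k = K.loc[types, types].to_numpy(dtype=float)
    k_scaled = np.where(np.eye(len(types), dtype=bool), k, alpha * k)
    X = np.empty_like(T.to_numpy(dtype=float))
    residuals = np.empty(T.shape[1])
    t_arr = T.to_numpy(dtype=float)
    for j in range(T.shape[1]):
        X[:, j], residuals[j] = optimize.nnls(k_scaled, t_arr[:, j])
    scores = pd.DataFrame(X, index=types, columns=T.columns)
    return AdjustedScores(
        scores=scores,
        residual_norms=pd.Series(residuals, index=T.columns, name="residual"),
        metadata={"alpha": alpha},
    )


def microenvironment_score(
    adjusted: AdjustedScores | pd.DataFrame,
    immune_types: list[str],
    stromal_types: list[str],
) -> pd.DataFrame:
    """Per-sample ImmuneScore, StromaScore and their sum, the
    MicroenvironmentScore (a proxy inversely related to tumor purity)."""
    scores = adjusted.scores if isinstance(adjusted, AdjustedScores) else adjusted
    unknown = [t for t in list(immune_types) + list(stromal_types) if t not in scores.index]
    if unknown:
        raise ValueError(f"unknown cell types in microenvironment lists: {unknown}")
    immune = scores.loc[list(immune_types)].sum(axis=0)
    stroma = scores.loc[list(stromal_types)].sum(axis=0)
    return pd.DataFrame(
        {
            "ImmuneScore": immune,
            "StromaScore": stroma,
            "MicroenvironmentScore": immune + stroma,
        }
    ).T


def xcell_scores(
    expr: pd.DataFrame,
    signatures: SignatureSet,
    params: dict[str, ParamBundle] | ParamBundle,
    platform: str = "sequencing",
    alpha: float | None = None,
    tau: float = DEFAULT_TAU,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> AdjustedScores:
    """Full pipeline: signature scores -> raw A -> transformed T -> adjusted x.

    ``platform`` selects the parameter bundle ('sequencing' or 'array');
    separate K matrices and calibration vectors are learned per family.
    Scores are most meaningful with many heterogeneous samples: the min-shift
    is taken within the input, so a single-sample matrix scores all zero.
    """
    if isinstance(params, ParamBundle):
        bundle = params
    else:
        if platform not in params:
            raise ValueError(f"no parameter bundle for platform {platform!r}")
        bundle = params[platform]
    if expr.shape[1] < 2:
        logger.warning(
            "scoring a single sample: the within-matrix min-shift forces all "
            "scores to 0; use at least 2 heterogeneous samples"
        )
    alpha = bundle.alpha if alpha is None else alpha
    sig_scores = score_signatures(expr, signatures, tau=tau, min_shared_genes=min_shared_genes)
    raw = raw_cell_scores(sig_scores)
    scored = [t for t in raw.index if t in bundle.P.index]
    T = transform_scores(raw.loc[scored], bundle)
    adjusted = spillover_compensate(T, bundle.K, alpha=alpha)
    adjusted.metadata.update(
        {
            "platform_family": bundle.platform_family,
            "tau": tau,
            "alpha": alpha,
            "n_signatures": len(signatures),
        }
    )
    return adjusted
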