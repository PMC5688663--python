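"""Score-vs-truth evaluation for simulated mixtures.

Correlates estimated cell-type scores with the ground-truth mixing
fractions: the diagonal (each type's score against its own fraction)
measures recovery, the off-diagonal cross-correlations measure spillover
between cell types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def correlation_report(
    scores: pd.DataFrame, fractions: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Pearson correlations of scores (types x samples) against true
    fractions (samples x types).

    Returns the per-type diagonal correlations and the full score-type x
    fraction-type cross-correlation matrix. Constant vectors have undefined
    correlation and are reported as NaN.
    """
    samples = list(scores.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to correlate")
    if set(samples) != set(fractions.index):
        raise ValueError("scores and fractions must cover the same samples")
    frac = fractions.loc[samples]
    score_types = list(scores.index)
    frac_types = list(frac.columns)
    cross = pd.DataFrame(np.nan, index=score_types, columns=frac_types)
    for st in score_types:
        s = scores.loc[st].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            continue
        for ft in frac_types:
            f = frac[ft].to_numpy(dtype=float)
            if np.ptp(f) == 0:
                continue
            cross.loc[st, ft] = float(np.corrcoef(s, f)[0, 1])
    shared = [t for t in frac_types if t in score_types]
    diag = pd.Series({t: cross.loc[t, t] for t in shared}, name="r")
    return diag, cross


def mean_offdiagonal(cross: pd.DataFrame) -> float:
    """Mean absolute off-diagonal score-fraction correlation (spill report)."""
    vals = []
    for st in cross.index:
        for ft in cross.columns:
            if st != ft and np.isfinite(cross.loc[st, ft]):
                vals.append(abs(float(cross.loc[st, ft])))
    return float(np.mean(vals)) if vals else float("nan")


def evaluate(
    fractions: pd.DataFrame,
    before: pd.DataFrame,
    after: pd.DataFrame,
) -> dict:
    """Before/after-compensation correlation report for one mixture set.

    ``before`` are transformed scores, ``after`` the spillover-compensated
    ones (both types x samples); ``fractions`` the ground truth.
    """
    diag_before, cross_before = correlation_report(before, fractions)
    diag_after, cross_after = correlation_report(after, fractions)
    return {
        "diag_before": diag_before,
        "diag_after": diag_after,
        "cross_before": cross_before,
        "cross_after": cross_after,
        "offdiag_before": mean_offdiagonal(cross_before),
        "offdiag_after": mean_offdiagonal(cross_after),
    }
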