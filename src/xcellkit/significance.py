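"""Significance of adjusted scores: is the cell type in the mixture at all?

The pipeline produces non-zero adjusted scores even for cell types absent
from a mixture. For each cell type X a null distribution of its score is
learned from random mixtures of all other cell types — excluding X and its
parent/descendants, so no genuine signal leaks in — and a beta distribution
is fitted to the resulting scores. The p-value of an observed score is the
null tail probability above it, under the null hypothesis that X is not
present. Cell types whose null scores are consistently zero get a constant
null at 0.001. A score with p > 0.2 is conventionally reported as
non-significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .atlas import ReferenceAtlas
from .calibration import ParamBundle
from .scoring import AdjustedScores, xcell_scores
from .signatures import SignatureSet
from .ssgsea import DEFAULT_TAU

logger = logging.getLogger("xcellkit")

NULL_NOISE_LEVEL = 0.05  # extra per-gene noise in null mixtures
CONSTANT_NULL_VALUE = 0.001
ZERO_SCORE_EPS = 1e-6
CLIP_EPS = 1e-6
NONSIGNIFICANT_P = 0.2
DEFAULT_NULL_MIXTURES = 1000


@dataclass
class NullDistribution:
    """Null model of one cell type's adjusted score in mixtures lacking it."""

    cell_type: str
    kind: str  # "beta" | "constant"
    a: float = float("nan")
    b: float = float("nan")
    constant_value: float = CONSTANT_NULL_VALUE
    platform_family: str = "sequencing"

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "constant"):
            raise ValueError(f"kind must be 'beta' or 'constant', got {self.kind!r}")
        if self.kind == "beta" and not (self.a > 0 and self.b > 0):
            raise ValueError("beta shape parameters must be positive")

    def pvalue(self, score: float) -> float:
        """P(null score >= observed score)."""
        if self.kind == "constant":
            return 1.0 if score <= self.constant_value else 0.0
        return float(stats.beta.sf(min(score, 1.0), self.a, self.b))


def generate_null_mixtures(
    atlas: ReferenceAtlas,
    excluded_type: str,
    n: int = DEFAULT_NULL_MIXTURES,
    seed: int = 0,
    platform: str | None = None,
) -> pd.DataFrame:
    """Random mixtures of ALL cell types except the excluded one and its
    parent/descendants, with 5% uniform per-gene noise.

    Each mixture draws a random replicate per cell type and Dirichlet
    fractions; sources of the requested platform family are cycled.
    """
    sources = atlas.sources_by_platform(platform) if platform else atlas.sources
    if not sources:
        raise ValueError(f"atlas has no sources for platform {platform!r}")
    if not any(excluded_type in s.cell_types for s in sources):
        raise ValueError(f"cell type {excluded_type!r} not present in the atlas")
    excluded = atlas.hierarchy.relatives(excluded_type)
    rng = np.random.default_rng(seed)
    genes = atlas.genes
    cols: dict[str, np.ndarray] = {}
    for i in range(n):
        src = sources[i % len(sources)]
        types = [t for t in src.cell_types if t not in excluded]
        if len(types) < 2:
            raise ValueError(
                f"excluding {excluded_type!r} and its relatives leaves fewer than "
                f"2 cell types in source {src.name!r}"
            )
        f = rng.dirichlet(np.ones(len(types)))
        M = np.column_stack(
            [
                src.expression.loc[genes, src.samples_of(t)[rng.integers(len(src.samples_of(t)))]]
                for t in types
            ]
        )
        profile = M @ f
        profile = profile * rng.uniform(1.0 - NULL_NOISE_LEVEL, 1.0 + NULL_NOISE_LEVEL, size=len(profile))
        cols[f"null{i + 1:04d}"] = profile
    return pd.DataFrame(cols, index=genes)


def fit_null(
    scores: np.ndarray | pd.Series, cell_type: str = "", platform_family: str = "sequencing"
) -> NullDistribution:
    """Fit a beta null to a vector of adjusted scores (>= 30 required).

    All-zero score vectors give the constant null at 0.001. Scores are
    capped at 1 and clipped away from the support edges before the
    maximum-likelihood fit; a failed fit falls back to method of moments.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 30:
        raise ValueError("need at least 30 null scores to fit a distribution")
    if (s <= ZERO_SCORE_EPS).all():
        return NullDistribution(
            cell_type=cell_type, kind="constant", platform_family=platform_family
        )
    capped = np.minimum(s, 1.0)
    if (capped < s).any():
        logger.info("capped %d null scores above 1 for %r", int((capped < s).sum()), cell_type)
    clipped = np.clip(capped, CLIP_EPS, 1.0 - CLIP_EPS)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(clipped, floc=0.0, fscale=1.0)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise RuntimeError("non-finite MLE")
    except Exception:
        logger.warning("beta MLE failed for %r; falling back to method of moments", cell_type)
        m, v = clipped.mean(), clipped.var()
        common = m * (1.0 - m) / max(v, 1e-12) - 1.0
        a, b = max(m * common, 1e-6), max((1.0 - m) * common, 1e-6)
    return NullDistribution(
        cell_type=cell_type, kind="beta", a=float(a), b=float(b), platform_family=platform_family
    )


def fit_nulls(
    atlas: ReferenceAtlas,
    signatures: SignatureSet,
    params: dict[str, ParamBundle] | ParamBundle,
    platform: str = "sequencing",
    cell_types: list[str] | None = None,
    n: int = DEFAULT_NULL_MIXTURES,
    seed: int = 0,
    tau: float = DEFAULT_TAU,
    min_shared_genes: int = 1,
) -> dict[str, NullDistribution]:
    """Learn a null distribution per cell type by excluding it from random
    mixtures and running the full scoring pipeline."""
    bundle = params if isinstance(params, ParamBundle) else params[platform]
    if cell_types is None:
        cell_types = [t for t in bundle.cell_types]
    rng = np.random.default_rng(seed)
    nulls: dict[str, NullDistribution] = {}
    for ct in cell_types:
        mixtures = generate_null_mixtures(
            atlas, ct, n=n, seed=int(rng.integers(2**31 - 1)), platform=platform
        )
        adjusted = xcell_scores(
            mixtures, signatures, bundle, platform=platform, tau=tau, min_shared_genes=min_shared_genes
        )
        nulls[ct] = fit_null(adjusted.scores.loc[ct], cell_type=ct, platform_family=platform)
    return nulls


def score_pvalues(
    adjusted: AdjustedScores | pd.DataFrame, nulls: dict[str, NullDistribution]
) -> pd.DataFrame:
    """Per-score p-values under each cell type's null; missing nulls give NaN."""
    scores = adjusted.scores if isinstance(adjusted, AdjustedScores) else adjusted
    out = pd.DataFrame(np.nan, index=scores.index, columns=scores.columns)
    for ct in scores.index:
        null = nulls.get(ct)
        if null is None:
            logger.warning("no null distribution for cell type %r; p-values missing", ct)
            continue
        if null.kind == "constant":
            out.loc[ct] = np.where(scores.loc[ct] <= null.constant_value, 1.0, 0.0)
        else:
            out.loc[ct] = stats.beta.sf(np.minimum(scores.loc[ct], 1.0), null.a, null.b)
    return out


def save_nulls(nulls: dict[str, NullDistribution], path: str | Path) -> None:
    data = [
        {
            "cell_type": d.cell_type,
            "kind": d.kind,
            "a": None if np.isnan(d.a) else float(d.a),
            "b": None if np.isnan(d.b) else float(d.b),
            "constant_value": float(d.constant_value),
            "platform_family": d.platform_family,
        }
        for d in nulls.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def load_nulls(path: str | Path) -> dict[str, NullDistribution]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    nulls = {}
    for entry in data:
        nulls[entry["cell_type"]] = NullDistribution(
            cell_type=entry["cell_type"],
            kind=entry["kind"],
            a=float("nan") if entry.get("a") is None else entry["a"],
            b=float("nan") if entry.get("b") is None else entry["b"],
            constant_value=entry.get("constant_value", CONSTANT_NULL_VALUE),
            platform_family=entry.get("platform_family", "sequencing"),
        )
    return nulls
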