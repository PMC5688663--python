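"""Learning score calibration parameters and the spillover matrix.

Raw ssGSEA-derived cell-type scores are neither linear in the underlying
cell-type fraction nor comparable across cell types. Both are fixed with
parameters learned from designed noiseless mixtures of the reference atlas:

* a titration series of one cell type against a platform control at doubling
  fractions 0.8%..25.6% yields a power coefficient P (score^P is linear in
  fraction) and a slope V1 per cell type;
* a panel of 25%-cell-type / 75%-control mixtures, scored and transformed,
  yields the spillover matrix K (how much cell type j's presence inflates
  cell type i's score) and the calibration diagonal V2.

K is learned per platform family (sequencing vs array) and cleaned so that
no compensation happens between a parent cell type and its descendants, nor
between children of different parents, with off-diagonal entries capped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .atlas import CellTypeHierarchy, ReferenceAtlas
from .signatures import SignatureSet
from .ssgsea import DEFAULT_TAU, raw_cell_scores, score_signatures

logger = logging.getLogger("xcellkit")

#: doubling titration fractions, 0.8% .. 25.6%
DEFAULT_TITRATION_LEVELS: tuple[float, ...] = (0.008, 0.016, 0.032, 0.064, 0.128, 0.256)
#: score divisor applied after min-shifting, fixed by the transform definition
SCORE_DIVISOR = 5000.0
DEFAULT_ALPHA = 0.5
SPILLOVER_CAP = 0.5
SPILLOVER_MIXTURE_LEVEL = 0.25


@dataclass
class ParamBundle:
    """Learned transformation parameters for one platform family."""

    platform_family: str  # "sequencing" | "array"
    P: pd.Series  # cell type -> power coefficient
    V1: pd.Series  # cell type -> linear slope
    V2: pd.Series  # cell type -> pre-normalization spillover diagonal
    K: pd.DataFrame  # spillover matrix: rows cell-type scores, columns cell types
    alpha: float = DEFAULT_ALPHA

    def validate(self) -> None:
        for name, vec in (("P", self.P), ("V1", self.V1), ("V2", self.V2)):
            if (vec <= 0).any():
                bad = vec.index[vec <= 0][0]
                raise ValueError(f"{name} must be positive for every cell type ({bad!r} is not)")
        k = self.K.to_numpy()
        if not np.allclose(np.diag(k), 1.0):
            raise ValueError("spillover matrix diagonal must be 1")
        off = k[~np.eye(k.shape[0], dtype=bool)]
        if (off < 0).any() or (off > SPILLOVER_CAP + 1e-12).any():
            raise ValueError(f"off-diagonal spillover must lie in [0, {SPILLOVER_CAP}]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.K.index)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "platform_family": self.platform_family,
            "alpha": float(self.alpha),
            "P": {t: float(v) for t, v in self.P.items()},
            "V1": {t: float(v) for t, v in self.V1.items()},
            "V2": {t: float(v) for t, v in self.V2.items()},
        }
        with open(directory / f"{self.platform_family}.params.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        self.K.to_csv(directory / f"{self.platform_family}.spillover.tsv", sep="\t", index_label="cell_type")

    @classmethod
    def load(cls, directory: str | Path, platform_family: str) -> "ParamBundle":
        directory = Path(directory)
        with open(directory / f"{platform_family}.params.yaml") as fh:
            meta = yaml.safe_load(fh)
        K = pd.read_csv(directory / f"{platform_family}.spillover.tsv", sep="\t", index_col=0)
        return cls(
            platform_family=meta["platform_family"],
            P=pd.Series(meta["P"]),
            V1=pd.Series(meta["V1"]),
            V2=pd.Series(meta["V2"]),
            K=K,
            alpha=float(meta.get("alpha", DEFAULT_ALPHA)),
        )


def save_params(bundles: dict[str, ParamBundle], directory: str | Path) -> None:
    for bundle in bundles.values():
        bundle.save(directory)


def load_params(directory: str | Path) -> dict[str, ParamBundle]:
    directory = Path(directory)
    bundles = {}
    for path in sorted(directory.glob("*.params.yaml")):
        family = path.name.removesuffix(".params.yaml")
        bundles[family] = ParamBundle.load(directory, family)
    if not bundles:
        raise FileNotFoundError(f"no parameter bundles found in {directory}")
    return bundles


def build_titration_series(
    atlas: ReferenceAtlas,
    source: str,
    cell_type: str,
    control_type: str,
    levels: tuple[float, ...] = DEFAULT_TITRATION_LEVELS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Noiseless median-profile mixtures of one cell type against a control.

    Level ``l`` mixes ``l`` of the cell type's median profile with ``1 - l``
    of the control's. Returns the genes x levels profile matrix and the
    fraction vector.
    """
    if control_type == cell_type:
        raise ValueError("control cell type must differ from the titrated cell type")
    src = atlas.get_source(source)
    for t in (cell_type, control_type):
        if t not in src.cell_types:
            raise ValueError(f"cell type {t!r} not present in source {source!r}")
    target = src.median_profile(cell_type).to_numpy()
    control = src.median_profile(control_type).to_numpy()
    fracs = np.asarray(levels, dtype=float)
    profiles = target[:, None] * fracs[None, :] + control[:, None] * (1.0 - fracs[None, :])
    cols = [f"titr_{l:g}" for l in levels]
    return pd.DataFrame(profiles, index=src.expression.index, columns=cols), fracs


def fit_power_coefficient(
    scores: np.ndarray,
    fractions: np.ndarray,
    fit_range: tuple[float, float] = (0.008, 0.256),
    method: str = "linearize",
) -> float:
    """Fit a power relation between titration scores and fractions; return
    the power coefficient P, the exponent that makes score^P linear in
    fraction.

    Scores are shifted to 0 at their minimum (the lowest titration level) and
    divided by 5000; the fit uses the points in ``fit_range`` with positive
    shifted score (the shift reference itself is always 0 and drops out).

    The transform exists to linearize the score-fraction relation, so the
    default ``method='linearize'`` chooses (P, a) minimizing the residual of
    score^P = a * fraction directly. ``method='nls'`` fits score = c * f^b
    by nonlinear least squares in the score domain and returns 1/b;
    ``method='loglog'`` is ordinary least squares of log(score) on
    log(fraction) (relative residuals). The log-log slope seeds both
    iterative fits and serves as their fallback.
    """
    scores = np.asarray(scores, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if len(scores) < 4:
        raise ValueError("need at least 4 titration points")
    if method not in ("linearize", "nls", "loglog"):
        raise ValueError(f"method must be 'linearize', 'nls' or 'loglog', got {method!r}")
    shifted = (scores - scores.min()) / SCORE_DIVISOR
    mask = (shifted > 0) & (fractions >= fit_range[0] - 1e-12) & (fractions <= fit_range[1] + 1e-12)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 positive titration scores; cannot fit power function")
    sh, fr = shifted[mask], fractions[mask]
    logf, logs = np.log(fr), np.log(sh)
    b_init, log_c = np.polyfit(logf, logs, 1)
    if b_init <= 0:
        raise ValueError(f"degenerate power fit (log-log slope {b_init:.4g} <= 0)")
    P = 1.0 / b_init
    if mask.sum() >= 3:
        try:
            if method == "linearize":
                # scale-balance the residuals: normalize adjusted scores by
                # their top point so P and a are on comparable footing
                def resid(theta):
                    p, a = theta
                    adj = sh**p
                    return adj / adj.max() - a * fr
                res = optimize.least_squares(
                    resid,
                    x0=[P, 1.0 / fr.max()],
                    bounds=([0.05, 1e-8], [50.0, 1e8]),
                )
                if res.success and np.isfinite(res.x[0]):
                    P = float(res.x[0])
            elif method == "nls":
                popt, _ = optimize.curve_fit(
                    lambda f, c, bb: c * f**bb,
                    fr,
                    sh,
                    p0=[float(np.exp(log_c)), float(max(b_init, 0.05))],
                    maxfev=10000,
                )
                if np.isfinite(popt[1]) and popt[1] > 0:
                    P = float(1.0 / popt[1])
        except RuntimeError:
            logger.warning("iterative power fit failed; using log-log slope")
    return float(P)


def fit_linear_calibration(adjusted_scores: np.ndarray, fractions: np.ndarray) -> float:
    """Intercept-free least-squares slope of adjusted score on fraction (V1)."""
    s = np.asarray(adjusted_scores, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if not np.any(s != 0):
        raise ValueError("all adjusted scores are zero; cannot calibrate")
    return float(np.dot(f, s) / np.dot(f, f))


def _titration_raw_scores(
    atlas: ReferenceAtlas,
    source: str,
    cell_type: str,
    signatures: SignatureSet,
    tau: float,
    levels: tuple[float, ...],
) -> tuple[np.ndarray, np.ndarray]:
    src = atlas.get_source(source)
    control = atlas.control_for(src.platform, exclude=cell_type)
    profiles, fracs = build_titration_series(atlas, source, cell_type, control, levels)
    sig_scores = score_signatures(profiles, signatures, tau=tau, min_shared_genes=1)
    raw = raw_cell_scores(sig_scores)
    return raw.loc[cell_type].to_numpy(), fracs


def fit_transformation_params(
    atlas: ReferenceAtlas,
    signatures: SignatureSet,
    platform_family: str,
    tau: float = DEFAULT_TAU,
    levels: tuple[float, ...] = DEFAULT_TITRATION_LEVELS,
) -> tuple[pd.Series, pd.Series]:
    """Learn P and V1 for every cell type of one platform family.

    The power coefficient is fit per source and averaged across the family's
    sources containing the cell type; V1 is then fit per source with the
    averaged P and averaged likewise.
    """
    sources = atlas.sources_by_platform(platform_family)
    if not sources:
        raise ValueError(f"atlas has no {platform_family!r} sources")
    cell_types = sorted({t for s in sources for t in s.cell_types})
    scored_types = set(signatures.cell_types)
    P: dict[str, float] = {}
    V1: dict[str, float] = {}
    cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for ct in cell_types:
        if ct not in scored_types:
            continue
        control = atlas.control_for(platform_family, exclude=ct)
        p_fits = []
        for src in sources:
            if ct not in src.cell_types or control not in src.cell_types:
                continue
            cache[(src.name, ct)] = _titration_raw_scores(atlas, src.name, ct, signatures, tau, levels)
            p_fits.append(fit_power_coefficient(*cache[(src.name, ct)]))
        if not p_fits:
            logger.warning("no titratable source for %r in %s family; skipping", ct, platform_family)
            continue
        P[ct] = float(np.mean(p_fits))
        v1_fits = []
        for src in sources:
            if (src.name, ct) not in cache:
                continue
            scores, fracs = cache[(src.name, ct)]
            shifted = (scores - scores.min()) / SCORE_DIVISOR
            v1_fits.append(fit_linear_calibration(shifted ** P[ct], fracs))
        V1[ct] = float(np.mean(v1_fits))
    return pd.Series(P, name="P"), pd.Series(V1, name="V1")


def learn_spillover_matrix(
    atlas: ReferenceAtlas,
    signatures: SignatureSet,
    P: pd.Series,
    V1: pd.Series,
    platform_family: str,
    tau: float = DEFAULT_TAU,
    mixture_level: float = SPILLOVER_MIXTURE_LEVEL,
) -> tuple[pd.DataFrame, pd.Series]:
    """Learn the spillover matrix K and calibration diagonal V2.

    Every non-control cell type of the family is mixed at 25% with 75%
    control (median profiles), the mixtures are scored and transformed with
    the learned P and V1 (V2 provisionally 1), score matrices are averaged
    across the family's sources, and each row is divided by its diagonal.
    The pre-normalisation diagonal is returned as V2.

    The control cell types themselves are present at 75% in every mixture
    and are therefore never absent — their scores have no baseline anchor in
    this panel. They get identity K rows/columns and V2 = 1: controls exist
    for calibration, not for spillover compensation.
    """
    from .scoring import transform_scores  # local import; scoring depends on this module

    sources = atlas.sources_by_platform(platform_family)
    if not sources:
        raise ValueError(f"atlas has no {platform_family!r} sources")
    controls = set(atlas.control_types.get(platform_family, []))
    scored_types = (set(signatures.cell_types) & set(P.index)) - controls
    mats = []
    for src in sources:
        types = [t for t in src.cell_types if t in scored_types]
        cols = {}
        for ct in types:
            control = atlas.control_for(platform_family, exclude=ct)
            target = src.median_profile(ct).to_numpy()
            ctrl = src.median_profile(control).to_numpy()
            cols[ct] = mixture_level * target + (1.0 - mixture_level) * ctrl
        profiles = pd.DataFrame(cols, index=src.expression.index)
        raw = raw_cell_scores(score_signatures(profiles, signatures, tau=tau, min_shared_genes=1))
        raw = raw.loc[[t for t in raw.index if t in scored_types]]
        provisional = ParamBundle(
            platform_family=platform_family,
            P=P,
            V1=V1,
            V2=pd.Series(1.0, index=P.index),
            K=pd.DataFrame(np.eye(len(P)), index=P.index, columns=P.index),
        )
        mats.append(transform_scores(raw, provisional))
    combined = pd.concat(mats).groupby(level=0).mean()
    # square it up: rows are scored types, columns the mixed types
    types = sorted(set(combined.index) & set(combined.columns))
    pre = combined.loc[types, types]
    diag = pd.Series(np.diag(pre.to_numpy()), index=types, name="V2")
    zero = diag[diag <= 0]
    if not zero.empty:
        raise ValueError(f"zero spillover diagonal for cell type {zero.index[0]!r}")
    K = pre.div(diag, axis=0)
    ctrl_present = sorted(controls & set(P.index))
    if ctrl_present:
        all_types = types + ctrl_present
        K_full = pd.DataFrame(np.eye(len(all_types)), index=all_types, columns=all_types)
        K_full.loc[types, types] = K
        K = K_full
        diag = pd.concat([diag, pd.Series(1.0, index=ctrl_present)])
    return K, diag


def clean_spillover(
    K: pd.DataFrame, hierarchy: CellTypeHierarchy, cap: float = SPILLOVER_CAP
) -> pd.DataFrame:
    """Apply the hierarchy rules and cap to a spillover matrix.

    Parent cell types are compensated only against other parents; child cell
    types only against children of the same parent and against parents other
    than their own. Entries between a parent and its descendants are zeroed
    in both directions. Remaining off-diagonal entries are clipped to
    [0, cap]; the diagonal is untouched. Idempotent.
    """
    if not 0.0 < cap <= 1.0:
        raise ValueError(f"cap must be in (0, 1], got {cap}")
    K = K.copy()
    types = list(K.index)
    for i in types:
        for j in K.columns:
            if i == j:
                continue
            i_parent = hierarchy.is_parent(i)
            j_parent = hierarchy.is_parent(j)
            allowed = (
                (i_parent and j_parent)
                or (not i_parent and j_parent and hierarchy.parent_of(i) != j)
                or (not i_parent and not j_parent and hierarchy.parent_of(i) == hierarchy.parent_of(j))
            )
            if not allowed:
                K.loc[i, j] = 0.0
            else:
                K.loc[i, j] = min(max(K.loc[i, j], 0.0), cap)
    return K


def complete_cross_family(bundles: dict[str, ParamBundle]) -> dict[str, ParamBundle]:
    """Fill cell types missing from one platform family with the other's
    parameters and K columns, copied verbatim."""
    if len(bundles) < 2:
        return bundles
    families = list(bundles)
    for fam in families:
        other = bundles[[f for f in families if f != fam][0]]
        own = bundles[fam]
        missing = [t for t in other.cell_types if t not in own.cell_types]
        if not missing:
            continue
        all_types = list(own.cell_types) + missing
        K = pd.DataFrame(np.eye(len(all_types)), index=all_types, columns=all_types)
        K.loc[own.K.index, own.K.columns] = own.K
        for t in missing:
            donors = [c for c in other.K.columns if c in all_types]
            K.loc[t, donors] = other.K.loc[t, donors]
            K.loc[donors, t] = other.K.loc[donors, t]
        bundles[fam] = ParamBundle(
            platform_family=own.platform_family,
            P=pd.concat([own.P, other.P[missing]]),
            V1=pd.concat([own.V1, other.V1[missing]]),
            V2=pd.concat([own.V2, other.V2[missing]]),
            K=K,
            alpha=own.alpha,
        )
    return bundles


def learn_params(
    atlas: ReferenceAtlas,
    signatures: SignatureSet,
    tau: float = DEFAULT_TAU,
    levels: tuple[float, ...] = DEFAULT_TITRATION_LEVELS,
    alpha: float = DEFAULT_ALPHA,
    cap: float = SPILLOVER_CAP,
) -> dict[str, ParamBundle]:
    """Learn a full ParamBundle for every platform family present in the atlas."""
    bundles: dict[str, ParamBundle] = {}
    families = sorted({s.platform for s in atlas.sources})
    for family in families:
        P, V1 = fit_transformation_params(atlas, signatures, family, tau=tau, levels=levels)
        K, V2 = learn_spillover_matrix(atlas, signatures, P, V1, family, tau=tau)
        K = clean_spillover(K, atlas.hierarchy, cap=cap)
        order = list(K.index)
        bundles[family] = ParamBundle(
            platform_family=family,
            P=P[order],
            V1=V1[order],
            V2=V2[order],
            K=K,
            alpha=alpha,
        )
        bundles[family].validate()
        logger.info(
            "learned %s params for %d cell types", family, len(order)
        )
    return complete_cross_family(bundles)
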