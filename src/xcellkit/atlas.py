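"""Synthetic multi-source reference atlases and in-silico bulk mixtures.

The generator emulates the structure of the curated pure-cell-type atlases
used to learn cell-type signatures: several data sources that share cell
types but differ by platform (sequencing vs array), per-cell-type planted
marker genes, within-cell-type replicate variability, multiplicative
per-source platform effects, and a carcinoma cell-line panel for the
cancer-gene filter. Mixtures are simulated as M x f — a convex combination
of pure profiles — in three modes: noiseless median profiles, randomly drawn
replicates, or a single replicate with bounded per-gene noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import validate_expression

MIXTURE_MODES = ("median_noiseless", "random_sample", "perturbed_single")


class HierarchyError(ValueError):
    pass


@dataclass(frozen=True)
class CellTypeHierarchy:
    """A two-level cell-type hierarchy: parents and their children.

    ``parent`` maps a child cell type to its parent; types absent from the
    map are parents (roots). Used to disable spillover compensation and
    null-mixture inclusion between a type and its relatives.
    """

    parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if par in self.parent:
                raise HierarchyError(
                    f"{par!r} is both a child and a parent; depth must be <= 2"
                )
            if child == par:
                raise HierarchyError(f"{child!r} is its own parent")

    def parent_of(self, cell_type: str) -> str | None:
        return self.parent.get(cell_type)

    def children_of(self, cell_type: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == cell_type)

    def is_parent(self, cell_type: str) -> bool:
        return cell_type not in self.parent

    def related(self, a: str, b: str) -> bool:
        """True if one of a, b is an ancestor of the other (or a == b)."""
        return a == b or self.parent.get(a) == b or self.parent.get(b) == a

    def relatives(self, cell_type: str) -> set[str]:
        """The cell type itself plus its parent and all its descendants."""
        out = {cell_type}
        par = self.parent.get(cell_type)
        if par is not None:
            out.add(par)
        out.update(self.children_of(cell_type))
        return out


@dataclass
class SourceData:
    """One data source: an expression matrix with sample annotations."""

    name: str
    platform: str  # "sequencing" | "array"
    expression: pd.DataFrame  # genes x samples
    annotations: pd.Series  # sample -> cell type
    test_samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.platform not in ("sequencing", "array"):
            raise ValueError(f"platform must be 'sequencing' or 'array', got {self.platform!r}")
        missing = set(self.annotations.index) - set(self.expression.columns)
        if missing:
            raise ValueError(f"annotated samples missing from expression: {sorted(missing)[:5]}")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.annotations.unique())

    def samples_of(self, cell_type: str, include_test: bool = False) -> list[str]:
        samples = [s for s, t in self.annotations.items() if t == cell_type]
        if not include_test:
            samples = [s for s in samples if s not in self.test_samples]
        if not samples:
            raise ValueError(f"cell type {cell_type!r} has no samples in source {self.name!r}")
        return samples

    def median_profile(self, cell_type: str) -> pd.Series:
        cols = self.samples_of(cell_type)
        return self.expression[cols].median(axis=1)


@dataclass
class ReferenceAtlas:
    """A multi-source reference of pure cell-type expression profiles."""

    sources: list[SourceData]
    hierarchy: CellTypeHierarchy = field(default_factory=CellTypeHierarchy)
    control_types: dict[str, list[str]] = field(default_factory=dict)
    markers: dict[str, tuple[str, ...]] | None = None  # planted ground truth

    @property
    def cell_types(self) -> list[str]:
        types: set[str] = set()
        for src in self.sources:
            types.update(src.cell_types)
        return sorted(types)

    @property
    def genes(self) -> list[str]:
        """Shared gene universe: intersection across sources."""
        shared: set[str] | None = None
        for src in self.sources:
            genes = set(src.expression.index)
            shared = genes if shared is None else shared & genes
        return sorted(shared or set())

    def get_source(self, name: str) -> SourceData:
        for src in self.sources:
            if src.name == name:
                return src
        raise KeyError(f"no source named {name!r}")

    def sources_with(self, cell_type: str) -> list[SourceData]:
        return [s for s in self.sources if cell_type in s.cell_types]

    def sources_by_platform(self, platform: str) -> list[SourceData]:
        return [s for s in self.sources if s.platform == platform]

    def control_for(self, platform: str, exclude: str | None = None) -> str:
        """First declared control cell type for the platform family, skipping
        ``exclude`` (so a control can itself be titrated against the other)."""
        controls = [c for c in self.control_types.get(platform, []) if c != exclude]
        if not controls:
            raise ValueError(f"no usable control cell type for platform {platform!r}")
        return controls[0]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta: dict = {
            "sources": [],
            "control_types": self.control_types,
            "hierarchy": dict(self.hierarchy.parent),
        }
        if self.markers is not None:
            meta["markers"] = {t: list(g) for t, g in self.markers.items()}
        for src in self.sources:
            src.expression.to_csv(directory / f"{src.name}.expr.tsv", sep="\t", index_label="gene")
            ann = pd.DataFrame(
                {
                    "sample": src.annotations.index,
                    "cell_type": src.annotations.values,
                    "is_test": [s in src.test_samples for s in src.annotations.index],
                }
            )
            ann.to_csv(directory / f"{src.name}.annot.tsv", sep="\t", index=False)
            meta["sources"].append({"name": src.name, "platform": src.platform})
        with open(directory / "meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceAtlas":
        directory = Path(directory)
        with open(directory / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        sources = []
        for entry in meta["sources"]:
            name = entry["name"]
            expr = pd.read_csv(directory / f"{name}.expr.tsv", sep="\t", index_col=0)
            expr = validate_expression(expr)
            ann = pd.read_csv(directory / f"{name}.annot.tsv", sep="\t")
            annotations = pd.Series(ann["cell_type"].values, index=ann["sample"].astype(str))
            test = frozenset(ann.loc[ann["is_test"], "sample"].astype(str))
            sources.append(
                SourceData(
                    name=name,
                    platform=entry["platform"],
                    expression=expr,
                    annotations=annotations,
                    test_samples=test,
                )
            )
        markers = meta.get("markers")
        return cls(
            sources=sources,
            hierarchy=CellTypeHierarchy(dict(meta.get("hierarchy", {}))),
            control_types={k: list(v) for k, v in meta.get("control_types", {}).items()},
            markers={t: tuple(g) for t, g in markers.items()} if markers else None,
        )


@dataclass(frozen=True)
class MixtureSpec:
    """Specification of a single simulated mixture over chosen cell types."""

    cell_types: tuple[str, ...]
    fractions: tuple[float, ...]
    source: str
    mode: str = "random_sample"
    noise_level: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MIXTURE_MODES:
            raise ValueError(f"mode must be one of {MIXTURE_MODES}, got {self.mode!r}")
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != len(self.cell_types):
            raise ValueError("fractions and cell_types must have equal length")
        if (f < 0).any():
            raise ValueError("fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {f.sum():.12f})")


def generate_atlas(
    n_cell_types: int = 8,
    n_sources: int = 3,
    genes_per_signature: int = 25,
    n_genes: int = 1200,
    samples_per_type: int = 4,
    marker_overlap: dict[tuple[str, str], float] | None = None,
    platform_effect_sigma: float = 0.3,
    sample_noise_sigma: float = 0.2,
    marker_strength: float = 6.0,
    platforms: list[str] | None = None,
    parent_map: dict[str, str] | None = None,
    control_names: tuple[str, str] = ("CtrlA", "CtrlB"),
    reserve_test_sample: bool = False,
    seed: int = 0,
) -> ReferenceAtlas:
    """Generate a synthetic multi-source reference atlas with planted markers.

    Each of the ``n_cell_types`` cell types (named CT01, CT02, ...) receives
    ``genes_per_signature`` marker genes expressed ``marker_strength`` log2
    units above baseline in that type. Two dedicated control cell types with
    unrelated markers are appended and declared as the titration controls
    for both platform families (each control is titratable against the
    other).

    ``marker_overlap`` maps (donor, recipient) cell-type-name pairs to a
    relatedness fraction p, emulating the partially shared transcriptional
    programs of closely related cell types: a fraction p of the donor's
    markers replaces the tail of the recipient's marker list (expressed at
    full strength in both types), and the remaining markers of each member
    of the pair are cross-expressed in the other at p * marker_strength.
    The graded cross-expression is what makes the pair's signatures
    inseparable and produces genuine score spillover downstream; with
    p = 0 types are orthogonal and the learned spillover matrix is
    essentially the identity.

    Sources differ by per-(gene, source) multiplicative platform factors
    (log-normal, sigma in log2 units) and samples within a type by
    log-normal replicate noise.

    Returns a :class:`ReferenceAtlas` whose ``markers`` attribute carries the
    planted ground truth.
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    total_types = n_cell_types + 2  # + two controls
    if n_genes < total_types * genes_per_signature:
        raise ValueError(
            f"marker budget infeasible: need at least {total_types * genes_per_signature} "
            f"genes for {total_types} cell types x {genes_per_signature} markers, "
            f"got n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    type_names = [f"CT{i + 1:02d}" for i in range(n_cell_types)] + list(control_names)
    if platforms is None:
        platforms = ["sequencing" if i % 2 == 0 else "array" for i in range(n_sources)]
    if len(platforms) != n_sources:
        raise ValueError("platforms must have one entry per source")

    # disjoint marker blocks, then apply requested overlaps
    dedicated: dict[str, list[str]] = {}
    for k, t in enumerate(type_names):
        start = k * genes_per_signature
        dedicated[t] = genes[start : start + genes_per_signature]
    markers = {t: list(g) for t, g in dedicated.items()}
    for (donor, recipient), frac in (marker_overlap or {}).items():
        if donor not in markers or recipient not in markers:
            raise ValueError(f"marker_overlap names unknown cell type: {(donor, recipient)}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("marker_overlap fractions must be in [0, 1]")
        k = int(round(frac * genes_per_signature))
        if k:
            markers[recipient] = dedicated[recipient][:-k] + dedicated[donor][:k]

    baseline = np.exp2(rng.normal(5.0, 1.5, size=n_genes))  # linear FPKM-like
    gene_idx = {g: i for i, g in enumerate(genes)}
    type_idx = {t: k for k, t in enumerate(type_names)}
    boost_log2 = np.zeros((n_genes, total_types))
    for k, t in enumerate(type_names):
        for g in markers[t]:
            boost_log2[gene_idx[g], k] = marker_strength
    # graded cross-expression between related pairs (symmetric)
    for (donor, recipient), frac in (marker_overlap or {}).items():
        level = frac * marker_strength
        for a, b in ((donor, recipient), (recipient, donor)):
            kb = type_idx[b]
            for g in markers[a]:
                gi = gene_idx[g]
                boost_log2[gi, kb] = max(boost_log2[gi, kb], level)
    boost = np.exp2(boost_log2)

    n_train = samples_per_type
    n_per_type = samples_per_type + (1 if reserve_test_sample else 0)
    sources: list[SourceData] = []
    for s in range(n_sources):
        platform_factor = np.exp2(rng.normal(0.0, platform_effect_sigma, size=n_genes))
        cols: dict[str, np.ndarray] = {}
        annotations: dict[str, str] = {}
        test: set[str] = set()
        for k, t in enumerate(type_names):
            pure = baseline * boost[:, k] * platform_factor
            for j in range(n_per_type):
                noise = np.exp2(rng.normal(0.0, sample_noise_sigma, size=n_genes))
                sample = f"S{s + 1}_{t}_{j + 1}"
                cols[sample] = pure * noise
                annotations[sample] = t
                if j >= n_train:
                    test.add(sample)
        expr = pd.DataFrame(cols, index=genes)
        sources.append(
            SourceData(
                name=f"src{s + 1}",
                platform=platforms[s],
                expression=expr,
                annotations=pd.Series(annotations),
                test_samples=frozenset(test),
            )
        )

    control_types = {p: list(control_names) for p in set(platforms)}
    return ReferenceAtlas(
        sources=sources,
        hierarchy=CellTypeHierarchy(dict(parent_map or {})),
        control_types=control_types,
        markers={t: tuple(g) for t, g in markers.items()},
    )


def generate_cellline_panel(
    atlas: ReferenceAtlas,
    n_lines: int = 100,
    imitator_fraction: float = 0.0,
    overexpression_line_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Generate a carcinoma-like cell-line expression panel over the atlas genes.

    A fraction ``imitator_fraction`` of all planted marker genes is made to
    imitate cancer expression: overexpressed (8-fold above baseline) in
    ``overexpression_line_fraction`` of the lines — above the 5% filtering
    threshold when that fraction exceeds 0.05. All other genes stay at
    baseline with tight replicate noise, so their overexpression rate is 0.

    Returns ``(panel, imitated_genes)``; the second element is the planted
    ground truth of cancer-imitating markers.
    """
    if not 0.0 <= imitator_fraction <= 1.0:
        raise ValueError("imitator_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = atlas.genes
    n_genes = len(genes)
    baseline = np.exp2(rng.normal(5.0, 1.5, size=n_genes))
    all_markers = sorted({g for ms in (atlas.markers or {}).values() for m in [ms] for g in m})
    n_imitators = int(round(imitator_fraction * len(all_markers)))
    imitated = sorted(rng.choice(all_markers, size=n_imitators, replace=False)) if n_imitators else []
    imitated_idx = [genes.index(g) for g in imitated]

    panel = baseline[:, None] * np.exp2(rng.normal(0.0, 0.05, size=(n_genes, n_lines)))
    n_over = max(1, int(round(overexpression_line_fraction * n_lines)))
    for gi in imitated_idx:
        lines = rng.choice(n_lines, size=n_over, replace=False)
        panel[gi, lines] *= 8.0
    df = pd.DataFrame(panel, index=genes, columns=[f"line{j + 1:03d}" for j in range(n_lines)])
    return df, list(imitated)


def _build_mixture_matrix(
    source: SourceData, spec: MixtureSpec, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for t in spec.cell_types:
        if spec.mode == "median_noiseless":
            col = source.median_profile(t)
        else:
            samples = source.samples_of(t)
            pick = samples[rng.integers(len(samples))]
            col = source.expression[pick].copy()
            if spec.mode == "perturbed_single":
                factors = rng.uniform(1.0 - spec.noise_level, 1.0 + spec.noise_level, size=len(col))
                col = col * factors
        cols[t] = col
    return pd.DataFrame(cols)


def simulate_mixture(atlas: ReferenceAtlas, spec: MixtureSpec) -> tuple[pd.Series, np.ndarray]:
    """Simulate one mixed expression profile as M x f.

    Columns of M are pure profiles of the requested cell types built per the
    mixture mode; f is the fraction vector. Returns the profile and the
    ground-truth fractions.
    """
    source = atlas.get_source(spec.source)
    missing = [t for t in spec.cell_types if t not in source.cell_types]
    if missing:
        raise ValueError(f"cell types {missing} not present in source {spec.source!r}")
    rng = np.random.default_rng(spec.seed)
    M = _build_mixture_matrix(source, spec, rng)
    f = np.asarray(spec.fractions, dtype=float)
    profile = pd.Series(M.to_numpy() @ f, index=M.index, name="mixture")
    return profile, f


def simulate_mixture_set(
    atlas: ReferenceAtlas,
    cell_types: list[str],
    n_mixtures: int = 500,
    mode: str = "random_sample",
    seed: int = 0,
    source: str | None = None,
    noise_level: float = 0.20,
    dirichlet_alpha: float = 1.0,
    filler_type: str | None = None,
    max_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a set of mixtures with randomly drawn fractions.

    By default each mixture draws f from a symmetric Dirichlet over the
    chosen cell types and rebuilds M per the mode. With ``filler_type``,
    each chosen cell type instead receives an INDEPENDENT uniform fraction
    in [0, max_fraction] (default 1/n_types) and the filler cell type
    absorbs the remainder — fractions of distinct cell types are then
    uncorrelated, which disentangles score spillover from the negative
    compositional correlation a simplex draw imposes.

    Cell types that cannot be distinguished — a parent together with its
    child — are rejected.

    Returns ``(profiles, fractions)``: a genes x n_mixtures matrix and an
    n_mixtures x cell-type fraction table (rows sum to 1; the filler, when
    used, appears as the last fraction column).
    """
    if n_mixtures < 1:
        raise ValueError("n_mixtures must be >= 1")
    for i, a in enumerate(cell_types):
        for b in cell_types[i + 1 :]:
            if atlas.hierarchy.related(a, b):
                raise ValueError(
                    f"cell types {a!r} and {b!r} are parent/descendant and cannot "
                    "be jointly included in a mixture"
                )
    if filler_type is not None and filler_type in cell_types:
        raise ValueError("filler_type must not be among the chosen cell types")
    if source is None:
        source = atlas.sources[0].name
    src = atlas.get_source(source)
    rng = np.random.default_rng(seed)
    all_types = list(cell_types) + ([filler_type] if filler_type else [])
    cap = max_fraction if max_fraction is not None else 1.0 / len(cell_types)
    profiles = {}
    fracs = np.empty((n_mixtures, len(all_types)))
    for i in range(n_mixtures):
        if filler_type is None:
            f = rng.dirichlet(np.full(len(cell_types), dirichlet_alpha))
        else:
            signal = rng.uniform(0.0, cap, size=len(cell_types))
            f = np.append(signal, 1.0 - signal.sum())
        spec = MixtureSpec(
            cell_types=tuple(all_types),
            fractions=tuple(f),
            source=source,
            mode=mode,
            noise_level=noise_level,
            seed=int(rng.integers(2**31 - 1)),
        )
        M = _build_mixture_matrix(src, spec, np.random.default_rng(spec.seed))
        profiles[f"mix{i + 1:04d}"] = M.to_numpy() @ f
        fracs[i] = f
    expr = pd.DataFrame(profiles, index=src.expression.index)
    frac_df = pd.DataFrame(fracs, index=list(expr.columns), columns=all_types)
    return expr, frac_df
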