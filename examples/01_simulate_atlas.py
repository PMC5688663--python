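"""Generate a synthetic multi-source reference atlas and simulate mixtures.

The atlas plants marker genes for each cell type across several data
sources (with platform effects and replicate noise); mixtures are convex
combinations M x f of pure profiles with known fractions — the ground truth
every later stage is judged against.
"""

from xcellkit import generate_atlas, simulate_mixture_set

atlas = generate_atlas(
    n_cell_types=5,
    n_sources=2,
    genes_per_signature=20,
    n_genes=600,
    samples_per_type=4,
    marker_overlap={("CT01", "CT02"): 0.5},  # a closely related pair
    seed=11,
)
print("cell types:", ", ".join(atlas.cell_types))
print("shared gene universe:", len(atlas.genes), "genes")
for src in atlas.sources:
    print(f"source {src.name}: platform={src.platform}, "
          f"{src.expression.shape[1]} samples of {len(src.cell_types)} cell types")

mixtures, fractions = simulate_mixture_set(
    atlas, ["CT01", "CT02", "CT03"], n_mixtures=5, mode="random_sample", seed=3
)
print("\nsimulated", mixtures.shape[1], "mixtures over", mixtures.shape[0], "genes")
print("ground-truth fractions (each row sums to 1):")
print(fractions.round(3).to_string())
# Each mixture column is a bulk expression profile whose true cell-type
# composition is the corresponding fraction row.
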