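import numpy as np
import pandas as pd
import pytest

from _oracles import welch_t
from xcellkit.atlas import CellTypeHierarchy, SourceData
from xcellkit.signatures import (
    DEFAULT_Q_PAIRS,
    DEFAULT_THRESHOLDS,
    compute_overexpression_rates,
    derive_signatures,
    filter_cancer_genes,
    learn_signatures,
    log_transform,
    select_best_signatures,
)


class TestLogTransform:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, np.log2(3)), (5.0, 3.0), (13.0, 4.0), (1.0, 2.0)]
    )
    def test_closed_form(self, x, expected):
        assert log_transform(np.array([x]))[0] == pytest.approx(expected, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([-1.0]))

    def test_dataframe_in_dataframe_out(self, tiny_expr):
        out = log_transform(tiny_expr)
        assert isinstance(out, pd.DataFrame)
        assert out.shape == tiny_expr.shape


class TestOverexpressionRates:
    def test_direct_count_oracle_for_bimodal_gene(self):
        """95 lines at 1, 5 lines at 10: mode ~ 1, threshold 2, rate 5/100."""
        values = np.array([1.0] * 95 + [10.0] * 5)
        panel = pd.DataFrame([values], index=["G1"], columns=[f"l{i}" for i in range(100)])
        rates = compute_overexpression_rates(panel)
        assert rates["G1"] == pytest.approx(0.05)

    def test_constant_gene_has_rate_zero(self):
        panel = pd.DataFrame(
            [[5.0] * 20, [0.0] * 20], index=["G1", "G2"], columns=[f"l{i}" for i in range(20)]
        )
        rates = compute_overexpression_rates(panel)
        assert rates["G1"] == 0.0  # no line exceeds 2x mode
        assert rates["G2"] == 0.0  # all-zero: threshold 0, strict comparison

    def test_rate_is_fraction_of_overexpressing_lines(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(4.9, 5.1, size=50)
        base[:10] = 60.0  # 20% of lines far above the peak
        panel = pd.DataFrame([base], index=["G1"], columns=[f"l{i}" for i in range(50)])
        assert compute_overexpression_rates(panel)["G1"] == pytest.approx(0.2)

    def test_panel_must_have_ten_lines(self):
        panel = pd.DataFrame([[1.0] * 5], index=["G1"], columns=list("abcde"))
        with pytest.raises(ValueError, match="10"):
            compute_overexpression_rates(panel)


class TestFilterCancerGenes:
    def test_cutoff_is_strict(self):
        rates = pd.Series({"KEEP": 0.049, "DROP": 0.05})
        allowed = filter_cancer_genes(["KEEP", "DROP"], rates, "B cells")
        assert allowed == ["KEEP"]

    def test_cell_of_origin_types_exempt(self):
        rates = pd.Series({"G1": 0.9, "G2": 0.9})
        assert filter_cancer_genes(["G1", "G2"], rates, "hepatocytes") == ["G1", "G2"]
        assert filter_cancer_genes(["G1", "G2"], rates, "Epithelial Cells") == ["G1", "G2"]

    def test_everything_filtered_returns_empty(self):
        rates = pd.Series({"G1": 0.5})
        assert filter_cancer_genes(["G1"], rates, "T cells") == []


def _toy_source(n_samples_per_type=3, seed=0):
    """Two cell types, one clean marker each, one flat gene."""
    rng = np.random.default_rng(seed)
    genes = ["MARK_A", "MARK_B", "FLAT1", "FLAT2"]
    cols, annot = {}, {}
    for t, marker in (("A", "MARK_A"), ("B", "MARK_B")):
        for j in range(n_samples_per_type):
            profile = pd.Series(rng.uniform(4.8, 5.2, size=4), index=genes)
            profile[marker] *= 100
            name = f"{t}{j}"
            cols[name] = profile
            annot[name] = t
    return SourceData(
        name="toy", platform="sequencing",
        expression=pd.DataFrame(cols), annotations=pd.Series(annot),
    )


class TestDeriveSignatures:
    def test_grid_is_fully_crossed(self, small_atlas):
        """4 q-pairs x 3 ranks x 7 thresholds = 84 configurations per cell
        type; every emitted candidate carries one of those configurations."""
        src = small_atlas.sources[0]
        candidates = derive_signatures(src, min_genes=1, max_genes=10_000)
        assert len(DEFAULT_Q_PAIRS) * 3 * len(DEFAULT_THRESHOLDS) == 84
        per_type = {}
        for c in candidates:
            per_type.setdefault(c.gene_set.cell_type, set()).add(
                (c.q_low, c.rank, c.threshold)
            )
        for configs in per_type.values():
            assert len(configs) <= 84
        # with no size bounds every configuration yields a candidate
        assert all(len(cfgs) == 84 for cfgs in per_type.values())

    def test_flat_gene_never_enters_positive_threshold_signature(self):
        src = _toy_source()
        candidates = derive_signatures(src, min_genes=1, max_genes=100)
        for c in candidates:
            if c.threshold > 0:
                assert "FLAT1" not in c.gene_set.genes
                assert "FLAT2" not in c.gene_set.genes

    def test_planted_marker_included_up_to_its_quantile_gap(self):
        src = _toy_source()
        candidates = derive_signatures(src, min_genes=1, max_genes=100)
        for c in candidates:
            if c.gene_set.cell_type == "A" and c.threshold <= 4:
                assert "MARK_A" in c.gene_set.genes

    def test_size_bounds_enforced(self, small_atlas):
        candidates = derive_signatures(small_atlas.sources[0])
        assert all(8 <= len(c.gene_set) <= 200 for c in candidates)

    def test_invariant_to_sample_and_gene_order(self):
        src = _toy_source()
        shuffled = SourceData(
            name="toy", platform="sequencing",
            expression=src.expression.iloc[::-1, ::-1],
            annotations=src.annotations,
        )
        def key(cands):
            return sorted((c.gene_set.name, tuple(sorted(c.gene_set.genes))) for c in cands)
        assert key(derive_signatures(src, min_genes=1, max_genes=100)) == key(
            derive_signatures(shuffled, min_genes=1, max_genes=100)
        )

    def test_parent_child_excluded_from_opposing_quantiles(self, hierarchy_atlas):
        """A child's high expression must not suppress its parent's markers."""
        src = hierarchy_atlas.sources[0]
        candidates = derive_signatures(
            src, hierarchy=hierarchy_atlas.hierarchy, min_genes=1, max_genes=400
        )
        parent_markers = set(hierarchy_atlas.markers["CT01"])
        best = [
            c for c in candidates
            if c.gene_set.cell_type == "CT01" and c.rank == 1 and c.threshold == 3.0
        ]
        assert best and any(parent_markers & c.gene_set.genes for c in best)


class TestSelectBestSignatures:
    def test_welch_statistic_matches_textbook_formula(self):
        x, y = np.array([3.0, 4.0, 5.0]), np.array([0.0, 1.0])
        from xcellkit.signatures import _welch_t

        assert _welch_t(x, y) == pytest.approx(welch_t(x, y), rel=1e-12)

    def test_at_most_three_signatures_per_type_and_source(self, small_atlas, small_signatures):
        counts = {}
        for gs in small_signatures:
            counts[(gs.cell_type, gs.source)] = counts.get((gs.cell_type, gs.source), 0) + 1
        assert counts and max(counts.values()) <= 3

    def test_single_positive_candidate_is_selected(self, small_atlas):
        src = small_atlas.sources[0]
        candidates = [
            c for c in derive_signatures(src)
            if c.gene_set.cell_type == "CT01"
        ][:1]
        selected = select_best_signatures(candidates, small_atlas)
        assert len(selected) == 1
        assert selected.signatures[0].name == "CT01%src1%1"

    def test_selected_signatures_score_own_type_highest_in_other_source(
        self, small_atlas, small_signatures
    ):
        """Cross-source generalization: in the source a signature was NOT
        learned from, its cell type's samples outscore all other samples."""
        from xcellkit.ssgsea import score_signatures

        held_out = small_atlas.sources[1]
        own = [gs for gs in small_signatures if gs.source == "src1"]
        scores = score_signatures(held_out.expression, own, min_shared_genes=1)
        ann = held_out.annotations
        for gs in own:
            row = scores.loc[gs.name]
            own_min = row[ann[row.index] == gs.cell_type].min()
            other_max = row[ann[row.index] != gs.cell_type].max()
            assert own_min > other_max


class TestLearnSignatures:
    def test_derivation_log_covers_all_sources(self, small_atlas):
        _, log = learn_signatures(small_atlas)
        assert set(log["source"]) == {s.name for s in small_atlas.sources}
        assert {"cell_type", "q_pair", "rank", "threshold", "n_genes", "t_stat"} <= set(log.columns)

    def test_cancer_filter_excludes_imitated_markers_from_signatures(self, small_atlas):
        from xcellkit.atlas import generate_cellline_panel

        panel, imitated = generate_cellline_panel(
            small_atlas, imitator_fraction=0.15, seed=3
        )
        sig_set, _ = learn_signatures(small_atlas, cellline_panel=panel)
        selected_genes = {g for gs in sig_set for g in gs.genes}
        assert imitated and not (set(imitated) & selected_genes)
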