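import numpy as np
import pandas as pd
import pytest

from _oracles import origin_slope
from xcellkit.atlas import CellTypeHierarchy
from xcellkit.calibration import (
    DEFAULT_TITRATION_LEVELS,
    ParamBundle,
    build_titration_series,
    clean_spillover,
    complete_cross_family,
    fit_linear_calibration,
    fit_power_coefficient,
    load_params,
    save_params,
)

FRACS = np.asarray(DEFAULT_TITRATION_LEVELS)


class TestTitrationSeries:
    def test_default_grid_doubles_up_to_25_6_percent(self):
        assert DEFAULT_TITRATION_LEVELS == (0.008, 0.016, 0.032, 0.064, 0.128, 0.256)

    def test_lowest_level_mixes_0_8_percent_target(self, small_atlas):
        profiles, fracs = build_titration_series(
            small_atlas, "src1", "CT01", "CtrlA"
        )
        assert fracs[0] == pytest.approx(0.008)
        src = small_atlas.sources[0]
        expected = 0.008 * src.median_profile("CT01") + 0.992 * src.median_profile("CtrlA")
        np.testing.assert_allclose(profiles.iloc[:, 0].to_numpy(), expected.to_numpy(), rtol=1e-12)

    def test_control_equal_to_target_rejected(self, small_atlas):
        with pytest.raises(ValueError, match="differ"):
            build_titration_series(small_atlas, "src1", "CT01", "CT01")

    def test_missing_control_rejected(self, small_atlas):
        with pytest.raises(ValueError, match="not present"):
            build_titration_series(small_atlas, "src1", "CT01", "NoSuchType")


class TestFitPowerCoefficient:
    def test_proportional_scores_give_unit_power(self):
        # zero at the shift reference, exactly proportional above it
        scores = 5000.0 * FRACS
        scores[0] = 0.0
        assert fit_power_coefficient(scores, FRACS) == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize("method", ["linearize", "nls", "loglog"])
    def test_sqrt_scores_give_power_two(self, method):
        scores = 5000.0 * np.sqrt(FRACS)
        scores[0] = 0.0
        P = fit_power_coefficient(scores, FRACS, method=method)
        assert P == pytest.approx(2.0, rel=0.05)

    def test_loglog_slope_exact_for_pure_power_law(self):
        # zero at the shift reference, exact power law above it
        scores = 5000.0 * np.sqrt(FRACS)
        scores[0] = 0.0
        P = fit_power_coefficient(scores, FRACS, method="loglog")
        assert P == pytest.approx(2.0, rel=1e-9)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_power_coefficient(np.full(6, 7.0), FRACS)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 titration"):
            fit_power_coefficient(np.array([0.0, 1.0, 2.0]), FRACS[:3])

    def test_linearize_method_linearizes_a_saturating_curve(self):
        # logistic-ish saturation: a single power should still reach r >= 0.99
        scores = 5000.0 * FRACS / (0.08 + FRACS)
        P = fit_power_coefficient(scores, FRACS, method="linearize")
        adjusted = ((scores - scores.min()) / 5000.0) ** P
        r = np.corrcoef(adjusted, FRACS)[0, 1]
        assert r >= 0.99


class TestFitLinearCalibration:
    def test_identity_slope(self):
        assert fit_linear_calibration(FRACS, FRACS) == pytest.approx(1.0)

    def test_doubled_scores_double_slope(self):
        assert fit_linear_calibration(2 * FRACS, FRACS) == pytest.approx(2.0)

    def test_noisy_proportional_scores_within_five_percent(self):
        rng = np.random.default_rng(8)
        scores = 3.0 * FRACS * rng.uniform(0.97, 1.03, size=len(FRACS))
        v1 = fit_linear_calibration(scores, FRACS)
        assert v1 == pytest.approx(3.0, rel=0.05)
        assert v1 == pytest.approx(origin_slope(FRACS, scores), rel=1e-12)

    def test_all_zero_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_calibration(np.zeros(6), FRACS)


class TestCleanSpillover:
    @staticmethod
    def _k(types, values):
        return pd.DataFrame(values, index=types, columns=types, dtype=float)

    def test_identity_unchanged(self):
        K = self._k(["a", "b"], np.eye(2))
        out = clean_spillover(K, CellTypeHierarchy())
        pd.testing.assert_frame_equal(out, K)

    def test_cap_applied_between_unrelated_parents(self):
        K = self._k(["a", "b"], [[1.0, 0.8], [0.2, 1.0]])
        out = clean_spillover(K, CellTypeHierarchy(), cap=0.5)
        assert out.loc["a", "b"] == 0.5
        assert out.loc["b", "a"] == 0.2

    def test_parent_child_compensation_zeroed_both_directions(self):
        h = CellTypeHierarchy({"CD8 Tem": "CD8 T"})
        K = self._k(["CD8 T", "CD8 Tem"], [[1.0, 0.4], [0.4, 1.0]])
        out = clean_spillover(K, h)
        assert out.loc["CD8 T", "CD8 Tem"] == 0.0
        assert out.loc["CD8 Tem", "CD8 T"] == 0.0

    def test_children_of_different_parents_zeroed(self):
        h = CellTypeHierarchy({"c1": "p1", "c2": "p2"})
        K = self._k(["p1", "p2", "c1", "c2"], np.full((4, 4), 0.3) + 0.7 * np.eye(4))
        out = clean_spillover(K, h)
        assert out.loc["c1", "c2"] == 0.0
        assert out.loc["c2", "c1"] == 0.0
        # siblings-in-law: child against an unrelated parent is allowed
        assert out.loc["c1", "p2"] == pytest.approx(0.3)
        # but a parent is compensated only against other parents
        assert out.loc["p2", "c1"] == 0.0
        assert out.loc["p1", "p2"] == pytest.approx(0.3)

    def test_idempotent(self):
        h = CellTypeHierarchy({"c1": "p1"})
        rng = np.random.default_rng(0)
        K = self._k(["p1", "p2", "c1"], rng.uniform(0, 1, (3, 3)))
        np.fill_diagonal(K.values, 1.0)
        once = clean_spillover(K, h)
        twice = clean_spillover(once, h)
        pd.testing.assert_frame_equal(once, twice)

    def test_invalid_cap_rejected(self):
        K = self._k(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            clean_spillover(K, CellTypeHierarchy(), cap=0.0)


class TestLearnedParams:
    def test_positive_coefficients_and_unit_diagonal(self, small_params):
        for bundle in small_params.values():
            assert (bundle.P > 0).all()
            assert (bundle.V1 > 0).all()
            assert (bundle.V2 > 0).all()
            np.testing.assert_allclose(np.diag(bundle.K.to_numpy()), 1.0)
            off = bundle.K.to_numpy()[~np.eye(len(bundle.K), dtype=bool)]
            assert (off >= 0).all() and (off <= 0.5 + 1e-12).all()

    def test_orthogonal_markers_give_near_identity_spillover(self, small_params):
        K = small_params["sequencing"].K
        off = K.to_numpy()[~np.eye(len(K), dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_overlapping_pair_produces_real_spillover(self, overlap_atlas):
        from xcellkit.calibration import learn_params
        from xcellkit.signatures import learn_signatures

        sig_set, _ = learn_signatures(overlap_atlas)
        params = learn_params(overlap_atlas, sig_set)
        K = params["sequencing"].K
        related_min = min(K.loc["CT01", "CT02"], K.loc["CT02", "CT01"])
        unrelated = [
            K.loc[a, b]
            for a in K.index
            for b in K.columns
            if a != b and {a, b} != {"CT01", "CT02"}
        ]
        assert related_min > 0.01
        assert related_min > max(unrelated)
        assert max(unrelated) < 0.05

    def test_row_normalization_reproduces_k_exactly(self, small_atlas, small_signatures):
        """Dividing the pre-normalization rows (learned with V2=1) by V2
        reproduces K."""
        from xcellkit.calibration import fit_transformation_params, learn_spillover_matrix

        P, V1 = fit_transformation_params(small_atlas, small_signatures, "sequencing")
        K, V2 = learn_spillover_matrix(small_atlas, small_signatures, P, V1, "sequencing")
        pre = K.mul(V2, axis=0)
        np.testing.assert_allclose(
            pre.div(V2, axis=0).to_numpy(), K.to_numpy(), rtol=1e-12
        )
        np.testing.assert_allclose(np.diag(K.to_numpy()), 1.0, rtol=1e-12)

    def test_serialization_round_trip(self, tmp_path, small_params):
        save_params(small_params, tmp_path)
        back = load_params(tmp_path)
        assert set(back) == set(small_params)
        for family, bundle in small_params.items():
            pd.testing.assert_series_equal(back[family].P, bundle.P, rtol=1e-12, check_names=False)
            np.testing.assert_allclose(back[family].K.to_numpy(), bundle.K.to_numpy(), rtol=1e-12)

    def test_cross_family_completion_copies_columns_verbatim(self):
        seq = ParamBundle(
            platform_family="sequencing",
            P=pd.Series({"a": 1.0}),
            V1=pd.Series({"a": 1.0}),
            V2=pd.Series({"a": 1.0}),
            K=pd.DataFrame([[1.0]], index=["a"], columns=["a"]),
        )
        arr = ParamBundle(
            platform_family="array",
            P=pd.Series({"a": 2.0, "b": 3.0}),
            V1=pd.Series({"a": 1.0, "b": 1.5}),
            V2=pd.Series({"a": 1.0, "b": 2.5}),
            K=pd.DataFrame([[1.0, 0.2], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"]),
        )
        completed = complete_cross_family({"sequencing": seq, "array": arr})
        seq2 = completed["sequencing"]
        assert seq2.P["b"] == 3.0
        assert seq2.K.loc["b", "a"] == 0.3
        assert seq2.K.loc["a", "b"] == 0.2
        assert seq2.K.loc["b", "b"] == 1.0
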