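"""Expression aggregation, reflection, intersection, z-scoring, similarity."""

import numpy as np
import pandas as pd
import pytest

from crossneuro.synthetic import (
    ExpressionSpec,
    default_gene_homology_map,
    simulate_expression_pair,
)
from crossneuro.transcriptomics import (
    aggregate_expression,
    intersect_homologous_genes,
    reflect_hemisphere,
    transcriptional_similarity,
    zscore_across_regions,
    zscore_pair,
)

REGIONS = [f"r{i}" for i in range(8)]


class TestAggregate:
    def test_weighted_mean_hand_example(self):
        mat = pd.DataFrame({"u1": [3.0], "u2": [6.0]}, index=["g"])
        labels = pd.Series({"u1": "roi", "u2": "roi"})
        weights = pd.Series({"u1": 2.0, "u2": 1.0})
        out, _ = aggregate_expression(mat, labels, weights)
        assert out.loc["g", "roi"] == pytest.approx(4.0)

    def test_singleton_unit_passthrough_and_uniform_weights(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.standard_normal((5, 3)), columns=["u1", "u2", "u3"])
        labels = pd.Series({"u1": "a", "u2": "b", "u3": "b"})
        out, report = aggregate_expression(mat, labels)
        np.testing.assert_allclose(out["a"], mat["u1"])
        uniform, _ = aggregate_expression(
            mat, labels, pd.Series({"u1": 3.0, "u2": 3.0, "u3": 3.0})
        )
        np.testing.assert_allclose(uniform.to_numpy(), out.to_numpy())

    def test_unmapped_units_counted(self):
        mat = pd.DataFrame(np.ones((2, 2)), columns=["u1", "u2"])
        labels = pd.Series({"u1": "a"})
        _, report = aggregate_expression(mat, labels)
        assert report["n_units_ignored"] == 1

    def test_errors(self):
        mat = pd.DataFrame(np.ones((2, 2)), columns=["u1", "u2"])
        with pytest.raises(ValueError, match="no units"):
            aggregate_expression(mat, pd.Series(dtype=object))
        with pytest.raises(ValueError, match="positive"):
            aggregate_expression(
                mat, pd.Series({"u1": "a", "u2": "a"}),
                pd.Series({"u1": -1.0, "u2": 2.0}),
            )


class TestReflect:
    def _registry(self):
        return pd.DataFrame(
            {
                "label": ["Hypothalamus", "Hypothalamus", "Pons"],
                "hemisphere": ["L", "R", "M"],
            }
        )

    def test_missing_side_copied_from_counterpart(self):
        mat = pd.DataFrame({"Hypothalamus|L": [1.0, 2.0], "Pons|M": [3.0, 4.0]})
        out, report = reflect_hemisphere(mat, self._registry())
        np.testing.assert_allclose(out["Hypothalamus|R"], out["Hypothalamus|L"])
        assert report["reflected"] == ["Hypothalamus|R"]

    def test_both_sides_present_is_noop(self):
        mat = pd.DataFrame(
            {"Hypothalamus|L": [1.0], "Hypothalamus|R": [9.0], "Pons|M": [3.0]}
        )
        out, report = reflect_hemisphere(mat, self._registry())
        pd.testing.assert_frame_equal(out, mat)
        assert report["reflected"] == []

    def test_midline_missing_stays_missing(self):
        mat = pd.DataFrame({"Hypothalamus|L": [1.0], "Hypothalamus|R": [2.0]})
        out, report = reflect_hemisphere(mat, self._registry())
        assert "Pons|M" not in out.columns and report["missing"] == ["Pons|M"]


class TestIntersect:
    def test_synthetic_map_full_intersection(self):
        gmap = default_gene_homology_map(200)
        rng = np.random.default_rng(1)
        mat_h = pd.DataFrame(rng.standard_normal((200, 4)),
                             index=gmap["human_gene"], columns=REGIONS[:4])
        mat_m = pd.DataFrame(rng.standard_normal((200, 4)),
                             index=gmap["mouse_gene"], columns=REGIONS[:4])
        out_h, out_m = intersect_homologous_genes(mat_h, mat_m, gmap)
        assert list(out_h.index) == list(out_m.index) == list(gmap["human_gene"])

    def test_disjoint_sets_error(self):
        gmap = default_gene_homology_map(10)
        mat_h = pd.DataFrame(np.ones((3, 2)), index=["X1", "X2", "X3"],
                             columns=["a", "b"])
        mat_m = pd.DataFrame(np.ones((3, 2)), index=["y1", "y2", "y3"],
                             columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            intersect_homologous_genes(mat_h, mat_m, gmap)

    def test_duplicate_map_entry_rejected(self):
        gmap = pd.DataFrame(
            {"human_gene": ["G1", "G1"], "mouse_gene": ["g1", "g2"]}
        )
        mat = pd.DataFrame(np.ones((2, 2)), index=["G1", "G2"], columns=["a", "b"])
        with pytest.raises(ValueError, match="duplicate"):
            intersect_homologous_genes(mat, mat, gmap)


class TestZscore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.standard_normal((10, 6)), columns=REGIONS[:6])
        z, dropped = zscore_across_regions(mat)
        assert dropped == []
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.standard_normal((5, 6)), columns=REGIONS[:6])
        z1, _ = zscore_across_regions(mat)
        z2, _ = zscore_across_regions(mat * 7.0 - 3.0)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_constant_gene_dropped_pairwise(self):
        rng = np.random.default_rng(4)
        mat_h = pd.DataFrame(rng.standard_normal((4, 5)),
                             index=list("abcd"), columns=REGIONS[:5])
        mat_m = mat_h.copy()
        mat_h.loc["c"] = 2.0  # constant in the human matrix only
        zh, zm, dropped = zscore_pair(mat_h, mat_m)
        assert dropped == ["c"]
        assert list(zh.index) == list(zm.index) == ["a", "b", "d"]

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            zscore_across_regions(pd.DataFrame({"only": [1.0, 2.0]}))


class TestSimilarity:
    def test_identity_and_antipodal_limits(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.standard_normal((30, 6)), columns=REGIONS[:6])
        z, _ = zscore_across_regions(mat)
        same = transcriptional_similarity(z, z)
        np.testing.assert_allclose(same["similarity"], 1.0, atol=1e-12)
        flipped = transcriptional_similarity(z, -z)
        np.testing.assert_allclose(flipped["similarity"], -1.0, atol=1e-12)

    def test_symmetric_in_species_order(self):
        spec = ExpressionSpec(n_genes=100, region_labels=REGIONS,
                              target_similarity=0.4, seed=6)
        mat_h, mat_m, _ = simulate_expression_pair(spec)
        zh, zm, _ = zscore_pair(mat_h, mat_m)
        ab = transcriptional_similarity(zh, zm)["similarity"]
        ba = transcriptional_similarity(zm, zh)["similarity"]
        np.testing.assert_allclose(ab, ba, atol=1e-12)

    def test_gene_subset_restriction(self):
        spec = ExpressionSpec(n_genes=50, region_labels=REGIONS,
                              target_similarity=0.9, seed=7)
        mat_h, mat_m, _ = simulate_expression_pair(spec)
        zh, zm, _ = zscore_pair(mat_h, mat_m)
        subset = list(zh.index[:10])
        out = transcriptional_similarity(zh, zm, gene_subset=subset,
                                         subset_tag="x_linked")
        assert (out["n_genes"] == 10).all() and (out["gene_subset"] == "x_linked").all()
        with pytest.raises(ValueError, match="outside"):
            transcriptional_similarity(zh, zm, gene_subset=["nope"] * 3)

    def test_similarity_monotone_in_target_rho(self):
        from scipy.stats import spearmanr

        rho = np.linspace(0.0, 0.9, 56)
        spec = ExpressionSpec(n_genes=2835,
                              region_labels=[f"roi{i}" for i in range(56)],
                              target_similarity=rho, seed=8)
        mat_h, mat_m, _ = simulate_expression_pair(spec)
        zh, zm, _ = zscore_pair(mat_h, mat_m)
        sim = transcriptional_similarity(zh, zm)["similarity"].to_numpy()
        assert spearmanr(rho, sim).statistic >= 0.95
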