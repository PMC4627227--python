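"""Category set algebra, condition distances, and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest

from solodiff import (
    NormalizedMatrix,
    RunConfig,
    SimulationDesign,
    classify_de_genes,
    cluster_conditions,
    condition_distance_matrix,
    generate_experiment,
    heatmap_groups,
    run_pipeline,
)
from solodiff.classify import ClassifyError
from solodiff.simulate import DE_CATEGORIES


def _calls(up=(), down=(), universe=()) -> pd.DataFrame:
    universe = set(universe) | set(up) | set(down)
    call = {g: "unchanged" for g in universe}
    call.update({g: "up" for g in up})
    call.update({g: "down" for g in down})
    genes = sorted(universe)
    return pd.DataFrame(
        {"score": 0.0, "log2fc_point": 0.0, "call": [call[g] for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )


def _norm(values: np.ndarray, genes, libs) -> NormalizedMatrix:
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=libs)
    return NormalizedMatrix(df, pd.Series(1000.0, index=df.index))


class TestClassify:
    def test_venn_set_algebra(self):
        cats = classify_de_genes(
            _calls(up=["a", "b"], universe="abc"), _calls(up=["b", "c"], universe="abc")
        )
        assert cats.up_both == {"b"}
        assert cats.up_SR_only == {"a"}
        assert cats.up_SEN_only == {"c"}
        assert not cats.discordant

    def test_empty_calls_empty_categories(self):
        cats = classify_de_genes(_calls(universe="ab"), _calls(universe="ab"))
        assert all(len(s) == 0 for s in cats.as_dict().values())

    def test_discordant_gene_flagged_and_kept_in_both_only_sets(self):
        cats = classify_de_genes(
            _calls(up=["x"], universe="xy"), _calls(down=["x"], universe="xy")
        )
        assert cats.discordant == {"x"}
        assert "x" in cats.up_SR_only and "x" in cats.down_SEN_only

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ClassifyError):
            classify_de_genes(_calls(universe="ab"), _calls(universe="abc"))

    def test_category_counts_invariant_to_gene_order(self):
        sr = _calls(up=["a", "d"], down=["b"], universe="abcde")
        sen = _calls(up=["d"], down=["b", "c"], universe="abcde")
        c1 = classify_de_genes(sr, sen)
        c2 = classify_de_genes(sr.iloc[::-1], sen.sample(frac=1, random_state=0))
        assert c1.counts() == c2.counts()

    def test_proportions_sum_to_one_over_de_genes(self):
        cats = classify_de_genes(
            _calls(up=["a", "b"], down=["c"], universe="abcdef"),
            _calls(up=["b"], universe="abcdef"),
        )
        assert sum(cats.proportions().values()) == pytest.approx(1.0)


class TestDistances:
    def test_identical_profiles_distance_zero(self):
        v = np.tile(np.array([[1.0], [5.0], [9.0]]), (1, 2))
        d = condition_distance_matrix(_norm(v, ["g1", "g2", "g3"], ["a", "b"]))
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        v = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        d = condition_distance_matrix(_norm(v, ["g1", "g2", "g3"], ["a", "b"]))
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_constant_profile_rejected(self):
        v = np.array([[1.0, 3.0], [1.0, 2.0], [1.0, 1.0]])
        with pytest.raises(ClassifyError, match="constant"):
            condition_distance_matrix(_norm(v, ["g1", "g2", "g3"], ["a", "b"]))

    def test_monotone_transform_invariance(self):
        """Spearman distance ignores per-library monotone rescaling."""
        rng = np.random.default_rng(8)
        v = rng.lognormal(0, 1, size=(40, 4))
        libs = ["a", "b", "c", "d"]
        d1 = condition_distance_matrix(_norm(v, range(40), libs))
        transformed = v.copy()
        transformed[:, 0] = v[:, 0] ** 3
        transformed[:, 2] = 10 * v[:, 2] ** 1.5
        d2 = condition_distance_matrix(_norm(transformed, range(40), libs))
        assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


class TestCluster:
    def _distances(self, m, labels):
        return pd.DataFrame(np.asarray(m, dtype=float), index=labels, columns=labels)

    def test_identical_pair_merges_first_at_height_zero(self):
        d = self._distances(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 3], [5, 5, 3, 0]],
            ["w", "x", "y", "z"],
        )
        dg = cluster_conditions(d)
        assert dg.linkage[0, 2] == pytest.approx(0.0)
        first = {dg.labels[int(dg.linkage[0, 0])], dg.labels[int(dg.linkage[0, 1])]}
        assert first == {"w", "x"}

    def test_two_identical_of_three_merge_first_any_linkage(self):
        d = self._distances([[0, 0, 7], [0, 0, 7], [7, 7, 0]], ["a", "b", "c"])
        for method in ("average", "complete", "single"):
            dg = cluster_conditions(d, method=method)
            first = {dg.labels[int(dg.linkage[0, 0])], dg.labels[int(dg.linkage[0, 1])]}
            assert first == {"a", "b"}

    def test_library_order_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(1, 5, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = ["p", "q", "r", "s"]
        d = self._distances(m, labels)
        dg1 = cluster_conditions(d)
        perm = ["r", "p", "s", "q"]
        dg2 = cluster_conditions(d.loc[perm, perm])
        assert dg1.newick == dg2.newick
        assert dg1.leaf_order == dg2.leaf_order

    def test_asymmetric_matrix_rejected(self):
        d = self._distances([[0, 1], [2, 0]], ["a", "b"])
        with pytest.raises(ClassifyError):
            cluster_conditions(d)

    def test_outlier_leaf_detection(self):
        d = self._distances(
            [[0, 1, 1, 9], [1, 0, 1, 9], [1, 1, 0, 9], [9, 9, 9, 0]],
            ["a", "b", "c", "far"],
        )
        assert cluster_conditions(d).outlier_leaf() == "far"


class TestHeatmapGroups:
    def test_group_sizes_match_category_cardinalities(self):
        cats = classify_de_genes(
            _calls(up=["a", "b"], down=["c"], universe="abcdef"),
            _calls(up=["b"], down=["c", "d"], universe="abcdef"),
        )
        v = np.arange(24, dtype=float).reshape(6, 4)
        norm = _norm(v, list("abcdef"), ["w", "x", "y", "z"])
        table = heatmap_groups(cats, norm)
        sizes = table["group"].value_counts().to_dict()
        assert sizes == {k: v for k, v in cats.counts().items() if v}

    def test_empty_categories_empty_table(self):
        cats = classify_de_genes(_calls(universe="ab"), _calls(universe="ab"))
        norm = _norm(np.ones((2, 2)) * [[1.0], [2.0]], ["a", "b"], ["x", "y"])
        assert len(heatmap_groups(cats, norm)) == 0

    def test_within_group_sorted_by_mean_expression(self):
        cats = classify_de_genes(
            _calls(up=["lo", "hi", "mid"], universe=["lo", "hi", "mid"]),
            _calls(up=["lo", "hi", "mid"], universe=["lo", "hi", "mid"]),
        )
        v = np.array([[1.0, 1.0], [9.0, 9.0], [5.0, 5.0]])
        norm = _norm(v, ["lo", "hi", "mid"], ["x", "y"])
        table = heatmap_groups(cats, norm)
        assert list(table.index) == ["hi", "mid", "lo"]


class TestParameterRecovery:
    def test_programmed_categories_recovered_at_depth(self):
        """Deeply sequenced experiment: per-category Jaccard vs truth >= 0.8."""
        design = SimulationDesign(library_depths=(5e7,) * 4, seed=11)
        counts, annotation, spikes, truth = generate_experiment(design)
        res = run_pipeline(counts, annotation, RunConfig(seed=11), spikein=spikes)
        cats = res.categories.as_dict()
        for cat in DE_CATEGORIES:
            t = set(truth.index[truth.category == cat])
            p = set(cats[cat])
            jaccard = len(t & p) / len(t | p)
            assert jaccard >= 0.8, f"{cat}: Jaccard {jaccard:.3f}"

    def test_sen_il2_plus_is_outlier_condition(self):
        design = SimulationDesign(seed=1)
        counts, annotation, spikes, _ = generate_experiment(design)
        res = run_pipeline(counts, annotation, RunConfig(seed=1), spikein=spikes)
        assert res.dendrogram.outlier_leaf() == "SEN_IL2plus"
        assert res.dendrogram.leaf_order[-1] == "SEN_IL2plus" or (
            res.dendrogram.leaf_order[0] == "SEN_IL2plus"
        )
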