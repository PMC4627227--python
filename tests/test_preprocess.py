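"""Spike-in QC, CPM filtering, and the anchor normalization formulas."""

import numpy as np
import pandas as pd
import pytest

from solodiff import (
    CountMatrix,
    FilterScope,
    GeneAnnotation,
    compute_actb_scaling,
    counts_per_million,
    ercc_qc,
    filter_low_expression,
    normalize_expression,
    spikein_table,
)
from solodiff.preprocess import NormalizationError, QCError


def _cm(data: dict, genes, spikeins=()) -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(data, index=pd.Index(genes, name="gene_id")),
        spikein_ids=frozenset(spikeins),
    )


class TestErccQC:
    def test_perfect_proportionality_gives_unit_fit(self):
        spikes = spikein_table(n_spikein=20, seed=0)
        # large observed counts exactly proportional to concentration
        obs = (spikes["expected_concentration"] * 1e4).round().astype(np.int64)
        cm = _cm({"lib1": obs.to_numpy()}, spikes.index, spikeins=spikes.index)
        report = ercc_qc(cm, spikes)
        assert report.loc["lib1", "pearson_r"] > 0.999
        assert report.loc["lib1", "slope"] == pytest.approx(1.0, abs=0.02)
        assert not report.loc["lib1", "flagged"]

    def test_permuted_counts_are_flagged(self):
        """Null permutations decorrelate observed from expected."""
        spikes = spikein_table(seed=0)
        obs = (spikes["expected_concentration"] * 1e4).round().astype(np.int64).to_numpy()
        rng = np.random.default_rng(42)
        rs = []
        for _ in range(200):
            cm = _cm({"lib1": rng.permutation(obs)}, spikes.index, spikeins=spikes.index)
            rep = ercc_qc(cm, spikes)
            rs.append(rep.loc["lib1", "pearson_r"])
            assert rep.loc["lib1", "flagged"]
        assert np.mean(np.abs(rs)) < 0.2

    def test_fewer_than_three_species_rejected(self):
        spikes = spikein_table(n_spikein=2, seed=0)
        cm = _cm({"lib1": [10, 20]}, spikes.index, spikeins=spikes.index)
        with pytest.raises(QCError, match="3"):
            ercc_qc(cm, spikes)

    def test_constant_observed_counts_rejected(self):
        spikes = spikein_table(n_spikein=5, seed=0)
        cm = _cm({"lib1": [7] * 5}, spikes.index, spikeins=spikes.index)
        with pytest.raises(QCError, match="equal"):
            ercc_qc(cm, spikes)


class TestFilter:
    def test_zero_gene_removed(self):
        cm = _cm({"a": [0, 100], "b": [0, 100]}, ["dead", "alive"])
        kept, removed = filter_low_expression(cm, 1.0)
        assert removed == ["dead"]
        assert list(kept.gene_ids) == ["alive"]

    def test_cpm_exactly_one_retained(self):
        """Removal is strict '< 1': a gene at CPM exactly 1 survives."""
        genes = ["g_boundary"] + [f"f{i}" for i in range(10)]
        col = [1] + [99_999 + i for i in range(10)]
        total = sum(col)
        # scale the filler so the library total is exactly 1e6
        col[1] += 10**6 - total
        cm = _cm({"lib": col}, genes)
        assert counts_per_million(cm).loc["g_boundary", "lib"] == pytest.approx(1.0)
        _, removed = filter_low_expression(cm, 1.0)
        assert "g_boundary" not in removed

    def test_scope_enumeration(self):
        data = {
            "l1": [50, 10_000],
            "l2": [0, 10_000],
            "l3": [0, 10_000],
            "l4": [0, 10_000],
        }
        cm = _cm(data, ["sparse", "filler"])
        kept_any, _ = filter_low_expression(cm, 1.0, FilterScope.ANY_LIBRARY)
        assert "sparse" in set(kept_any.gene_ids)
        kept_all, removed_all = filter_low_expression(cm, 1.0, FilterScope.ALL_LIBRARIES)
        assert "sparse" in removed_all

    def test_spikeins_exempt(self):
        cm = _cm({"lib": [0, 500]}, ["ERCC-00001", "gene"], spikeins=["ERCC-00001"])
        kept, removed = filter_low_expression(cm, 1.0)
        assert "ERCC-00001" in set(kept.gene_ids) and removed == []

    def test_idempotence(self, four_library_counts):
        once, removed1 = filter_low_expression(four_library_counts, 1.0)
        twice, removed2 = filter_low_expression(once, 1.0)
        assert once.equals(twice) and removed2 == []


class TestActbScaling:
    def test_equal_anchor_counts_give_unit_factors(self):
        cm = _cm({"l1": [100, 5], "l2": [100, 9]}, ["ACTB", "g"])
        s = compute_actb_scaling(cm, "ACTB")
        assert (s["factor"] == 1.0).all()

    @pytest.mark.parametrize(
        "actb_counts,expected",
        [
            ((100, 300), (2.0, 0.6667)),
            ((100, 200, 400), (2.3333, 1.1667, 0.5833)),
        ],
    )
    def test_hand_computed_factors(self, actb_counts, expected):
        libs = [f"l{i}" for i in range(len(actb_counts))]
        cm = _cm({l: [c, 10] for l, c in zip(libs, actb_counts)}, ["ACTB", "g"])
        s = compute_actb_scaling(cm, "ACTB")
        assert s["factor"].to_numpy() == pytest.approx(expected, abs=5e-5)

    def test_conservation_anchor_product_constant(self):
        """c_ACTB,j x s_j equals the cross-library mean anchor count."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            actb = rng.integers(50, 5000, size=4)
            cm = _cm({f"l{i}": [a, 10] for i, a in enumerate(actb)}, ["ACTB", "g"])
            s = compute_actb_scaling(cm, "ACTB")
            prod = actb * s["factor"].to_numpy()
            assert np.allclose(prod, actb.mean(), rtol=1e-9)

    def test_zero_anchor_count_names_library(self):
        cm = _cm({"good": [100, 5], "bad": [0, 5]}, ["ACTB", "g"])
        with pytest.raises(NormalizationError, match="bad"):
            compute_actb_scaling(cm, "ACTB")

    def test_missing_anchor_rejected(self):
        cm = _cm({"l1": [5]}, ["g"])
        with pytest.raises(NormalizationError):
            compute_actb_scaling(cm, "ACTB")


class TestNormalize:
    def test_unit_scaling_and_length_is_identity(self):
        cm = _cm({"l1": [100, 7], "l2": [100, 9]}, ["ACTB", "g"])
        ann = GeneAnnotation(pd.Series([1.0, 1.0], index=["ACTB", "g"]))
        s = compute_actb_scaling(cm, "ACTB")
        norm = normalize_expression(cm, ann, s)
        assert np.allclose(norm.values.to_numpy(), cm.counts.to_numpy())

    def test_direct_cell_evaluation(self):
        # c=500, s=2, l=1000 -> e = 1.0
        cm = _cm({"l1": [100, 500], "l2": [300, 600]}, ["ACTB", "g"])
        ann = GeneAnnotation(pd.Series([2000.0, 1000.0], index=["ACTB", "g"]))
        s = compute_actb_scaling(cm, "ACTB")  # factors (2.0, 2/3)
        norm = normalize_expression(cm, ann, s)
        assert norm.values.loc["g", "l1"] == pytest.approx(500 * 2.0 / 1000)

    def test_anchor_row_constant_after_normalization(self, four_library_counts, annotation):
        s = compute_actb_scaling(four_library_counts, "ACTB")
        norm = normalize_expression(four_library_counts, annotation, s)
        actb = norm.values.loc["ACTB"]
        expected = four_library_counts.counts.loc["ACTB"].mean() / annotation.length_of("ACTB")
        assert np.allclose(actb.to_numpy(), expected, rtol=1e-9)

    def test_scale_equivariance_up_to_global_constant(self, four_library_counts, annotation):
        """Rescaling one library rescales the whole normalized matrix uniformly.

        Multiplying library j's counts (anchor included) by alpha cancels
        inside e_ij except through the cross-library anchor mean, which is a
        single global factor: between-library expression ratios are exactly
        preserved.
        """
        s1 = compute_actb_scaling(four_library_counts, "ACTB")
        n1 = normalize_expression(four_library_counts, annotation, s1)
        scaled = four_library_counts.counts.copy()
        scaled["SR_IL2plus"] = scaled["SR_IL2plus"] * 7
        cm2 = CountMatrix(scaled)
        s2 = compute_actb_scaling(cm2, "ACTB")
        n2 = normalize_expression(cm2, annotation, s2)
        actb1 = four_library_counts.counts.loc["ACTB"]
        actb2 = cm2.counts.loc["ACTB"]
        gamma = actb2.mean() / actb1.mean()
        assert np.allclose(n2.values.to_numpy(), gamma * n1.values.to_numpy(), rtol=1e-9)

    def test_missing_length_rejected(self):
        cm = _cm({"l1": [100, 5]}, ["ACTB", "g"])
        ann = GeneAnnotation(pd.Series([2000.0], index=["ACTB"]))
        s = compute_actb_scaling(cm, "ACTB")
        with pytest.raises(NormalizationError, match="g"):
            normalize_expression(cm, ann, s)
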