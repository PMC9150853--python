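import numpy as np
import pandas as pd
import pytest

from polyshock.expression import (
    build_mix,
    categorize_ubiquity,
    compute_tpm,
    hclust_profiles,
    sample_pca,
)
from polyshock.io_core import CountMatrix, ExpressionMatrix, SampleSheet, TISSUES


def _cm(counts: dict, lengths: dict) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index.name = "gene_id"
    return CountMatrix(df, pd.Series(lengths))


class TestComputeTpm:
    def test_single_gene_is_one_million(self):
        cm = _cm({"s1": [7]}, {0: 100})
        assert compute_tpm(cm).tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalization_ratio(self):
        cm = _cm({"s1": [10, 10]}, {0: 1000, 1: 2000})
        tpm = compute_tpm(cm).tpm["s1"]
        assert tpm.iloc[0] / tpm.iloc[1] == pytest.approx(2.0)

    def test_matches_hand_computation(self, rng):
        counts = rng.integers(0, 500, size=(5, 3))
        lengths = rng.integers(300, 3000, size=5)
        cm = _cm({f"s{j}": counts[:, j] for j in range(3)}, dict(enumerate(lengths)))
        tpm = compute_tpm(cm).tpm.to_numpy()
        expected = np.empty_like(tpm, dtype=float)
        for j in range(3):
            rate = counts[:, j] / lengths
            expected[:, j] = rate / rate.sum() * 1e6
        assert np.allclose(tpm, expected, rtol=1e-9)

    def test_column_sums_one_million(self, small_dataset):
        _, counts, _, _ = small_dataset
        for cm in counts.values():
            sums = compute_tpm(cm).tpm.sum(axis=0)
            assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_all_zero_sample_warns(self):
        cm = _cm({"s1": [0, 0]}, {0: 100, 1: 100})
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(cm).tpm
        assert (tpm["s1"] == 0).all()


class TestBuildMix:
    def test_mix_tpm_halves_with_equal_libraries(self, small_dataset):
        _, counts, sheet, _ = small_dataset
        cm_mix, mix_sheet = build_mix(counts["AA"], counts["DD"], sheet)
        tpm_mix = compute_tpm(cm_mix).tpm
        tpm_aa = compute_tpm(counts["AA"]).tpm
        gene = counts["AA"].counts.index[0]
        # library sizes are drawn near-equal, so the union denominator
        # roughly doubles and the A-gene TPM roughly halves
        ratio = tpm_mix.loc[gene, "MIX_leaf_r1"] / tpm_aa.loc[gene, "AA_leaf_r1"]
        assert 0.4 < ratio < 0.6

    def test_mix_column_sums_one_million(self, mixed_dataset):
        *_, tpm = mixed_dataset
        sums = tpm["MIX"].tpm.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_commutes_with_concatenation(self, small_dataset):
        _, counts, sheet, _ = small_dataset
        cm_mix, _ = build_mix(counts["AA"], counts["DD"], sheet)
        via_mix = compute_tpm(cm_mix).tpm
        concat = CountMatrix(
            cm_mix.counts, cm_mix.gene_length
        )  # same stacked matrix, TPM directly
        direct = compute_tpm(concat).tpm
        pd.testing.assert_frame_equal(via_mix, direct)

    def test_shared_gene_rejected(self, small_dataset):
        _, counts, sheet, _ = small_dataset
        bad = CountMatrix(
            counts["AA"].counts.rename(index={counts["AA"].counts.index[0]:
                                              counts["DD"].counts.index[0]}),
            counts["AA"].gene_length.rename(index={counts["AA"].counts.index[0]:
                                                   counts["DD"].counts.index[0]}),
        )
        with pytest.raises(ValueError, match="disjoint"):
            build_mix(bad, counts["DD"], sheet)

    def test_missing_counterpart_rejected(self, small_dataset):
        _, counts, sheet, _ = small_dataset
        t = sheet.table
        reduced = SampleSheet(
            t[~((t["genotype"] == "DD") & (t["tissue"] == "leaf") & (t["replicate"] == 2))]
            .reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="counterpart"):
            build_mix(counts["AA"], counts["DD"], reduced)


class TestUbiquity:
    def _expr_sheet(self, tissue_means: dict):
        """One gene; replicate TPM equal to the tissue mean."""
        rows, cols, vals = [], [], []
        for tissue in TISSUES:
            for rep in (1, 2, 3):
                sid = f"AA_{tissue}_r{rep}"
                rows.append((sid, "AA", tissue, rep))
                cols.append(sid)
                vals.append(tissue_means.get(tissue, 0.0))
        sheet = SampleSheet(
            pd.DataFrame(rows, columns=["sample_id", "genotype", "tissue", "replicate"])
        )
        em = ExpressionMatrix(pd.DataFrame([vals], index=["g1"], columns=cols))
        return em, sheet

    @pytest.mark.parametrize(
        "tissue_means, expected, n",
        [
            ({}, "silent", 0),
            ({"leaf": 5.0}, "specific", 1),
            ({t: 5.0 for t in TISSUES[:4]}, "intermediate", 4),
            ({t: 5.0 for t in TISSUES[:8]}, "conserved", 8),
            ({t: 5.0 for t in TISSUES}, "conserved", 9),
        ],
    )
    def test_category_boundaries(self, tissue_means, expected, n):
        em, sheet = self._expr_sheet(tissue_means)
        out = categorize_ubiquity(em, sheet, "AA")
        assert out.loc[0, "category"] == expected
        assert out.loc[0, "n_tissues_expressed"] == n

    def test_replicate_order_invariance(self, mixed_dataset):
        _, counts, sheet, *_ , tpm = mixed_dataset
        em = tpm["AA"]
        base = categorize_ubiquity(em, sheet, "AA")
        shuffled = ExpressionMatrix(em.tpm[em.tpm.columns[::-1]])
        again = categorize_ubiquity(shuffled, sheet, "AA")
        pd.testing.assert_frame_equal(base, again)

    def test_requires_nine_tissues(self, mixed_dataset):
        _, counts, sheet, *_ , tpm = mixed_dataset
        t = sheet.table
        partial = SampleSheet(t[t["tissue"] != "leaf"].reset_index(drop=True))
        with pytest.raises(ValueError, match="9 tissues"):
            categorize_ubiquity(tpm["AA"], partial, "AA")

    def test_all_rule_stricter_than_mean(self, mixed_dataset):
        *_, tpm = mixed_dataset
        _, counts, sheet, *_ = mixed_dataset
        mean_out = categorize_ubiquity(tpm["AA"], sheet, "AA", rule="mean")
        all_out = categorize_ubiquity(tpm["AA"], sheet, "AA", rule="all")
        assert (all_out["n_tissues_expressed"] <= mean_out["n_tissues_expressed"]).all()


class TestSamplePca:
    def test_identical_samples_zero_variance(self):
        em = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 5.0, 9.0], "s2": [1.0, 5.0, 9.0]}, index=list("abc"))
        )
        with pytest.raises(ValueError, match="constant"):
            sample_pca(em)

    def test_planted_two_cluster_separation(self, rng):
        base1 = rng.uniform(1, 100, 50)
        base2 = rng.uniform(1, 100, 50)
        cols = {}
        for i in range(4):
            cols[f"g1_{i}"] = base1 + rng.normal(0, 0.5, 50)
        for i in range(4):
            cols[f"g2_{i}"] = base2 + rng.normal(0, 0.5, 50)
        em = ExpressionMatrix(pd.DataFrame(cols).clip(lower=0))
        coords, var = sample_pca(em)
        pc1 = coords["PC1"]
        g1 = pc1[[c for c in coords.index if c.startswith("g1")]]
        g2 = pc1[[c for c in coords.index if c.startswith("g2")]]
        assert max(g1.max(), g2.max()) * min(g1.min(), g2.min()) != 0
        assert (g1.max() < g2.min()) or (g2.max() < g1.min())

    def test_variance_ratio_properties(self, mixed_dataset):
        *_, tpm = mixed_dataset
        _, var = sample_pca(tpm["AT2"])
        assert (var >= 0).all()
        assert (np.diff(var) <= 1e-12).all()
        assert var.sum() <= 1.0 + 1e-9


def test_hclust_runs_on_profiles(mixed_dataset):
    *_, tpm = mixed_dataset
    lk = hclust_profiles(tpm["AA"].tpm.T.iloc[:, :50])
    assert lk.shape == (tpm["AA"].tpm.shape[1] - 1, 4)
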