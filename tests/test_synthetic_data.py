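import numpy as np
import pandas as pd
import pytest

from polyshock.orthology import ng86_ka_ks, promoter_pdistance
from polyshock.synthetic_data import (
    SynthConfig,
    generate_module_profiles,
    generate_module_structure,
    generate_quadruplet_counts,
    generate_sequence_pairs,
)


def _mean_log_ratios(counts, sheet, truth, tissue="primary_root"):
    """Empirical A and B per pair from length-scaled replicate-mean counts,
    taken within single libraries (MIX for A, AT2 for B) so sample
    normalization cancels from the ratio."""
    from polyshock.expression import build_mix

    counts_mix, mix_sheet = build_mix(counts["AA"], counts["DD"], sheet)
    la = counts["AA"].gene_length.loc[truth["gene_A"]].to_numpy()
    ld = counts["DD"].gene_length.loc[truth["gene_D"]].to_numpy()
    s_mix = mix_sheet.samples_for("MIX", tissue)
    s_at2 = sheet.samples_for("AT2", tissue)
    ad = counts_mix.counts.loc[truth["gene_A"], s_mix].mean(axis=1).to_numpy() / la
    dd = counts_mix.counts.loc[truth["gene_D"], s_mix].mean(axis=1).to_numpy() / ld
    at = counts["AT2"].counts.loc[truth["gene_A"], s_at2].mean(axis=1).to_numpy() / la
    dt = counts["AT2"].counts.loc[truth["gene_D"], s_at2].mean(axis=1).to_numpy() / ld
    return np.log2(ad / dd), np.log2(at / dt)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_reps": 0},
            {"module_cohesion": 1.5},
            {"n_modules": 1},
            {"category_mix": {"conserved": 0.5}},
            {"category_mix": {"bogus": 1.0}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)


class TestGenerateQuadrupletCounts:
    def test_determinism(self):
        cfg = SynthConfig(n_pairs=60, seed=5)
        c1, s1, t1 = generate_quadruplet_counts(cfg)
        c2, s2, t2 = generate_quadruplet_counts(cfg)
        for gt in c1:
            pd.testing.assert_frame_equal(c1[gt].counts, c2[gt].counts)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_conserved_null_ratios(self):
        cfg = SynthConfig(
            n_pairs=80,
            category_mix={"conserved": 1.0},
            dispersion=1e-12,
            silent_fraction=0.0,
            n_reps=3,
            seed=2,
        )
        counts, sheet, truth = generate_quadruplet_counts(cfg)
        a, b = _mean_log_ratios(counts, sheet, truth)
        assert np.abs(a).max() < 0.2 and np.abs(b).max() < 0.2

    def test_cis_only_forces_equal_ratios(self):
        cfg = SynthConfig(
            n_pairs=80,
            category_mix={"cis_only": 1.0},
            effect_size=2.0,
            dispersion=1e-12,
            silent_fraction=0.0,
            seed=3,
        )
        counts, sheet, truth = generate_quadruplet_counts(cfg)
        a, b = _mean_log_ratios(counts, sheet, truth)
        signs = np.sign(truth["c"].to_numpy())
        assert np.allclose(a * signs, 2.0, atol=0.25)
        assert np.allclose(b * signs, 2.0, atol=0.25)

    def test_ratio_bias_vanishes_with_replicates(self):
        # empirical A and B converge to c+t and c: |bias| < 0.05 at n_reps=50
        # the 1:1 mix carries a global normalization offset between the two
        # parental transcriptomes that averages out over a large gene set
        cfg = SynthConfig(
            n_pairs=1500,
            dispersion=1e-12,
            n_reps=50,
            silent_fraction=0.0,
            seed=4,
        )
        counts, sheet, truth = generate_quadruplet_counts(cfg)
        a, b = _mean_log_ratios(counts, sheet, truth)
        bias_a = a - truth["mix_ratio"].to_numpy()
        bias_b = b - truth["at2_ratio"].to_numpy()
        assert np.abs(np.mean(bias_a)) < 0.05
        assert np.abs(np.mean(bias_b)) < 0.05

    def test_silent_pairs_have_zero_counts(self):
        cfg = SynthConfig(n_pairs=100, silent_fraction=0.5, seed=6)
        counts, _, truth = generate_quadruplet_counts(cfg)
        silent_a = truth.loc[~truth["expressed"], "gene_A"]
        assert (counts["AA"].counts.loc[silent_a] == 0).all().all()
        assert (counts["AT2"].counts.loc[silent_a] == 0).all().all()

    def test_counts_nonnegative_and_integral(self, small_dataset):
        _, counts, _, _ = small_dataset
        for cm in counts.values():
            assert (cm.counts.to_numpy() >= 0).all()
            assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)

    def test_trajectory_truth_consistent_with_ratios(self):
        cfg = SynthConfig(
            n_pairs=200,
            heb_trajectory_mix={t: 0.25 for t in
                                ("parental_legacy", "convergence", "divergence", "reversion")},
            effect_size=2.0,
            seed=7,
        )
        _, _, truth = generate_quadruplet_counts(cfg)
        conv = truth[truth["heb_trajectory"] == "convergence"]
        assert (conv["mix_ratio"].abs() > 1).all()
        assert (conv["at2_ratio"].abs() <= 1).all()
        rev = truth[truth["heb_trajectory"] == "reversion"]
        assert (np.sign(rev["mix_ratio"]) == -np.sign(rev["at2_ratio"])).all()


class TestModuleStructure:
    def test_full_cohesion_gives_unit_correlation(self):
        profiles, labels = generate_module_profiles(2, 20, 12, cohesion=1.0, seed=1)
        block = profiles[labels == 0]
        r = np.corrcoef(block.to_numpy())
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_zero_cohesion_uncorrelated(self):
        profiles, labels = generate_module_profiles(2, 100, 50, cohesion=0.0, seed=1)
        block = profiles[labels == 0].to_numpy()
        r = np.corrcoef(block)
        off = r[np.triu_indices_from(r, 1)]
        assert abs(off.mean()) < 0.05

    def test_planted_convergence_contexts(self):
        cfg = SynthConfig(n_pairs=300, rewiring_mix={"convergence": 1.0}, seed=8)
        _, assignment = generate_module_structure(cfg)
        assert (assignment["module_Ad"] != assignment["module_Dd"]).all()
        assert (assignment["module_At"] == assignment["module_Dt"]).all()

    def test_cohesion_out_of_range(self):
        with pytest.raises(ValueError):
            generate_module_profiles(2, 10, 5, cohesion=1.2)


class TestSequencePairs:
    def test_zero_targets_identical_sequences(self):
        cds, prom, _ = generate_sequence_pairs(5, 0.0, 0.0, 0.0, seed=1)
        for i in range(5):
            assert cds[f"gA{i:05d}"] == cds[f"gD{i:05d}"]
            assert prom[f"gA{i:05d}"] == prom[f"gD{i:05d}"]

    def test_promoter_divergence_binomial(self):
        _, prom, truth = generate_sequence_pairs(
            20, 0.0, 0.0, 0.1, seed=2, promoter_len=1000
        )
        frac = np.mean(
            [
                promoter_pdistance(prom[f"gA{i:05d}"], prom[f"gD{i:05d}"])
                for i in range(20)
            ]
        )
        assert abs(frac - 0.1) < 0.02  # ~3 sigma of binomial error at n=20000

    def test_seed_reproducibility(self):
        a = generate_sequence_pairs(3, 0.1, 0.02, 0.05, seed=9)
        b = generate_sequence_pairs(3, 0.1, 0.02, 0.05, seed=9)
        assert a[0] == b[0] and a[1] == b[1]

    def test_saturated_target_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            generate_sequence_pairs(2, 0.6, 0.0, 0.0)

    def test_planted_ks_recovered(self):
        cds, _, _ = generate_sequence_pairs(30, 0.1, 0.0, 0.0, seed=3)
        ka = []
        ks = []
        for i in range(30):
            a, s = ng86_ka_ks(cds[f"gA{i:05d}"], cds[f"gD{i:05d}"])
            ka.append(a)
            ks.append(s)
        assert np.mean(ka) < 0.005
        assert abs(np.mean(ks) - 0.1) < 0.02
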