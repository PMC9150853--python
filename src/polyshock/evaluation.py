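"""Recovery and calibration evaluations against planted ground truth.

Each function generates a dataset with the synthetic generator, runs the
relevant pipeline stage, and scores the result against the planted truth.
Category and trajectory recovery are evaluated per pair via the modal
call across the nine tissues (the planted regulatory architecture is a
pair-level property shared by all tissues, and the per-pair modal category
is this package's cross-tissue summary statistic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexpr, expression, heb, hse, network, synthetic_data
from .io_core import TISSUES
from .synthetic_data import SynthConfig


def _tpm_and_mix(counts, sheet):
    tpm = {gt: expression.compute_tpm(cm) for gt, cm in counts.items()}
    counts_mix, mix_sheet = expression.build_mix(counts["AA"], counts["DD"], sheet)
    tpm["MIX"] = expression.compute_tpm(counts_mix)
    return tpm, counts_mix, mix_sheet


def _quad_tpm(tpm, sheet, mix_sheet, truth, tissue):
    s_mix = mix_sheet.samples_for("MIX", tissue)
    s_at2 = sheet.samples_for("AT2", tissue)
    return {
        "Ad": tpm["MIX"].tpm.loc[truth["gene_A"], s_mix].to_numpy(),
        "Dd": tpm["MIX"].tpm.loc[truth["gene_D"], s_mix].to_numpy(),
        "At": tpm["AT2"].tpm.loc[truth["gene_A"], s_at2].to_numpy(),
        "Dt": tpm["AT2"].tpm.loc[truth["gene_D"], s_at2].to_numpy(),
    }


def _modal(labels: pd.DataFrame) -> pd.Series:
    """Modal label per row over tissue columns, ties broken alphabetically."""

    def one(row):
        counts = row.value_counts()
        return sorted(counts.index[counts == counts.max()])[0]

    return labels.apply(one, axis=1)


def hse_recovery(
    seed: int,
    n_per_category: int = 300,
    effect_size: float = 1.5,
    n_reps: int = 3,
    dispersion: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category recall of the seven-way cis/trans classifier.

    Plants ``n_per_category`` pairs per category (all expressed), runs the
    per-tissue classifier on mix/AT2 TPM quadruplets, and scores the modal
    category per pair against the planted one. Returns a table with
    per-category recall at both the modal (pair) and per-tissue level.
    """
    mix = {c: 1.0 / len(synthetic_data.HSE_CATEGORIES) for c in synthetic_data.HSE_CATEGORIES}
    cfg = SynthConfig(
        n_pairs=n_per_category * len(synthetic_data.HSE_CATEGORIES),
        category_mix=mix,
        effect_size=effect_size,
        n_reps=n_reps,
        dispersion=dispersion,
        silent_fraction=0.0,
        seed=seed,
    )
    counts, sheet, truth = synthetic_data.generate_quadruplet_counts(cfg)
    tpm, _, mix_sheet = _tpm_and_mix(counts, sheet)
    per_tissue = {}
    for tissue in cfg.tissues:
        quad = _quad_tpm(tpm, sheet, mix_sheet, truth, tissue)
        stats_df = hse.hse_statistics(quad["Ad"], quad["Dd"], quad["At"], quad["Dt"])
        per_tissue[tissue] = hse.classify_hse(stats_df, alpha)
    calls = pd.DataFrame(per_tissue, index=truth["pair_id"])
    modal = _modal(calls)
    planted = pd.Series(truth["hse_category"].to_numpy(), index=truth["pair_id"])
    rows = []
    for cat in synthetic_data.HSE_CATEGORIES:
        sel = planted == cat
        rows.append(
            {
                "category": cat,
                "n": int(sel.sum()),
                "recall_modal": float((modal[sel] == cat).mean()),
                "recall_per_tissue": float((calls.loc[sel] == cat).to_numpy().mean()),
            }
        )
    return pd.DataFrame(rows)


def heb_truth_table() -> pd.DataFrame:
    """All nine (mix, at2) bias combinations and their assigned group."""
    rows = []
    for m in ("A", "D", "none"):
        for a in ("A", "D", "none"):
            rows.append({"mix": m, "at2": a, "group": heb.classify_heb_group(m, a)})
    return pd.DataFrame(rows)


def heb_trajectory_recovery(
    seed: int,
    n_per_class: int = 300,
    effect_size: float = 2.0,
    n_reps: int = 3,
    dispersion: float = 0.05,
) -> pd.DataFrame:
    """Per-class recall of the four-group bias-trajectory classifier,
    scored on the modal group per pair across tissues."""
    mix = {c: 0.25 for c in synthetic_data.HEB_TRAJECTORIES}
    cfg = SynthConfig(
        n_pairs=n_per_class * 4,
        heb_trajectory_mix=mix,
        effect_size=effect_size,
        n_reps=n_reps,
        dispersion=dispersion,
        silent_fraction=0.0,
        seed=seed,
    )
    counts, sheet, truth = synthetic_data.generate_quadruplet_counts(cfg)
    counts_mix, mix_sheet = expression.build_mix(counts["AA"], counts["DD"], sheet)
    len_a = counts["AA"].gene_length.loc[truth["gene_A"]].to_numpy()
    len_d = counts["DD"].gene_length.loc[truth["gene_D"]].to_numpy()
    per_tissue = {}
    for tissue in cfg.tissues:
        s_mix = mix_sheet.samples_for("MIX", tissue)
        s_at2 = sheet.samples_for("AT2", tissue)
        mix_call = heb.call_heb(
            counts_mix.counts.loc[truth["gene_A"], s_mix].to_numpy(),
            counts_mix.counts.loc[truth["gene_D"], s_mix].to_numpy(),
            len_a,
            len_d,
        )
        at2_call = heb.call_heb(
            counts["AT2"].counts.loc[truth["gene_A"], s_at2].to_numpy(),
            counts["AT2"].counts.loc[truth["gene_D"], s_at2].to_numpy(),
            len_a,
            len_d,
        )
        per_tissue[tissue] = heb.classify_heb_group(mix_call["bias"], at2_call["bias"])
    calls = pd.DataFrame(per_tissue, index=truth["pair_id"])
    modal = _modal(calls)
    planted = pd.Series(truth["heb_trajectory"].to_numpy(), index=truth["pair_id"])
    rows = []
    for cls in synthetic_data.HEB_TRAJECTORIES:
        sel = planted == cls
        rows.append(
            {
                "class": cls,
                "n": int(sel.sum()),
                "recall_modal": float((modal[sel] == cls).mean()),
                "recall_per_tissue": float((calls.loc[sel] == cls).to_numpy().mean()),
            }
        )
    return pd.DataFrame(rows)


def de_null_calibration(seed: int, n_genes: int = 2000) -> float:
    """Fraction of genes with p < 0.05 in an At-vs-Ad contrast with no
    planted effect (all pairs conserved)."""
    cfg = SynthConfig(
        n_pairs=n_genes,
        category_mix={"conserved": 1.0},
        silent_fraction=0.0,
        seed=seed,
    )
    counts, sheet, _ = synthetic_data.generate_quadruplet_counts(cfg)
    tissue = TISSUES[0]
    s_t = sheet.samples_for("AT2", tissue)
    s_d = sheet.samples_for("AA", tissue)
    genes = list(counts["AA"].counts.index)
    joint = pd.concat(
        [counts["AT2"].counts.loc[genes, s_t], counts["AA"].counts.loc[genes, s_d]],
        axis=1,
    )
    res = diffexpr.de_contrast(joint, s_t, s_d)
    p = res["p"].dropna()
    return float((p < 0.05).mean())


def de_planted_recovery(
    seed: int, n_genes: int = 2000, de_fraction: float = 0.25, de_log2fc: float = 2.0
) -> dict:
    """Sensitivity, empirical FDR and fold-change accuracy of the NB Wald
    engine on planted 4-fold changes (At vs Ad, one tissue)."""
    cfg = SynthConfig(
        n_pairs=n_genes,
        category_mix={"conserved": 1.0},
        silent_fraction=0.0,
        de_fraction=de_fraction,
        de_log2fc=de_log2fc,
        seed=seed,
    )
    counts, sheet, truth = synthetic_data.generate_quadruplet_counts(cfg)
    tissue = TISSUES[0]
    s_t = sheet.samples_for("AT2", tissue)
    s_d = sheet.samples_for("AA", tissue)
    genes = list(truth["gene_A"])
    joint = pd.concat(
        [counts["AT2"].counts.loc[genes, s_t], counts["AA"].counts.loc[genes, s_d]],
        axis=1,
    )
    res = diffexpr.de_contrast(joint, s_t, s_d).set_index("gene_id")
    planted = truth.set_index("gene_A")["de_A"]
    called = res["call"]
    is_de = planted != "none"
    hit = (called.loc[is_de[is_de].index] == planted[is_de]).mean()
    n_called = (called != "none").sum()
    false = int(((called != "none") & ~is_de.reindex(called.index)).sum())
    planted_de = res.loc[is_de.reindex(res.index).fillna(False)]
    lfc_signed = planted_de["log2fc"] * planted.map({"up": 1, "down": -1, "none": 0})
    return {
        "sensitivity": float(hit),
        "fdr_empirical": float(false / n_called) if n_called else 0.0,
        "median_abs_lfc_error": float((lfc_signed - de_log2fc).abs().median()),
        "n_planted": int(is_de.sum()),
    }


def net_heb_null_rate(seed: int, n_pairs: int = 2000) -> float:
    """Net-HEB call rate when no ratio shift is planted (conserved pairs)."""
    cfg = SynthConfig(
        n_pairs=n_pairs,
        category_mix={"conserved": 1.0},
        silent_fraction=0.0,
        seed=seed,
    )
    counts, sheet, truth = synthetic_data.generate_quadruplet_counts(cfg)
    tpm, _, mix_sheet = _tpm_and_mix(counts, sheet)
    quad = _quad_tpm(tpm, sheet, mix_sheet, truth, TISSUES[0])
    res = heb.net_heb(quad["Ad"], quad["Dd"], quad["At"], quad["Dt"])
    return float((res["call"] != "none").mean())


def heb_null_rate(seed: int, n_pairs: int = 2000) -> float:
    """Bias-call rate for pairs with no planted bias."""
    cfg = SynthConfig(
        n_pairs=n_pairs,
        category_mix={"conserved": 1.0},
        silent_fraction=0.0,
        seed=seed,
    )
    counts, sheet, truth = synthetic_data.generate_quadruplet_counts(cfg)
    s_at2 = sheet.samples_for("AT2", TISSUES[0])
    res = heb.call_heb(
        counts["AT2"].counts.loc[truth["gene_A"], s_at2].to_numpy(),
        counts["AT2"].counts.loc[truth["gene_D"], s_at2].to_numpy(),
        counts["AA"].gene_length.loc[truth["gene_A"]].to_numpy(),
        counts["DD"].gene_length.loc[truth["gene_D"]].to_numpy(),
    )
    return float((res["bias"] != "none").mean())


def module_recovery_ari(
    seed: int,
    n_modules: int = 3,
    nodes_per_module: int = 100,
    cohesion: float = 0.9,
    n_samples: int = 9,
    beta: int = 6,
) -> float:
    """Adjusted Rand index of detected vs planted modules on a
    planted-partition profile set."""
    from sklearn.metrics import adjusted_rand_score

    profiles, labels = synthetic_data.generate_module_profiles(
        n_modules, nodes_per_module, n_samples, cohesion, seed=seed
    )
    net = network.build_network(profiles, beta=beta, min_module_size=min(30, nodes_per_module))
    detected = net.modules.reindex(labels.index).fillna(0)
    return float(adjusted_rand_score(labels.to_numpy(), detected.to_numpy()))


def kaks_recovery(
    seed: int, n_pairs: int = 40, ks_target: float = 0.1, ka_target: float = 0.0
) -> dict:
    """Mean NG86 Ka and Ks over generated pairs with planted divergence."""
    from .orthology import ng86_ka_ks

    cds, _, _ = synthetic_data.generate_sequence_pairs(
        n_pairs, ks_target, ka_target, 0.0, seed=seed
    )
    kas, kss = [], []
    for i in range(n_pairs):
        ka, ks = ng86_ka_ks(cds[f"gA{i:05d}"], cds[f"gD{i:05d}"])
        kas.append(ka)
        kss.append(ks)
    return {"mean_ka": float(np.mean(kas)), "mean_ks": float(np.mean(kss))}
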