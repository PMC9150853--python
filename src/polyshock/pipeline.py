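"""End-to-end pipeline: simulate (or ingest) -> pair -> TPM/mix -> DE ->
HEB -> HSE -> networks -> SDRG -> report, driven by one flat config and a
single seed. Every stage writes a canonical TSV so re-runs with the same
config and seed are byte-identical."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, expression, heb, hse, network, orthology, synthetic_data
from .io_core import (
    AlignmentRecord,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    SampleSheet,
    SPIKE_TISSUES,
    TISSUES,
    load_config,
    write_alignments,
    write_annotation,
    write_counts,
    write_expression,
    write_fasta,
    write_sample_sheet,
    write_table,
)

log = logging.getLogger("polyshock")


@dataclass
class PipelineConfig:
    """Flat pipeline parameters. Thresholds default to the values the
    study design fixes: DEG fold change > 2 at FDR < 0.05, TPM > 1
    expression filter, ortholog calling at >60% coverage and >=90%
    identity with E < 1e-5, soft powers 18/18/9 for the homoeolog,
    quadruplet and spike networks, minModuleSize 30 and mergeCutHeight
    0.25, HSE alpha 0.05."""

    out_dir: str = "polyshock_run"
    seed: int = 0
    # simulation block (used when no external inputs are given)
    simulate: dict = field(default_factory=dict)
    # external inputs (alternative to simulate)
    counts_paths: dict = field(default_factory=dict)  # genotype -> counts tsv
    lengths_path: str | None = None
    sample_sheet_path: str | None = None
    alignments_path: str | None = None
    annotation_path: str | None = None
    cds_fasta: str | None = None
    promoter_fasta: str | None = None
    pairs_path: str | None = None
    # thresholds
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    alpha: float = 0.05
    tpm_threshold: float = 1.0
    expression_rule: str = "mean"
    min_cov: float = 0.60
    min_ident: float = 0.90
    max_evalue: float = 1e-5
    epsilon: float = 0.5
    beta_homoeolog: int = 18
    beta_quadruplet: int = 18
    beta_spike: int = 9
    min_module_size: int = 30
    merge_cut: float = 0.25
    neighbor_quantile: float = 0.95
    sdrg_fold: float = 2.0
    sdrg_nonspike_agg: str = "max"
    # sequence simulation
    ks_target: float = 0.15
    ka_target: float = 0.03
    promoter_div: float = 0.10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate and not self.counts_paths:
            raise ValueError("config needs either a simulate block or counts_paths")


def _synthetic_alignments(
    cds: dict[str, str], seq_truth: pd.DataFrame
) -> list[AlignmentRecord]:
    """Full-length alignment records for the generated pairs, with identity
    taken from the actual sequence mismatch count."""
    records = []
    for r in seq_truth.itertuples(index=False):
        a, d = cds[r.gene_A], cds[r.gene_D]
        mism = sum(1 for x, y in zip(a, d) if x != y)
        ident = 100.0 * (1.0 - mism / len(a))
        records.append(
            AlignmentRecord(
                query=r.gene_A,
                subject=r.gene_D,
                pct_identity=round(ident, 2),
                aln_length=len(a),
                mismatch=mism,
                gapopen=0,
                qstart=1,
                qend=len(a),
                sstart=1,
                send=len(a),
                evalue=1e-180,
                bitscore=round(2.0 * len(a) * ident / 100.0, 1),
            )
        )
    return records


def _quadruplet_tpm(
    tpm_mix: ExpressionMatrix,
    tpm_at2: ExpressionMatrix,
    sheet: SampleSheet,
    mix_sheet: SampleSheet,
    pairs: pd.DataFrame,
    tissue: str,
) -> dict[str, np.ndarray]:
    s_mix = mix_sheet.samples_for("MIX", tissue)
    s_at2 = sheet.samples_for("AT2", tissue)
    return {
        "Ad": tpm_mix.tpm.loc[pairs["gene_A"], s_mix].to_numpy(),
        "Dd": tpm_mix.tpm.loc[pairs["gene_D"], s_mix].to_numpy(),
        "At": tpm_at2.tpm.loc[pairs["gene_A"], s_at2].to_numpy(),
        "Dt": tpm_at2.tpm.loc[pairs["gene_D"], s_at2].to_numpy(),
    }


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and write per-stage TSVs plus a summary report.

    Returns the run directory. Outputs are a pure function of
    (config, seed).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: data ----------------------------------------------------
    if cfg.simulate:
        sim = synthetic_data.SynthConfig(**{**cfg.simulate, "seed": cfg.seed})
        counts, sheet, truth = synthetic_data.generate_quadruplet_counts(sim)
        cds, promoters, seq_truth = synthetic_data.generate_sequence_pairs(
            sim.n_pairs,
            cfg.ks_target,
            cfg.ka_target,
            cfg.promoter_div,
            seed=cfg.seed + 1,
        )
        alignments = _synthetic_alignments(cds, seq_truth)
        annot = synthetic_data.annotation_from_truth(truth)
        annot.cds.update(cds)
        annot.promoter.update(promoters)
        write_table(truth, out / "truth.tsv")
        write_fasta(cds, out / "cds.fasta")
        write_fasta(promoters, out / "promoters.fasta")
        write_alignments(alignments, out / "alignments.tsv")
    else:
        from .io_core import read_alignments, read_annotation, read_counts, read_sample_sheet

        sheet = read_sample_sheet(cfg.sample_sheet_path)
        counts = {
            gt: read_counts(path, cfg.lengths_path)
            for gt, path in cfg.counts_paths.items()
        }
        annot = read_annotation(cfg.annotation_path, cfg.cds_fasta, cfg.promoter_fasta)
        alignments = read_alignments(cfg.alignments_path) if cfg.alignments_path else []
        truth = None

    write_sample_sheet(sheet, out / "sample_sheet.tsv")
    for gt, cm in counts.items():
        write_counts(cm, out / f"counts_{gt}.tsv", out / f"lengths_{gt}.tsv")

    # ---- stage 2: pairing and divergence ----------------------------------
    if cfg.pairs_path:
        pairs = pd.read_csv(cfg.pairs_path, sep="\t")
    else:
        called = orthology.call_pairs(
            alignments, annot, cfg.min_cov, cfg.min_ident, cfg.max_evalue
        )
        pairs = orthology.pairs_to_frame(called)
    if annot.cds:
        divergence = orthology.pair_divergence(
            pairs, annot.cds, annot.promoter or None
        )
        write_table(divergence, out / "divergence.tsv")
    write_table(pairs, out / "pairs.tsv")

    # ---- stage 3: TPM and parental mix ------------------------------------
    tpm = {gt: expression.compute_tpm(cm) for gt, cm in counts.items()}
    counts_mix, mix_sheet = expression.build_mix(counts["AA"], counts["DD"], sheet)
    tpm["MIX"] = expression.compute_tpm(counts_mix)
    for gt, em in tpm.items():
        write_expression(em, out / f"tpm_{gt}.tsv")

    # expression filter: pairs with both members TPM <= threshold in every
    # tissue of both the mix and the tetraploid are discarded
    mix_means = expression.mean_tissue_tpm(tpm["MIX"], mix_sheet, "MIX")
    at2_means = expression.mean_tissue_tpm(tpm["AT2"], sheet, "AT2")
    pair_max = np.max(
        [
            mix_means.loc[pairs["gene_A"]].max(axis=1).to_numpy(),
            mix_means.loc[pairs["gene_D"]].max(axis=1).to_numpy(),
            at2_means.loc[pairs["gene_A"]].max(axis=1).to_numpy(),
            at2_means.loc[pairs["gene_D"]].max(axis=1).to_numpy(),
        ],
        axis=0,
    )
    pairs = pairs.loc[pair_max > cfg.tpm_threshold].reset_index(drop=True)
    log.info("expression filter: %d pairs retained", len(pairs))
    write_table(pairs, out / "pairs_expressed.tsv")

    # ---- stage 4: ubiquity -------------------------------------------------
    genes_a = list(counts["AA"].counts.index)
    genes_d = list(counts["DD"].counts.index)
    ubiq = []
    for context, (gt, genes) in {
        "Ad": ("AA", genes_a),
        "Dd": ("DD", genes_d),
        "At": ("AT2", genes_a),
        "Dt": ("AT2", genes_d),
    }.items():
        em = ExpressionMatrix(tpm[gt].tpm.loc[genes])
        u = expression.categorize_ubiquity(
            em, sheet, gt, cfg.tpm_threshold, cfg.expression_rule
        )
        u["context"] = context
        ubiq.append(u)
    write_table(pd.concat(ubiq, ignore_index=True), out / "ubiquity.tsv")

    # ---- stage 5: differential expression ----------------------------------
    de_tables = {}
    for sub, genes in (("A", genes_a), ("D", genes_d)):
        per_tissue = diffexpr.subgenome_contrasts(
            counts["AT2"],
            counts["AA" if sub == "A" else "DD"],
            sheet,
            "AT2",
            "AA" if sub == "A" else "DD",
            genes,
            cfg.fc_threshold,
            cfg.fdr_threshold,
        )
        de_tables[sub] = per_tissue
        long = pd.concat(
            [t.assign(tissue=tissue, subgenome=sub) for tissue, t in per_tissue.items()],
            ignore_index=True,
        )
        write_table(long, out / f"de_{sub}.tsv")
    deg_cats = []
    for sub in ("A", "D"):
        calls = pd.DataFrame(
            {t: tab.set_index("gene_id")["call"] for t, tab in de_tables[sub].items()}
        )
        cat = diffexpr.categorize_degs(calls)
        cat["subgenome"] = sub
        deg_cats.append(cat)
    write_table(pd.concat(deg_cats, ignore_index=True), out / "deg_categories.tsv")

    # ---- stage 6: HEB ------------------------------------------------------
    len_a = counts["AA"].gene_length.loc[pairs["gene_A"]].to_numpy()
    len_d = counts["DD"].gene_length.loc[pairs["gene_D"]].to_numpy()
    heb_rows = []
    net_rows = []
    at2_calls = {}
    tissues = [t for t in TISSUES if t in set(sheet.table["tissue"])]
    for tissue in tissues:
        s_mix = mix_sheet.samples_for("MIX", tissue)
        s_at2 = sheet.samples_for("AT2", tissue)
        mix_call = heb.call_heb(
            counts_mix.counts.loc[pairs["gene_A"], s_mix].to_numpy(),
            counts_mix.counts.loc[pairs["gene_D"], s_mix].to_numpy(),
            len_a,
            len_d,
            cfg.fc_threshold,
            cfg.fdr_threshold,
        )
        at2_call = heb.call_heb(
            counts["AT2"].counts.loc[pairs["gene_A"], s_at2].to_numpy(),
            counts["AT2"].counts.loc[pairs["gene_D"], s_at2].to_numpy(),
            len_a,
            len_d,
            cfg.fc_threshold,
            cfg.fdr_threshold,
        )
        at2_calls[tissue] = pd.Series(at2_call["bias"].to_numpy(), index=pairs["pair_id"])
        group = heb.classify_heb_group(mix_call["bias"], at2_call["bias"])
        quad = _quadruplet_tpm(tpm["MIX"], tpm["AT2"], sheet, mix_sheet, pairs, tissue)
        net = heb.net_heb(
            quad["Ad"], quad["Dd"], quad["At"], quad["Dt"], cfg.epsilon
        )
        heb_rows.append(
            pd.DataFrame(
                {
                    "pair_id": pairs["pair_id"],
                    "tissue": tissue,
                    "mix_bias": mix_call["bias"],
                    "at2_bias": at2_call["bias"],
                    "group": group,
                }
            )
        )
        net_rows.append(
            pd.DataFrame(
                {
                    "pair_id": pairs["pair_id"],
                    "tissue": tissue,
                    "delta": net["delta"],
                    "p": net["p"],
                    "call": net["call"],
                }
            )
        )
    heb_long = pd.concat(heb_rows, ignore_index=True)
    net_long = pd.concat(net_rows, ignore_index=True)
    write_table(heb_long, out / "heb.tsv")
    write_table(net_long, out / "net_heb.tsv")
    stable = heb.stable_spike_heb(pd.DataFrame(at2_calls))
    stable.insert(0, "pair_id", stable.index)
    write_table(stable.reset_index(drop=True), out / "stable_heb.tsv")

    # ---- stage 7: HSE ------------------------------------------------------
    hse_rows = []
    for tissue in tissues:
        quad = _quadruplet_tpm(tpm["MIX"], tpm["AT2"], sheet, mix_sheet, pairs, tissue)
        expressed = np.stack([q.mean(axis=1) for q in quad.values()]).max(axis=0) > cfg.tpm_threshold
        hse_rows.append(
            hse.run_hse_tissue(
                quad, list(pairs["pair_id"]), tissue, cfg.epsilon, cfg.alpha, expressed
            )
        )
    hse_long = pd.concat(hse_rows, ignore_index=True)
    write_table(hse_long, out / "hse.tsv")
    freq, conservation = hse.hse_summary(hse_long)
    write_table(freq, out / "hse_frequencies.tsv")
    write_table(conservation, out / "hse_conservation.tsv")

    # ---- stage 8: networks -------------------------------------------------
    def profile_block(em: ExpressionMatrix, genes, means: pd.DataFrame, suffix: str):
        prof = np.log2(means.loc[genes].to_numpy() + 1.0)
        idx = [f"{g}@{suffix}" for g in genes]
        return pd.DataFrame(prof, index=idx, columns=list(means.columns))

    pg_a, pg_d = list(pairs["gene_A"]), list(pairs["gene_D"])
    prof_ad = profile_block(tpm["MIX"], pg_a, mix_means, "Ad")
    prof_dd = profile_block(tpm["MIX"], pg_d, mix_means, "Dd")
    prof_at = profile_block(tpm["AT2"], pg_a, at2_means, "At")
    prof_dt = profile_block(tpm["AT2"], pg_d, at2_means, "Dt")

    networks = {
        "mix": (pd.concat([prof_ad, prof_dd]), cfg.beta_homoeolog),
        "at2": (pd.concat([prof_at, prof_dt]), cfg.beta_homoeolog),
        "quadruplet": (
            pd.concat([prof_ad, prof_dd, prof_at, prof_dt]),
            cfg.beta_quadruplet,
        ),
    }
    nets = {}
    for name, (profiles, beta) in networks.items():
        net_obj = network.build_network(
            profiles, beta, cfg.min_module_size, cfg.merge_cut
        )
        nets[name] = net_obj
        mods = net_obj.modules.rename("module").reset_index().rename(columns={"index": "node"})
        write_table(mods, out / f"modules_{name}.tsv")

    # HEC in the mix and AT2 homoeolog networks
    hec_rows = []
    for name, (ca, cb) in {"mix": ("Ad", "Dd"), "at2": ("At", "Dt")}.items():
        net_obj = nets[name]
        present = set(net_obj.node_ids)
        for pid, ga, gd in pairs[["pair_id", "gene_A", "gene_D"]].itertuples(index=False):
            na, nb = f"{ga}@{ca}", f"{gd}@{cb}"
            if na not in present or nb not in present:
                continue
            res = network.hec_score(net_obj, na, nb, cfg.neighbor_quantile)
            hec_rows.append({"pair_id": pid, "context": name, **res})
    hec_df = pd.DataFrame(hec_rows)
    write_table(hec_df, out / "hec.tsv")

    # rewiring classes from the quadruplet network
    quad_net = nets["quadruplet"]
    mods = quad_net.modules

    def module_lookup(node: str) -> int:
        return int(mods.loc[node]) if node in mods.index else 0

    rew = pd.DataFrame(
        {
            "pair_id": pairs["pair_id"],
            "module_Ad": [module_lookup(f"{g}@Ad") for g in pg_a],
            "module_Dd": [module_lookup(f"{g}@Dd") for g in pg_d],
            "module_At": [module_lookup(f"{g}@At") for g in pg_a],
            "module_Dt": [module_lookup(f"{g}@Dt") for g in pg_d],
        }
    )
    rew["class"] = network.classify_rewiring(
        rew["module_Ad"], rew["module_Dd"], rew["module_At"], rew["module_Dt"]
    )
    write_table(rew, out / "rewiring.tsv")

    # ---- stage 9: SDRGs and spike network ----------------------------------
    down_calls = {}
    for sub in ("A", "D"):
        for tissue in SPIKE_TISSUES:
            if tissue in de_tables[sub]:
                tab = de_tables[sub][tissue].set_index("gene_id")["call"]
                down_calls.setdefault(tissue, []).append(tab)
    down_by_tissue = pd.DataFrame(
        {t: pd.concat(parts) for t, parts in down_calls.items()}
    )
    sdrg = diffexpr.identify_sdrgs(
        tpm["MIX"], mix_sheet, down_by_tissue, cfg.sdrg_fold, cfg.sdrg_nonspike_agg
    )
    write_table(sdrg, out / "sdrg.tsv")

    sdrg_genes = list(sdrg.loc[sdrg["sdrg"], "gene_id"])
    module_tests = pd.DataFrame()
    if len(sdrg_genes) >= cfg.min_module_size:
        spike_mix = mix_means.loc[sdrg_genes, list(SPIKE_TISSUES)]
        spike_at2 = at2_means.loc[sdrg_genes, list(SPIKE_TISSUES)]
        spike_prof = pd.DataFrame(
            np.log2(
                np.concatenate([spike_mix.to_numpy(), spike_at2.to_numpy()], axis=1) + 1.0
            ),
            index=sdrg_genes,
            columns=[f"MIX_{t}" for t in SPIKE_TISSUES] + [f"AT2_{t}" for t in SPIKE_TISSUES],
        )
        spike_net = network.build_network(
            spike_prof, cfg.beta_spike, cfg.min_module_size, cfg.merge_cut
        )
        write_table(
            spike_net.modules.rename("module").reset_index().rename(columns={"index": "node"}),
            out / "modules_spike.tsv",
        )
        subg = pd.Series(
            ["A" if g.startswith("gA") or g in genes_a else "D" for g in spike_net.node_ids],
            index=spike_net.node_ids,
        )
        subg.loc[subg.index.isin(genes_d)] = "D"
        module_tests = network.module_subgenome_test(spike_net.modules, subg)
        write_table(module_tests, out / "module_subgenome.tsv")

    # ---- stage 10: report --------------------------------------------------
    report_rows = []

    def add(metric: str, value) -> None:
        report_rows.append({"metric": metric, "value": value})

    add("n_pairs_called", len(pairs))
    for sub in ("A", "D"):
        n_deg = sum((t["call"] != "none").sum() for t in de_tables[sub].values())
        add(f"n_deg_calls_{sub}", int(n_deg))
    for grp, cnt in heb_long["group"].value_counts().items():
        add(f"heb_group_{grp}", int(cnt))
    for cat, cnt in hse_long["category"].value_counts(dropna=True).items():
        add(f"hse_{cat}", int(cnt))
    for grp, cnt in hec_df.groupby(["context", "group"]).size().items():
        add(f"hec_{grp[0]}_{grp[1]}", int(cnt))
    for cls, cnt in rew["class"].value_counts().items():
        add(f"rewiring_{cls}", int(cnt))
    add("n_sdrg", int(sdrg["sdrg"].sum()))
    if "stably_down" in sdrg:
        add("n_sdrg_stably_down", int(sdrg["stably_down"].sum()))
    write_table(pd.DataFrame(report_rows), out / "report.tsv")
    log.info("run_pipeline: wrote %s", out)
    return out
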