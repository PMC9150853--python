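"""TPM computation, in-silico parental mix, expression filtering and
ubiquity categories, plus sample-level summaries (PCA, hierarchical
clustering)."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .io_core import (
    CountMatrix,
    ExpressionMatrix,
    SampleSheet,
    TISSUES,
)

log = logging.getLogger("polyshock")

UBIQUITY_LEVELS = ("silent", "specific", "intermediate", "conserved")


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million: length-normalized rates scaled to 1e6 per
    sample. An all-zero sample yields an all-zero column with a warning."""
    rate = counts.counts.div(counts.gene_length, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero sample(s): {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return ExpressionMatrix(tpm)


def build_mix(
    counts_AA: CountMatrix, counts_DD: CountMatrix, sheet: SampleSheet
) -> tuple[CountMatrix, SampleSheet]:
    """In-silico 1:1 parental mix at the count level.

    MIX sample (tissue, replicate i) stacks the A-subgenome counts from the
    AA sample and the D-subgenome counts from the DD sample of the same
    (tissue, replicate). Computing TPM over the union gene set then halves
    each gene's TPM relative to its single-parent value, exactly as 1:1
    read mixing would. Gene sets must be disjoint and every AA replicate
    must have a DD counterpart.
    """
    shared = counts_AA.counts.index.intersection(counts_DD.counts.index)
    if len(shared):
        raise ValueError(f"gene sets not disjoint: {shared[0]!r} present in both parents")

    aa = sheet.table[sheet.table["genotype"] == "AA"]
    dd = sheet.table[sheet.table["genotype"] == "DD"]
    dd_key = {(r.tissue, r.replicate): r.sample_id for r in dd.itertuples(index=False)}

    mix_cols = {}
    rows = []
    for r in aa.itertuples(index=False):
        key = (r.tissue, r.replicate)
        if key not in dd_key:
            raise ValueError(f"no DD counterpart for AA replicate {key}")
        sid = f"MIX_{r.tissue}_r{r.replicate}"
        mix_cols[sid] = pd.concat(
            [counts_AA.counts[r.sample_id], counts_DD.counts[dd_key[key]]]
        )
        rows.append((sid, "MIX", r.tissue, r.replicate))
    mix_counts = pd.DataFrame(mix_cols)
    lengths = pd.concat([counts_AA.gene_length, counts_DD.gene_length])
    mix_sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "tissue", "replicate"])
    )
    log.info("build_mix: %d MIX samples over %d genes", len(rows), len(mix_counts))
    return CountMatrix(mix_counts, lengths), mix_sheet


def mean_tissue_tpm(
    expr: ExpressionMatrix, sheet: SampleSheet, genotype: str
) -> pd.DataFrame:
    """Replicate-mean TPM per tissue (genes x tissues) for one genotype."""
    out = {}
    for tissue in sheet.table.loc[sheet.table["genotype"] == genotype, "tissue"].unique():
        samples = sheet.samples_for(genotype, tissue)
        out[tissue] = expr.tpm[samples].mean(axis=1)
    return pd.DataFrame(out)


def categorize_ubiquity(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    genotype: str,
    tpm_threshold: float = 1.0,
    rule: str = "mean",
) -> pd.DataFrame:
    """Expression-ubiquity category per gene for one genotype context.

    A gene counts as expressed in a tissue when its replicate TPM exceeds
    the threshold under ``rule`` (``mean`` of replicates, or ``all``
    replicates). Categories over the nine tissues: silent (0), specific
    (1), intermediate (2-7), conserved (8-9).
    """
    tissues = sorted(set(sheet.table.loc[sheet.table["genotype"] == genotype, "tissue"]))
    if len(tissues) != len(TISSUES):
        raise ValueError(
            f"ubiquity categories are defined for {len(TISSUES)} tissues; got {len(tissues)}"
        )
    if rule not in ("mean", "all"):
        raise ValueError("rule must be 'mean' or 'all'")
    expressed = {}
    for tissue in tissues:
        samples = sheet.samples_for(genotype, tissue)
        sub = expr.tpm[samples]
        expressed[tissue] = (
            sub.mean(axis=1) > tpm_threshold
            if rule == "mean"
            else (sub > tpm_threshold).all(axis=1)
        )
    n_expr = pd.DataFrame(expressed).sum(axis=1)
    category = pd.cut(
        n_expr,
        bins=[-1, 0, 1, 7, 9],
        labels=UBIQUITY_LEVELS,
    ).astype(str)
    return pd.DataFrame(
        {
            "gene_id": n_expr.index,
            "genotype": genotype,
            "n_tissues_expressed": n_expr.to_numpy(),
            "category": category.to_numpy(),
        }
    )


def sample_pca(expr: ExpressionMatrix, n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(TPM + 1), genes as features, centered.

    Returns per-sample coordinates and the variance-explained ratios
    (non-negative, non-increasing, summing to <= 1).
    """
    x = np.log2(expr.tpm.to_numpy().T + 1.0)
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if np.allclose(x, x[0]):
        raise ValueError("constant expression matrix: PCA undefined")
    k = n_components or min(x.shape[0] - 1, x.shape[1], 10)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    df = pd.DataFrame(
        coords, index=expr.sample_ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    return df, pca.explained_variance_ratio_


def hclust_profiles(profiles: pd.DataFrame):
    """Average-linkage hierarchical clustering on 1 - Pearson correlation.

    Reporting utility for sample/profile dendrograms; returns a scipy
    linkage matrix over the rows of ``profiles``.
    """
    r = np.corrcoef(profiles.to_numpy())
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method="average")
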