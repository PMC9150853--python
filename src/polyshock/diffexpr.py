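"""Negative-binomial differential expression, DEG categorization and
spike-development gene (SDRG) calls.

The DE engine is a self-contained NB Wald test in the DESeq2 tradition
(median-of-ratios size factors, per-gene method-of-moments dispersion,
Wald statistic on the log2 fold change) — DESeq2-like, not bit-compatible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    CountMatrix,
    ExpressionMatrix,
    SampleSheet,
    SPIKE_TISSUES,
    NON_SPIKE_TISSUES,
)

log = logging.getLogger("polyshock")

_DISP_FLOOR = 1e-8
_LFC_PSEUDO = 0.5  # added to group means for the fold-change ratio only


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over the full matrix.

    Falls back to library-size ratios when fewer than 10 genes have
    all-positive counts (the geometric-mean reference is then undefined
    for most genes).
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if positive.sum() < 10:
        lib = x.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=counts.columns)
    logx = np.log(x[positive])
    ref = logx.mean(axis=1)
    sf = np.exp(np.median(logx - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def nb_wald_test(
    counts1: np.ndarray,
    counts2: np.ndarray,
    sf1: np.ndarray | None = None,
    sf2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB Wald test of group 1 vs group 2, per gene.

    ``counts1``/``counts2`` are (genes x replicates) arrays; size factors
    default to 1. Per-gene dispersion is estimated by method of moments on
    the normalized counts, pooled across the two groups and floored at
    1e-8. The Wald statistic on the log2 fold change is referred to a t
    distribution with ``n1 + n2 - 2`` degrees of freedom — at typical
    replicate numbers (n = 3) the moment dispersion estimate is noisy and
    the normal reference is anticonservative. Genes with zero counts in
    every sample of both groups return NaN. Returns ``(log2fc, p)``.
    """
    c1 = np.atleast_2d(np.asarray(counts1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts2, dtype=float))
    n1, n2 = c1.shape[1], c2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    if not c1.any():
        raise ValueError("group 1 has all-zero counts in every gene")
    if not c2.any():
        raise ValueError("group 2 has all-zero counts in every gene")
    sf1 = np.ones(n1) if sf1 is None else np.asarray(sf1, dtype=float)
    sf2 = np.ones(n2) if sf2 is None else np.asarray(sf2, dtype=float)
    if (sf1 <= 0).any() or (sf2 <= 0).any():
        raise ValueError("size factors must be positive")

    q1, q2 = c1 / sf1, c2 / sf2
    m1, m2 = q1.mean(axis=1), q2.mean(axis=1)
    v1 = q1.var(axis=1, ddof=1)
    v2 = q2.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = (v1 - m1) / m1**2
        d2 = (v2 - m2) / m2**2
        # pooled across groups, weighting by residual df
        phi = np.nansum(
            np.stack([(n1 - 1) * np.nan_to_num(d1), (n2 - 1) * np.nan_to_num(d2)]), axis=0
        ) / (n1 + n2 - 2)
    phi = np.maximum(phi, _DISP_FLOOR)

    lfc = np.log2(m1 + _LFC_PSEUDO) - np.log2(m2 + _LFC_PSEUDO)
    var_mean1 = (m1 + phi * m1**2) / n1
    var_mean2 = (m2 + phi * m2**2) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = (
            np.sqrt(
                var_mean1 / (m1 + _LFC_PSEUDO) ** 2 + var_mean2 / (m2 + _LFC_PSEUDO) ** 2
            )
            / np.log(2)
        )
        z = lfc / se
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)
    p = np.where(se == 0, np.where(lfc == 0, 1.0, 0.0), p)

    untested = (c1.sum(axis=1) == 0) & (c2.sum(axis=1) == 0)
    lfc = np.where(untested, np.nan, lfc)
    p = np.where(untested, np.nan, p)
    return lfc, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up within one contrast; NaNs pass through
    and are excluded from the number of tests."""
    p = np.asarray(p, dtype=float)
    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return fdr


def call_degs(
    lfc: np.ndarray,
    fdr: np.ndarray,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the DEG thresholds (|fold change| > fc_threshold, FDR below
    fdr_threshold). Returns ``(call, strong)`` where call is up/down/none
    and ``strong`` flags responders beyond 4-fold change."""
    lfc_thr = np.log2(fc_threshold)
    sig = (fdr < fdr_threshold) & ~np.isnan(lfc)
    call = np.where(sig & (lfc > lfc_thr), "up", np.where(sig & (lfc < -lfc_thr), "down", "none"))
    strong = (call != "none") & (np.abs(lfc) > np.log2(4.0))
    return call, strong


def de_contrast(
    counts: pd.DataFrame,
    samples1: list[str],
    samples2: list[str],
    sf: pd.Series | None = None,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One tissue-level contrast over a shared gene axis.

    ``counts`` holds both groups' samples; size factors default to
    median-of-ratios over the two groups' columns. FDR is computed within
    this contrast only. Genes with zero counts in all samples of the
    contrast are reported NA and excluded from the BH family.
    """
    if sf is None:
        sf = size_factors(counts[samples1 + samples2])
    lfc, p = nb_wald_test(
        counts[samples1].to_numpy(),
        counts[samples2].to_numpy(),
        sf.loc[samples1].to_numpy(),
        sf.loc[samples2].to_numpy(),
    )
    fdr = bh_adjust(p)
    call, strong = call_degs(lfc, fdr, fc_threshold, fdr_threshold)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "call": call,
            "strong": strong,
        }
    )


def subgenome_contrasts(
    counts_t: CountMatrix,
    counts_d: CountMatrix,
    sheet: SampleSheet,
    genotype_t: str,
    genotype_d: str,
    genes: list[str],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-tissue DE of the tetraploid context vs its parental context
    (e.g. At vs Ad) over a shared set of subgenome genes. Returns a mapping
    tissue -> DE table."""
    out = {}
    tissues = sorted(set(sheet.table.loc[sheet.table["genotype"] == genotype_t, "tissue"]))
    for tissue in tissues:
        s_t = sheet.samples_for(genotype_t, tissue)
        s_d = sheet.samples_for(genotype_d, tissue)
        joint = pd.concat(
            [counts_t.counts.loc[genes, s_t], counts_d.counts.loc[genes, s_d]], axis=1
        )
        out[tissue] = de_contrast(joint, s_t, s_d, None, fc_threshold, fdr_threshold)
    return out


DEG_UBIQUITY = ("specific_DE", "intermediate_DE", "conserved_DE")


def categorize_degs(calls_by_tissue: pd.DataFrame) -> pd.DataFrame:
    """DEG ubiquity and direction categories across the nine tissues.

    ``calls_by_tissue`` is genes x tissues with values up/down/none. Genes
    with no DE tissue are excluded. Ubiquity: specific_DE (1 tissue),
    intermediate_DE (2-7), conserved_DE (8-9). Direction (defined for >= 2
    DE tissues): up_conserved / down_conserved when the sign agrees in
    every DE tissue, otherwise divergent.
    """
    is_de = calls_by_tissue.isin(["up", "down"])
    n_de = is_de.sum(axis=1)
    kept = calls_by_tissue.loc[n_de > 0]
    n_de = n_de.loc[n_de > 0]
    n_up = (kept == "up").sum(axis=1)
    n_down = (kept == "down").sum(axis=1)
    ubiquity = pd.cut(
        n_de, bins=[0, 1, 7, 9], labels=DEG_UBIQUITY
    ).astype(str)
    direction = np.where(
        n_de < 2,
        "undefined",
        np.where(n_up == n_de, "up_conserved", np.where(n_down == n_de, "down_conserved", "divergent")),
    )
    return pd.DataFrame(
        {
            "gene_id": kept.index,
            "n_de_tissues": n_de.to_numpy(),
            "ubiquity_DE": ubiquity.to_numpy(),
            "direction": direction,
        }
    )


def identify_sdrgs(
    expr_mix: ExpressionMatrix,
    sheet_mix: SampleSheet,
    down_calls_spike: pd.DataFrame | None = None,
    fold: float = 2.0,
    nonspike_agg: str = "max",
) -> pd.DataFrame:
    """Spike-development-related genes in the parental mix.

    A gene is an SDRG when its replicate-mean TPM in at least one spike
    stage reaches ``fold`` times the aggregate (default: max, the stricter
    reading) of its four non-spike tissue means. With ``down_calls_spike``
    (genes x spike tissues, values up/down/none, from the AT2-vs-Mix
    contrast) SDRGs down-called in at least three of the five spike stages
    are flagged stably downregulated.
    """
    if nonspike_agg not in ("max", "mean"):
        raise ValueError("nonspike_agg must be 'max' or 'mean'")
    means = {}
    for tissue in SPIKE_TISSUES + NON_SPIKE_TISSUES:
        samples = sheet_mix.samples_for("MIX", tissue)
        if not samples:
            raise ValueError(f"missing tissue {tissue!r} in MIX samples")
        means[tissue] = expr_mix.tpm[samples].mean(axis=1)
    means = pd.DataFrame(means)
    nonspike = means[list(NON_SPIKE_TISSUES)]
    baseline = nonspike.max(axis=1) if nonspike_agg == "max" else nonspike.mean(axis=1)
    spike = means[list(SPIKE_TISSUES)]
    is_sdrg = (spike.ge(fold * baseline.clip(lower=1e-9), axis=0)).any(axis=1) & (
        spike.max(axis=1) > 0
    )
    out = pd.DataFrame({"gene_id": means.index, "sdrg": is_sdrg.to_numpy()})
    if down_calls_spike is not None:
        n_down = (down_calls_spike == "down").sum(axis=1).reindex(means.index).fillna(0)
        out["stably_down"] = out["sdrg"].to_numpy() & (n_down.to_numpy() >= 3)
    log.info("identify_sdrgs: %d SDRGs of %d genes", int(is_sdrg.sum()), len(out))
    return out
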