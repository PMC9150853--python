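"""Homoeolog expression bias: per-tissue bias calls, four-group tracing
between the parental mix and the allopolyploid, Flagel-Wendel net HEB, and
stable spike-stage bias."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, nb_wald_test
from .io_core import SPIKE_TISSUES

log = logging.getLogger("polyshock")

HEB_GROUPS = ("parental_legacy", "convergence", "divergence", "reversion")


def call_heb(
    counts_A: np.ndarray,
    counts_D: np.ndarray,
    length_A: np.ndarray,
    length_D: np.ndarray,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """A-vs-D bias calls for homoeolog pairs within one context and tissue.

    ``counts_A``/``counts_D`` are (pairs x replicates) raw counts of the
    two pair members measured in the same samples, so no library size
    factor is needed; counts are rescaled to a common per-kilobase scale
    before testing because homoeologs may differ in CDS length. Bias
    requires fold change above ``fc_threshold`` and BH FDR below
    ``fdr_threshold`` (FDR across the pairs of this call set). Pairs with
    both members all-zero get bias ``none`` with NaN FDR.
    """
    cA = np.atleast_2d(np.asarray(counts_A, dtype=float))
    cD = np.atleast_2d(np.asarray(counts_D, dtype=float))
    lA = np.asarray(length_A, dtype=float)[:, None]
    lD = np.asarray(length_D, dtype=float)[:, None]
    lfc, p = nb_wald_test(cA * 1e3 / lA, cD * 1e3 / lD)
    fdr = bh_adjust(p)
    thr = np.log2(fc_threshold)
    sig = (fdr < fdr_threshold) & ~np.isnan(lfc)
    bias = np.where(sig & (lfc > thr), "A", np.where(sig & (lfc < -thr), "D", "none"))
    return pd.DataFrame({"log2fc_AvsD": lfc, "fdr": fdr, "bias": bias})


def classify_heb_group(mix_bias, at2_bias):
    """Four-group trajectory from the (mix, AT2) bias calls.

    Identical direction (including none/none) is parental legacy; bias in
    the mix lost in AT2 is convergence; de novo bias only in AT2 is
    divergence; opposite directions is reversion. Total over the nine
    (mix, at2) cells. Accepts scalars or arrays.
    """
    mix = np.asarray(mix_bias, dtype=object)
    at2 = np.asarray(at2_bias, dtype=object)
    out = np.where(
        mix == at2,
        "parental_legacy",
        np.where(
            at2 == "none",
            "convergence",
            np.where(mix == "none", "divergence", "reversion"),
        ),
    )
    return out.item() if out.ndim == 0 else out


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test along axis 1 with the degenerate
    conventions: both groups constant -> p = 1 if means equal else 0."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    p = 2.0 * stats.t.sf(np.abs(t), np.where(np.isnan(df) | (df <= 0), 1.0, df))
    p = np.where(se2 == 0, np.where(m1 == m2, 1.0, 0.0), p)
    return p


def net_heb(
    tpm_A_mix: np.ndarray,
    tpm_D_mix: np.ndarray,
    tpm_A_at2: np.ndarray,
    tpm_D_at2: np.ndarray,
    epsilon: float = 0.5,
    p_threshold: float = 0.05,
    delta_threshold: float = 1.0,
) -> pd.DataFrame:
    """Net bias after subtracting the parental ratio (Flagel-Wendel).

    Per replicate the pair is reduced to ``r = log2((TPM_A + eps) /
    (TPM_D + eps))``; the AT2 ratios are tested against the mix ratios with
    a two-sided Welch t-test. ``delta`` is the mean AT2 ratio minus the
    mean mix ratio; the call is A when delta > 1 with p below threshold,
    D symmetric. Pairs with both members zero in every replicate of both
    contexts are uncallable (NaN p, call none).
    """
    inputs = [np.atleast_2d(np.asarray(x, dtype=float)) for x in
              (tpm_A_mix, tpm_D_mix, tpm_A_at2, tpm_D_at2)]
    am, dm, aa, da = inputs
    r_mix = np.log2(am + epsilon) - np.log2(dm + epsilon)
    r_at2 = np.log2(aa + epsilon) - np.log2(da + epsilon)
    delta = r_at2.mean(axis=1) - r_mix.mean(axis=1)
    p = _welch(r_at2, r_mix)
    undefined = (am + dm).sum(axis=1) + (aa + da).sum(axis=1) == 0
    p = np.where(undefined, np.nan, p)
    delta = np.where(undefined, np.nan, delta)
    sig = (p < p_threshold) & ~np.isnan(p)
    call = np.where(
        sig & (delta > delta_threshold),
        "A",
        np.where(sig & (delta < -delta_threshold), "D", "none"),
    )
    return pd.DataFrame({"delta": delta, "p": p, "call": call})


def stable_spike_heb(calls_by_stage: pd.DataFrame, min_stages: int = 3) -> pd.DataFrame:
    """Stable spike-stage bias: A-bias (D-bias) in at least ``min_stages``
    of the five spike stages. ``calls_by_stage`` is pairs x spike stages
    with values A/D/none."""
    missing = set(SPIKE_TISSUES) - set(calls_by_stage.columns)
    if missing:
        raise ValueError(f"missing spike stage(s): {sorted(missing)}")
    sub = calls_by_stage[list(SPIKE_TISSUES)]
    return pd.DataFrame(
        {
            "stable_A": (sub == "A").sum(axis=1) >= min_stages,
            "stable_D": (sub == "D").sum(axis=1) >= min_stages,
        },
        index=calls_by_stage.index,
    )
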