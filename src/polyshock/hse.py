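"""Seven-category cis/trans regulatory-divergence (homoeolog-specific
expression) classification.

Per pair and tissue, expression divergence in the parental mix,
``A = log2(Ad/Dd)``, reflects combined cis and trans divergence; in the
shared allopolyploid nucleus the trans environments equalize so
``B = log2(At/Dt)`` isolates the cis component, and ``A - B`` estimates
the trans component. Three t-tests (A vs 0, B vs 0, A vs B) feed a
seven-way decision table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .heb import _welch
from .synthetic_data import HSE_CATEGORIES

__all__ = ["HSE_CATEGORIES", "hse_statistics", "classify_hse", "hse_summary", "run_hse_tissue"]


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """Vectorized two-sided one-sample t vs 0 along axis 1, with the
    degenerate conventions: zero variance with zero mean -> p = 1; zero
    variance with nonzero mean -> p = 0."""
    n = x.shape[1]
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return np.where(s == 0, np.where(m == 0, 1.0, 0.0), p)


def hse_statistics(
    tpm_Ad: np.ndarray,
    tpm_Dd: np.ndarray,
    tpm_At: np.ndarray,
    tpm_Dt: np.ndarray,
    epsilon: float = 0.5,
) -> pd.DataFrame:
    """A, B, trans estimates and the three test p-values per pair.

    Inputs are (pairs x replicates) TPM arrays for the four contexts.
    Per replicate, ``a_i = log2((Ad_i + eps)/(Dd_i + eps))`` and
    ``b_i = log2((At_i + eps)/(Dt_i + eps))``; ``p_A`` and ``p_B`` are
    one-sample two-sided t-tests vs 0 and ``p_AB`` a two-sample Welch
    t-test of the a's vs the b's (the two contexts are independent
    samples).
    """
    ad, dd, at, dt = (np.atleast_2d(np.asarray(x, dtype=float)) for x in
                      (tpm_Ad, tpm_Dd, tpm_At, tpm_Dt))
    a = np.log2(ad + epsilon) - np.log2(dd + epsilon)
    b = np.log2(at + epsilon) - np.log2(dt + epsilon)
    return pd.DataFrame(
        {
            "A": a.mean(axis=1),
            "B": b.mean(axis=1),
            "trans_est": a.mean(axis=1) - b.mean(axis=1),
            "p_A": _one_sample_t(a),
            "p_B": _one_sample_t(b),
            "p_AB": _welch(a, b),
        }
    )


def classify_hse(
    stats_df: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> np.ndarray:
    """Seven-way category from the three significance calls and the signs.

    With ``sig_X`` meaning ``p_X < alpha`` (optionally BH-adjusted across
    pairs when ``adjust``), "X = 0" meaning not sig_X and "A = B" meaning
    not sig_AB:

    - conserved:        A = B, A = 0, B = 0
    - cis_only:         A = B, A != 0, B != 0
    - trans_only:       A != B, A != 0, B = 0
    - cis_plus_trans:   A != B, both nonzero, sign(A) == sign(B)
    - cis_times_trans:  A != B, both nonzero, sign(A) != sign(B)
    - compensatory:     A != B, A = 0, B != 0
    - ambiguous:        every remaining pattern
    """
    p_A, p_B, p_AB = (stats_df[c].to_numpy() for c in ("p_A", "p_B", "p_AB"))
    if adjust:
        from .diffexpr import bh_adjust

        p_A, p_B, p_AB = bh_adjust(p_A), bh_adjust(p_B), bh_adjust(p_AB)
    sA, sB, sAB = p_A < alpha, p_B < alpha, p_AB < alpha
    sign_same = np.sign(stats_df["A"].to_numpy()) == np.sign(stats_df["B"].to_numpy())

    out = np.full(len(stats_df), "ambiguous", dtype=object)
    out[~sA & ~sB & ~sAB] = "conserved"
    out[sA & sB & ~sAB] = "cis_only"
    out[sA & ~sB & sAB] = "trans_only"
    out[sA & sB & sAB & sign_same] = "cis_plus_trans"
    out[sA & sB & sAB & ~sign_same] = "cis_times_trans"
    out[~sA & sB & sAB] = "compensatory"
    return out


def run_hse_tissue(
    tpm_quadruplet: dict[str, np.ndarray],
    pair_ids: list[str],
    tissue: str,
    epsilon: float = 0.5,
    alpha: float = 0.05,
    expressed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Statistics plus category for one tissue; pairs failing the
    expression filter (``expressed`` False) are reported NA."""
    df = hse_statistics(
        tpm_quadruplet["Ad"],
        tpm_quadruplet["Dd"],
        tpm_quadruplet["At"],
        tpm_quadruplet["Dt"],
        epsilon,
    )
    df.insert(0, "tissue", tissue)
    df.insert(0, "pair_id", pair_ids)
    cat = classify_hse(df, alpha)
    if expressed is not None:
        cat = np.where(np.asarray(expressed, dtype=bool), cat, None)
    df["category"] = cat
    return df


def hse_summary(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue category frequencies, and the per-pair modal category
    with the number of tissues sharing it.

    ``results`` concatenates per-tissue classifications with columns
    ``pair_id``, ``tissue``, ``category`` (NA rows excluded from both
    summaries). Modal-category ties break alphabetically for determinism.
    """
    classified = results.dropna(subset=["category"])
    freq = (
        classified.groupby("tissue")["category"]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )

    def modal(group: pd.Series) -> pd.Series:
        counts = group.value_counts()
        top = counts.max()
        winner = sorted(counts.index[counts == top])[0]
        return pd.Series({"modal_category": winner, "n_tissues_modal": int(top)})

    conservation = classified.groupby("pair_id")["category"].apply(modal).unstack()
    conservation["n_tissues_modal"] = conservation["n_tissues_modal"].astype(int)
    return freq, conservation.reset_index()
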