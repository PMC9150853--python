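"""Homoeolog/ortholog pair calling and sequence divergence.

Pairs A- and D-subgenome genes from tabular BLAST alignments by coverage,
identity and E-value filters followed by reciprocal best hit, and computes
Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction plus promoter
p-distance for called pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import AlignmentRecord, GeneAnnotation

log = logging.getLogger("polyshock")


@dataclass(frozen=True)
class HomoeologPair:
    pair_id: str
    gene_A: str
    gene_D: str


def pairs_to_frame(pairs: list[HomoeologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.pair_id, p.gene_A, p.gene_D) for p in pairs],
        columns=["pair_id", "gene_A", "gene_D"],
    )


def frame_to_pairs(df: pd.DataFrame) -> list[HomoeologPair]:
    return [
        HomoeologPair(r.pair_id, r.gene_A, r.gene_D) for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Pair calling
# ---------------------------------------------------------------------------


def call_pairs(
    alignments: list[AlignmentRecord],
    annotation: GeneAnnotation,
    min_cov: float = 0.60,
    min_ident: float = 0.90,
    max_evalue: float = 1e-5,
) -> list[HomoeologPair]:
    """One-to-one A-D pairs by filtered reciprocal best hit.

    A record survives when its E-value is below ``max_evalue``, its percent
    identity is at least ``100 * min_ident``, and the aligned region covers
    more than ``min_cov`` of the CDS length of *both* sequences. Multiple
    HSPs for one gene pair are not chained: the single best-bitscore HSP
    represents the pair. Surviving records are paired by reciprocal best
    bitscore, ties broken by higher identity then lexicographic partner id.
    """
    lengths: dict[str, int] = {}

    def cds_len(gene: str) -> int:
        if gene not in lengths:
            if gene not in annotation.subgenome.index:
                raise ValueError(f"alignment names gene {gene!r} absent from annotation")
            if gene not in annotation.cds:
                raise ValueError(f"no CDS for gene {gene!r}; cannot compute coverage")
            lengths[gene] = len(annotation.cds[gene])
        return lengths[gene]

    # filter + collapse HSPs to the best one per (query, subject)
    best_hsp: dict[tuple[str, str], AlignmentRecord] = {}
    n_in = len(alignments)
    for rec in alignments:
        qlen, slen = cds_len(rec.query), cds_len(rec.subject)
        if rec.evalue >= max_evalue:
            continue
        if rec.pct_identity < 100.0 * min_ident:
            continue
        if rec.aln_length / qlen <= min_cov or rec.aln_length / slen <= min_cov:
            continue
        key = (rec.query, rec.subject)
        prev = best_hsp.get(key)
        if prev is None or (rec.bitscore, rec.pct_identity) > (prev.bitscore, prev.pct_identity):
            best_hsp[key] = rec

    # orient as (A gene, D gene); skip same-subgenome hits
    sub = annotation.subgenome
    scored: dict[tuple[str, str], tuple[float, float]] = {}
    for (q, s), rec in best_hsp.items():
        sq, ss = sub.loc[q], sub.loc[s]
        if sq == ss:
            continue
        a, d = (q, s) if sq == "A" else (s, q)
        key = (a, d)
        val = (rec.bitscore, rec.pct_identity)
        if key not in scored or val > scored[key]:
            scored[key] = val

    def best_partner(candidates: list[tuple[str, float, float]]) -> str:
        # candidates: (partner, bitscore, identity); best by bitscore, then
        # identity, then lexicographically smallest partner id
        return min(candidates, key=lambda c: (-c[1], -c[2], c[0]))[0]

    by_a: dict[str, list] = {}
    by_d: dict[str, list] = {}
    for (a, d), (bs, ident) in scored.items():
        by_a.setdefault(a, []).append((d, bs, ident))
        by_d.setdefault(d, []).append((a, bs, ident))

    pairs = []
    for a in sorted(by_a):
        d = best_partner(by_a[a])
        if best_partner(by_d[d]) == a:
            pairs.append(HomoeologPair(f"{a}:{d}", a, d))
    log.info(
        "call_pairs: %d alignments -> %d filtered hits -> %d reciprocal pairs",
        n_in,
        len(scored),
        len(pairs),
    )
    return pairs


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _TABLE[stop] = "*"
    return _TABLE


import functools


@functools.lru_cache(maxsize=4096)
def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous site counts of one codon.

    Each position contributes (synonymous changes)/3 synonymous sites;
    changes producing stop codons count as non-synonymous.
    """
    table = _codon_table()
    aa = table[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and table[alt] == aa:
                syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """Total (synonymous, non-synonymous) site counts of a CDS, NG86 style."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    S = N = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        if codon in _STOPS:
            raise ValueError(f"stop codon {codon} at position {i}")
        s, n = _codon_sites(codon)
        S += s
        N += n
    return S, N


@functools.lru_cache(maxsize=65536)
def _codon_path_changes(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous change counts over all minimal
    mutational paths between two codons; paths through stop codons are
    discarded (all-stop path sets fall back to counting every path)."""
    table = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if table[cur] == table[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((sd, nd, through_stop))
    valid = [(s, n) for s, n, stop in paths if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        warnings.warn(f"substitution proportion {p:.3f} >= 3/4: saturated, returning NaN")
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(cds_A: str, cds_D: str) -> tuple[float, float]:
    """Nei-Gojobori (1986) Ka and Ks with Jukes-Cantor correction.

    Expects an equal-length, gap-free, in-frame codon alignment. Codons
    containing ``N`` in either sequence are skipped. Returns ``(Ka, Ks)``;
    a class with zero sites, or a saturated proportion (p >= 3/4), yields
    NaN for that class.
    """
    a, d = cds_A.upper(), cds_D.upper()
    if len(a) != len(d):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3 != 0:
        raise ValueError("alignment length not divisible by 3")

    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cd = a[i : i + 3], d[i : i + 3]
        if "N" in ca or "N" in cd or "-" in ca or "-" in cd:
            continue
        if ca in _STOPS or cd in _STOPS:
            raise ValueError(f"internal stop codon at position {i}")
        sa, na = _codon_sites(ca)
        sd_, nd_ = _codon_sites(cd)
        S += (sa + sd_) / 2.0
        N += (na + nd_) / 2.0
        cs, cn = _codon_path_changes(ca, cd)
        Sd += cs
        Nd += cn

    ks = _jukes_cantor(Sd / S) if S > 0 else float("nan")
    ka = _jukes_cantor(Nd / N) if N > 0 else float("nan")
    return ka, ks


def promoter_pdistance(prom_A: str, prom_D: str) -> float:
    """p-distance over aligned promoter columns; columns with N or a gap in
    either sequence are excluded. Zero comparable columns yields NaN."""
    a, d = prom_A.upper(), prom_D.upper()
    if len(a) != len(d):
        raise ValueError("promoters must be aligned to equal length")
    compared = mismatch = 0
    for x, y in zip(a, d):
        if x not in _BASES or y not in _BASES:
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        return float("nan")
    return mismatch / compared


def pair_divergence(
    pairs_df: pd.DataFrame,
    cds: dict[str, str],
    promoters: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Ka, Ks and promoter p-distance for every pair in a pairs table."""
    rows = []
    for r in pairs_df.itertuples(index=False):
        ka, ks = ng86_ka_ks(cds[r.gene_A], cds[r.gene_D])
        pdist = (
            promoter_pdistance(promoters[r.gene_A], promoters[r.gene_D])
            if promoters is not None
            else float("nan")
        )
        rows.append({"pair_id": r.pair_id, "Ka": ka, "Ks": ks, "promoter_pdist": pdist})
    return pd.DataFrame(rows)
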