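"""Synthetic quadruplet data generator with known ground truth.

Generates negative-binomial count matrices for the three genotypes (AA, DD,
AT2) over nine tissues and replicated samples, together with toy CDS and
promoter sequences, so that the whole downstream pipeline — homoeolog
pairing, differential expression, homoeolog expression bias, cis/trans
classification, co-expression networks — can be exercised against planted
truth with no external data.

Generative model
----------------
Each homoeolog pair carries a cis effect ``c`` and a trans effect ``t``
(log2 units). In the parental mix the two orthologs see their own parental
trans environments, so the expected log-ratio is ``log2(Ad/Dd) = c + t``;
in the allopolyploid nucleus the trans environment is shared and only the
cis difference survives: ``log2(At/Dt) = c``. The seven regulatory
categories are planted by choosing ``(c, t)`` patterns that invert the
downstream decision rules; homoeolog-bias trajectories follow from the
implied (mix, AT2) ratios. Tissue profiles come from a planted-partition
latent-factor model, and counts are negative binomial with a gene-shared
dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import CountMatrix, GeneAnnotation, SampleSheet, TISSUES

HSE_CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_times_trans",
    "compensatory",
    "ambiguous",
)

HEB_TRAJECTORIES = ("parental_legacy", "convergence", "divergence", "reversion")

REWIRING_CLASSES = (
    "conserved_same",
    "conserved_different",
    "convergence",
    "divergence",
    "other",
)

CONTEXTS = ("Ad", "Dd", "At", "Dt")

#: Default category proportions: bimodal world dominated by conserved pairs,
#: with cis-only divergence the most common non-conserved pattern, mirroring
#: what interspecific comparisons of close relatives typically show.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "conserved": 0.40,
    "cis_only": 0.22,
    "trans_only": 0.10,
    "cis_plus_trans": 0.06,
    "cis_times_trans": 0.01,
    "compensatory": 0.06,
    "ambiguous": 0.15,
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic quadruplet generator.

    ``dispersion`` is the negative-binomial dispersion ``phi`` with
    ``var = m + phi * m**2`` (so the coefficient of variation floors at
    ``sqrt(phi)`` for well-expressed genes). ``effect_size`` is the planted
    regulatory effect in log2 units. ``category_mix`` gives the proportions
    of the seven cis/trans categories; ``heb_trajectory_mix``, when set,
    plants bias trajectories instead (each trajectory maps to a fixed
    ``(c, t)`` pattern). ``rewiring_mix`` plants quadruplet module-rewiring
    classes through the latent-factor assignment of the four node contexts.
    """

    n_pairs: int = 2000
    n_tissues: int = 9
    n_reps: int = 3
    dispersion: float = 0.05
    lib_size_mean: float = 2e7
    lib_size_cv: float = 0.05
    category_mix: Mapping[str, float] | None = None
    effect_size: float = 1.5
    heb_trajectory_mix: Mapping[str, float] | None = None
    n_modules: int = 3
    module_cohesion: float = 0.8
    module_amplitude: float = 2.0
    rewiring_mix: Mapping[str, float] | None = None
    silent_fraction: float = 0.2
    mu_mean: float = 5.0
    mu_sd: float = 1.5
    de_fraction: float = 0.0
    de_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 1 <= self.n_tissues <= len(TISSUES):
            raise ValueError(f"n_tissues must be in [1, {len(TISSUES)}]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.module_cohesion <= 1.0:
            raise ValueError("module_cohesion must lie in [0, 1]")
        if self.n_modules < 2:
            raise ValueError("n_modules must be >= 2")
        for name, mix, levels in (
            ("category_mix", self.category_mix, HSE_CATEGORIES),
            ("heb_trajectory_mix", self.heb_trajectory_mix, HEB_TRAJECTORIES),
            ("rewiring_mix", self.rewiring_mix, REWIRING_CLASSES),
        ):
            if mix is None:
                continue
            unknown = set(mix) - set(levels)
            if unknown:
                raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
            total = sum(mix.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(f"{name} proportions must sum to 1 (got {total})")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} proportions must be non-negative")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]


def _effects_for_category(category: str, sign: int, e: float, rng: np.random.Generator):
    """Map a planted category to a (c, t) pair.

    cis x trans requires both A = c + t and B = c nonzero with opposite
    signs, which (c, t) = (e, -e) cannot produce (that pattern is
    compensatory); it is planted as (±e, ∓2e).
    """
    if category == "conserved":
        return 0.0, 0.0
    if category == "cis_only":
        return sign * e, 0.0
    if category == "trans_only":
        return 0.0, sign * e
    if category == "cis_plus_trans":
        return sign * e, sign * e
    if category == "cis_times_trans":
        return sign * e, -2.0 * sign * e
    if category == "compensatory":
        return sign * e, -sign * e
    if category == "ambiguous":
        c, t = rng.uniform(-0.25, 0.25, size=2)
        return float(c), float(t)
    raise ValueError(f"unknown category {category!r}")


_TRAJECTORY_EFFECTS = {
    # trajectory -> (c, t) in units of effect_size; mix ratio = c+t, at2 = c
    "parental_legacy": (1.0, 0.0),
    "convergence": (0.0, 1.0),
    "divergence": (1.0, -1.0),
    "reversion": (1.0, -2.0),
}


def _category_from_effects(c: float, t: float, threshold: float = 0.5) -> str:
    """True category implied by (c, t); threshold separates planted effects
    from the sub-threshold jitter used for ambiguous pairs."""
    A, B = c + t, c
    nzA, nzB = abs(A) > threshold, abs(B) > threshold
    dAB = abs(A - B) > threshold
    if not nzA and not nzB and not dAB:
        return "conserved"
    if nzA and nzB and not dAB:
        return "cis_only"
    if nzA and not nzB and dAB:
        return "trans_only"
    if nzA and nzB and dAB:
        return "cis_plus_trans" if np.sign(A) == np.sign(B) else "cis_times_trans"
    if not nzA and nzB and dAB:
        return "compensatory"
    return "ambiguous"


def _trajectory_from_ratios(mix: float, at2: float, threshold: float = 1.0) -> str:
    """HEB trajectory implied by the planted log2 ratios, at the pipeline's
    bias threshold (|log2 ratio| > 1, i.e. fold change > 2)."""

    def bias(r: float) -> str:
        if r > threshold:
            return "A"
        if r < -threshold:
            return "D"
        return "none"

    bm, ba = bias(mix), bias(at2)
    if bm == ba:
        return "parental_legacy"
    if ba == "none":
        return "convergence"
    if bm == "none":
        return "divergence"
    return "reversion"


# ---------------------------------------------------------------------------
# Module / rewiring structure
# ---------------------------------------------------------------------------


def generate_module_structure(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Latent tissue factors and per-context module assignments.

    Returns ``(factors, assignment)`` where ``factors`` is an
    ``(n_modules, n_tissues)`` matrix of standard-normal module profiles and
    ``assignment`` has one row per pair with columns ``rewiring_class`` and
    ``module_Ad .. module_Dt`` (1-based module ids). The rewiring class
    dictates which contexts share a factor: e.g. for planted convergence,
    Ad and Dd sit in different modules while At and Dt share one.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n_pairs, config.n_modules
    factors = rng.standard_normal((k, config.n_tissues))

    mix = config.rewiring_mix or {"conserved_same": 1.0}
    classes = rng.choice(
        list(mix.keys()), size=n, p=np.asarray(list(mix.values()), dtype=float)
    )
    m1 = rng.integers(0, k, size=n)
    offset = rng.integers(1, k, size=n)
    m2 = (m1 + offset) % k  # guaranteed != m1
    m3 = rng.integers(0, k, size=n)

    mods = np.empty((n, 4), dtype=int)
    for i, cls in enumerate(classes):
        a, b, c = m1[i], m2[i], m3[i]
        if cls == "conserved_same":
            mods[i] = (a, a, a, a)
        elif cls == "conserved_different":
            mods[i] = (a, b, a, b)
        elif cls == "convergence":
            mods[i] = (a, b, c, c)
        elif cls == "divergence":
            mods[i] = (a, a, a, b)
        elif cls == "other":
            mods[i] = (a, b, b, a)
        else:  # pragma: no cover
            raise ValueError(f"unknown rewiring class {cls!r}")

    assignment = pd.DataFrame(
        {
            "rewiring_class": classes,
            **{f"module_{ctx}": mods[:, j] + 1 for j, ctx in enumerate(CONTEXTS)},
        }
    )
    return factors, assignment


def generate_module_profiles(
    n_modules: int,
    nodes_per_module: int,
    n_samples: int,
    cohesion: float,
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Standalone planted-partition profile generator for network tests.

    Each node profile is ``sqrt(cohesion) * factor + sqrt(1 - cohesion) *
    noise`` so the expected within-module correlation equals ``cohesion``
    and the between-module correlation is 0.
    """
    if not 0.0 <= cohesion <= 1.0:
        raise ValueError("cohesion must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_modules, n_samples))
    labels = np.repeat(np.arange(n_modules), nodes_per_module)
    noise = rng.standard_normal((len(labels), n_samples))
    x = amplitude * (
        math.sqrt(cohesion) * factors[labels] + math.sqrt(1.0 - cohesion) * noise
    )
    idx = [f"node{i:04d}" for i in range(len(labels))]
    return (
        pd.DataFrame(x, index=idx, columns=[f"s{j}" for j in range(n_samples)]),
        pd.Series(labels, index=idx, name="module"),
    )


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def generate_quadruplet_counts(
    config: SynthConfig,
) -> tuple[dict[str, CountMatrix], SampleSheet, pd.DataFrame]:
    """Generate per-genotype count matrices, sample sheet and ground truth.

    Returns ``(counts, sheet, truth)`` where ``counts`` maps genotype
    (``AA``, ``DD``, ``AT2``) to a :class:`CountMatrix` (the AT2 matrix
    carries both subgenomes' genes), ``sheet`` covers all generated samples,
    and ``truth`` has one row per pair with the planted cis/trans effects,
    category, bias trajectory, DE status and module assignment. All outputs
    are a pure function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    tissues = config.tissues
    e = config.effect_size

    genes_a = [f"gA{i:05d}" for i in range(n)]
    genes_d = [f"gD{i:05d}" for i in range(n)]
    len_a = rng.integers(200, 1000, size=n) * 3
    len_d = rng.integers(200, 1000, size=n) * 3

    expressed = rng.random(n) >= config.silent_fraction
    mu = rng.normal(config.mu_mean, config.mu_sd, size=n)

    signs = rng.choice([-1, 1], size=n)
    if config.heb_trajectory_mix is not None:
        mix = config.heb_trajectory_mix
        labels = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
        c_arr = np.empty(n)
        t_arr = np.empty(n)
        for i, lab in enumerate(labels):
            cc, tt = _TRAJECTORY_EFFECTS[lab]
            c_arr[i], t_arr[i] = signs[i] * cc * e, signs[i] * tt * e
        categories = np.array([_category_from_effects(c_arr[i], t_arr[i]) for i in range(n)])
        trajectories = labels
    else:
        mix = config.category_mix or DEFAULT_CATEGORY_MIX
        cats = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
        c_arr = np.empty(n)
        t_arr = np.empty(n)
        for i, cat in enumerate(cats):
            c_arr[i], t_arr[i] = _effects_for_category(cat, signs[i], e, rng)
        categories = cats
        trajectories = np.array(
            [_trajectory_from_ratios(c_arr[i] + t_arr[i], c_arr[i]) for i in range(n)]
        )

    mix_ratio = c_arr + t_arr
    at2_ratio = c_arr.copy()

    # Tissue structure: module latent factors plus a pair-shared idiosyncratic
    # profile. The pair-shared part cancels from every within-tissue ratio, so
    # it shapes co-expression without perturbing DE/HEB/HSE truth.
    factors, assignment = generate_module_structure(config, rng)
    g_pair = rng.standard_normal((n, config.n_tissues))
    w = config.module_cohesion
    amp = config.module_amplitude
    shared = amp * math.sqrt(1.0 - w) * g_pair
    ctx_profiles = {}
    for ctx in CONTEXTS:
        m = assignment[f"module_{ctx}"].to_numpy() - 1
        ctx_profiles[ctx] = amp * math.sqrt(w) * factors[m] + shared

    # Allopolyploidy-induced DE, applied to the tetraploid contexts.
    de_a = np.full(n, "none", dtype=object)
    de_d = np.full(n, "none", dtype=object)
    if config.de_fraction > 0:
        for arr in (de_a, de_d):
            u = rng.random(n)
            arr[u < config.de_fraction / 2] = "up"
            arr[(u >= config.de_fraction / 2) & (u < config.de_fraction)] = "down"
    delta_a = np.where(de_a == "up", config.de_log2fc, np.where(de_a == "down", -config.de_log2fc, 0.0))
    delta_d = np.where(de_d == "up", config.de_log2fc, np.where(de_d == "down", -config.de_log2fc, 0.0))

    # Per-context per-tissue expression on the TPM-like scale.
    mu_col = mu[:, None]
    tpm = {
        "Ad": 2.0 ** (mu_col + ctx_profiles["Ad"] + mix_ratio[:, None] / 2),
        "Dd": 2.0 ** (mu_col + ctx_profiles["Dd"] - mix_ratio[:, None] / 2),
        "At": 2.0 ** (mu_col + ctx_profiles["At"] + at2_ratio[:, None] / 2 + delta_a[:, None]),
        "Dt": 2.0 ** (mu_col + ctx_profiles["Dt"] - at2_ratio[:, None] / 2 + delta_d[:, None]),
    }
    for ctx in CONTEXTS:
        tpm[ctx][~expressed] = 0.0

    # Counts: expected count proportional to expression * length/1e3,
    # scaled to the sample's library size.
    lens = {"Ad": len_a, "Dd": len_d, "At": len_a, "Dt": len_d}
    genotype_contexts = {"AA": ["Ad"], "DD": ["Dd"], "AT2": ["At", "Dt"]}
    sheet_rows = []
    count_blocks: dict[str, dict[str, np.ndarray]] = {gt: {} for gt in genotype_contexts}
    for gt, ctxs in genotype_contexts.items():
        weights_by_tissue = {}
        for ti, tissue in enumerate(tissues):
            wvec = np.concatenate([tpm[ctx][:, ti] * lens[ctx] / 1e3 for ctx in ctxs])
            weights_by_tissue[tissue] = wvec
        for tissue in tissues:
            for rep in range(1, config.n_reps + 1):
                sid = f"{gt}_{tissue}_r{rep}"
                sheet_rows.append((sid, gt, tissue, rep))
                lib = rng.normal(config.lib_size_mean, config.lib_size_cv * config.lib_size_mean)
                lib = max(lib, 1000.0)
                wvec = weights_by_tissue[tissue]
                total = wvec.sum()
                mean = wvec / total * lib if total > 0 else np.zeros_like(wvec)
                count_blocks[gt][sid] = _nb_counts(rng, mean, config.dispersion)

    sheet = SampleSheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "genotype", "tissue", "replicate"])
    )
    lengths_all = pd.Series(
        np.concatenate([len_a, len_d]), index=genes_a + genes_d, dtype=int
    )
    counts: dict[str, CountMatrix] = {}
    for gt, ctxs in genotype_contexts.items():
        gene_index = genes_a if ctxs == ["Ad"] else genes_d if ctxs == ["Dd"] else genes_a + genes_d
        df = pd.DataFrame(count_blocks[gt], index=gene_index).astype(np.int64)
        counts[gt] = CountMatrix(df, lengths_all.loc[gene_index])

    truth = pd.DataFrame(
        {
            "pair_id": [f"{a}:{d}" for a, d in zip(genes_a, genes_d)],
            "gene_A": genes_a,
            "gene_D": genes_d,
            "length_A": len_a,
            "length_D": len_d,
            "expressed": expressed,
            "mu_log2": mu,
            "c": c_arr,
            "t": t_arr,
            "mix_ratio": mix_ratio,
            "at2_ratio": at2_ratio,
            "hse_category": categories,
            "heb_trajectory": trajectories,
            "de_A": de_a,
            "de_D": de_d,
        }
    )
    truth = pd.concat([truth, assignment], axis=1)
    return counts, sheet, truth


def annotation_from_truth(truth: pd.DataFrame) -> GeneAnnotation:
    """Subgenome annotation for the generated gene universe."""
    sub = pd.concat(
        [
            pd.Series("A", index=truth["gene_A"].to_numpy()),
            pd.Series("D", index=truth["gene_D"].to_numpy()),
        ]
    )
    sub.index.name = "gene_id"
    return GeneAnnotation(sub)


# ---------------------------------------------------------------------------
# Sequence generator
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    if _CODON_TABLE:
        return _CODON_TABLE
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _single_nt_variants(codon: str, synonymous: bool) -> list[str]:
    table = _build_codon_table()
    aa = table[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            if (table[alt] == aa) == synonymous:
                out.append(alt)
    return out


def _jc_inverse(d: float) -> float:
    """Proportion of sites p that yields Jukes-Cantor distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def generate_sequence_pairs(
    n_pairs: int,
    ks_target: float,
    ka_target: float,
    promoter_div: float,
    seed: int = 0,
    n_codons: int = 200,
    promoter_len: int = 500,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Toy CDS and promoter pairs with controlled divergence.

    ``ks_target``/``ka_target`` are target substitutions per synonymous /
    non-synonymous site (Jukes-Cantor scale); each pair receives a binomial
    number of planted single-nucleotide changes of the corresponding class.
    Targets above 0.5 are refused as saturated. Returns ``(cds, promoters,
    truth)`` where the sequence dicts hold both members of every pair
    (``gA####``/``gD####`` ids).
    """
    for name, v in (("ks_target", ks_target), ("ka_target", ka_target)):
        if not 0.0 <= v <= 0.5:
            raise ValueError(f"{name} must lie in [0, 0.5] (saturation)")
    if not 0.0 <= promoter_div <= 1.0:
        raise ValueError("promoter_div must lie in [0, 1]")

    from .orthology import ng86_site_counts  # deferred: avoids import cycle at module load

    rng = np.random.default_rng(seed)
    sense_codons = sorted(set(_build_codon_table()) - _STOPS)
    cds: dict[str, str] = {}
    promoters: dict[str, str] = {}
    rows = []
    for i in range(n_pairs):
        codons = list(rng.choice(sense_codons, size=n_codons))
        seq_a = "".join(codons)
        syn_sites, nonsyn_sites = ng86_site_counts(seq_a)
        n_syn = rng.binomial(max(int(round(syn_sites)), 1), _jc_inverse(ks_target))
        n_non = rng.binomial(max(int(round(nonsyn_sites)), 1), _jc_inverse(ka_target))
        mutated = list(codons)
        order = rng.permutation(n_codons)
        planted_syn = planted_non = 0
        it = iter(order)
        for want_syn, quota in ((True, n_syn), (False, n_non)):
            planted = 0
            while planted < quota:
                try:
                    j = next(it)
                except StopIteration:
                    break
                variants = _single_nt_variants(mutated[j], synonymous=want_syn)
                if not variants:
                    continue
                mutated[j] = variants[rng.integers(len(variants))]
                planted += 1
            if want_syn:
                planted_syn = planted
            else:
                planted_non = planted
        seq_d = "".join(mutated)

        prom_a = "".join(rng.choice(list(_BASES), size=promoter_len))
        hit = rng.random(promoter_len) < promoter_div
        prom_d = list(prom_a)
        for j in np.flatnonzero(hit):
            prom_d[j] = rng.choice([b for b in _BASES if b != prom_a[j]])
        prom_d = "".join(prom_d)

        ga, gd = f"gA{i:05d}", f"gD{i:05d}"
        cds[ga], cds[gd] = seq_a, seq_d
        promoters[ga], promoters[gd] = prom_a, prom_d
        rows.append(
            {
                "pair_id": f"{ga}:{gd}",
                "gene_A": ga,
                "gene_D": gd,
                "n_syn_planted": planted_syn,
                "n_nonsyn_planted": planted_non,
                "n_promoter_mut": int(hit.sum()),
            }
        )
    return cds, promoters, pd.DataFrame(rows)
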