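# polyshock

Analysis pipeline for **transcriptome shock in a synthetic allopolyploid**:
how gene expression reorganizes when two diploid genomes (an A genome and a
D genome, as in synthetic AADD wheat) are merged into one nucleus. The
package compares the allopolyploid (AT2) against an *in-silico* 1:1 mix of
its diploid parents across nine tissues/developmental stages and three
replicates, and traces, pair by pair of homoeologs, where expression
divergence comes from and how it rewires.

It is written for researchers analyzing polyploid RNA-seq designs who want
every statistical step of such a study — from ortholog pairing to network
rewiring — as tested, reusable library code, exercised end-to-end on a
synthetic-data generator with known ground truth.

## What it computes

For each homoeolog pair, with `Ad`/`Dd` the two orthologs in the parental
mix and `At`/`Dt` the homoeologs in the allopolyploid:

- **Homoeolog pairing** — reciprocal best hit over BLAST-tabular CDS
  alignments (E < 1e−5, ≥ 90 % identity, > 60 % coverage of both CDS), plus
  Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction and promoter
  p-distance.
- **TPM and the parental mix** — TPM normalization; the mix is built at the
  count level by stacking parental replicate counts, so TPM over the union
  gene set reproduces 1:1 read mixing.
- **Differential expression** — a self-contained negative-binomial Wald test
  (median-of-ratios size factors, method-of-moments dispersion, BH FDR);
  DEG = fold change > 2 at FDR < 0.05; DEG ubiquity and direction classes;
  spike-development-related genes (SDRGs) and stably downregulated SDRGs.
- **Homoeolog expression bias (HEB)** — A-vs-D bias per tissue in mix and
  AT2, the four-group trajectory (parental legacy / convergence /
  divergence / reversion), net HEB after subtracting the parental ratio
  (Flagel–Wendel), and stable spike-stage bias.
- **Cis/trans classification (HSE)** — per tissue, `A = log2(Ad/Dd)`
  combines cis and trans divergence, `B = log2(At/Dt)` isolates cis in the
  shared nucleus, and `A − B` estimates trans; three t-tests feed a
  seven-way decision table (conserved, cis-only, trans-only, cis + trans,
  cis × trans, compensatory, ambiguous).
- **Co-expression networks** — WGCNA-style unsigned adjacency `|r|^β`,
  topological overlap, deterministic module detection with eigengene
  merging; homoeolog expression connectivity (HEC: shared-neighbor overlap
  with a hypergeometric test, groups A/B/C); five quadruplet rewiring
  classes; per-module subgenome binomial tests.

The `synthetic_data` module is first-class: it plants cis/trans effects,
bias trajectories, DE, co-expression modules and rewiring classes with
negative-binomial noise, and emits the ground truth used by the test suite
and acceptance script.

## Worked example

```sh
cat > sim.yaml <<'YAML'
out_dir: example_run
simulate:
  n_pairs: 300
  n_modules: 3
  rewiring_mix:
    conserved_same: 0.5
    conserved_different: 0.2
    convergence: 0.15
    divergence: 0.1
    other: 0.05
min_module_size: 20
YAML
polyshock run --config sim.yaml --seed 1
polyshock report --run-dir example_run
```

prints (abridged):

```
                      metric  value
              n_pairs_called    247
   heb_group_parental_legacy   1500
       heb_group_convergence    349
        heb_group_divergence    235
         heb_group_reversion    139
               hse_conserved    607
                hse_cis_only    435
     rewiring_conserved_same     97
              rewiring_other     91
                      n_sdrg    115
          n_sdrg_stably_down     20
```

Reading it: of 300 simulated pairs, 247 pass the TPM > 1 expression filter
and are analyzed in all nine tissues (hence 247 × 9 = 2223 pair–tissue
HEB calls, most of them parental legacy — bias inherited unchanged from
the parents). The HSE counts show the planted mixture of regulatory
categories dominated by conserved and cis-only pairs, and the rewiring
counts reflect the planted module structure of the quadruplet network.
Every stage also writes its full per-gene/per-pair table
(`heb.tsv`, `hse.tsv`, `hec.tsv`, `rewiring.tsv`, `sdrg.tsv`, …) into the
run directory.

The same stages are available as subcommands (`simulate`, `pair`,
`divergence`, `tpm`, `mix`, `ubiquity`, `de`, `run`, `report`) and as
library functions (`polyshock.hse.classify_hse`,
`polyshock.network.hec_score`, …).

## Limitations

Module *identities* are not comparable with a WGCNA run (the dynamic
hybrid tree cut is replaced by a deterministic height sweep); only module
relationships (HEC, rewiring) are interpreted. Real-data figures and
percentages from any particular study depend on the deposited samples and
are not reproduction targets. See `docs/methods.md` for the model,
parameter defaults, and known limitations.
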