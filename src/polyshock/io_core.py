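"""Readers/writers for tabular and sequence formats, sample-sheet model,
configuration and logging.

All on-disk tables are plain TSV (UTF-8, LF line endings, ``.`` decimal);
the gene identifier column is literally named ``gene_id``. Every other
module consumes only the types defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("polyshock")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

GENOTYPES = ("AA", "DD", "AT2", "MIX")

#: The nine tissues/developmental stages, in fixed order: two early seedling
#: tissues, two trefoil-stage tissues, and five successive spike (inflorescence)
#: stages named by spike length in cm.
TISSUES = (
    "primary_root",
    "shoot",
    "root",
    "leaf",
    "spike_0.5",
    "spike_1.0",
    "spike_1.5",
    "spike_2.0",
    "spike_2.5",
)

SPIKE_TISSUES = ("spike_0.5", "spike_1.0", "spike_1.5", "spike_2.0", "spike_2.5")
NON_SPIKE_TISSUES = ("primary_root", "shoot", "root", "leaf")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per sample with genotype, tissue, replicate.

    ``MIX`` samples are always derived in memory (see
    :func:`polyshock.expression.build_mix`), never read from disk.
    """

    table: pd.DataFrame  # columns: sample_id, genotype, tissue, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "genotype", "tissue", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad_gt = set(t["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotype(s): {sorted(bad_gt)}")
        bad_tissue = set(t["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue label(s): {sorted(bad_tissue)}")
        if (t["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        key = t[["genotype", "tissue", "replicate"]]
        if key.duplicated().any():
            row = key.loc[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (genotype, tissue, replicate) triple: "
                f"({row['genotype']}, {row['tissue']}, {row['replicate']})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(
        self,
        genotype: str | None = None,
        tissue: str | None = None,
    ) -> "SampleSheet":
        t = self.table
        if genotype is not None:
            t = t[t["genotype"] == genotype]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return SampleSheet(t.reset_index(drop=True))

    def samples_for(self, genotype: str, tissue: str) -> list[str]:
        """Sample ids for one (genotype, tissue) cell, ordered by replicate."""
        t = self.table
        sel = t[(t["genotype"] == genotype) & (t["tissue"] == tissue)]
        return list(sel.sort_values("replicate")["sample_id"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str, "tissue": str})
    t["replicate"] = t["replicate"].astype(int)
    if (t["genotype"] == "MIX").any():
        raise ValueError("MIX samples are derived, never read from disk")
    sheet = SampleSheet(t)
    log.info("read_sample_sheet: %d samples from %s", len(t), path)
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    _write_tsv(sheet.table, path)


# ---------------------------------------------------------------------------
# Count and expression matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus per-gene lengths (bp)."""

    counts: pd.DataFrame  # index: gene_id, columns: sample_id, dtype int
    gene_length: pd.Series  # index: gene_id, bp

    def __post_init__(self) -> None:
        c = self.counts
        if c.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = c.index.difference(self.gene_length.index)
        if len(missing):
            raise ValueError(f"no gene length for gene {missing[0]!r}")
        self.gene_length = self.gene_length.reindex(c.index)
        if (self.gene_length <= 0).any():
            bad = self.gene_length.index[self.gene_length <= 0][0]
            raise ValueError(f"non-positive gene length for {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.gene_length)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.gene_length.loc[list(gene_ids)])


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM values (non-negative reals), same axes as counts."""

    tpm: pd.DataFrame  # index: gene_id, columns: sample_id

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


def read_counts(path: str | Path, lengths_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix plus a gene-length table.

    The count TSV has a header of sample ids and a first column ``gene_id``;
    the lengths TSV maps ``gene_id`` to ``length`` in bp. Row and column
    order are preserved. A counted gene with no length entry, or a
    non-integral count, is a hard error.
    """
    c = pd.read_csv(path, sep="\t", index_col="gene_id")
    arr = c.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = arr != np.floor(arr)
        if np.isnan(arr).any() or frac.any():
            i, j = np.argwhere(np.isnan(arr) | frac)[0]
            raise ValueError(
                f"non-integer count at gene {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        c = c.astype(np.int64)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length"]
    missing = c.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"gene {missing[0]!r} present in counts but absent from lengths file")
    cm = CountMatrix(c, lengths.loc[c.index].astype(int))
    log.info(
        "read_counts: %d genes x %d samples from %s", len(c), c.shape[1], path
    )
    return cm


def write_counts(cm: CountMatrix, path: str | Path, lengths_path: str | Path | None = None) -> None:
    _write_tsv(cm.counts.reset_index().rename(columns={"index": "gene_id"}), path)
    if lengths_path is not None:
        lt = cm.gene_length.rename("length").reset_index()
        lt.columns = ["gene_id", "length"]
        _write_tsv(lt, lengths_path)


def read_expression(path: str | Path) -> ExpressionMatrix:
    t = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(t.astype(float))


def write_expression(em: ExpressionMatrix, path: str | Path, float_format: str = "%.6g") -> None:
    out = em.tpm.reset_index()
    out.columns = ["gene_id", *em.sample_ids]
    _write_tsv(out, path, float_format=float_format)


# ---------------------------------------------------------------------------
# Gene annotation and sequences
# ---------------------------------------------------------------------------

_CDS_ALPHABET = set("ACGTN")


@dataclass
class GeneAnnotation:
    """Per-gene annotation: subgenome of origin and optional sequences."""

    subgenome: pd.Series  # index: gene_id, values in {"A", "D"}
    cds: dict[str, str] = field(default_factory=dict)
    promoter: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.subgenome.unique()) - {"A", "D"}
        if bad:
            raise ValueError(f"unknown subgenome label(s): {sorted(bad)}")
        for gid, seq in self.cds.items():
            if len(seq) % 3 != 0:
                raise ValueError(f"CDS length of {gid!r} not divisible by 3")
            if set(seq.upper()) - _CDS_ALPHABET:
                raise ValueError(f"CDS of {gid!r} contains non-ACGTN characters")


def read_annotation(
    subgenome_path: str | Path,
    cds_fasta: str | Path | None = None,
    promoter_fasta: str | Path | None = None,
) -> GeneAnnotation:
    t = pd.read_csv(subgenome_path, sep="\t", index_col="gene_id")
    cds = read_fasta(cds_fasta) if cds_fasta else {}
    prom = read_fasta(promoter_fasta) if promoter_fasta else {}
    return GeneAnnotation(t["subgenome"], cds, prom)


def write_annotation(annot: GeneAnnotation, subgenome_path: str | Path) -> None:
    t = annot.subgenome.rename("subgenome").reset_index()
    t.columns = ["gene_id", "subgenome"]
    _write_tsv(t, subgenome_path)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Alignments (BLAST tabular, outfmt 6)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """One HSP from a BLAST outfmt-6 table (12 standard columns)."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Parse a 12-column BLAST outfmt-6 table, preserving record order."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            records.append(
                AlignmentRecord(
                    query=parts[0],
                    subject=parts[1],
                    pct_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
    log.info("read_alignments: %d records from %s", len(records), path)
    return records


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query,
                        r.subject,
                        f"{r.pct_identity:.2f}",
                        str(r.aln_length),
                        str(r.mismatch),
                        str(r.gapopen),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        f"{r.evalue:.2e}",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic TSV / YAML helpers
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=float_format)


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Canonical TSV writer for stage outputs (tab, '.' decimal, LF)."""
    _write_tsv(df, path, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
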