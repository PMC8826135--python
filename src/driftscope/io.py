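"""Readers and writers shared by every stage of the pipeline.

Conventions
-----------
* All in-memory coordinates are 0-based, half-open, on the forward strand of
  the named sequence.  GFF3 is 1-based inclusive on disk and converted on the
  way in and out.
* FASTA is wrapped at 80 columns on write; FASTQ is the plain 4-line dialect
  with Phred+33 qualities.  Files ending in ``.gz`` are compressed/decompressed
  transparently.
* Strand-aware sequence extraction reverse-complements minus-strand features.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_gff3",
    "write_gff3",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_json",
    "write_json",
    "revcomp",
    "extract_transcript",
]

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N passes through)."""
    return seq.translate(_RC)[::-1]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequence content is upper-cased so that round-trips through
    mixed-case, line-wrapped files compare equal at the sequence level.
    """
    with _open(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, seqs: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in items)
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def read_fastq_pairs(path1, path2) -> list[tuple[str, str, str]]:
    """Read paired FASTQ files into ``(name, mate1, mate2)`` tuples.

    Raises ``ValueError`` (naming the offending record) on truncated files
    or on mate-name mismatches.
    """
    pairs: list[tuple[str, str, str]] = []
    with _open(path1, "rt") as fh1, _open(path2, "rt") as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        try:
            for (t1, s1, _q1), (t2, s2, _q2) in zip(it1, it2, strict=True):
                n1 = t1.split()[0].removesuffix("/1")
                n2 = t2.split()[0].removesuffix("/2")
                if n1 != n2:
                    raise ValueError(f"mate name mismatch: {n1!r} vs {n2!r}")
                pairs.append((n1, s1.upper(), s2.upper()))
        except ValueError as exc:
            if "zip()" in str(exc):
                raise ValueError(
                    f"unpaired records after {len(pairs)} pairs "
                    f"({path1} vs {path2})") from exc
            raise
    return pairs


def write_fastq_pairs(path1, path2, pairs: Iterable[tuple[str, str, str]],
                      quality_char: str = "I") -> None:
    with _open(path1, "wt") as fh1, _open(path2, "wt") as fh2:
        for name, s1, s2 in pairs:
            fh1.write(f"@{name}/1\n{s1}\n+\n{quality_char * len(s1)}\n")
            fh2.write(f"@{name}/2\n{s2}\n+\n{quality_char * len(s2)}\n")


# ---------------------------------------------------------------------------
# Gene models / GFF3
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with exon and CDS structure on a named chromosome.

    ``exons`` and ``cds`` are lists of 0-based half-open ``(start, end)``
    intervals on the forward strand, sorted by start.  ``frame`` is the
    frame offset of the first CDS interval.  ``allele_of`` records which
    haplotype the model describes (``standard``, ``driver`` or
    ``other-chromosome``).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    frame: int = 0
    allele_of: str = "standard"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.gene_id}: overlapping exons {a} and {b}")

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exons or self.cds
        return (min(s for s, _ in ivs), max(e for _, e in ivs))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds) - self.frame


def extract_transcript(chrom_seq: str, gene: GeneModel, which: str = "exons") -> str:
    """Spliced transcript (or CDS) sequence of ``gene``, strand-corrected."""
    ivs = gene.exons if which == "exons" else gene.cds
    s = "".join(chrom_seq[a:b] for a, b in ivs)
    if gene.strand == "-":
        s = revcomp(s)
    if which == "cds" and gene.frame:
        s = s[gene.frame:]
    return s


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based inclusive -> 0-based half-open)."""
    genes: dict[str, GeneModel] = {}
    with _open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, phase, attrs = parts
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = GeneModel(
                    gene_id=gid, chromosome=chrom, strand=strand,
                    allele_of=attr.get("allele_of", "standard"))
            elif ftype in ("exon", "CDS"):
                gid = attr.get("Parent") or attr["ID"]
                g = genes[gid]
                if ftype == "exon":
                    g.exons.append(iv)
                    g.exons.sort()
                else:
                    g.cds.append(iv)
                    g.cds.sort()
                    if phase not in (".", ""):
                        g.frame = int(phase)
    return list(genes.values())


def write_gff3(path, genes: Sequence[GeneModel]) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write("\t".join([
                g.chromosome, "driftscope", "gene", str(s + 1), str(e),
                ".", g.strand, ".", f"ID={g.gene_id};allele_of={g.allele_of}"]) + "\n")
            for a, b in g.exons:
                fh.write("\t".join([
                    g.chromosome, "driftscope", "exon", str(a + 1), str(b),
                    ".", g.strand, ".", f"Parent={g.gene_id}"]) + "\n")
            for i, (a, b) in enumerate(g.cds):
                phase = str(g.frame if i == 0 else 0)
                fh.write("\t".join([
                    g.chromosome, "driftscope", "CDS", str(a + 1), str(b),
                    ".", g.strand, phase, f"Parent={g.gene_id}"]) + "\n")


# ---------------------------------------------------------------------------
# Sample sheets and JSON manifests
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "genotype", "modality", "tissue", "fastq1", "fastq2"]


def read_sample_sheet(path, check_files: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    bad = df[(df["modality"] == "RNA") & (df["tissue"] == "NA")]
    if len(bad):
        raise ValueError(f"RNA samples without tissue: {bad['sample_id'].tolist()}")
    if check_files:
        base = Path(path).parent
        for col in ("fastq1", "fastq2"):
            for p in df[col]:
                if p != "NA" and not (base / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(p)
    return df[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(path, df: pd.DataFrame) -> None:
    df[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_json(path):
    with _open(path, "rt") as fh:
        return json.load(fh)


def write_json(path, obj) -> None:
    with _open(path, "wt") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
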