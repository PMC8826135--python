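"""Synthetic diploid carrier/control cohorts with a diverged driver haplotype.

The generator emulates the study design the pipeline is built for: a focal
chromosome whose "driver" haplotype is diverged from the standard copy at a
configurable per-site rate (default 0.022), does not recombine, carries
tandem copy-number gains, one or two genes translocated from another
chromosome (one intact with elevated nonsynonymous divergence, one truncated
to a short ORF), and premature STOP codons planted in a minority of driver
alleles.  Carriers are +/driver heterozygotes; controls carry two standard
copies.  Paired-end DNA and RNA libraries are simulated with truth encoded
in every read name, and a truth manifest records gene classes, fold
changes, variants, CNV intervals and gained genes for downstream
evaluation.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .io import GeneModel, revcomp
from .molevol import SENSE_CODONS, STOP_CODONS, AA, _CodonModel

__all__ = [
    "CohortConfig",
    "LibrarySpec",
    "Library",
    "GenomePair",
    "SyntheticDataset",
    "mutate_haplotype",
    "simulate_reads",
    "build_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass
class LibrarySpec:
    """Parameters of one sequencing library."""

    sample_id: str
    genotype: str               # carrier | control
    modality: str               # DNA | RNA
    tissue: str | None = None
    read_length: int = 91
    fragment_mean: float = 180.0
    fragment_sd: float = 10.0
    error_rate: float = 0.0
    n_pairs: int = 1000
    random_orientation: bool = False
    seed: int = 0


@dataclass
class Library:
    spec: LibrarySpec
    pairs: list[tuple[str, str, str]]


@dataclass
class GenomePair:
    """Standard chromosomes plus the structurally edited driver haplotype.

    ``variant_list`` holds every substitution distinguishing the driver from
    the standard focal chromosome as (position, ref, alt) in standard
    coordinates; structural events (tandem gains, translocated insertions)
    are recorded separately in ``cnv_truth`` and ``gained_genes``.
    """

    standard: dict[str, str]
    driver_seq: str
    focal_chromosome: str
    variant_list: list[tuple[int, str, str]]
    gained_genes: list[tuple[str, int, str]]       # (source gene, locus, intact|truncated)
    cnv_truth: list[tuple[str, int, int, int]]     # (chrom, start, end, extra copies)


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort (defaults are the standard run).

    Divergence, read geometry, cohort sizes and truth-class counts default
    to the conditions the pipeline is designed around: a 0.022-per-site
    driver divergence, 91 bp paired reads with 180 +/- 10 bp fragments,
    four RNA mice per genotype across four tissues, six DNA mice per
    genotype at ~30x combined depth, 20 genes per expression class, five
    tandem copy gains centred on increased-class genes and two translocated
    gains.
    """

    seed: int = 0
    # gene content
    n_conserved: int = 20
    n_decreased: int = 20
    n_increased: int = 20
    cds_codons: int = 200
    utr_len: int = 30
    spacer_len: int = 3400
    focal_chromosome: str = "chr17"
    other_chromosome: str = "chr5"
    # divergence and structure
    divergence: float = 0.022
    n_cnv_gains: int = 5
    cnv_extra_copies: int = 1
    cnv_flank: int = 5700
    n_gained_genes: int = 2
    n_premature_stop: int = 3
    gained_nonsyn_subs: int = 20
    gained_syn_subs: int = 5
    truncated_codons: int = 80
    # outgroups (for molecular-evolution truth)
    outgroup1_branch: float = 0.15   # expected substitutions per codon
    outgroup2_branch: float = 0.50
    outgroup_omega: float = 0.2
    outgroup_kappa: float = 2.0
    # expression truth
    tissues: tuple[str, ...] = ("testis", "brain", "liver", "spleen")
    decreased_fold: float = 0.25
    increased_fold: float = 4.0
    expression_cv: float = 0.10
    base_mean: float = 30.0
    base_sigma: float = 0.5
    tissue_sigma: float = 0.3
    off_tissue_prob: float = 0.15
    gained_expression: float = 300.0
    # background transcriptome (non-focal genes expressed equally in both
    # genotypes); keeps the focal complement a small share of the TPM
    # denominator, as in a genome-wide transcriptome
    n_background_genes: int = 10
    background_mean: float = 1050.0
    # libraries
    n_rna_per_genotype: int = 4
    n_dna_per_genotype: int = 6
    rna_pairs_per_library: int = 12000
    dna_depth: float = 30.0
    read_length: int = 91
    fragment_mean: float = 180.0
    fragment_sd: float = 10.0
    error_rate: float = 0.0

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A null cohort: no divergence, no structural events, no folds."""
        base = dict(n_conserved=30, n_decreased=0, n_increased=0,
                    divergence=0.0, n_cnv_gains=0, n_gained_genes=0,
                    n_premature_stop=0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        tis = data.get("tissues")
        if tis is not None:
            data["tissues"] = tuple(tis)
        return cls(**data)

    def validate(self) -> None:
        if not 0 <= self.divergence < 0.25:
            raise ConfigError(f"divergence must be in [0, 0.25), got {self.divergence}")
        if self.n_decreased > 0 and not self.decreased_fold < 1:
            raise ConfigError("decreased-class genes require a fold change < 1")
        if self.n_increased > 0 and not self.increased_fold > 1:
            raise ConfigError("increased-class genes require a fold change > 1")
        if self.n_gained_genes not in (0, 1, 2):
            raise ConfigError("n_gained_genes must be 0, 1 or 2")
        if self.n_premature_stop > self.n_decreased:
            raise ConfigError("cannot plant more premature STOPs than decreased genes")
        if self.n_cnv_gains > self.n_increased:
            raise ConfigError("copy gains are centred on increased-class genes")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def mutate_haplotype(seq: str, divergence: float = 0.022,
                     rng: np.random.Generator | int = 0
                     ) -> tuple[str, list[tuple[int, str, str]]]:
    """Substitute sites independently at the given per-site rate (no indels).

    Returns the diverged sequence and the variant list (position, ref, alt).
    The substituted base is uniform over the three alternatives.
    """
    if not 0 <= divergence < 0.25:
        raise ConfigError(f"divergence must be in [0, 0.25), got {divergence}")
    if not seq:
        raise ConfigError("sequence must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < divergence)
    variants: list[tuple[int, str, str]] = []
    if len(hit):
        code = np.searchsorted(_BASES, arr[hit])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, size=len(hit))
        new = _BASES[(code + shift) % 4]
        for pos, old, nb in zip(hit.tolist(), arr[hit].tolist(), new.tolist()):
            variants.append((pos, chr(old), chr(nb)))
        arr[hit] = new
    return arr.tobytes().decode("ascii"), variants


def simulate_reads(spec: LibrarySpec,
                   sources: Sequence[tuple[str, str, float]],
                   rng: np.random.Generator | int = 0
                   ) -> list[tuple[str, str, str]]:
    """Paired-end reads from weighted source sequences.

    Fragment lengths are Normal(fragment_mean, fragment_sd) rounded,
    truncated into [20, source length]; fragments shorter than the read
    length yield mates clipped to the fragment (read-through).  Mate 2 is
    the reverse complement of the fragment end.  With
    ``spec.random_orientation`` the fragment strand is flipped with
    probability 1/2 (double-stranded DNA).  Substitution errors are applied
    per base at ``spec.error_rate``.  Read names encode the true source as
    ``sample|source|start|fragment_length|index`` (positions refer to the
    forward strand of the source).
    """
    sources = [s for s in sources if len(s[1]) >= 20 and s[2] > 0]
    if not sources:
        raise ValueError("empty source set")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    weights = np.array([w for _, _, w in sources], dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(spec.n_pairs, weights)
    rl = spec.read_length
    pairs: list[tuple[str, str, str]] = []
    idx = 0
    for (name, seq, _w), n in zip(sources, counts):
        if n == 0:
            continue
        L = len(seq)
        frags = np.rint(rng.normal(spec.fragment_mean, spec.fragment_sd, size=n))
        frags = np.clip(frags, 20, L).astype(np.int64)
        starts = (rng.random(n) * (L - frags + 1)).astype(np.int64)
        flips = (rng.random(n) < 0.5) if spec.random_orientation else np.zeros(n, bool)
        for fl, st, flip in zip(frags.tolist(), starts.tolist(), flips.tolist()):
            frag = seq[st:st + fl]
            if flip:
                frag = revcomp(frag)
            m1 = frag[:rl]
            m2 = revcomp(frag)[:rl]
            pairs.append((f"{spec.sample_id}|{name}|{st}|{fl}|{idx}", m1, m2))
            idx += 1
    if spec.error_rate > 0:
        noisy = []
        for name, m1, m2 in pairs:
            noisy.append((name, _add_errors(m1, spec.error_rate, rng),
                          _add_errors(m2, spec.error_rate, rng)))
        pairs = noisy
    return pairs


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit):
        code = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(code + rng.integers(1, 4, size=len(hit))) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS),
                                                  size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _evolve_cds(cds: str, t: float, model: _CodonModel, kappa: float,
                omega: float, rng: np.random.Generator) -> str:
    """Evolve a CDS (keeping its final STOP) under the codon model."""
    core = cds[:-3]
    states = np.array([SENSE_CODONS.index(core[i:i + 3])
                       for i in range(0, len(core), 3)])
    P = model.transition(kappa, omega, t)
    out = np.empty_like(states)
    for s in np.unique(states):
        m = states == s
        out[m] = rng.choice(len(SENSE_CODONS), size=int(m.sum()), p=P[s])
    return "".join(SENSE_CODONS[i] for i in out) + cds[-3:]


@dataclass
class SyntheticDataset:
    """A complete simulated cohort plus its ground truth."""

    config: CohortConfig
    genome: GenomePair
    gene_models: list[GeneModel]
    std_transcripts: dict[str, str]        # gene -> standard-allele transcript
    drv_transcripts: dict[str, str]        # gene -> driver-allele transcript
    std_cds: dict[str, str]
    drv_cds: dict[str, str]
    outgroup_cds: dict[str, dict[str, str]]
    gained_transcripts: dict[str, str]     # "gained|<source gene>" -> transcript
    truth_class: dict[str, str]            # focal gene -> conserved|decreased|increased
    truth_fold: dict[str, dict[str, float]]
    truth_base: dict[str, dict[str, float]]
    truth_divergence: dict[str, float]     # per-gene transcript divergence
    premature_stop_genes: list[str]
    libraries: list[Library]
    sample_sheet: pd.DataFrame

    # -- convenience views -------------------------------------------------
    def rna_libraries(self, genotype: str | None = None) -> list[Library]:
        out = [l for l in self.libraries if l.spec.modality == "RNA"]
        if genotype:
            out = [l for l in out if l.spec.genotype == genotype]
        return out

    def dna_libraries(self, genotype: str | None = None) -> list[Library]:
        out = [l for l in self.libraries if l.spec.modality == "DNA"]
        if genotype:
            out = [l for l in out if l.spec.genotype == genotype]
        return out

    @property
    def focal_genes(self) -> list[str]:
        return sorted(self.truth_class)

    def truth_manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["tissues"] = list(cfg["tissues"])
        genes = {}
        for g in self.focal_genes:
            genes[g] = {
                "class": self.truth_class[g],
                "fold": self.truth_fold[g],
                "base": self.truth_base[g],
                "divergence": self.truth_divergence[g],
                "premature_stop": g in self.premature_stop_genes,
            }
        return {
            "config": cfg,
            "genes": genes,
            "variants": [list(v) for v in self.genome.variant_list],
            "cnv": [list(c) for c in self.genome.cnv_truth],
            "gained": [list(g) for g in self.genome.gained_genes],
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_fasta(out / "genome_standard.fa", self.genome.standard)
        dio.write_fasta(out / "genome_driver.fa",
                        {self.genome.focal_chromosome + "_driver": self.genome.driver_seq})
        dio.write_fasta(out / "transcripts_standard.fa", self.std_transcripts)
        dio.write_fasta(out / "transcripts_driver.fa", self.drv_transcripts)
        if self.gained_transcripts:
            dio.write_fasta(out / "transcripts_gained.fa", self.gained_transcripts)
        dio.write_gff3(out / "genes.gff3", self.gene_models)
        rows = []
        for lib in self.libraries:
            f1 = f"{lib.spec.sample_id}_1.fastq"
            f2 = f"{lib.spec.sample_id}_2.fastq"
            dio.write_fastq_pairs(out / f1, out / f2, lib.pairs)
            rows.append({"sample_id": lib.spec.sample_id,
                         "genotype": lib.spec.genotype,
                         "modality": lib.spec.modality,
                         "tissue": lib.spec.tissue or "NA",
                         "fastq1": f1, "fastq2": f2})
        dio.write_sample_sheet(out / "samples.tsv", pd.DataFrame(rows))
        dio.write_json(out / "truth.json", self.truth_manifest())


def build_cohort(config: CohortConfig | None = None) -> SyntheticDataset:
    """Generate a full cohort (genomes, truth tables, DNA and RNA libraries).

    Deterministic given ``config.seed``; rejects inconsistent configs.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_expr, rng_lib = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_genes = cfg.n_conserved + cfg.n_decreased + cfg.n_increased
    classes = (["conserved"] * cfg.n_conserved + ["decreased"] * cfg.n_decreased
               + ["increased"] * cfg.n_increased)
    rng_genome.shuffle(classes)
    gene_ids = [f"g{i + 1:03d}" for i in range(n_genes)]
    truth_class = dict(zip(gene_ids, classes))

    # --- focal chromosome -------------------------------------------------
    strands = ["+" if rng_genome.random() < 0.7 else "-" for _ in gene_ids]
    std_cds = {g: _random_cds(rng_genome, cfg.cds_codons) for g in gene_ids}
    gene_models: list[GeneModel] = []
    parts: list[str] = []
    pos = 0
    tx_len = 2 * cfg.utr_len + 3 * cfg.cds_codons
    for g, strand in zip(gene_ids, strands):
        parts.append(_random_seq(rng_genome, cfg.spacer_len))
        pos += cfg.spacer_len
        utr5 = _random_seq(rng_genome, cfg.utr_len)
        utr3 = _random_seq(rng_genome, cfg.utr_len)
        tx = utr5 + std_cds[g] + utr3
        genomic = tx if strand == "+" else revcomp(tx)
        parts.append(genomic)
        if strand == "+":
            cds_iv = (pos + cfg.utr_len, pos + cfg.utr_len + len(std_cds[g]))
        else:
            cds_iv = (pos + cfg.utr_len, pos + tx_len - cfg.utr_len)
        gene_models.append(GeneModel(
            gene_id=g, chromosome=cfg.focal_chromosome, strand=strand,
            exons=[(pos, pos + tx_len)], cds=[cds_iv], allele_of="standard"))
        pos += tx_len
    parts.append(_random_seq(rng_genome, cfg.spacer_len))
    chr_std = "".join(parts)

    # --- other chromosome: translocation sources + background genes -------
    source_ids = [f"gx{i + 1:03d}" for i in range(2)]
    background_ids = [f"bg{i + 1:03d}" for i in range(cfg.n_background_genes)]
    src_cds = {g: _random_cds(rng_genome, cfg.cds_codons)
               for g in source_ids + background_ids}
    parts5: list[str] = []
    pos5 = 0
    for g in source_ids + background_ids:
        parts5.append(_random_seq(rng_genome, cfg.spacer_len))
        pos5 += cfg.spacer_len
        tx = (_random_seq(rng_genome, cfg.utr_len) + src_cds[g]
              + _random_seq(rng_genome, cfg.utr_len))
        parts5.append(tx)
        gene_models.append(GeneModel(
            gene_id=g, chromosome=cfg.other_chromosome, strand="+",
            exons=[(pos5, pos5 + tx_len)],
            cds=[(pos5 + cfg.utr_len, pos5 + cfg.utr_len + len(src_cds[g]))],
            allele_of="other-chromosome"))
        pos5 += tx_len
    parts5.append(_random_seq(rng_genome, cfg.spacer_len))
    chr_other = "".join(parts5)

    # --- driver haplotype: point divergence ------------------------------
    drv_base, variants = mutate_haplotype(chr_std, cfg.divergence, rng_genome)
    drv_arr = list(drv_base)

    models_by_gene = {m.gene_id: m for m in gene_models}

    def set_codon(gene: str, codon_idx: int, codon: str) -> None:
        m = models_by_gene[gene]
        cs, ce = m.cds[0]
        if m.strand == "+":
            gpos = cs + 3 * codon_idx
            new = codon
        else:
            gpos = ce - 3 * (codon_idx + 1)
            new = revcomp(codon)
        for off, b in enumerate(new):
            old = drv_arr[gpos + off]
            if old != b:
                variants.append((gpos + off, chr_std[gpos + off], b))
            drv_arr[gpos + off] = b

    decreased = [g for g in gene_ids if truth_class[g] == "decreased"]
    premature = decreased[: cfg.n_premature_stop]
    for g in premature:
        set_codon(g, cfg.cds_codons // 2, "TAA")
    drv_base = "".join(drv_arr)

    # driver-allele transcripts/CDS (point edits only, so standard
    # coordinates remain valid on the pre-structural driver sequence)
    drv_transcripts, std_transcripts, drv_cds = {}, {}, {}
    for m in gene_models:
        if m.chromosome != cfg.focal_chromosome:
            continue
        g = m.gene_id
        std_transcripts[g] = dio.extract_transcript(chr_std, m)
        drv_transcripts[g] = dio.extract_transcript(drv_base, m)
        drv_cds[g] = dio.extract_transcript(drv_base, m, which="cds")
    truth_divergence = {}
    for g in std_transcripts:
        a = np.frombuffer(std_transcripts[g].encode(), dtype=np.uint8)
        b = np.frombuffer(drv_transcripts[g].encode(), dtype=np.uint8)
        truth_divergence[g] = float(np.count_nonzero(a != b) / len(a))

    # --- structural events -------------------------------------------------
    increased = [g for g in gene_ids if truth_class[g] == "increased"]
    cnv_genes: list[str] = []
    cnv_truth: list[tuple[str, int, int, int]] = []
    taken: list[tuple[int, int]] = []
    for g in increased:
        if len(cnv_genes) >= cfg.n_cnv_gains:
            break
        s, e = models_by_gene[g].span
        iv = (max(0, s - cfg.cnv_flank), min(len(chr_std), e + cfg.cnv_flank))
        if any(iv[0] < t1 and t0 < iv[1] for t0, t1 in taken):
            continue
        cnv_genes.append(g)
        taken.append(iv)
        cnv_truth.append((cfg.focal_chromosome, iv[0], iv[1], cfg.cnv_extra_copies))

    gained: list[tuple[str, int, str]] = []
    gained_transcripts: dict[str, str] = {}
    gained_cds: dict[str, str] = {}
    if cfg.n_gained_genes >= 1:
        # intact copy with elevated nonsynonymous divergence
        g = source_ids[0]
        cds = src_cds[g]
        core = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
        n_cod = len(core)
        picks = rng_genome.choice(np.arange(1, n_cod),
                                  size=cfg.gained_nonsyn_subs
                                  + cfg.gained_syn_subs, replace=False)
        for rank, ci in enumerate(picks.tolist()):
            want_syn = rank >= cfg.gained_nonsyn_subs
            cur = core[ci]
            opts = []
            for p in range(3):
                for b in "ACGT":
                    if b == cur[p]:
                        continue
                    alt = cur[:p] + b + cur[p + 1:]
                    if alt in STOP_CODONS:
                        continue
                    if (AA[alt] == AA[cur]) == want_syn:
                        opts.append(alt)
            if opts:
                core[ci] = opts[int(rng_genome.integers(0, len(opts)))]
        new_cds = "".join(core) + cds[-3:]
        tx = (_random_seq(rng_genome, cfg.utr_len) + new_cds
              + _random_seq(rng_genome, cfg.utr_len))
        gained_transcripts[f"gained|{g}"] = tx
        gained_cds[f"gained|{g}"] = new_cds
        gained.append((g, 0, "intact"))
    if cfg.n_gained_genes >= 2:
        # truncated copy: a nonsense codon truncates the ORF to a short
        # peptide while the transcript itself stays (near) full-length
        g = source_ids[1]
        cds = src_cds[g]
        nonsense = (cds[: 3 * cfg.truncated_codons] + "TAA"
                    + cds[3 * cfg.truncated_codons + 3:])
        arr = list(nonsense)
        n_subs = max(5, int(round(cfg.divergence * len(arr))))
        for p in rng_genome.choice(np.arange(3, len(arr) - 3), size=n_subs,
                                   replace=False).tolist():
            arr[p] = "ACGT"[(("ACGT".index(arr[p])) + 1
                             + int(rng_genome.integers(0, 3))) % 4]
        nonsense = "".join(arr)
        tx = (_random_seq(rng_genome, cfg.utr_len) + nonsense
              + _random_seq(rng_genome, cfg.utr_len))
        gained_transcripts[f"gained|{g}"] = tx
        gained_cds[f"gained|{g}"] = nonsense[: 3 * cfg.truncated_codons + 3]
        gained.append((g, 0, "truncated"))

    # choose insertion loci in spacers away from CNV intervals, then apply
    # all edits right to left so earlier coordinates stay valid
    edits: list[tuple[int, str]] = []
    spacer_mids = [models_by_gene[g].span[1] + cfg.spacer_len // 2
                   for g in gene_ids[:-1]]
    free_mids = [p for p in spacer_mids
                 if not any(t0 - 200 < p < t1 + 200 for t0, t1 in taken)]
    for i, (g, _locus, flag) in enumerate(gained):
        locus = free_mids[(i + 1) * len(free_mids) // (len(gained) + 1)]
        gained[i] = (g, locus, flag)
        edits.append((locus, gained_transcripts[f"gained|{g}"]))
    for chrom, s, e, extra in cnv_truth:
        for _ in range(extra):
            edits.append((e, drv_base[s:e]))
    driver_final = drv_base
    for p, ins in sorted(edits, key=lambda x: -x[0]):
        driver_final = driver_final[:p] + ins + driver_final[p:]

    genome = GenomePair(
        standard={cfg.focal_chromosome: chr_std, cfg.other_chromosome: chr_other},
        driver_seq=driver_final, focal_chromosome=cfg.focal_chromosome,
        variant_list=sorted(variants), gained_genes=gained, cnv_truth=cnv_truth)

    # --- outgroup CDSs for molecular evolution ----------------------------
    model = _CodonModel(np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS)))
    outgroup_cds: dict[str, dict[str, str]] = {}
    for g in gene_ids:
        outgroup_cds[g] = {
            "out1": _evolve_cds(std_cds[g], cfg.outgroup1_branch, model,
                                cfg.outgroup_kappa, cfg.outgroup_omega, rng_genome),
            "out2": _evolve_cds(std_cds[g], cfg.outgroup2_branch, model,
                                cfg.outgroup_kappa, cfg.outgroup_omega, rng_genome),
        }
    for g in source_ids:
        outgroup_cds[g] = {
            "out1": _evolve_cds(src_cds[g], cfg.outgroup1_branch, model,
                                cfg.outgroup_kappa, cfg.outgroup_omega, rng_genome),
            "out2": _evolve_cds(src_cds[g], cfg.outgroup2_branch, model,
                                cfg.outgroup_kappa, cfg.outgroup_omega, rng_genome),
        }

    # --- expression truth --------------------------------------------------
    tissues = list(cfg.tissues)
    truth_base: dict[str, dict[str, float]] = {}
    truth_fold: dict[str, dict[str, float]] = {}
    for g in gene_ids:
        base_g = float(np.exp(rng_expr.normal(np.log(cfg.base_mean), cfg.base_sigma)))
        base = {}
        fold = {}
        cls = truth_class[g]
        n_aff = min(len(tissues), 1 + int(rng_expr.random() < 0.4))
        affected = set(rng_expr.choice(tissues, size=n_aff, replace=False).tolist()) \
            if cls != "conserved" else set()
        for t in tissues:
            b = base_g * float(np.exp(rng_expr.normal(0, cfg.tissue_sigma)))
            if t not in affected and rng_expr.random() < cfg.off_tissue_prob:
                b *= 1e-5  # effectively silent tissue
            base[t] = b
            if g in cnv_genes:
                fold[t] = float(1 + cfg.cnv_extra_copies)  # dosage from copy gain
            elif t in affected and cls == "decreased":
                fold[t] = cfg.decreased_fold
            elif t in affected and cls == "increased":
                fold[t] = cfg.increased_fold
            else:
                fold[t] = 1.0
        truth_base[g] = base
        truth_fold[g] = fold
    _check_truth_consistency(truth_class, truth_fold)

    gained_tissue = {"intact": tissues[0], "truncated": tissues[1 % len(tissues)]}
    src_base = {g: cfg.base_mean for g in source_ids}
    src_base.update({g: cfg.background_mean for g in background_ids})

    # --- libraries ----------------------------------------------------------
    libraries: list[Library] = []
    rl = cfg.read_length
    copies = {
        "carrier": [(cfg.focal_chromosome + "_std", chr_std, 1),
                    (cfg.focal_chromosome + "_drv", driver_final, 1),
                    (cfg.other_chromosome, chr_other, 2)],
        "control": [(cfg.focal_chromosome + "_std", chr_std, 2),
                    (cfg.other_chromosome, chr_other, 2)],
    }
    gcode = {"carrier": "c", "control": "n"}
    lib_seeds = iter(ss.spawn(2 * cfg.n_dna_per_genotype
                              + 2 * cfg.n_rna_per_genotype * len(tissues)))
    for genotype in ("carrier", "control"):
        for i in range(cfg.n_dna_per_genotype):
            sources = [(name, seq, float(len(seq) * c))
                       for name, seq, c in copies[genotype]]
            haploid_total = sum(w for _, _, w in sources)
            n_pairs = int(round(cfg.dna_depth * haploid_total / (4 * rl)))
            spec = LibrarySpec(
                sample_id=f"dna_{gcode[genotype]}{i + 1}", genotype=genotype,
                modality="DNA", read_length=rl,
                fragment_mean=cfg.fragment_mean, fragment_sd=cfg.fragment_sd,
                error_rate=cfg.error_rate, n_pairs=n_pairs,
                random_orientation=True)
            rng = np.random.default_rng(next(lib_seeds))
            libraries.append(Library(spec, simulate_reads(spec, sources, rng)))
    eff = max(tx_len - cfg.fragment_mean + 1.0, 1.0)
    for genotype in ("carrier", "control"):
        for i in range(cfg.n_rna_per_genotype):
            mouse = f"rna_{gcode[genotype]}{i + 1}"
            for tissue in tissues:
                rng = np.random.default_rng(next(lib_seeds))
                sources = []
                sigma = np.sqrt(np.log(1 + cfg.expression_cv ** 2))
                for g in gene_ids:
                    noise_s = float(np.exp(rng.normal(0, sigma)))
                    b = truth_base[g][tissue]
                    if genotype == "carrier":
                        noise_d = float(np.exp(rng.normal(0, sigma)))
                        sources.append((f"tx|{g}|standard",
                                        std_transcripts[g], b * noise_s * eff))
                        sources.append((f"tx|{g}|driver", drv_transcripts[g],
                                        b * truth_fold[g][tissue] * noise_d * eff))
                    else:
                        sources.append((f"tx|{g}|standard",
                                        std_transcripts[g], 2 * b * noise_s * eff))
                for g in source_ids + background_ids:
                    noise = float(np.exp(rng.normal(0, sigma)))
                    m = models_by_gene[g]
                    sources.append((f"tx|{g}|standard",
                                    dio.extract_transcript(chr_other, m),
                                    2 * src_base[g] * noise * eff))
                if genotype == "carrier":
                    for g, _locus, flag in gained:
                        if gained_tissue[flag] == tissue:
                            noise = float(np.exp(rng.normal(0, sigma)))
                            tx = gained_transcripts[f"gained|{g}"]
                            eff_g = max(len(tx) - cfg.fragment_mean + 1.0, 1.0)
                            sources.append((f"tx|{g}|gained", tx,
                                            cfg.gained_expression * noise * eff_g))
                spec = LibrarySpec(
                    sample_id=f"{mouse}_{tissue}", genotype=genotype,
                    modality="RNA", tissue=tissue, read_length=rl,
                    fragment_mean=cfg.fragment_mean, fragment_sd=cfg.fragment_sd,
                    error_rate=cfg.error_rate, n_pairs=cfg.rna_pairs_per_library)
                libraries.append(Library(spec, simulate_reads(spec, sources, rng)))

    sheet = pd.DataFrame([{
        "sample_id": l.spec.sample_id, "genotype": l.spec.genotype,
        "modality": l.spec.modality, "tissue": l.spec.tissue or "NA",
        "fastq1": f"{l.spec.sample_id}_1.fastq",
        "fastq2": f"{l.spec.sample_id}_2.fastq"} for l in libraries])

    ds = SyntheticDataset(
        config=cfg, genome=genome, gene_models=gene_models,
        std_transcripts=std_transcripts, drv_transcripts=drv_transcripts,
        std_cds=std_cds | src_cds, drv_cds=drv_cds | gained_cds,
        outgroup_cds=outgroup_cds, gained_transcripts=gained_transcripts,
        truth_class=truth_class, truth_fold=truth_fold, truth_base=truth_base,
        truth_divergence=truth_divergence, premature_stop_genes=premature,
        libraries=libraries, sample_sheet=sheet)
    return ds


def _check_truth_consistency(truth_class: Mapping[str, str],
                             truth_fold: Mapping[str, Mapping[str, float]]) -> None:
    for g, cls in truth_class.items():
        folds = list(truth_fold[g].values())
        if cls == "decreased":
            if not any(f < 1 for f in folds) or any(f > 1 for f in folds):
                raise ConfigError(f"{g}: decreased class inconsistent with folds {folds}")
        elif cls == "increased":
            if not any(f > 1 for f in folds):
                raise ConfigError(f"{g}: increased class inconsistent with folds {folds}")
        elif any(f != 1 for f in folds):
            raise ConfigError(f"{g}: conserved class inconsistent with folds {folds}")
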