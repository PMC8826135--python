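# Methods

`driftscope` reconstructs, at desk scale and on fully synthetic data, the
analysis a carrier/control sequencing study performs on a non-recombining
"driver" haplotype such as the mouse *t*-haplotype: discovering
haplotype-specific transcripts from heterozygous carriers, quantifying
allele-specific expression (ASE) with a control-derived misassignment
correction, classifying per-gene expression changes, estimating
branch-specific protein evolution (dN/dS), and calling copy-number gains
from read depth.  This note records the models, the defaults and why they
were chosen, and what the synthetic cohorts do and do not establish about
real data.

## The synthetic cohort

A cohort consists of a focal chromosome carrying 60 single-exon genes
(20 per expression class), a second chromosome carrying translocation
source genes plus a background transcriptome, and two haplotypes of the
focal chromosome:

* the **standard** haplotype is the reference;
* the **driver** haplotype is derived from it by independent per-site
  substitutions at rate 0.022 (uniform over the three alternative bases),
  followed by structural edits: five tandem duplications (~12 kb each,
  centred on increased-class genes, +1 extra copy), the insertion of two
  genes copied from the other chromosome (one intact with ~20
  nonsynonymous and 5 synonymous substitutions, one with a nonsense codon
  truncating the ORF to 80 amino acids plus further substitutions at the
  cohort divergence), and premature STOP codons planted mid-CDS in three
  decreased-class driver alleles.

Carriers are standard/driver heterozygotes; controls carry two standard
copies.  Genes are 600 bp CDS plus 30 bp UTRs; intergenic spacers are
3.4 kb, so the five duplications cover about a quarter of the chromosome
(this matters for the median normalization in the CNV caller, below).
About 30% of genes lie on the minus strand so strand handling is
exercised everywhere.

**Expression truth.**  Per (gene, tissue) a base abundance is drawn
log-normally (median 30 units, sigma 0.5, tissue factor sigma 0.3; a
tissue is silenced with probability 0.15).  The driver allele's fold
change is 1 (conserved), 0.25 in one or two tissues (decreased), 4
(increased), or `1 + extra copies` in all tissues for duplicated genes
(dosage).  Translocated copies are expressed carrier-only, in a single
tissue, at a high level (300 units).  Ten background genes at 1,050
units per copy, identical in both genotypes, keep the focal complement a
small share (~15%) of each library: TPM is compositional, and without
this background the extra carrier-only expression would deflate every
carrier TPM by tens of percent — a regime the real study never enters
because its focal region is a sliver of the whole transcriptome.

**Libraries.**  Paired-end 91 bp reads, fragments Normal(180, 10)
truncated into [20, source length] (mates clip to short fragments), flat
Phred+33 quality, substitution errors at a configurable rate (0 by
default — the filters under test are about divergence, not error
correction).  RNA libraries are strand-specific (mate 1 forward); DNA
fragments are strand-flipped at random.  Each read name encodes sample,
true source sequence, fragment start and length, which is what all
truth-recovery tests consume.  Defaults: 4 RNA mice per genotype x 4
tissues at 12,000 pairs per library; 6 DNA mice per genotype at ~30x
combined diploid depth.  Everything derives from one seed through spawned
generator streams, so cohorts and the full pipeline report are
byte-reproducible.

**Outgroups.**  For dN/dS each gene carries two outgroup CDSs evolved
from the standard CDS under the codon model (0.15 and 0.50 expected
substitutions per codon, omega 0.2, kappa 2).  Because the point
divergence is placed entirely on the driver lineage, the standard branch
has essentially zero length in fitted trees; per-gene tests in the
pipeline therefore contrast the driver branch against the shared
background rather than driver-vs-standard (both parameterizations are
available in the library).

## Discovery

Three complementary strategies, run independently and merged with
provenance:

1. **diverged**: carrier RNA pairs whose mates both fail to map with
   fewer than three mismatches against the standard reference;
2. **k-mer**: canonical 31-mers present in every carrier library (RNA
   pooled per mouse across tissues, mirroring multi-tissue pools) and
   absent from every control library select carrier RNA pairs that share
   at least 30% of their k-mers with the set (either mate qualifies);
3. **unfiltered**: all carrier RNA reads.

Reads are assembled by a deterministic greedy overlap assembler (exact
suffix/prefix overlaps >= 40 bp, longest first, lexicographic
tie-breaks).  Contigs are masked by a DUST-style trinucleotide score
(window 64, threshold 2.0: homopolymers mask fully, uniform random
sequence masks < 1% of bases), filtered to >= 300 unmasked bp, then
screened by the strict genomic coverage rule: a scaffold survives only if
its perfect-match mate-1 abundance (per million library pairs, either
strand, end-to-end) is higher in every carrier DNA library than in any
control library.  Survivors are annotated to the gene with the longest
ungapped alignment (>= 300 bp) to the reference transcriptome, with a
CDS-overlap tie-break; per-gene scaffolds are merged when an overlap
covers >= 40% of one scaffold and overhangs stay <= 80%.

The assembler is a stand-in: with error-free reads from a single
haplotype its contigs are exact substrings of the source (a property the
tests assert), but when both alleles are assembled together (strategy 3)
contigs can mosaic across alleles in identical stretches, as any
overlap-based assembler may; the coverage filter then rejects such
mosaics, which is why strategy 3 alone recovers fewer genes than the
k-mer strategy and why the three strategies are merged.

## Allele-specific expression

Abundance uses the standard lightweight-mapping recipe: transcripts are
indexed by canonical 31-mers; a read pair's compatibility class is the
intersection of transcript sets over its indexed k-mers (unknown k-mers
are skipped; fully unknown reads are discarded); an EM distributes
class counts in proportion to abundance over effective length
(length − mean fragment + 1, floored at 1), converging at 1e-8 relative
change or 1,000 iterations with a non-decreasing log-likelihood.  TPM
sums to 1e6 per sample over the indexed transcriptome.

The quantifier is validated before use, mirroring the study design:
reads are simulated from each discovered driver/standard pair at a known
3:1 mixture and 100x depth; genes with no diagnostic sites, or whose
recovered ratio deviates more than 20%, are excluded from classification.

**Misassignment correction.**  Per gene, `f` = (mean driver-allele TPM in
control samples) / (mean total TPM in control samples); in every sample
`f x (gene total TPM)` is subtracted from both alleles, floored at zero.
Subtracting the unitless proportion itself would be dimensionally
incoherent; that literal reading is available as
`correct_tpm(..., mode="raw_proportion")`.  On noise-free synthetic data
the EM drives the control driver estimate to ~0 (the maximum-likelihood
solution when the driver transcript has no unique reads), so `f` is
typically tiny and the correction is a near no-op in the pipeline; the
correction arithmetic is therefore calibrated separately on simulated
tables with `f` up to 0.15, where truly conserved genes are misclassified
at no more than the test level.

**Testing and classification.**  Genes with mean TPM < 1 for both alleles
in every tissue are dropped; a tissue is "expressed" at mean TPM >= 1 for
either allele.  Per (gene, tissue) the four carrier driver-allele values
are compared with the four control standard-allele values divided by two
(per-allele baseline of a two-copy genotype) by an exact two-sided
rank-sum test computed by enumeration of all C(8,4) = 70 labelings with
mid-rank ties (minimum p = 2/70 ≈ 0.0286).  A paired signed-rank mode is
provided, but with four pairs its minimum two-sided p is 0.125, which can
never reach 0.05 — an unpaired exact test is the only reading under which
any tissue can be called significant at alpha = 0.05, so rank-sum is the
default and the mode used is recorded in the output.  No multiple-testing
correction is applied across tissues or genes by default.  Categories:
*increased* if the driver allele is significantly higher in at least one
expressed tissue (takes precedence), else *decreased* if significantly
lower in at least one, else *conserved*.  Copy-gain enrichment among
categories uses Fisher's exact test.

## Molecular evolution

Per-gene driver CDS slices are taken from assembled scaffolds placed on
the standard transcript (no indels arise in the cohort; a protein-guided
aligner with BLOSUM62 global peptide alignment and codon-triplet gap
back-propagation handles the general case), trimmed to frame, capped
before the terminal stop, and required to span >= 100 coding bp.  Genes
whose driver slice contains an internal STOP are flagged, excluded from
the concatenated alignment and from ML fits, but retained in the per-gene
counting table.

NG86 counting: fractional synonymous site counts per codon (changes
creating STOPs count as nonsynonymous), pathway-averaged difference
counts (paths through STOP codons excluded unless all paths are),
Jukes-Cantor correction, omega undefined when dS = 0 or a p-distance is
saturated.

The ML machinery is a GY94-style codon model: 61 sense codons, shared
kappa, F3x4 frequencies from the data (pseudo-count 0.1), rate matrix
normalized to one expected substitution per codon, transition matrices by
symmetrized eigendecomposition (cached per (kappa, omega)), pruning over
collapsed site patterns on the fixed tree ((driver, standard), out1,
out2) with gaps as missing data.  Branch lengths, kappa and the free
omega classes are optimized jointly (L-BFGS-B on log parameters, bounds
1e-7..10 on lengths, 0.1..40 on kappa, 1e-4..50 on omega, up to three
jittered starts seeded from distance-based initial values).  AIC is
2k − 2 lnL with k counting only the omega parameters a model estimates,
and an AIC drop above 2 prefers the alternative.  The omega > 1 screen is
a boundary LRT (focal omega free vs fixed at 1, chi-square tail halved;
an estimate <= 1 is never reported significant) — a deliberate
simplification of a branch-site test: site-class mixtures are out of
scope and the screen's type-I/power behaviour is what the tests pin down.

Parameter recovery and the type-I rate are verified under the matched
model (the simulating codon frequencies passed to the fit); fitting
simulated-uniform data with data-estimated F3x4 frequencies biases omega
upward by ~10-15%, which is a model-mismatch effect, not an optimizer
defect.

## Copy number

Mate-1 reads are placed by the seed-and-extend mapper (15 bp exact seeds,
ungapped extension, best hit) and counted in non-overlapping 1 kb and
5 kb windows, normalized per million library pairs, with the truncated
final window length-normalized.  Reads up to 5 mismatches are counted:
at 0.022 divergence a 91 bp driver read carries ~2 mismatches, and a
strict perfect-match count would suppress the very signal the caller
needs (a `max_mismatches=0` mode restores the strict behaviour).
Per-window ratios of each carrier against the pooled control mean are
divided by their chromosome-wide median before integer calling
(copy = round(2 x ratio), half-up): per-million normalization alone
deflates every ratio by the genome-size quotient when the carrier
haplotype is structurally expanded, and the median anchors the diploid
baseline as ploidy normalization does in standard callers — which
requires that gains cover well under half the chromosome, as they do in
the default cohort.  CNV segments are runs of >= 2 consecutive
non-baseline windows (masked windows break runs); per-gene copy number
averages the segment windows a gene intersects, per window size, then
across the two sizes, with non-overlapping genes reporting 2.

## Problem sizes and what the tests show

The default cohort (60 genes, 4 RNA mice x 4 tissues per genotype, 6 DNA
mice per genotype, ~250 kb standard chromosome) runs end-to-end in a few
minutes on one CPU.  The test suite exercises the same conditions at
reduced size — 15 genes, 2 tissues, 3 DNA mice — and verifies
byte-determinism on a 6-gene cohort run twice; omega recovery uses 5,000
codons and the type-I simulation 60 replicates of 300 codons.  These
sizes are the package's chosen operating points for routine verification,
and `scripts/acceptance.py` reruns the full default cohort from scratch.

Passing tests establish that the filters, estimators and tests behave as
specified on clean, indel-free, uniformly diverged data with known truth.
They do not establish robustness to sequencing error models, indels,
splice isoforms, repeat families beyond low-complexity tracts, GC bias,
or reference incompleteness — all deliberately outside the generator.

## Known limitations

* The greedy assembler mosaics across alleles in identical stretches
  (mitigated by the coverage filter, not eliminated).
* The misassignment correction assumes the leak scales with the gene
  total and is estimated from as few as four control samples.
* The omega > 1 screen is a branch-model boundary test, not a
  branch-site test; per-gene omega on 200-codon alignments is noisy.
* Median-ratio CNV normalization assumes most windows are diploid.
* TPM compositionality is only damped by the background transcriptome,
  not removed; strong genotype-specific expression still shifts all
  carrier TPMs slightly.
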