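# driftscope

Discovery and analysis of transcripts specific to a non-recombining
**driver haplotype** — a selfish chromosome variant such as the mouse
*t*-haplotype — from heterozygous carrier vs. non-carrier sequencing
libraries, exercised end-to-end on synthetic diploid cohorts with known
ground truth.

The package is aimed at researchers studying meiotic drive, segregation
distorters and other low-recombination haplotypes who need a tested,
reusable implementation of the following analysis chain:

1. **Haplotype-specific transcript discovery** from carrier RNA-seq by
   three complementary filters: diverged read pairs (both mates ≥ 3
   mismatches against the reference), case/control canonical 31-mer set
   algebra (k-mers in *all* carrier libraries and *no* control library,
   reads recovered at ≥ 30% k-mer fraction), and unfiltered assembly —
   each followed by a strict genomic coverage filter (perfect-match DNA
   read abundance higher in every carrier than in any control).
2. **Allele-specific expression (ASE)**: equivalence-class EM
   quantification over driver/standard transcript pairs, validation on
   simulated reads with known mixtures, a control-derived misassignment
   correction (per-gene `f` = driver share of the gene's TPM in
   controls, `f`·total subtracted from both alleles), the 1-TPM
   expression floor, an exact two-sided rank-sum test of the four
   carrier driver-allele values against the four control
   standard-allele values ÷ 2, and the three-way
   conserved / decreased / increased classification.
3. **Molecular evolution**: premature-STOP screening, protein-guided
   codon alignment against outgroups, Nei–Gojobori (1986) dN/dS, and a
   GY94-style codon model with branch-specific ω (dN/dS), likelihood-ratio
   tests, AIC = 2k − 2 lnL comparison (Δ > 2 rule) and a one-sided ω > 1
   boundary test.
4. **Copy number**: windowed (1 kb / 5 kb) carrier/control read-depth
   ratios, median-normalized, integer copy calls
   (copy = round(2 × ratio)), segments of ≥ 2 windows, gene-level
   averages over both window sizes.

All of it runs on a built-in synthetic cohort generator (diploid
carriers with a 0.022-per-site diverged driver haplotype, tandem copy
gains, translocated "gained" genes, planted premature STOPs, 91 bp
paired-end reads with 180 ± 10 bp fragments), so every stage is testable
against known truth without any downloads. See `docs/methods.md` for the
models and their assumptions.

## Worked example

```python
from driftscope import PipelineConfig, run_full

cfg = PipelineConfig()          # default synthetic study conditions
cfg.cohort.seed = 0
report = run_full(cfg, outdir="scratch/demo")

ev = report.evaluation
print(f"discovery recall    {ev['discovery_recall']:.2f} "
      f"over {ev['n_discoverable']} divergent genes")
print(f"gained genes found  {report.gained_candidates}")
print(f"classification acc  {ev['classification_accuracy']:.2f}")
print(f"CNV sensitivity     {ev['cnv_sensitivity']:.2f}")
c = report.molevol_concatenated
print(f"concatenated omega  focal {c['omega_focal']:.2f} "
      f"vs background {c['omega_background']:.2f} (LRT p={c['lrt_p']:.1e})")
```

Output from the run above:

```
discovery recall    1.00 over 59 divergent genes
gained genes found  ['gx001', 'gx002']
classification acc  0.89
CNV sensitivity     1.00
concatenated omega  focal 1.22 vs background 0.20 (LRT p=5.4e-55)
```

Reading this: all 59 truth genes whose driver allele diverged by ≥ 1%
were recovered by the union of the three strategies, the two genes
translocated onto the driver surface as non-focal-chromosome candidates,
89% of genes land in their true expression class (the misses are the
precedence rule meeting 4-vs-4 exact-test noise), every planted +1 copy
gain is recovered at gene level, and the driver branch of the
concatenated alignment shows the expected ~6-fold elevation of dN/dS
over the purifying background — the signature of relaxed/positive
selection on a non-recombining haplotype.

The same pipeline is scriptable from the shell:

```bash
driftscope simulate --out scratch/cohort --seed 1
driftscope run --out scratch/run --seed 1
driftscope dnds --aln alignment.fa --model focal
```

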