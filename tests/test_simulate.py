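"""Synthetic cohort generator: divergence, read simulation, truth integrity."""

import numpy as np
import pytest

from driftscope.io import revcomp
from driftscope.simulate import (ConfigError, LibrarySpec, build_cohort,
                                 mutate_haplotype, simulate_reads)
from tests.conftest import small_config


class TestMutateHaplotype:
    def test_zero_divergence_is_identity(self):
        seq = "ACGT" * 100
        out, variants = mutate_haplotype(seq, 0.0, rng=0)
        assert out == seq and variants == []

    def test_substitution_count_binomial(self):
        """0.022 on 10 kb: count within 3 binomial standard deviations."""
        rng = np.random.default_rng(42)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        out, variants = mutate_haplotype(seq, 0.022, rng=rng)
        n = len(variants)
        sd = (10_000 * 0.022 * 0.978) ** 0.5
        assert abs(n - 220) <= 3 * sd
        # variant list records every change
        diff = sum(a != b for a, b in zip(seq, out))
        assert diff == n
        for pos, ref, alt in variants:
            assert seq[pos] == ref and out[pos] == alt and ref != alt

    def test_out_of_range_divergence_rejected(self):
        with pytest.raises(ConfigError):
            mutate_haplotype("ACGT", 0.3)
        with pytest.raises(ConfigError):
            mutate_haplotype("", 0.01)

    def test_default_rate_is_observed_mean_divergence(self):
        import inspect
        sig = inspect.signature(mutate_haplotype)
        assert sig.parameters["divergence"].default == 0.022


class TestSimulateReads:
    def _spec(self, **kw):
        base = dict(sample_id="s", genotype="carrier", modality="RNA",
                    n_pairs=200)
        base.update(kw)
        return LibrarySpec(**base)

    def test_noise_free_reads_are_exact_substrings(self, rng):
        src = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        pairs = simulate_reads(self._spec(), [("src", src, 1.0)], rng)
        for _n, m1, m2 in pairs:
            assert m1 in src
            assert revcomp(m2) in src

    def test_fragment_mean_clt(self, rng):
        src = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        spec = self._spec(n_pairs=10_000)
        pairs = simulate_reads(spec, [("src", src, 1.0)], rng)
        frags = [int(n.split("|")[3]) for n, _1, _2 in pairs]
        assert abs(np.mean(frags) - 180) <= 3 * 10 / np.sqrt(len(frags))

    def test_defaults_match_design(self):
        spec = LibrarySpec(sample_id="x", genotype="carrier", modality="RNA")
        assert (spec.read_length, spec.fragment_mean, spec.fragment_sd) \
            == (91, 180.0, 10.0)

    def test_short_fragments_clip_mates(self, rng):
        src = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        spec = self._spec(fragment_mean=60, fragment_sd=5)
        pairs = simulate_reads(spec, [("src", src, 1.0)], rng)
        assert all(len(m1) <= 91 and len(m1) >= 20 for _n, m1, _2 in pairs)

    def test_empty_source_set_errors(self, rng):
        with pytest.raises(ValueError):
            simulate_reads(self._spec(), [], rng)

    def test_error_rate_perturbs_reads(self, rng):
        src = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        spec = self._spec(error_rate=0.05, n_pairs=100)
        pairs = simulate_reads(spec, [("src", src, 1.0)], rng)
        mismatched = sum(m1 not in src for _n, m1, _2 in pairs)
        assert mismatched > 50  # 91 bp at 5%: almost every read has an error

    def test_read_names_encode_source(self, rng):
        src = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        pairs = simulate_reads(self._spec(n_pairs=10), [("chr1", src, 1.0)], rng)
        for name, m1, _m2 in pairs:
            sample, source, start, frag, _i = name.split("|")
            assert sample == "s" and source == "chr1"
            assert src[int(start):int(start) + len(m1)] == m1


class TestBuildCohort:
    def test_deterministic_given_seed(self):
        cfg = small_config(seed=5, n_rna_per_genotype=1, n_dna_per_genotype=1,
                           rna_pairs_per_library=200)
        a, b = build_cohort(cfg), build_cohort(cfg)
        assert a.genome.driver_seq == b.genome.driver_seq
        assert [l.pairs for l in a.libraries] == [l.pairs for l in b.libraries]

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigError):
            build_cohort(small_config(increased_fold=0.5))
        with pytest.raises(ConfigError):
            build_cohort(small_config(decreased_fold=2.0))

    def test_truth_manifest_round_trips(self, small_cohort, tmp_path):
        from driftscope.io import read_json, write_json
        manifest = small_cohort.truth_manifest()
        path = tmp_path / "truth.json"
        write_json(path, manifest)
        assert read_json(path) == _jsonify(manifest)

    def test_driver_differs_only_at_variants_before_structure(self, small_cohort):
        ds = small_cohort
        chrom = ds.genome.standard[ds.genome.focal_chromosome]
        # reconstruct the pre-structural driver from the variant list
        arr = list(chrom)
        for pos, ref, alt in ds.genome.variant_list:
            assert arr[pos] == ref
            arr[pos] = alt
        base = "".join(arr)
        # every driver transcript extracted from the point-mutated base
        for g, tx in ds.drv_transcripts.items():
            assert tx in base or revcomp(tx) in base

    def test_class_counts_and_folds_consistent(self, small_cohort):
        ds = small_cohort
        counts = {c: 0 for c in ("conserved", "decreased", "increased")}
        for g, c in ds.truth_class.items():
            counts[c] += 1
            folds = list(ds.truth_fold[g].values())
            if c == "decreased":
                assert any(f < 1 for f in folds) and not any(f > 1 for f in folds)
            elif c == "increased":
                assert any(f > 1 for f in folds)
            else:
                assert all(f == 1 for f in folds)
        assert counts == {"conserved": 5, "decreased": 5, "increased": 5}

    def test_carrier_dna_covers_cnv_gain(self, small_cohort):
        """Raw carrier read coverage over a gain interval exceeds control
        coverage by ~(2 + extra)/2 in expectation (truth-level check using
        read names, before any mapping)."""
        ds = small_cohort
        chrom, s, e, extra = ds.genome.cnv_truth[0]
        std_id = ds.genome.focal_chromosome + "_std"
        drv_id = ds.genome.focal_chromosome + "_drv"

        def mean_cov(libs, interval_len):
            total = 0
            for lib in libs:
                for name, m1, _2 in lib.pairs:
                    _s, src, start, frag, _i = name.split("|")
                    start = int(start)
                    if src == std_id and s <= start < e:
                        total += 1
            return total / len(libs)

        # standard-haplotype coverage of the interval is genotype-independent;
        # the driver adds (1 + extra) more copies in carriers
        car = ds.dna_libraries("carrier")
        ctl = ds.dna_libraries("control")
        cov_car_std = mean_cov(car, e - s)
        cov_ctl_std = mean_cov(ctl, e - s)
        # per-copy density is equal across genotypes: controls carry 2
        # standard copies, carriers 1
        assert cov_ctl_std / cov_car_std == pytest.approx(2.0, rel=0.2)

    def test_fastq_round_trip(self, small_cohort, tmp_path):
        from driftscope.io import read_fastq_pairs, write_fastq_pairs
        lib = small_cohort.rna_libraries()[0]
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq_pairs(p1, p2, lib.pairs[:50])
        assert read_fastq_pairs(p1, p2) == lib.pairs[:50]

    def test_null_cohort_sequences_identical(self, null_cohort):
        ds = null_cohort
        assert ds.genome.driver_seq == ds.genome.standard[ds.genome.focal_chromosome]
        assert ds.genome.variant_list == []
        assert ds.genome.cnv_truth == [] and ds.genome.gained_genes == []


def _jsonify(obj):
    import json
    return json.loads(json.dumps(obj))
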