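"""Seed-and-extend mapping, diverged-pair selection and coverage filtering."""

import numpy as np
import pytest

from driftscope.io import revcomp
from driftscope.mapping import (ReferenceIndex, best_hit_mismatches,
                                coverage_filter, perfect_match_coverage,
                                select_diverged_pairs)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _plant(read, n_subs, rng):
    out = list(read)
    for p in rng.choice(len(read), size=n_subs, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


@pytest.fixture(scope="module")
def reference(rng=None):
    rng = np.random.default_rng(99)
    seqs = {"refA": _random_seq(rng, 2000), "refB": _random_seq(rng, 1500)}
    return seqs, ReferenceIndex(seqs)


class TestBestHit:
    def test_exact_substring_maps_with_zero_mismatches(self, reference):
        seqs, idx = reference
        res = best_hit_mismatches(seqs["refA"][100:191], idx)
        assert res.mapped and res.mismatch_count == 0
        assert (res.target_id, res.target_position, res.strand) == ("refA", 100, "+")

    def test_reverse_complement_maps(self, reference):
        seqs, idx = reference
        res = best_hit_mismatches(revcomp(seqs["refB"][50:141]), idx)
        assert res.mapped and res.strand == "-" and res.target_id == "refB"
        assert res.mismatch_count == 0 and res.target_position == 50

    def test_planted_substitutions_counted(self, reference):
        seqs, idx = reference
        rng = np.random.default_rng(3)
        read = _plant(seqs["refA"][500:591], 3, rng)
        res = best_hit_mismatches(read, idx)
        assert res.mapped and res.mismatch_count == 3

    def test_foreign_read_unmapped(self, reference):
        _seqs, idx = reference
        rng = np.random.default_rng(4)
        assert not best_hit_mismatches(_random_seq(rng, 91), idx).mapped

    def test_empty_reference_unmaps_everything(self):
        idx = ReferenceIndex({})
        assert not best_hit_mismatches("ACGT" * 25, idx).mapped

    def test_agrees_with_exhaustive_alignment(self):
        """Best-hit mismatch counts match a brute-force scan of every
        end-to-end offset on both strands (small instances)."""
        rng = np.random.default_rng(17)
        ref = _random_seq(rng, 600)
        idx = ReferenceIndex({"r": ref})
        for trial in range(20):
            start = int(rng.integers(0, 500))
            read = _plant(ref[start:start + 60], int(rng.integers(0, 4)), rng)
            if rng.random() < 0.5:
                read = revcomp(read)
            res = best_hit_mismatches(read, idx)
            best = min(
                sum(a != b for a, b in zip(q, ref[off:off + len(q)]))
                for q in (read, revcomp(read))
                for off in range(len(ref) - len(read) + 1))
            assert res.mapped and res.mismatch_count == best


class TestDivergedPairs:
    def _pairs(self, reference, specs):
        seqs, _ = reference
        rng = np.random.default_rng(5)
        out = []
        for name, (m1_subs, m2_subs) in specs.items():
            s = int(rng.integers(0, 1200))
            m1 = _plant(seqs["refA"][s:s + 91], m1_subs, rng)
            m2 = _plant(revcomp(seqs["refA"][s + 89:s + 180]), m2_subs, rng)
            out.append((name, m1, m2))
        return out

    def test_selection_rules(self, reference):
        _seqs, idx = reference
        pairs = self._pairs(reference, {
            "exact": (0, 0), "both3": (3, 3), "one_sided": (3, 0)})
        kept = select_diverged_pairs(pairs, idx, min_mismatches=3, policy="both")
        assert [p[0] for p in kept] == ["both3"]
        kept_either = select_diverged_pairs(pairs, idx, policy="either")
        assert [p[0] for p in kept_either] == ["both3", "one_sided"]


class TestCoverage:
    def test_normalized_counts(self):
        rng = np.random.default_rng(7)
        scaf = _random_seq(rng, 400)
        reads = [scaf[i:i + 91] for i in range(10)]
        libs = [("lib1", 1_000_000, reads), ("lib2", 1_000_000, [])]
        prof = perfect_match_coverage({"s": scaf}, libs)
        assert prof.loc["s", "lib1"] == pytest.approx(10.0)
        assert prof.loc["s", "lib2"] == 0.0

    def test_single_mismatch_contributes_nothing(self):
        rng = np.random.default_rng(8)
        scaf = _random_seq(rng, 200)
        bad = _plant(scaf[10:101], 1, rng)
        prof = perfect_match_coverage({"s": scaf}, [("l", 1000, [bad])])
        assert prof.loc["s", "l"] == 0.0

    def test_reverse_complement_reads_count(self):
        rng = np.random.default_rng(9)
        scaf = _random_seq(rng, 200)
        prof = perfect_match_coverage(
            {"s": scaf}, [("l", 1000, [revcomp(scaf[20:111])])])
        assert prof.loc["s", "l"] == pytest.approx(1000.0)

    def test_short_scaffold_warns_and_scores_zero(self):
        with pytest.warns(UserWarning):
            prof = perfect_match_coverage({"tiny": "ACGT" * 5},
                                          [("l", 10, ["A" * 91])])
        assert prof.loc["tiny", "l"] == 0.0

    def test_filter_strictness(self):
        import pandas as pd
        prof = pd.DataFrame(
            {"c1": [2.0, 2.0, 0.0], "c2": [1.5, 0.8, 0.0], "c3": [1.8, 1.2, 0.0],
             "n1": [1.0, 1.0, 0.0], "n2": [0.9, 0.9, 0.0]},
            index=["keep", "drop", "zero"])
        kept = coverage_filter(prof, ["c1", "c2", "c3"], ["n1", "n2"])
        assert kept == ["keep"]

    def test_filter_monotone_in_carrier_counts(self):
        """Adding perfect-match reads to a carrier library never loses a
        retained scaffold (library sizes held fixed)."""
        import pandas as pd
        rng = np.random.default_rng(11)
        for _ in range(20):
            prof = pd.DataFrame(rng.random((4, 4)) * 3,
                                index=list("abcd"),
                                columns=["c1", "c2", "n1", "n2"])
            before = coverage_filter(prof, ["c1", "c2"], ["n1", "n2"])
            boosted = prof.copy()
            boosted.loc["a", "c1"] += rng.random() * 2
            after = coverage_filter(boosted, ["c1", "c2"], ["n1", "n2"])
            assert set(before) <= set(after) | {"a"}
            for s in before:
                assert s in after


def test_minimal_sam_writer(tmp_path):
    rng = np.random.default_rng(21)
    ref = {"chrA": _random_seq(rng, 500)}
    idx = ReferenceIndex(ref)
    reads = [ref["chrA"][10:101], revcomp(ref["chrA"][200:291]), "T" * 91]
    results = [(r, best_hit_mismatches(r, idx, read_id=f"r{i}"))
               for i, r in enumerate(reads)]
    from driftscope.mapping import write_sam
    path = tmp_path / "out.sam"
    write_sam(path, results, {n: len(s) for n, s in ref.items()})
    lines = path.read_text().splitlines()
    assert lines[0].startswith("@HD") and lines[1] == "@SQ\tSN:chrA\tLN:500"
    fields = lines[2].split("\t")
    assert fields[1] == "0" and fields[3] == "11" and fields[5] == "91M"
    rev = lines[3].split("\t")
    assert rev[1] == "16" and rev[3] == "201"
    assert lines[4].split("\t")[1] == "4"  # unmapped
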