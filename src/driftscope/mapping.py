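"""Seed-and-extend read mapping, diverged-pair selection and coverage filters.

The aligner is deliberately minimal: exact seeds (default 15 bp) anchor an
ungapped end-to-end placement of the read, and the placement with the fewest
mismatches wins.  That is all the downstream filters need - they only ask
whether a read maps with fewer than three mismatches, or perfectly.
Spliced alignment and indels are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import revcomp

__all__ = [
    "MappingResult",
    "ReferenceIndex",
    "best_hit_mismatches",
    "select_diverged_pairs",
    "perfect_match_coverage",
    "coverage_filter",
]


@dataclass
class MappingResult:
    read_id: str
    target_id: str | None
    target_position: int | None
    strand: str | None
    mismatch_count: int | None
    mapped: bool

    @classmethod
    def unmapped(cls, read_id: str) -> "MappingResult":
        return cls(read_id, None, None, None, None, False)


class ReferenceIndex:
    """Exact-seed index over a set of reference sequences.

    Seeds of length ``seed_len`` are taken at every reference position; a
    query is seeded at non-overlapping offsets, which guarantees that any
    end-to-end placement with fewer than ``len(read) // seed_len`` mismatches
    is found.
    """

    def __init__(self, seqs: dict[str, str], seed_len: int = 15):
        self.seed_len = seed_len
        self.names = sorted(seqs)
        self.seqs = {n: seqs[n] for n in self.names}
        self.arrays = {n: np.frombuffer(seqs[n].encode("ascii"), dtype=np.uint8)
                       for n in self.names}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for name in self.names:
            s = self.seqs[name]
            for i in range(len(s) - seed_len + 1):
                self.seeds.setdefault(s[i:i + seed_len], []).append((name, i))

    def candidate_offsets(self, read: str) -> list[tuple[str, int]]:
        L, w = len(read), self.seed_len
        if L < w:
            return []
        offs = list(range(0, L - w + 1, w))
        if offs[-1] != L - w:
            offs.append(L - w)
        out: set[tuple[str, int]] = set()
        for o in offs:
            for name, pos in self.seeds.get(read[o:o + w], ()):
                start = pos - o
                if start >= 0 and start + L <= len(self.seqs[name]):
                    out.add((name, start))
        return sorted(out)


def best_hit_mismatches(read: str, index: ReferenceIndex,
                        read_id: str = "read") -> MappingResult:
    """Best end-to-end ungapped placement of ``read`` (either strand).

    Reads with no exact seed hit anywhere in the reference are unmapped.
    Ties are broken towards the forward strand, then the lexicographically
    first target and smallest position.
    """
    best: tuple[int, int, str, str, int] | None = None  # mm, strand_rank, name, _, pos
    read = read.upper()
    for strand, query in (("+", read), ("-", revcomp(read))):
        arr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        for name, start in index.candidate_offsets(query):
            ref = index.arrays[name]
            mm = int(np.count_nonzero(ref[start:start + len(arr)] != arr))
            key = (mm, 0 if strand == "+" else 1, name, strand, start)
            if best is None or key < best:
                best = key
    if best is None:
        return MappingResult.unmapped(read_id)
    mm, _, name, strand, start = best
    return MappingResult(read_id, name, start, strand, mm, True)


def write_sam(path, results: Sequence[tuple[str, "MappingResult"]],
              reference_lengths: dict[str, int]) -> None:
    """Minimal single-end SAM emission for debugging mapped placements.

    Writes @HD/@SQ headers and one unpaired record per (read sequence,
    MappingResult); alignments are ungapped, so CIGAR is ``<len>M``.
    """
    with open(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in sorted(reference_lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{reference_lengths[name]}\n")
        for seq, res in results:
            if res.mapped:
                flag = 16 if res.strand == "-" else 0
                out_seq = revcomp(seq) if res.strand == "-" else seq
                fh.write("\t".join([
                    res.read_id, str(flag), res.target_id,
                    str(res.target_position + 1), "255", f"{len(seq)}M",
                    "*", "0", "0", out_seq, "*",
                    f"NM:i:{res.mismatch_count}"]) + "\n")
            else:
                fh.write("\t".join([
                    res.read_id, "4", "*", "0", "0", "*",
                    "*", "0", "0", seq, "*"]) + "\n")


def select_diverged_pairs(pairs: Sequence[tuple[str, str, str]],
                          index: ReferenceIndex,
                          min_mismatches: int = 3,
                          policy: str = "both") -> list[tuple[str, str, str]]:
    """Retain read pairs diverged from the reference.

    A mate is "diverged" when it is unmapped or its best placement carries at
    least ``min_mismatches`` mismatches.  Under the default ``policy="both"``
    a pair is retained only when both mates are diverged;
    ``policy="either"`` relaxes this to one mate.
    """
    if policy not in ("both", "either"):
        raise ValueError(f"policy must be 'both' or 'either', got {policy!r}")
    kept = []
    for name, s1, s2 in pairs:
        flags = []
        for s in (s1, s2):
            res = best_hit_mismatches(s, index, read_id=name)
            flags.append((not res.mapped) or res.mismatch_count >= min_mismatches)
        ok = all(flags) if policy == "both" else any(flags)
        if ok:
            kept.append((name, s1, s2))
    return kept


def perfect_match_coverage(scaffolds: dict[str, str],
                           dna_libraries: Sequence[tuple[str, int, Iterable[str]]],
                           ) -> pd.DataFrame:
    """Per-scaffold, per-library normalized perfect-match read counts.

    ``dna_libraries`` is a sequence of ``(library_id, total_read_pairs,
    mate1_reads)``.  A read counts towards a scaffold when it matches a
    scaffold substring exactly, end to end, on either strand (no mismatches,
    so reads from the homologous non-driver allele do not cross-map).
    Normalized abundance is reads per million library read pairs.  Scaffolds
    shorter than the read length cannot host an end-to-end placement and
    receive zero counts (with a warning).
    """
    names = sorted(scaffolds)
    libs = [lib_id for lib_id, _, _ in dna_libraries]
    counts = pd.DataFrame(0.0, index=names, columns=libs)
    substr_index: dict[int, dict[str, tuple[str, ...]]] = {}

    def index_for(L: int) -> dict[str, tuple[str, ...]]:
        if L not in substr_index:
            idx: dict[str, set[str]] = {}
            short = [n for n in names if len(scaffolds[n]) < L]
            if short:
                warnings.warn(
                    f"{len(short)} scaffold(s) shorter than read length {L} "
                    "receive zero counts")
            for n in names:
                s = scaffolds[n]
                for i in range(len(s) - L + 1):
                    idx.setdefault(s[i:i + L], set()).add(n)
            substr_index[L] = {k: tuple(sorted(v)) for k, v in idx.items()}
        return substr_index[L]

    for lib_id, n_pairs, reads in dna_libraries:
        if n_pairs <= 0:
            raise ValueError(f"{lib_id}: library size must be positive")
        acc: dict[str, int] = {}
        for r in reads:
            idx = index_for(len(r))
            hits = idx.get(r) or idx.get(revcomp(r))
            if hits:
                for n in hits:
                    acc[n] = acc.get(n, 0) + 1
        for n, c in acc.items():
            counts.loc[n, lib_id] = c / n_pairs * 1e6
    return counts


def coverage_filter(profile: pd.DataFrame,
                    carrier_ids: Sequence[str],
                    control_ids: Sequence[str]) -> list[str]:
    """Scaffolds whose normalized abundance is strictly higher in every
    carrier library than in any control library.

    Equality rejects (an all-zero scaffold is never retained).
    """
    carrier_ids, control_ids = list(carrier_ids), list(control_ids)
    if not carrier_ids or not control_ids:
        raise ValueError("need at least one carrier and one control library")
    lo = profile[carrier_ids].min(axis=1)
    hi = profile[control_ids].max(axis=1)
    return sorted(profile.index[lo > hi])
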