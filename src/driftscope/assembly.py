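"""Low-complexity masking, greedy overlap assembly and scaffold annotation.

The assembler is a deterministic greedy overlap-layout stand-in, exact on
low-error data: it repeatedly merges the pair of sequences with the longest
exact suffix/prefix overlap above a floor.  It is intentionally simple - the
scientific content of the pipeline lives in the read filters around it, not
in the assembler.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import revcomp

__all__ = [
    "Scaffold",
    "mask_low_complexity",
    "unmasked_length",
    "greedy_assemble",
    "refine_by_gene",
    "annotate_scaffold",
    "TranscriptAnnotator",
]

_TRI_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _TRI_CODE[_b] = _c
    _TRI_CODE[_b + 32] = _c


@dataclass
class Scaffold:
    scaffold_id: str
    sequence: str
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)
    assigned_gene: str | None = None
    assembly_source: str = "unfiltered"

    @property
    def unmasked_length(self) -> int:
        return len(self.sequence) - sum(e - s for s, e in self.masked_intervals)


# ---------------------------------------------------------------------------
# DUST-style low-complexity masking
# ---------------------------------------------------------------------------

def mask_low_complexity(sequence: str, window: int = 64, step: int = 32,
                        threshold: float = 2.0) -> list[tuple[int, int]]:
    """Mask windows of skewed trinucleotide composition (DUST-style score).

    The score of a window is ``sum_t c_t (c_t - 1) / 2 / (n - 1)`` over
    trinucleotide counts ``c_t`` (n = number of trinucleotides in the
    window).  Homopolymers score ~w/2 and mask fully; uniform random
    sequence scores ~0.5 and masks well under 1% of bases at the default
    threshold.  Returns merged 0-based half-open intervals.
    """
    n = len(sequence)
    if n < 3:
        return []
    x = _TRI_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    ok = (x[:-2] != 255) & (x[1:-1] != 255) & (x[2:] != 255)
    tri = (x[:-2].astype(np.int64) * 16 + x[1:-1] * 4 + x[2:])
    tri[~ok] = -1
    hits: list[tuple[int, int]] = []
    starts = list(range(0, max(n - window, 0) + 1, step))
    if not starts:
        starts = [0]
    for s in starts:
        e = min(s + window, n)
        t = tri[s:max(e - 2, s)]
        t = t[t >= 0]
        if len(t) < 2:
            continue
        counts = np.bincount(t, minlength=64)
        score = float((counts * (counts - 1)).sum() / 2) / (len(t) - 1)
        if score > threshold:
            hits.append((s, e))
    merged: list[tuple[int, int]] = []
    for s, e in hits:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def unmasked_length(sequence: str, masked: list[tuple[int, int]]) -> int:
    return len(sequence) - sum(e - s for s, e in masked)


# ---------------------------------------------------------------------------
# Greedy overlap assembly
# ---------------------------------------------------------------------------

class _OverlapIndex:
    """Prefix index used to find the longest exact suffix/prefix overlap."""

    def __init__(self, min_overlap: int):
        self.w = min_overlap
        self.by_prefix: dict[str, set[int]] = {}
        self.seqs: dict[int, str] = {}

    def add(self, sid: int, seq: str) -> None:
        self.seqs[sid] = seq
        self.by_prefix.setdefault(seq[: self.w], set()).add(sid)

    def remove(self, sid: int) -> None:
        seq = self.seqs.pop(sid)
        bucket = self.by_prefix.get(seq[: self.w])
        if bucket is not None:
            bucket.discard(sid)
            if not bucket:
                del self.by_prefix[seq[: self.w]]

    def best_overlap_from(self, sid: int) -> tuple[int, int] | None:
        """Longest overlap (suffix of sid, prefix of other); ties to the
        lexicographically smallest partner sequence."""
        a = self.seqs[sid]
        la = len(a)
        for ov in range(la - 1, self.w - 1, -1):
            key = a[la - ov: la - ov + self.w]
            bucket = self.by_prefix.get(key)
            if not bucket:
                continue
            suffix = a[la - ov:]
            best: tuple[str, int] | None = None
            for other in bucket:
                if other == sid:
                    continue
                b = self.seqs[other]
                if len(b) >= ov and b[:ov] == suffix:
                    cand = (b, other)
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                return best[1], ov
        return None


def greedy_assemble(seqs: Iterable[str], min_overlap: int = 40) -> list[str]:
    """Greedy overlap assembly of (deduplicated) sequences into contigs.

    Repeatedly merges the pair with the longest exact suffix/prefix overlap
    of at least ``min_overlap`` bp; deterministic under input shuffling
    (sequences are sorted first, ties broken lexicographically).  Unmerged
    inputs are returned as singleton contigs.  Contigs are reported sorted
    by decreasing length, then sequence.
    """
    if min_overlap < 20:
        raise ValueError(f"min_overlap must be >= 20, got {min_overlap}")
    uniq = sorted({s.upper() for s in seqs if s})
    index = _OverlapIndex(min_overlap)
    for sid, s in enumerate(uniq):
        if len(s) >= min_overlap:
            index.add(sid, s)
    shorts = [s for s in uniq if len(s) < min_overlap]
    heap: list[tuple[int, str, int, int]] = []
    for sid in sorted(index.seqs):
        cand = index.best_overlap_from(sid)
        if cand is not None:
            other, ov = cand
            heapq.heappush(heap, (-ov, index.seqs[sid], sid, other))
    next_id = len(uniq)
    while heap:
        neg_ov, _, sid, other = heapq.heappop(heap)
        if sid not in index.seqs:
            continue
        if other not in index.seqs:
            # stale partner: recompute this sequence's best edge
            cand = index.best_overlap_from(sid)
            if cand is not None:
                o2, ov2 = cand
                heapq.heappush(heap, (-ov2, index.seqs[sid], sid, o2))
            continue
        ov = -neg_ov
        a, b = index.seqs[sid], index.seqs[other]
        if a[len(a) - ov:] != b[:ov]:
            # superseded edge; recompute
            cand = index.best_overlap_from(sid)
            if cand is not None:
                o2, ov2 = cand
                heapq.heappush(heap, (-ov2, a, sid, o2))
            continue
        merged = a + b[ov:]
        index.remove(sid)
        index.remove(other)
        mid = next_id
        next_id += 1
        index.add(mid, merged)
        cand = index.best_overlap_from(mid)
        if cand is not None:
            o2, ov2 = cand
            heapq.heappush(heap, (-ov2, merged, mid, o2))
    contigs = list(index.seqs.values()) + shorts
    return sorted(contigs, key=lambda s: (-len(s), s))


# ---------------------------------------------------------------------------
# Gene-group refinement (scaffold merging)
# ---------------------------------------------------------------------------

def _ungapped_offset(a: str, b: str, seed_len: int = 31,
                     max_mismatch_frac: float = 0.05) -> tuple[int, int] | None:
    """Best ungapped placement of ``b`` relative to ``a``.

    Returns ``(offset, overlap_length)`` where ``offset`` is the position of
    b[0] in a's coordinates (may be negative), or None when no shared seed
    supports a placement with an acceptable mismatch fraction in the overlap.
    """
    if len(a) < seed_len or len(b) < seed_len:
        return None
    pos_a: dict[str, int] = {}
    for i in range(len(a) - seed_len + 1):
        pos_a.setdefault(a[i:i + seed_len], i)
    votes: dict[int, int] = {}
    for j in range(0, len(b) - seed_len + 1):
        i = pos_a.get(b[j:j + seed_len])
        if i is not None:
            off = i - j
            votes[off] = votes.get(off, 0) + 1
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    best = None
    for off in sorted(votes, key=lambda o: (-votes[o], o)):
        s = max(0, off)
        e = min(len(a), off + len(b))
        if e <= s:
            continue
        ov = e - s
        mm = int(np.count_nonzero(aa[s:e] != bb[s - off:e - off]))
        if mm <= max_mismatch_frac * ov:
            cand = (ov, -abs(off), off)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    return best[2], best[0]


def refine_by_gene(groups: Mapping[str, Sequence[str]],
                   max_overhang: float = 0.8,
                   min_overlap_fraction: float = 0.4) -> dict[str, list[str]]:
    """Merge same-gene scaffolds that overlap substantially.

    Within each gene group, two scaffolds merge when their ungapped overlap
    covers at least ``min_overlap_fraction`` of at least one of them and the
    non-overlapping overhang of each is at most ``max_overhang`` of its
    length.  Merging proceeds longest-first; at merged positions the longer
    scaffold's base is kept.
    """
    out: dict[str, list[str]] = {}
    for gene in sorted(groups):
        seqs = sorted({s for s in groups[gene]}, key=lambda s: (-len(s), s))
        merged: list[str] = []
        for s in seqs:
            placed = False
            for i, m in enumerate(merged):
                hit = _ungapped_offset(m, s)
                if hit is None:
                    continue
                off, ov = hit
                if ov < min_overlap_fraction * min(len(m), len(s)):
                    continue
                if (len(m) - ov) > max_overhang * len(m):
                    continue
                if (len(s) - ov) > max_overhang * len(s):
                    continue
                left = s[:max(0, -off)]
                right_start = off + len(s)
                right = s[len(s) - max(0, right_start - len(m)):] if right_start > len(m) else ""
                merged[i] = left + m + right
                placed = True
                break
            if not placed:
                merged.append(s)
        out[gene] = sorted(merged, key=lambda s: (-len(s), s))
    return out


# ---------------------------------------------------------------------------
# Annotation against a reference transcriptome
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    scaffold_id: str
    gene_id: str | None
    alignment_length: int
    strand: str | None
    status: str  # assigned | multi-gene | unannotated


class TranscriptAnnotator:
    """Assign scaffolds to genes by longest alignment to reference transcripts.

    ``transcripts`` maps transcript id -> (gene_id, sequence, cds_interval)
    where ``cds_interval`` is 0-based half-open on the transcript.  Alignment
    is ungapped seed-and-extend on either strand; only alignments of at least
    ``min_alignment`` bp qualify.  When the two best genes tie on alignment
    length, the tie is broken by overlap with the CDS portion of the
    transcript; an unresolved tie is reported as ``multi-gene``.
    """

    def __init__(self, transcripts: Mapping[str, tuple[str, str, tuple[int, int]]],
                 min_alignment: int = 300, seed_len: int = 31):
        self.transcripts = {t: transcripts[t] for t in sorted(transcripts)}
        self.min_alignment = min_alignment
        self.seed_len = seed_len
        self.seed_index: dict[str, list[tuple[str, int]]] = {}
        for tid, (_g, seq, _c) in self.transcripts.items():
            for i in range(len(seq) - seed_len + 1):
                self.seed_index.setdefault(seq[i:i + seed_len], []).append((tid, i))

    def _candidates(self, seq: str) -> set[str]:
        tids: set[str] = set()
        step = max(1, self.seed_len // 3)
        for j in range(0, max(len(seq) - self.seed_len, 0) + 1, step):
            for tid, _ in self.seed_index.get(seq[j:j + self.seed_len], ()):
                tids.add(tid)
        return tids

    def annotate(self, scaffold_id: str, sequence: str) -> Annotation:
        best: dict[str, tuple[int, int, str]] = {}  # gene -> (aln_len, cds_ov, strand)
        for strand, query in (("+", sequence), ("-", revcomp(sequence))):
            for tid in sorted(self._candidates(query)):
                gene, tseq, (cs, ce) = self.transcripts[tid]
                hit = _ungapped_offset(tseq, query, seed_len=self.seed_len,
                                       max_mismatch_frac=0.15)
                if hit is None:
                    continue
                off, ov = hit
                if ov < self.min_alignment:
                    continue
                s = max(0, off)
                cds_ov = max(0, min(off + len(query), ce) - max(s, cs))
                cur = best.get(gene)
                if cur is None or (ov, cds_ov) > (cur[0], cur[1]):
                    best[gene] = (ov, cds_ov, strand)
        if not best:
            return Annotation(scaffold_id, None, 0, None, "unannotated")
        ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
        if len(ranked) > 1 and ranked[0][1][0] == ranked[1][1][0]:
            if ranked[0][1][1] == ranked[1][1][1]:
                return Annotation(scaffold_id, None, ranked[0][1][0], None, "multi-gene")
        gene, (ov, _cds, strand) = ranked[0]
        return Annotation(scaffold_id, gene, ov, strand, "assigned")


def annotate_scaffold(scaffold: Scaffold,
                      annotator: TranscriptAnnotator) -> Annotation:
    """Annotate one scaffold (convenience wrapper; sets ``assigned_gene``)."""
    ann = annotator.annotate(scaffold.scaffold_id, scaffold.sequence)
    scaffold.assigned_gene = ann.gene_id
    return ann
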