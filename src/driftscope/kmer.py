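"""Canonical k-mer sets, carrier-specific set algebra and read recovery.

k-mers are held as 2-bit packed ``uint64`` codes (A=0, C=1, G=2, T=3), so
integer order coincides with lexicographic order on the strings and the
canonical form (minimum of a k-mer and its reverse complement) can be taken
with ``np.minimum``.  Windows containing non-ACGT symbols are skipped and do
not count towards a read's k-mer denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KmerSet",
    "canonical",
    "count_kmers",
    "carrier_specific_kmers",
    "recover_reads_by_kmer_fraction",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_k(k: int) -> None:
    if k < 3 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 3 (canonicalization well-defined), got {k}")
    if k > 31:
        raise ValueError("k > 31 does not fit a 2-bit packed uint64")


def _encode_windows(seqs: Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-bit encode all length-k windows of ``seqs``.

    Returns ``(codes, valid, starts)`` where ``codes`` holds the canonical
    code of every window position over the 'N'-joined concatenation of the
    inputs, ``valid`` marks windows that lie within one sequence and contain
    only ACGT, and ``starts`` gives, per input sequence, the offset of its
    first window in the global arrays (length ``len(seqs) + 1``; sequences
    shorter than k own an empty slice).
    """
    if not seqs:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, dtype=bool), np.zeros(1, dtype=np.int64)
    joined = ("N".join(seqs)).encode("ascii")
    x = _CODE[np.frombuffer(joined, dtype=np.uint8)]
    n = len(x)
    nwin = n - k + 1
    if nwin <= 0:
        z = np.zeros(0, dtype=np.uint64)
        starts = np.zeros(len(seqs) + 1, dtype=np.int64)
        return z, np.zeros(0, dtype=bool), starts
    invalid = (x == 255).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    valid = (csum[k:] - csum[:-k]) == 0
    xv = np.where(x == 255, 0, x).astype(np.uint64)
    fwd = np.zeros(nwin, dtype=np.uint64)
    rc = np.zeros(nwin, dtype=np.uint64)
    for j in range(k):
        b = xv[j:j + nwin]
        fwd = (fwd << np.uint64(2)) | b
        rc |= (np.uint64(3) - b) << np.uint64(2 * j)
    codes = np.minimum(fwd, rc)
    # window-start offsets per sequence within the joined string
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    seq_starts = np.concatenate([[0], np.cumsum(lens + 1)])[:-1]
    counts = np.maximum(lens - k + 1, 0)
    starts = np.empty(len(seqs) + 1, dtype=np.int64)
    starts[:-1] = np.minimum(seq_starts, nwin)
    starts[-1] = nwin
    # clip: a sequence shorter than k should own an empty, in-range slice
    for i in range(len(seqs)):
        if counts[i] == 0:
            starts[i] = min(starts[i], nwin)
    return codes, valid, starts


def _decode(codes: np.ndarray, k: int) -> list[str]:
    if len(codes) == 0:
        return []
    out = np.empty((len(codes), k), dtype=np.uint8)
    c = codes.astype(np.uint64)
    for j in range(k - 1, -1, -1):
        out[:, j] = _BASES[(c & np.uint64(3)).astype(np.intp)]
        c = c >> np.uint64(2)
    return [row.tobytes().decode("ascii") for row in out]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return min(kmer.upper(), rc)


@dataclass
class KmerSet:
    """A set of canonical k-mers of fixed length ``k``.

    Members are stored as a sorted ``uint64`` array of 2-bit codes;
    ``members`` materializes them as strings for inspection.
    """

    k: int
    codes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.uint64))
    source_label: str = ""

    def __post_init__(self) -> None:
        _check_k(self.k)
        self.codes = np.unique(np.asarray(self.codes, dtype=np.uint64))

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        codes, valid, _ = _encode_windows([kmer], self.k)
        if not valid.any():
            return False
        i = np.searchsorted(self.codes, codes[0])
        return bool(i < len(self.codes) and self.codes[i] == codes[0])

    @property
    def members(self) -> frozenset[str]:
        return frozenset(_decode(self.codes, self.k))

    @classmethod
    def from_strings(cls, kmers: Iterable[str], k: int | None = None,
                     source_label: str = "") -> "KmerSet":
        kmers = list(kmers)
        if k is None:
            if not kmers:
                raise ValueError("k required for an empty set")
            k = len(kmers[0])
        for m in kmers:
            if len(m) != k:
                raise ValueError(f"k-mer {m!r} does not have length {k}")
        codes, valid, _ = _encode_windows([canonical(m) for m in kmers], k) if kmers \
            else (np.zeros(0, np.uint64), np.zeros(0, bool), None)
        return cls(k=k, codes=codes[valid] if kmers else codes, source_label=source_label)

    def write(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write(f"#k={self.k}\n")
            for m in _decode(self.codes, self.k):
                fh.write(m + "\n")

    @classmethod
    def read(cls, path) -> "KmerSet":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#k="):
                raise ValueError(f"{path}: missing '#k=' header")
            k = int(header[3:])
            kmers = [line.strip() for line in fh if line.strip()]
        return cls.from_strings(kmers, k=k)


def count_kmers(seqs: Iterable[str] | str, k: int = 31,
                source_label: str = "") -> KmerSet:
    """Canonical k-mers present at least once in ``seqs``.

    Emits a warning and returns an empty set when every input is shorter
    than ``k``.
    """
    _check_k(k)
    if isinstance(seqs, str):
        seqs = [seqs]
    seqs = list(seqs)
    codes, valid, _ = _encode_windows(seqs, k)
    kept = codes[valid]
    if seqs and len(kept) == 0:
        warnings.warn(f"no sequence yields a {k}-mer; returning an empty set")
    return KmerSet(k=k, codes=np.unique(kept), source_label=source_label)


def carrier_specific_kmers(carrier_sets: Sequence[KmerSet],
                           control_sets: Sequence[KmerSet]) -> KmerSet:
    """Intersection of all carrier sets minus the union of all control sets.

    Mirrors a case/control presence filter: a k-mer qualifies when it is seen
    in every carrier library and in no control library.
    """
    if not carrier_sets:
        raise ValueError("at least one carrier set required")
    ks = {s.k for s in list(carrier_sets) + list(control_sets)}
    if len(ks) != 1:
        raise ValueError(f"mixed k among input sets: {sorted(ks)}")
    k = ks.pop()
    inter = carrier_sets[0].codes
    for s in carrier_sets[1:]:
        inter = np.intersect1d(inter, s.codes, assume_unique=True)
    for s in control_sets:
        inter = np.setdiff1d(inter, s.codes, assume_unique=True)
    return KmerSet(k=k, codes=inter, source_label="carrier-specific")


def _mate_fractions(mates: Sequence[str], kset: KmerSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-mate (matching k-mers, valid k-mers) counts against ``kset``."""
    codes, valid, starts = _encode_windows(list(mates), kset.k)
    hit = np.zeros(len(codes), dtype=np.int64)
    if len(codes):
        idx = np.searchsorted(kset.codes, codes)
        idx = np.minimum(idx, max(len(kset.codes) - 1, 0))
        if len(kset.codes):
            hit = (kset.codes[idx] == codes) & valid
            hit = hit.astype(np.int64)
    vald = valid.astype(np.int64)
    csum_h = np.concatenate([[0], np.cumsum(hit)])
    csum_v = np.concatenate([[0], np.cumsum(vald)])
    n = len(mates)
    matches = np.empty(n, dtype=np.int64)
    totals = np.empty(n, dtype=np.int64)
    for i in range(n):
        a, b = starts[i], starts[i] + max(len(mates[i]) - kset.k + 1, 0)
        b = min(b, starts[-1])
        matches[i] = csum_h[b] - csum_h[a]
        totals[i] = csum_v[b] - csum_v[a]
    return matches, totals


def recover_reads_by_kmer_fraction(pairs: Sequence[tuple[str, str, str]],
                                   kmers: KmerSet,
                                   min_fraction: float = 0.3,
                                   mode: str = "either") -> list[tuple[str, str, str]]:
    """Retain read pairs whose mates share enough canonical k-mers with ``kmers``.

    A mate qualifies when (its k-mers found in the set) / (its valid k-mers)
    >= ``min_fraction``; mates shorter than k contribute zero k-mers and never
    qualify.  ``mode`` is ``"either"`` (default: one qualifying mate retains
    the pair) or ``"both"``.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if mode not in ("either", "both"):
        raise ValueError(f"mode must be 'either' or 'both', got {mode!r}")
    if not pairs:
        return []
    if len(kmers) == 0:
        return []
    mates: list[str] = []
    for _, s1, s2 in pairs:
        mates.append(s1)
        mates.append(s2)
    matches, totals = _mate_fractions(mates, kmers)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, matches / np.maximum(totals, 1), 0.0)
    ok = frac >= min_fraction
    q1, q2 = ok[0::2], ok[1::2]
    keep = (q1 | q2) if mode == "either" else (q1 & q2)
    return [p for p, kflag in zip(pairs, keep) if kflag]
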