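"""Protein-guided codon alignment, NG86 counting and branch-model dN/dS.

The maximum-likelihood machinery implements a Goldman-Yang-style codon
substitution model: 61 sense-codon states, a single transition/transversion
ratio kappa shared across branches, F3x4 codon frequencies estimated from
the data, and a dN/dS ratio (omega) that may be shared, branch-specific or
fixed, on a fixed small tree ((driver, standard), outgroup1, outgroup2).
Rate matrices are normalized to one expected substitution per codon per
unit branch length.  Nested models are compared with likelihood-ratio
tests and with AIC computed as 2k - 2 lnL where k counts the omega
parameters estimated by a model.

The omega > 1 screen is a boundary LRT of the focal-branch omega free
versus fixed at one (one-sided: the chi-square tail probability is halved,
and an estimate below one is never reported as significantly above one).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "SENSE_CODONS",
    "translate_and_screen",
    "CodonAlignment",
    "protein_guided_align",
    "NG86Result",
    "ng86_dnds",
    "BranchOmegaFit",
    "fit_branch_model",
    "lrt",
    "aic_compare",
    "omega_gt1_test",
    "simulate_alignment",
    "f3x4_frequencies",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA = {c: str(Seq(c).translate()) for c in SENSE_CODONS}

_N = len(SENSE_CODONS)  # 61
_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


# precomputed single-nucleotide-change structure of the 61x61 state space
_DIFF1 = np.zeros((_N, _N), dtype=bool)
_TS = np.zeros((_N, _N), dtype=bool)
_SYN = np.zeros((_N, _N), dtype=bool)
for _i, _a in enumerate(SENSE_CODONS):
    for _j, _b in enumerate(SENSE_CODONS):
        diffs = [p for p in range(3) if _a[p] != _b[p]]
        if len(diffs) == 1:
            _DIFF1[_i, _j] = True
            p = diffs[0]
            _TS[_i, _j] = _is_transition(_a[p], _b[p])
            _SYN[_i, _j] = AA[_a] == AA[_b]


# ---------------------------------------------------------------------------
# Translation and STOP screening
# ---------------------------------------------------------------------------

def translate_and_screen(cds: str, frame: int = 0) -> tuple[str, bool]:
    """Translate a CDS; flag premature (internal) STOP codons.

    Trailing bases that do not complete a codon are dropped with a warning.
    The returned peptide includes ``*`` for stops; the flag is True when a
    STOP occurs before the final codon.
    """
    s = cds.upper()[frame:]
    if len(s) % 3:
        warnings.warn(f"CDS length {len(s)} not a multiple of 3; "
                      f"dropping {len(s) % 3} trailing base(s)")
        s = s[: len(s) - len(s) % 3]
    pep = str(Seq(s).translate())
    internal = pep[:-1] if pep else ""
    return pep, "*" in internal


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-padded in-frame CDS alignment over named taxa.

    ``aligned`` maps taxon -> codon string with ``-`` gaps; all strings have
    equal length divisible by 3.  In-frame internal STOP codons are rejected
    unless ``allow_stops`` was set when building.
    """

    aligned: dict[str, str]
    allow_stops: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {lengths}")
        (L,) = lengths
        if L % 3:
            raise ValueError(f"alignment length {L} not divisible by 3")
        if not self.allow_stops:
            for taxon, s in self.aligned.items():
                codons = [s[i:i + 3] for i in range(0, L, 3)]
                for ci, c in enumerate(codons[:-1]):
                    if c in STOP_CODONS:
                        raise ValueError(
                            f"{taxon}: internal STOP {c} at codon {ci}")

    @property
    def taxa(self) -> list[str]:
        return list(self.aligned)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.aligned.values()))) // 3

    def codon_indices(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """(n_taxa, n_codons) sense-codon indices; -1 for gaps/stops/ambiguity."""
        taxa = list(taxa) if taxa is not None else self.taxa
        out = np.full((len(taxa), self.n_codons), -1, dtype=np.int64)
        for r, taxon in enumerate(taxa):
            s = self.aligned[taxon]
            for ci in range(self.n_codons):
                out[r, ci] = CODON_INDEX.get(s[3 * ci: 3 * ci + 3], -1)
        return out

    def ungapped_pair(self, a: str, b: str) -> tuple[str, str]:
        """Concatenated codon columns where both taxa are gap-free."""
        sa, sb = self.aligned[a], self.aligned[b]
        ca, cb = [], []
        for i in range(0, len(sa), 3):
            x, y = sa[i:i + 3], sb[i:i + 3]
            if "-" not in x and "-" not in y:
                ca.append(x)
                cb.append(y)
        return "".join(ca), "".join(cb)

    def aligned_bp(self, a: str, b: str) -> int:
        return len(self.ungapped_pair(a, b)[0])

    def concatenate(self, other: "CodonAlignment") -> "CodonAlignment":
        if set(self.aligned) != set(other.aligned):
            raise ValueError("taxa mismatch in concatenation")
        return CodonAlignment(
            {t: self.aligned[t] + other.aligned[t] for t in self.aligned},
            allow_stops=self.allow_stops or other.allow_stops)


def _peptide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def protein_guided_align(cds: Mapping[str, str],
                         min_aligned_bp: int = 100
                         ) -> tuple[CodonAlignment | None, dict[str, str]]:
    """Codon-aware multiple alignment guided by global peptide alignment.

    The first taxon serves as the reference: every other peptide is aligned
    to it globally (BLOSUM62, affine gaps) and gaps are back-propagated as
    codon triplets; taxon insertions relative to the reference become
    gap columns in the other taxa.  Untranslatable sequences (internal
    STOPs, empty after trimming) are excluded with a reason.  Returns
    ``(alignment, excluded)``; the alignment is None when fewer than two
    taxa survive or the reference/non-reference aligned span is below
    ``min_aligned_bp``.
    """
    excluded: dict[str, str] = {}
    peptides: dict[str, str] = {}
    codons: dict[str, list[str]] = {}
    for taxon, seq in cds.items():
        pep, premature = translate_and_screen(seq)
        if premature:
            excluded[taxon] = "premature STOP codon"
            continue
        pep = pep[:-1] if pep.endswith("*") else pep
        if not pep:
            excluded[taxon] = "untranslatable (empty peptide)"
            continue
        peptides[taxon] = pep
        s = seq.upper()[: 3 * len(pep)]
        codons[taxon] = [s[i:i + 3] for i in range(0, len(s), 3)]
    taxa = list(peptides)
    if len(taxa) < 2:
        return None, excluded
    ref = taxa[0]
    aligner = _peptide_aligner()
    # per taxon: map ref peptide position -> taxon codon index, plus
    # insertions anchored before a ref position
    maps: dict[str, dict[int, int]] = {}
    inserts: dict[str, dict[int, list[int]]] = {}
    for taxon in taxa[1:]:
        aln = aligner.align(peptides[ref], peptides[taxon])[0]
        m: dict[int, int] = {}
        ins: dict[int, list[int]] = {}
        prev_r = prev_q = 0
        for (rs, re), (qs, qe) in zip(*aln.aligned):
            if qs > prev_q:  # taxon insertion before ref position rs
                ins.setdefault(rs, []).extend(range(prev_q, qs))
            for r, q in zip(range(rs, re), range(qs, qe)):
                m[r] = q
            prev_r, prev_q = re, qe
        if prev_q < len(peptides[taxon]):
            ins.setdefault(len(peptides[ref]), []).extend(
                range(prev_q, len(peptides[taxon])))
        maps[taxon] = m
        inserts[taxon] = ins
    cols: dict[str, list[str]] = {t: [] for t in taxa}
    for r in range(len(peptides[ref]) + 1):
        for taxon in taxa[1:]:
            for q in inserts[taxon].get(r, ()):  # taxon-specific insertion
                for t2 in taxa:
                    cols[t2].append(codons[taxon][q] if t2 == taxon else "---")
        if r < len(peptides[ref]):
            for t2 in taxa:
                if t2 == ref:
                    cols[t2].append(codons[ref][r])
                else:
                    q = maps[t2].get(r)
                    cols[t2].append(codons[t2][q] if q is not None else "---")
    aln_obj = CodonAlignment({t: "".join(cols[t]) for t in taxa})
    others = taxa[1:]
    if min(aln_obj.aligned_bp(ref, t) for t in others) < min_aligned_bp:
        return None, excluded | {"__alignment__": f"aligned span < {min_aligned_bp} bp"}
    return aln_obj, excluded


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@dataclass
class NG86Result:
    dn: float
    ds: float
    omega: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    flags: list[str] = field(default_factory=list)


def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes (number of synonymous single-base changes)/3
    synonymous sites; changes creating STOP codons count as nonsynonymous.
    """
    syn = 0.0
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if alt not in STOP_CODONS and AA.get(alt) == AA.get(codon):
                syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def _pathway_diffs(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts."""
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = a
        sd = nd = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways pass through a STOP; count direct changes
        paths = [(0.0, float(len(diffs)))]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_dnds(cds_a: str, cds_b: str) -> NG86Result:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.

    Operates on gap-free codon columns only; codons containing gaps,
    ambiguity codes or STOPs in either sequence are skipped.  omega is None
    when dS = 0 or when either p-distance is saturated (p >= 3/4).
    """
    a, b = cds_a.upper(), cds_b.upper()
    L = min(len(a), len(b)) // 3
    S = Nn = Sd = Nd = 0.0
    used = 0
    flags: list[str] = []
    for i in range(L):
        ca, cb = a[3 * i: 3 * i + 3], b[3 * i: 3 * i + 3]
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue
        used += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        Nn += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p: float) -> float:
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1 - 4 * p / 3)

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / Nn if Nn > 0 else 0.0
    ds = jc(ps)
    dn = jc(pn)
    if math.isnan(ds) or math.isnan(dn):
        flags.append("saturated")
    omega: float | None
    if math.isnan(ds) or math.isnan(dn) or ds <= 0:
        omega = None
        if ds == 0:
            flags.append("dS=0")
    else:
        omega = dn / ds
    return NG86Result(dn=dn, ds=ds, omega=omega, syn_sites=S, nonsyn_sites=Nn,
                      syn_diffs=Sd, nonsyn_diffs=Nd, n_codons=used, flags=flags)


# ---------------------------------------------------------------------------
# GY94-style branch models
# ---------------------------------------------------------------------------

def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies over sense codons, floored and renormalized."""
    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for s in aln.aligned.values():
        for i in range(0, len(s), 3):
            c = s[i:i + 3]
            if c in CODON_INDEX:
                for p in range(3):
                    counts[p, base_idx[c[p]]] += 1
    counts += 0.1  # pseudo-count guards empty positions
    freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([freq[0, base_idx[c[0]]] * freq[1, base_idx[c[1]]]
                   * freq[2, base_idx[c[2]]] for c in SENSE_CODONS])
    pi = np.maximum(pi, 1e-8)
    return pi / pi.sum()


def _rate_matrix(kappa: float, omega: float, pi: np.ndarray
                 ) -> tuple[np.ndarray, float, float]:
    """Normalized rate matrix plus its synonymous/nonsynonymous flux split."""
    M = np.where(_DIFF1, 1.0, 0.0)
    M = M * np.where(_TS, kappa, 1.0) * np.where(_SYN | ~_DIFF1, 1.0, omega)
    M = M * pi[None, :]
    np.fill_diagonal(M, 0.0)
    rates = M.sum(axis=1)
    scale = float((pi * rates).sum())
    Q = M / scale
    np.fill_diagonal(Q, -rates / scale)
    flux_syn = float((pi[:, None] * M * _SYN).sum() / scale)
    return Q, flux_syn, 1.0 - flux_syn


class _CodonModel:
    """Eigendecomposition cache for transition matrices P(t)."""

    def __init__(self, pi: np.ndarray):
        self.pi = pi
        self.sq = np.sqrt(pi)
        self._cache: dict[tuple[float, float], tuple] = {}

    def _eig(self, kappa: float, omega: float):
        key = (round(kappa, 12), round(omega, 12))
        hit = self._cache.get(key)
        if hit is None:
            Q, fs, fn = _rate_matrix(kappa, omega, self.pi)
            B = Q * (self.sq[:, None] / self.sq[None, :])
            B = (B + B.T) / 2  # enforce symmetry against rounding
            w, V = np.linalg.eigh(B)
            hit = (w, V, fs, fn)
            if len(self._cache) > 64:
                self._cache.clear()
            self._cache[key] = hit
        return hit

    def transition(self, kappa: float, omega: float, t: float) -> np.ndarray:
        w, V, _, _ = self._eig(kappa, omega)
        E = V * np.exp(w * t)[None, :]
        P = (E @ V.T) * (self.sq[None, :] / self.sq[:, None])
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def flux_split(self, kappa: float, omega: float) -> tuple[float, float]:
        _, _, fs, fn = self._eig(kappa, omega)
        return fs, fn


_ROLES4 = ("driver", "standard", "out1", "out2")


def _branch_sets(taxa: Sequence[str]) -> list[str]:
    present = [r for r in _ROLES4 if r in taxa]
    if len(present) != len(taxa):
        raise ValueError(
            f"taxa must use role names from {_ROLES4}, got {list(taxa)}")
    branches = list(present)
    if "out1" in present and "out2" in present:
        branches.append("internal")
    return branches


def _model_classes(model: str, branches: Sequence[str],
                   focal: str = "driver") -> tuple[dict[str, str], dict[str, float]]:
    """Branch -> omega-class mapping and fixed class values for a model."""
    fixed: dict[str, float] = {}
    if model == "shared":
        classes = {b: "w0" for b in branches}
    elif model == "focal":
        classes = {b: ("w_focal" if b == focal else "w0") for b in branches}
    elif model == "focal-fixed-1":
        classes = {b: ("w_focal" if b == focal else "w0") for b in branches}
        fixed["w_focal"] = 1.0
    elif model == "per-branch":
        classes = {b: f"w_{b}" for b in branches}
    elif model == "pair-shared":
        classes = {b: ("w_pair" if b in ("driver", "standard") else "w0")
                   for b in branches}
    elif model == "pair-distinct":
        classes = {b: (f"w_{b}" if b in ("driver", "standard") else "w0")
                   for b in branches}
    else:
        raise ValueError(f"unknown model {model!r}")
    return classes, fixed


@dataclass
class BranchOmegaFit:
    model: str
    lnl: float
    kappa: float
    branch_lengths: dict[str, float]
    omega_by_class: dict[str, float]
    omega_by_branch: dict[str, float]
    n_omega_params: int
    aic: float
    per_branch: pd.DataFrame
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:  # AIC parameter count (omega values estimated)
        return self.n_omega_params


class _Likelihood:
    def __init__(self, aln: CodonAlignment, pi: np.ndarray | None = None):
        self.taxa = [r for r in _ROLES4 if r in aln.taxa]
        self.branches = _branch_sets(self.taxa)
        self.pi = pi if pi is not None else f3x4_frequencies(aln)
        self.model = _CodonModel(self.pi)
        idx = aln.codon_indices(self.taxa)
        patterns, counts = np.unique(idx, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = counts.astype(float)
        eye = np.eye(_N)
        self.tips = {}
        for r, taxon in enumerate(self.taxa):
            col = patterns[r]
            L = np.ones((_N, patterns.shape[1]))
            known = col >= 0
            L[:, known] = eye[:, col[known]]
            self.tips[taxon] = L

    def lnl(self, bl: dict[str, float], kappa: float,
            omega_by_branch: dict[str, float]) -> float:
        P = {b: self.model.transition(kappa, omega_by_branch[b], bl[b])
             for b in self.branches}
        if "internal" in self.branches:
            node1 = (P["driver"] @ self.tips["driver"]) * \
                    (P["standard"] @ self.tips["standard"])
            root = (P["internal"] @ node1) * \
                   (P["out1"] @ self.tips["out1"]) * \
                   (P["out2"] @ self.tips["out2"])
        else:
            root = np.ones((_N, self.patterns.shape[1]))
            for b in self.branches:
                root = root * (P[b] @ self.tips[b])
        site = self.pi @ root
        site = np.maximum(site, 1e-300)
        return float(self.weights @ np.log(site))


def fit_branch_model(aln: CodonAlignment, model: str = "shared",
                     focal_branch: str = "driver",
                     kappa0: float = 2.0, n_starts: int = 3,
                     seed: int = 0, pi: np.ndarray | None = None,
                     ) -> BranchOmegaFit:
    """Maximum-likelihood branch-model fit on the fixed small tree.

    ``model`` is one of ``shared``, ``focal``, ``focal-fixed-1``,
    ``per-branch``, ``pair-shared``, ``pair-distinct`` (see
    ``_model_classes``).  Branch lengths (expected substitutions per codon),
    kappa and the free omega classes are optimized jointly from
    ``n_starts`` jittered starting points.  Raises ``RuntimeError`` when no
    start converges.
    """
    lik = _Likelihood(aln, pi=pi)
    classes, fixed = _model_classes(model, lik.branches, focal=focal_branch)
    free_classes = sorted({c for c in classes.values() if c not in fixed})
    branches = lik.branches
    rng = np.random.default_rng(seed)

    # crude initial branch lengths from pairwise codon mismatch fractions
    idx = {t: i for i, t in enumerate(lik.taxa)}
    pat, wts = lik.patterns, lik.weights

    def pdist(a: str, b: str) -> float:
        ra, rb = pat[idx[a]], pat[idx[b]]
        ok = (ra >= 0) & (rb >= 0)
        tot = wts[ok].sum()
        if tot == 0:
            return 0.01
        return float(wts[ok][(ra != rb)[ok]].sum() / tot)

    if "internal" in branches:
        d_ds = pdist("driver", "standard")
        d_out = pdist("out1", "out2")
        d_cross = (pdist("driver", "out1") + pdist("standard", "out2")) / 2
        init = {
            "driver": max(d_ds / 2, 1e-3),
            "standard": max(d_ds / 2, 1e-3),
            "out1": max(d_out / 2, 1e-3),
            "out2": max(d_out / 2, 1e-3),
            "internal": max(d_cross - d_ds / 2 - d_out / 2, 1e-3),
        }
    else:
        d = max(pdist(branches[0], branches[-1]) if len(branches) > 1 else 0.01, 2e-3)
        init = {b: d / len(branches) for b in branches}

    nb = len(branches)
    lo = np.concatenate([np.full(nb, math.log(1e-7)), [math.log(0.1)],
                         np.full(len(free_classes), math.log(1e-4))])
    hi = np.concatenate([np.full(nb, math.log(10.0)), [math.log(40.0)],
                         np.full(len(free_classes), math.log(50.0))])

    def unpack(x):
        bl = {b: math.exp(x[i]) for i, b in enumerate(branches)}
        kappa = math.exp(x[nb])
        om = dict(fixed)
        for i, c in enumerate(free_classes):
            om[c] = math.exp(x[nb + 1 + i])
        return bl, kappa, {b: om[classes[b]] for b in branches}, om

    def nll(x):
        bl, kappa, omb, _ = unpack(x)
        return -lik.lnl(bl, kappa, omb)

    best = None
    any_success = False
    for s in range(max(n_starts, 1)):
        jitter = rng.uniform(0.6, 1.6, size=nb) if s else np.ones(nb)
        x0 = np.concatenate([
            [math.log(max(init[b] * jitter[i], 1e-6)) for i, b in enumerate(branches)],
            [math.log(kappa0 * (1.0 if s == 0 else rng.uniform(0.7, 1.5)))],
            [math.log([0.4, 1.0, 2.5][s % 3])] * len(free_classes),
        ])
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": 500, "ftol": 1e-10})
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"branch-model optimization failed: {best}")
    if not any_success:
        warnings.warn("no optimizer start reported convergence; using best point")
    bl, kappa, omb, om_class = unpack(best.x)
    lnl = -float(best.fun)
    flags = []
    if sum(bl.values()) < 1e-4:
        flags.append("zero-divergence: omega unidentifiable")
    # per-branch expected substitution bookkeeping
    fs1, fn1 = lik.model.flux_split(kappa, 1.0)
    rows = []
    ncod = int(lik.weights.sum())
    for b in branches:
        fs, fn = lik.model.flux_split(kappa, omb[b])
        t = bl[b]
        ds = (t * fs) / (3 * fs1)
        dn = (t * fn) / (3 * fn1)
        rows.append({"branch": b, "t": t, "omega": omb[b],
                     "exp_syn_subs": t * fs * ncod,
                     "exp_nonsyn_subs": t * fn * ncod,
                     "dS": ds, "dN": dn})
    per_branch = pd.DataFrame(rows).set_index("branch")
    n_omega = len(free_classes)
    return BranchOmegaFit(
        model=model, lnl=lnl, kappa=kappa, branch_lengths=bl,
        omega_by_class=om_class, omega_by_branch=omb,
        n_omega_params=n_omega, aic=2 * n_omega - 2 * lnl,
        per_branch=per_branch, converged=bool(any_success), flags=flags)


def lrt(lnl_null: float, lnl_alt: float, df: int, tol: float = 1e-6) -> float:
    """Chi-square likelihood-ratio test p-value of nested fits."""
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -tol:
        warnings.warn(f"alternative lnL below null by {-stat / 2:.3g}; "
                      "statistic clamped to 0")
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0


def aic_compare(null_fit: BranchOmegaFit, alt_fit: BranchOmegaFit,
                threshold: float = 2.0) -> dict:
    """Prefer the alternative model when AIC drops by more than ``threshold``."""
    delta = null_fit.aic - alt_fit.aic
    return {"delta_aic": delta,
            "preferred": alt_fit.model if delta > threshold else null_fit.model}


def omega_gt1_test(aln: CodonAlignment, focal_branch: str = "driver",
                   seed: int = 0, n_starts: int = 3,
                   pi: np.ndarray | None = None) -> dict:
    """One-sided boundary LRT for omega > 1 on the focal branch.

    Alternative: focal-branch omega free; null: focal omega fixed at 1
    (background omega free in both).  The chi-square tail is halved for the
    boundary; an estimate at or below one is never reported significant.
    """
    alt = fit_branch_model(aln, model="focal", focal_branch=focal_branch,
                           seed=seed, n_starts=n_starts, pi=pi)
    null = fit_branch_model(aln, model="focal-fixed-1", focal_branch=focal_branch,
                            seed=seed + 1, n_starts=n_starts, pi=pi)
    stat = max(2.0 * (alt.lnl - null.lnl), 0.0)
    omega_hat = alt.omega_by_class["w_focal"]
    if omega_hat > 1.0:
        p = 0.5 * float(stats.chi2.sf(stat, 1))
    else:
        p = 1.0
    return {"p": p, "omega_focal": omega_hat, "lrt_stat": stat,
            "alt": alt, "null": null}


# ---------------------------------------------------------------------------
# Simulation under the codon model
# ---------------------------------------------------------------------------

def simulate_alignment(n_codons: int, branch_lengths: Mapping[str, float],
                       kappa: float, omega: float | Mapping[str, float],
                       pi: np.ndarray | None = None,
                       seed: int | np.random.Generator = 0) -> CodonAlignment:
    """Simulate a codon alignment on the fixed 4-taxon (or 2-taxon) tree.

    ``branch_lengths`` names a subset of driver/standard/out1/out2(/internal);
    ``omega`` is shared or a per-branch mapping.  Root states are drawn from
    ``pi`` (F3x4-like uniform over sense codons by default) at the outgroup
    junction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pi is None:
        pi = np.full(_N, 1.0 / _N)
    om = omega if isinstance(omega, Mapping) else \
        {b: float(omega) for b in branch_lengths}
    model = _CodonModel(pi)

    def evolve(states: np.ndarray, branch: str) -> np.ndarray:
        P = model.transition(kappa, om[branch], branch_lengths[branch])
        out = np.empty_like(states)
        for s in np.unique(states):
            mask = states == s
            out[mask] = rng.choice(_N, size=int(mask.sum()), p=P[s])
        return out

    root = rng.choice(_N, size=n_codons, p=pi)
    seqs: dict[str, np.ndarray] = {}
    if "internal" in branch_lengths:
        node1 = evolve(root, "internal")
        seqs["driver"] = evolve(node1, "driver")
        seqs["standard"] = evolve(node1, "standard")
        seqs["out1"] = evolve(root, "out1")
        seqs["out2"] = evolve(root, "out2")
    else:
        for b in branch_lengths:
            seqs[b] = evolve(root, b)
    aligned = {t: "".join(SENSE_CODONS[i] for i in seqs[t])
               for t in seqs}
    return CodonAlignment(aligned)
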