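"""EM quantification, misassignment correction, exact tests, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driftscope import ase
from driftscope.io import revcomp
from driftscope.simulate import LibrarySpec, simulate_reads


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _reads_from(seq, n, rng, frag=180, rl=91):
    out = []
    for i in range(n):
        start = int(rng.integers(0, len(seq) - frag + 1))
        f = seq[start:start + frag]
        out.append((f"r{i}", f[:rl], revcomp(f)[:rl]))
    return out


class TestQuantifier:
    def test_fully_diagnostic_reads_go_to_one_transcript(self):
        rng = np.random.default_rng(0)
        a = _random_seq(rng, 600)
        b = _random_seq(rng, 600)  # unrelated: every read diagnostic
        reads = _reads_from(a, 50, rng)
        res = ase.quantify(reads, {"A": a, "B": b})
        assert res.tpm["A"] == pytest.approx(1e6)
        assert res.tpm["B"] == 0.0

    def test_identical_transcripts_split_evenly(self):
        rng = np.random.default_rng(1)
        a = _random_seq(rng, 600)
        reads = _reads_from(a, 40, rng)
        res = ase.quantify(reads, {"A": a, "B": a})
        assert res.counts["A"] == pytest.approx(res.counts["B"], rel=1e-6)
        assert res.tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_mixture_ratio_recovered(self):
        """3:1 allele mixture at ~100x depth recovered within 10%."""
        rng = np.random.default_rng(2)
        std = _random_seq(rng, 660)
        drv = list(std)
        for p in rng.choice(660, size=14, replace=False):  # ~2% divergence
            drv[p] = "ACGT"[("ACGT".index(drv[p]) + 1) % 4]
        drv = "".join(drv)
        n = int(100 * 660 / 182)
        reads = (_reads_from(drv, 3 * n, rng) + _reads_from(std, n, rng))
        res = ase.quantify(reads, {"drv": drv, "std": std})
        ratio = res.tpm["drv"] / res.tpm["std"]
        assert ratio == pytest.approx(3.0, rel=0.10)

    def test_tpm_sums_to_one_million(self):
        rng = np.random.default_rng(3)
        txs = {f"t{i}": _random_seq(rng, 500) for i in range(5)}
        reads = []
        for t in txs.values():
            reads += _reads_from(t, 20, rng)
        res = ase.quantify(reads, txs)
        assert res.tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        a = _random_seq(rng, 500)
        b = a[:250] + _random_seq(rng, 250)
        reads = _reads_from(a, 30, rng) + _reads_from(b, 10, rng)
        res = ase.quantify(reads, {"A": a, "B": b})
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_no_compatible_reads_warns(self):
        rng = np.random.default_rng(5)
        res_tx = {"A": _random_seq(rng, 400)}
        foreign = _reads_from(_random_seq(rng, 400), 5, rng)
        with pytest.warns(UserWarning):
            res = ase.quantify(foreign, res_tx)
        assert res.tpm["A"] == 0.0


class TestMisassignmentCorrection:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "allele", "sample",
                                           "tissue", "raw_tpm"])

    def test_zero_driver_in_controls_gives_f0(self):
        t = self._table([("g", "driver", "n1", "t", 0.0),
                         ("g", "standard", "n1", "t", 100.0)])
        f = ase.misassignment_proportion(t, ["n1"])
        assert f["g"] == 0.0

    def test_f_is_driver_share_of_total(self):
        t = self._table([("g", "driver", "n1", "t", 10.0),
                         ("g", "standard", "n1", "t", 90.0),
                         ("g", "driver", "n2", "t", 10.0),
                         ("g", "standard", "n2", "t", 90.0)])
        f = ase.misassignment_proportion(t, ["n1", "n2"])
        assert f["g"] == pytest.approx(0.1)

    def test_all_zero_controls_flagged_nan(self):
        t = self._table([("g", "driver", "n1", "t", 0.0),
                         ("g", "standard", "n1", "t", 0.0)])
        assert np.isnan(ase.misassignment_proportion(t, ["n1"])["g"])

    def test_correction_subtracts_share_of_total(self):
        t = self._table([("g", "driver", "c1", "t", 30.0),
                         ("g", "standard", "c1", "t", 90.0)])
        out = ase.correct_tpm(t, pd.Series({"g": 0.1}))
        got = out.set_index("allele")["corrected_tpm"]
        assert got["driver"] == pytest.approx(18.0)   # 30 - 0.1 * 120
        assert got["standard"] == pytest.approx(78.0)

    def test_correction_floors_at_zero(self):
        t = self._table([("g", "driver", "c1", "t", 1.0),
                         ("g", "standard", "c1", "t", 119.0)])
        out = ase.correct_tpm(t, pd.Series({"g": 0.1}))
        assert out.set_index("allele")["corrected_tpm"]["driver"] == 0.0

    def test_f0_is_identity(self):
        t = self._table([("g", "driver", "c1", "t", 30.0),
                         ("g", "standard", "c1", "t", 90.0)])
        out = ase.correct_tpm(t, pd.Series({"g": 0.0}))
        assert (out["corrected_tpm"] == out["raw_tpm"]).all()


class TestExpressionFilter:
    def test_threshold_rules(self):
        rows = []
        for s in ("a", "b"):
            rows += [("on", "driver", s, "t1", 1.2), ("on", "standard", s, "t1", 0.1),
                     ("on", "driver", s, "t2", 0.2), ("on", "standard", s, "t2", 0.3),
                     ("off", "driver", s, "t1", 0.0), ("off", "standard", s, "t1", 0.0),
                     ("off", "driver", s, "t2", 0.0), ("off", "standard", s, "t2", 0.0)]
        table = pd.DataFrame(rows, columns=["gene", "allele", "sample",
                                            "tissue", "raw_tpm"])
        retained, expressed = ase.expression_filter(table)
        assert retained == ["on"]
        assert bool(expressed.loc["on", "t1"]) and not bool(expressed.loc["on", "t2"])


class TestRankTest:
    def test_identical_groups_give_p1(self):
        assert ase.rank_test([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_complete_separation_4v4(self):
        p = ase.rank_test([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70)

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 4), (5, 4), (6, 6)])
    def test_matches_brute_force_enumeration(self, n, m, rng):
        """Exact two-sided p equals direct enumeration of all labelings."""
        for _ in range(5):
            pooled = rng.normal(size=n + m)
            x, y = pooled[:n], pooled[n:]
            got = ase.rank_test(x, y)
            ranks = stats.rankdata(pooled)
            mu = n * (n + m + 1) / 2
            obs = abs(ranks[:n].sum() - mu)
            hits = total = 0
            for combo in itertools.combinations(range(n + m), n):
                total += 1
                if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
                    hits += 1
            assert got == pytest.approx(hits / total)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=4) + rng.normal() * 0.5
            ours = ase.rank_test(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_signed_rank_minimum_p_with_4_pairs(self):
        p = ase.signed_rank_test([5, 6, 7, 8], [1, 2, 3, 4])
        assert p == pytest.approx(2 / 16)  # can never reach 0.05


class TestEnrichment:
    def test_diagonal_table(self):
        orat, p = ase.category_enrichment([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)

    def test_identical_proportions_or1(self):
        orat, p = ase.category_enrichment([[4, 8], [2, 4]])
        assert orat == pytest.approx(1.0)

    def test_empty_margin_gives_p1(self):
        assert ase.category_enrichment([[0, 0], [3, 5]])[1] == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        """Two-sided p equals summing hypergeometric probabilities of all
        tables (fixed margins) no more probable than the observed one."""
        for _ in range(10):
            a, b, c, d = rng.integers(0, 8, size=4)
            n = a + b + c + d
            if n == 0 or (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = ase.category_enrichment([[a, b], [c, d]])
            hg = stats.hypergeom(n, a + b, a + c)
            p0 = hg.pmf(a)
            total = sum(hg.pmf(k) for k in range(max(0, a + c - (c + d)),
                                                 min(a + b, a + c) + 1)
                        if hg.pmf(k) <= p0 * (1 + 1e-9))
            assert p == pytest.approx(total, rel=1e-6)


class TestClassification:
    def _res(self, *triples):
        return [ase.TissueResult(f"t{i}", p, d, e)
                for i, (p, d, e) in enumerate(triples)]

    def test_no_significant_tissue_is_conserved(self):
        assert ase.classify_gene(self._res((0.5, 1, True), (0.8, -1, True))) \
            == "conserved"

    def test_increased_takes_precedence(self):
        res = self._res((0.01, 1, True), (0.01, -1, True))
        assert ase.classify_gene(res) == "increased"

    def test_single_down_tissue_is_decreased(self):
        assert ase.classify_gene(self._res((0.01, -1, True), (0.9, 1, True))) \
            == "decreased"

    def test_unexpressed_gene_excluded(self):
        assert ase.classify_gene(self._res((0.01, -1, False))) == "excluded"

    def test_significance_in_unexpressed_tissue_ignored(self):
        res = self._res((0.01, 1, False), (0.6, 1, True))
        assert ase.classify_gene(res) == "conserved"


class TestValidateQuantifier:
    def test_zero_diagnostic_gene_flagged(self, rng):
        seq = _random_seq(rng, 600)
        seq2 = _random_seq(rng, 600)
        spec = LibrarySpec(sample_id="v", genotype="carrier", modality="RNA",
                           n_pairs=2000)
        df = ase.validate_quantifier(
            {"same": (seq, seq), "diff": (seq2, _mutate(seq2, 10, rng))},
            true_ratio=3.0, simulate_reads=simulate_reads, library_spec=spec,
            rng=rng)
        by_gene = df.set_index("gene")
        assert by_gene.loc["same", "flag"] == "unquantifiable"
        assert by_gene.loc["diff", "flag"] == "ok"
        assert by_gene.loc["diff", "recovered_ratio"] == pytest.approx(3.0, rel=0.2)


def _mutate(seq, n, rng):
    out = list(seq)
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


class TestMultipleTesting:
    def test_bh_adjustment_matches_direct_formula(self, rng):
        p = rng.uniform(size=25)
        q = ase.benjamini_hochberg(p)
        # monotone in p and bounded by 1
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()
        # spot check against the step-up definition
        n = len(p)
        ranked = np.sort(p)
        direct = np.minimum.accumulate((ranked * n / np.arange(1, n + 1))[::-1])[::-1]
        assert np.allclose(np.sort(q), np.minimum(direct, 1.0))

    def test_bh_mode_is_more_conservative(self):
        rows = []
        rng = np.random.default_rng(8)
        for i in range(30):
            g = f"g{i}"
            shift = 0.3 if i < 5 else 0.0
            for s in range(4):
                rows += [(g, "driver", f"c{s}", "t",
                          float(10 * np.exp(rng.normal(shift, 0.1)))),
                         (g, "standard", f"c{s}", "t", 10.0),
                         (g, "driver", f"n{s}", "t", 0.0),
                         (g, "standard", f"n{s}", "t",
                          float(20 * np.exp(rng.normal(0, 0.1))))]
        table = pd.DataFrame(rows, columns=["gene", "allele", "sample",
                                            "tissue", "raw_tpm"])
        table["corrected_tpm"] = table["raw_tpm"]
        car, ctl = [f"c{s}" for s in range(4)], [f"n{s}" for s in range(4)]
        plain = ase.classify_table(table, car, ctl)
        bh = ase.classify_table(table, car, ctl, multiple_testing="bh")
        n_sig = (plain["category"] != "conserved").sum()
        n_sig_bh = (bh["category"] != "conserved").sum()
        assert n_sig_bh <= n_sig
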