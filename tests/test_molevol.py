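"""Codon alignment, NG86 counting and the branch-model likelihood machinery."""

import math

import numpy as np
import pytest

from driftscope import molevol as mol


class TestTranslateAndScreen:
    def test_clean_cds(self):
        pep, flag = mol.translate_and_screen("ATGGCC")
        assert pep == "MA" and not flag

    def test_internal_stop_flagged(self):
        pep, flag = mol.translate_and_screen("ATGTAAGGG")
        assert flag

    def test_terminal_stop_not_premature(self):
        pep, flag = mol.translate_and_screen("ATGGCCTAA")
        assert pep == "MA*" and not flag

    def test_trailing_bases_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            pep, _ = mol.translate_and_screen("ATGGCCTA")
        assert pep == "MA"


class TestProteinGuidedAlign:
    def test_identical_cds_align_without_gaps(self):
        cds = "ATGGCCAAAGGGTTTCCCGATGAAGCTTGGCATAAGCTGATCGTAGCTGGGTTT" * 3
        aln, excluded = mol.protein_guided_align(
            {"driver": cds, "standard": cds}, min_aligned_bp=100)
        assert not excluded
        assert aln.aligned["driver"] == aln.aligned["standard"] == cds

    def test_codon_insertion_becomes_triplet_gap(self):
        base = "ATGGCCAAAGGGTTTCCCGATGAAGCTTGGCATAAGCTGATCGTAGCTGGGTTTATGGCC" \
               "AAAGGGTTTCCCGATGAAGCTTGGCATAAGCTGATCGTAGCTGGGTTT"
        with_ins = base[:30] + "GAA" + base[30:]
        aln, _ = mol.protein_guided_align(
            {"driver": with_ins, "standard": base}, min_aligned_bp=60)
        assert aln is not None
        s = aln.aligned["standard"]
        assert s.count("-") == 3 and "---" in s
        assert aln.aligned["driver"].replace("-", "") == with_ins

    def test_short_alignable_region_dropped(self):
        a = "ATGGCCAAAGGGTTTCCCGATGAAGCTTGG"  # 30 bp < 100 bp floor
        aln, excluded = mol.protein_guided_align(
            {"driver": a, "standard": a}, min_aligned_bp=100)
        assert aln is None and "__alignment__" in excluded

    def test_premature_stop_taxon_excluded(self):
        good = "ATGGCCAAAGGGTTTCCCGATGAAGCTTGGCATAAGCTGATCGTAGCTGGGTTT" * 2
        bad = good[:9] + "TGA" + good[12:]
        aln, excluded = mol.protein_guided_align(
            {"driver": good, "standard": good, "out1": bad}, min_aligned_bp=60)
        assert excluded == {"out1": "premature STOP codon"}
        assert aln is not None and "out1" not in aln.aligned


class TestNG86:
    def test_identical_sequences(self):
        r = mol.ng86_dnds("ATGGCC" * 20, "ATGGCC" * 20)
        assert r.dn == 0 and r.ds == 0 and r.omega is None
        assert "dS=0" in r.flags

    def test_single_synonymous_difference(self):
        a = "TTT" * 10
        b = "TTC" + "TTT" * 9
        r = mol.ng86_dnds(a, b)
        assert r.nonsyn_diffs == 0 and r.syn_diffs == 1
        assert r.dn == 0 and r.ds > 0

    def test_single_nonsynonymous_difference(self):
        a = "ATGGCC" * 10
        b = "ATGTCC" + "ATGGCC" * 9   # A->S at codon 2
        r = mol.ng86_dnds(a, b)
        assert r.syn_diffs == 0 and r.nonsyn_diffs == 1
        assert r.ds == 0 and r.omega is None

    def test_symmetry(self, rng):
        a = mol.simulate_alignment(100, {"driver": 0.2, "standard": 0.2},
                                   kappa=2, omega=0.7, seed=5)
        x, y = a.aligned["driver"], a.aligned["standard"]
        r1, r2 = mol.ng86_dnds(x, y), mol.ng86_dnds(y, x)
        assert r1.dn == pytest.approx(r2.dn)
        assert r1.ds == pytest.approx(r2.ds)

    def test_site_counts_match_hand_enumeration(self):
        # TTT (Phe): only TTC is synonymous among the 9 single-base changes
        s, n = mol._codon_sites("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(3 - 1 / 3)
        # pathway counts for a 2-difference codon pair, averaged over orders
        sd, nd = mol._pathway_diffs("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)

    def test_agrees_with_biopython_on_random_pair(self):
        """Cross-check dN/dS against an independent implementation."""
        codonalign = pytest.importorskip("Bio.codonalign.codonseq")
        import warnings
        a = mol.simulate_alignment(
            300, {"driver": 0.15, "standard": 0.15}, kappa=2, omega=0.5, seed=9)
        x, y = a.aligned["driver"], a.aligned["standard"]
        ours = mol.ng86_dnds(x, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = codonalign.cal_dn_ds(
                codonalign.CodonSeq(x), codonalign.CodonSeq(y), method="NG86")
        assert ours.dn == pytest.approx(dn, rel=0.05, abs=5e-3)
        assert ours.ds == pytest.approx(ds, rel=0.05, abs=5e-3)


def _toy_alignment():
    return mol.CodonAlignment({
        "driver": "ATGGCCAAATTTGGA",
        "standard": "ATGGCGAAATTCGGA",
        "out1": "ATGGCCAACTTTGGA",
        "out2": "ATGACCAAATTTGCA",
    })


class TestLikelihood:
    def test_matches_direct_site_pattern_summation(self):
        """Pruning lnL equals brute-force summation over the internal node
        states on a toy 4-taxon alignment."""
        aln = _toy_alignment()
        lik = mol._Likelihood(aln)
        bl = {"driver": 0.2, "standard": 0.1, "internal": 0.15,
              "out1": 0.05, "out2": 0.3}
        kappa, omega = 2.0, 0.6
        omb = {b: omega for b in bl}
        got = lik.lnl(bl, kappa, omb)

        pi = lik.pi
        P = {b: lik.model.transition(kappa, omega, t) for b, t in bl.items()}
        idx = aln.codon_indices(["driver", "standard", "out1", "out2"])
        total = 0.0
        for site in range(idx.shape[1]):
            d, s, o1, o2 = idx[:, site]
            acc = 0.0
            for root in range(61):          # root = outgroup junction
                for n1 in range(61):        # driver/standard ancestor
                    acc += (pi[root] * P["internal"][root, n1]
                            * P["driver"][n1, d] * P["standard"][n1, s]
                            * P["out1"][root, o1] * P["out2"][root, o2])
            total += math.log(acc)
        assert got == pytest.approx(total, abs=1e-8)

    def test_two_taxon_likelihood_brute_force(self):
        aln = mol.CodonAlignment({"driver": "ATGGCCAAA", "standard": "ATGGCGAAC"})
        lik = mol._Likelihood(aln)
        bl = {"driver": 0.07, "standard": 0.12}
        got = lik.lnl(bl, 1.5, {b: 0.8 for b in bl})
        pi = lik.pi
        P = {b: lik.model.transition(1.5, 0.8, t) for b, t in bl.items()}
        idx = aln.codon_indices(["driver", "standard"])
        total = 0.0
        for site in range(idx.shape[1]):
            d, s = idx[:, site]
            acc = sum(pi[r] * P["driver"][r, d] * P["standard"][r, s]
                      for r in range(61))
            total += math.log(acc)
        assert got == pytest.approx(total, abs=1e-8)

    def test_transition_matrix_rows_sum_to_one(self):
        lik = mol._Likelihood(_toy_alignment())
        P = lik.model.transition(2.0, 0.5, 0.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_stationarity(self):
        lik = mol._Likelihood(_toy_alignment())
        P = lik.model.transition(2.0, 0.5, 0.7)
        assert np.allclose(lik.pi @ P, lik.pi, atol=1e-10)


class TestBranchFits:
    def test_omega_recovery_shared_model(self):
        pi = np.full(61, 1 / 61)
        aln = mol.simulate_alignment(
            1500, {"driver": 0.25, "standard": 0.1, "internal": 0.1,
                   "out1": 0.15, "out2": 0.35}, kappa=2.0, omega=0.5, seed=2,
            pi=pi)
        fit = mol.fit_branch_model(aln, model="shared", seed=0, pi=pi)
        assert fit.omega_by_class["w0"] == pytest.approx(0.5, rel=0.15)
        assert fit.kappa == pytest.approx(2.0, rel=0.25)

    def test_identical_taxa_flagged(self):
        cds = "ATGGCCAAATTTGGA" * 4
        aln = mol.CodonAlignment({t: cds for t in
                                  ("driver", "standard", "out1", "out2")})
        fit = mol.fit_branch_model(aln, model="shared", seed=0, n_starts=1)
        assert any("unidentifiable" in fl for fl in fit.flags)

    def test_two_taxon_ml_agrees_with_ng86(self):
        """At low divergence the ML omega and the NG86 counting omega agree
        within 20% relative."""
        pi = np.full(61, 1 / 61)
        aln = mol.simulate_alignment(3000, {"driver": 0.04, "standard": 0.04},
                                     kappa=1.0, omega=0.4, seed=3, pi=pi)
        fit = mol.fit_branch_model(aln, model="shared", seed=0, pi=pi)
        ng = mol.ng86_dnds(aln.aligned["driver"], aln.aligned["standard"])
        assert fit.omega_by_class["w0"] == pytest.approx(ng.omega, rel=0.2)

    def test_aic_uses_omega_parameter_count(self):
        aln = mol.simulate_alignment(
            200, {"driver": 0.2, "standard": 0.1, "internal": 0.1,
                  "out1": 0.1, "out2": 0.2}, kappa=2, omega=0.5, seed=4)
        fit1 = mol.fit_branch_model(aln, model="shared", seed=0, n_starts=1)
        fit2 = mol.fit_branch_model(aln, model="focal", seed=0, n_starts=1)
        assert fit1.aic == pytest.approx(2 * 1 - 2 * fit1.lnl)
        assert fit2.aic == pytest.approx(2 * 2 - 2 * fit2.lnl)
        assert fit2.lnl >= fit1.lnl - 1e-6  # nested


class TestLRTandAIC:
    def test_equal_likelihoods_give_p1(self):
        assert mol.lrt(-100.0, -100.0, 1) == 1.0

    def test_chi2_quantile(self):
        p = mol.lrt(-100.0, -100.0 + 3.84 / 2, 1)
        assert p == pytest.approx(0.05, abs=2e-3)

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert mol.lrt(-99.0, -100.0, 1) == 1.0

    def test_aic_delta_rule(self):
        import copy
        aln = _toy_alignment()
        f0 = mol.fit_branch_model(aln, model="shared", seed=0, n_starts=1)
        f1 = copy.copy(f0)
        f1.model = "focal"
        # delta = 0 -> null retained
        f1.aic = f0.aic
        assert mol.aic_compare(f0, f1)["preferred"] == "shared"
        f1.aic = f0.aic - 2.5
        assert mol.aic_compare(f0, f1)["preferred"] == "focal"


class TestOmegaGt1:
    def test_strong_positive_selection_detected(self):
        aln = mol.simulate_alignment(
            1200, {"driver": 0.3, "standard": 0.1, "internal": 0.1,
                   "out1": 0.15, "out2": 0.3}, kappa=2.0,
            omega={"driver": 3.0, "standard": 0.3, "internal": 0.3,
                   "out1": 0.3, "out2": 0.3}, seed=6)
        res = mol.omega_gt1_test(aln, seed=0, n_starts=2)
        assert res["omega_focal"] > 1
        assert res["p"] < 0.05

    def test_omega_below_one_never_significant(self):
        aln = mol.simulate_alignment(
            600, {"driver": 0.2, "standard": 0.1, "internal": 0.1,
                  "out1": 0.15, "out2": 0.3}, kappa=2.0, omega=0.2, seed=7)
        res = mol.omega_gt1_test(aln, seed=0, n_starts=1)
        assert res["omega_focal"] < 1 and res["p"] == 1.0


class TestSimulateAlignment:
    def test_no_stops_and_expected_divergence(self):
        aln = mol.simulate_alignment(500, {"driver": 0.3, "standard": 0.0},
                                     kappa=2, omega=1.0, seed=8)
        for s in aln.aligned.values():
            codons = {s[i:i + 3] for i in range(0, len(s), 3)}
            assert not codons & mol.STOP_CODONS
        idx = aln.codon_indices(["driver", "standard"])
        frac = (idx[0] != idx[1]).mean()
        # ~0.3 substitutions/codon with back-substitutions: 20-30% of codons
        assert 0.15 < frac < 0.35
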