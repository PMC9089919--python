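"""Codon site models: likelihood correctness against a dense
matrix-exponential oracle, nested-model behavior, LRTs, and site
identification."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from drbkit import codons
from drbkit.sitemodels import (
    CodonSiteModel,
    N_STATES,
    chi2_upper_tail,
    codon_rate_matrix,
    discrete_beta,
    likelihood_ratio_test,
)

EQ_PI = np.full(N_STATES, 1.0 / N_STATES)


def oracle_loglik_pair(seq_a, seq_b, t_total, kappa, omega):
    """Dense expm likelihood for a 2-taxon tree (reversible: only the path
    length matters)."""
    Q, r = codon_rate_matrix(kappa, omega, EQ_PI)
    P = expm(Q * t_total / r)
    ll = 0.0
    for ca, cb in zip(codons.codons_of(seq_a), codons.codons_of(seq_b)):
        i, j = codons.CODON_INDEX[ca], codons.CODON_INDEX[cb]
        ll += math.log(EQ_PI[i] * P[i, j])
    return ll


def oracle_loglik_triple(seqs, blens, kappa, omega):
    """Dense expm likelihood for a 3-taxon star tree by explicit summation
    over the internal node state."""
    Q, r = codon_rate_matrix(kappa, omega, EQ_PI)
    Ps = [expm(Q * t / r) for t in blens]
    ll = 0.0
    cods = [codons.codons_of(s) for s in seqs]
    for site in range(len(cods[0])):
        idx = [codons.CODON_INDEX[c[site]] for c in cods]
        site_l = sum(
            EQ_PI[x] * Ps[0][x, idx[0]] * Ps[1][x, idx[1]] * Ps[2][x, idx[2]]
            for x in range(N_STATES)
        )
        ll += math.log(site_l)
    return ll


class TestLikelihood:
    def test_identical_sequences_zero_branches_reduce_to_root_frequencies(self):
        aln = {"A": "ATGATGATG", "B": "ATGATGATG"}
        m = CodonSiteModel(aln, tree="(A:0,B:0);", model="M0", codon_freq="equal")
        assert m.loglike({"kappa": 2.0, "omega": 0.5}) == pytest.approx(
            3 * math.log(1 / 61), abs=1e-10
        )

    @pytest.mark.parametrize("kappa, omega, t", [(2.0, 0.5, 0.5), (1.3, 2.0, 0.12)])
    def test_two_taxon_toy_matches_expm_oracle(self, kappa, omega, t):
        aln = {"A": "ATGTTTGGG", "B": "ATATTCGGA"}
        m = CodonSiteModel(aln, tree=f"(A:{t / 2},B:{t / 2});", model="M0",
                           codon_freq="equal")
        got = m.loglike({"kappa": kappa, "omega": omega})
        want = oracle_loglik_pair(aln["A"], aln["B"], t, kappa, omega)
        assert got == pytest.approx(want, abs=1e-8)

    def test_three_taxon_toy_matches_expm_oracle(self):
        aln = {"A": "ATGTTTGGGCCT", "B": "ATATTCGGACCT", "C": "ATGTTGGGACCA"}
        blens = [0.2, 0.35, 0.1]
        tree = f"(A:{blens[0]},B:{blens[1]},C:{blens[2]});"
        m = CodonSiteModel(aln, tree=tree, model="M0", codon_freq="equal")
        got = m.loglike({"kappa": 1.8, "omega": 0.7})
        want = oracle_loglik_triple(
            [aln["A"], aln["B"], aln["C"]], blens, 1.8, 0.7
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_m2a_with_empty_positive_class_reproduces_m1a(self):
        aln = {"A": "ATGTTTGGGCCT", "B": "ATATTCGGACCT", "C": "ATGTTGGGACCA"}
        tree = "(A:0.2,B:0.35,C:0.1);"
        m1 = CodonSiteModel(aln, tree=tree, model="M1a", codon_freq="equal")
        m2 = CodonSiteModel(aln, tree=tree, model="M2a", codon_freq="equal")
        p1 = {"kappa": 2.0, "p0": 0.6, "omega0": 0.2}
        p2 = {"kappa": 2.0, "p0": 0.6, "p1": 0.4, "p2": 0.0,
              "omega0": 0.2, "omega2": 3.0}
        assert m2.loglike(p2) == pytest.approx(m1.loglike(p1), abs=1e-6)

    def test_stop_codon_in_alignment_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonSiteModel({"A": "TAAGGG", "B": "TTTGGG"}, tree="(A:0.1,B:0.1);")

    def test_tree_tip_mismatch_rejected(self):
        with pytest.raises(ValueError, match="tips"):
            CodonSiteModel({"A": "TTTGGG", "B": "TTCGGG"}, tree="(A:0.1,X:0.1);")


class TestFits:
    def test_nested_model_dominance(self, mixed_selection_fit):
        fits = mixed_selection_fit["fits"]
        assert fits["M2a"].lnL >= fits["M1a"].lnL - 1e-4
        assert fits["M8"].lnL >= fits["M7"].lnL - 1e-4
        assert fits["M1a"].lnL >= fits["M0"].lnL - 1e-4

    def test_per_site_posteriors_sum_to_one(self, mixed_selection_fit):
        post = mixed_selection_fit["fits"]["M2a"].site_posteriors()
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_positive_class_recovers_omega_above_one(self, mixed_selection_fit):
        assert mixed_selection_fit["fits"]["M2a"].params["omega2"] > 1.0

    def test_flagged_sites_enriched_in_truly_selected_codons(self, mixed_selection_fit):
        fits = mixed_selection_fit["fits"]
        truth = set((np.nonzero(mixed_selection_fit["omegas"] == 4.0)[0] + 1).tolist())
        flagged = set(fits["M2a"].selected_sites(threshold=0.9).index)
        assert flagged, "no sites flagged at 0.9"
        base_rate = len(truth) / len(mixed_selection_fit["omegas"])
        precision = len(flagged & truth) / len(flagged)
        assert precision > base_rate

    def test_neb_and_beb_posteriors_are_correlated(self, mixed_selection_fit):
        fit = mixed_selection_fit["fits"]["M2a"]
        neb = fit.positive_class_posterior("NEB")
        beb = fit.positive_class_posterior("BEB")
        assert beb.shape == neb.shape
        assert np.all((beb >= 0) & (beb <= 1))
        assert np.corrcoef(neb, beb)[0, 1] > 0.5

    def test_site_identification_requires_positive_class_model(self, mixed_selection_fit):
        with pytest.raises(ValueError, match="positive"):
            mixed_selection_fit["fits"]["M1a"].selected_sites()

    def test_no_variation_flags_nothing(self):
        aln = {n: "ATGTTTGGGCCTGCA" * 2 for n in "ABC"}
        fit = CodonSiteModel(aln, tree="(A:0.05,B:0.05,C:0.05);", model="M2a",
                             codon_freq="equal").fit(restarts=1, seed=0)
        assert fit.selected_sites(threshold=0.95).empty

    def test_summary_reports_model_and_classes(self, mixed_selection_fit):
        text = mixed_selection_fit["fits"]["M2a"].summary()
        assert "M2a" in text and "lnL" in text and "omega=" in text


class TestLRT:
    def test_equal_likelihoods_give_p_one(self, mixed_selection_fit):
        f = mixed_selection_fit["fits"]["M1a"]
        r = likelihood_ratio_test(f, f, df=2)
        assert r.delta == 0.0 and r.p == 1.0

    @pytest.mark.parametrize(
        "delta, expected_p",
        [(10.34, math.exp(-10.34 / 2)), (10.38, math.exp(-10.38 / 2))],
    )
    def test_chi_square_df2_closed_form(self, delta, expected_p):
        assert chi2_upper_tail(delta, 2) == pytest.approx(expected_p, rel=1e-10)
        assert chi2_upper_tail(delta, 2) < 0.01

    def test_non_nested_pair_rejected(self, mixed_selection_fit):
        fits = mixed_selection_fit["fits"]
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(fits["M1a"], fits["M8"])


class TestBetaDiscretization:
    @pytest.mark.parametrize("p,q", [(0.2, 0.3), (1.0, 1.0), (2.0, 5.0)])
    def test_category_means_average_to_distribution_mean(self, p, q):
        w = discrete_beta(p, q, 10)
        assert len(w) == 10
        assert np.all((w > 0) & (w < 1))
        assert w.mean() == pytest.approx(p / (p + q), abs=1e-6)
        assert np.all(np.diff(w) >= 0)
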