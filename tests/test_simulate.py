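"""Allele-pool, genotype, and clone simulation: invariants and calibration."""

import numpy as np
import pytest
from scipy import stats

from drbkit import codons
from drbkit.simulate import (
    CHIMERA,
    FAITHFUL,
    POINT_ERROR,
    simulate_allele_pool,
    simulate_clones,
    simulate_genotypes,
    simulate_study_cohort,
)


class TestAllelePool:
    def test_single_sequence_pool(self):
        pool = simulate_allele_pool(1, 0, n_codons=80, seed=0)
        (seq,) = pool.functional_alleles
        assert len(seq) == 242
        assert not codons.premature_stops(seq, 2)

    def test_study_sized_pool_lengths_and_deletions(self):
        pool = simulate_allele_pool(11, 3, n_codons=80, seed=2)
        assert len(pool.functional_alleles) == 11
        assert all(len(s) == 242 for s in pool.functional_alleles)
        assert all(len(s) == 241 for s in pool.pseudogene_alleles)
        # every pseudogene is one deletion away from some functional allele
        for ps in pool.pseudogene_alleles:
            assert any(
                ps == f[:i] + f[i + 1 :]
                for f in pool.functional_alleles
                for i in range(len(f))
            )

    def test_functional_alleles_unique_and_stop_free(self):
        pool = simulate_allele_pool(11, 3, seed=4)
        assert len(set(pool.functional_alleles)) == 11
        for s in pool.functional_alleles:
            assert not codons.premature_stops(s, pool.frame_offset)

    def test_divergence_calibration(self):
        # Monte-Carlo mean of realized p-distance across replicate seeds
        vals = [
            simulate_allele_pool(8, 0, target_divergence=0.05, seed=s)
            .mean_pairwise_p_distance()
            for s in range(200)
        ]
        assert 0.04 <= np.mean(vals) <= 0.06

    def test_zero_divergence_multiple_alleles_unsatisfiable(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            simulate_allele_pool(2, 0, target_divergence=0.0)


class TestGenotypes:
    def test_degenerate_frequency_gives_everyone_the_allele(self):
        pool = simulate_allele_pool(1, 0, seed=1)
        truth = simulate_genotypes(
            pool, {"east": [{"F01": 1.0}]}, {"east": 10}, seed=0
        )
        assert all(ind.alleles == frozenset({"F01"}) for ind in truth.individuals)

    def test_linked_pair_always_co_occurs(self, study_cohort):
        _, truth, _ = study_cohort
        assert truth.check_linkage()
        for a, b in truth.linkage_pairs:
            for ind in truth.individuals:
                assert (a in ind.alleles) == (b in ind.alleles)

    def test_split_linked_pair_in_table_is_rejected(self):
        pool = simulate_allele_pool(3, 0, seed=1)
        freqs = {"east": [{"F02": 0.5, "F03": 0.5}]}
        with pytest.raises(ValueError, match="linked pair"):
            simulate_genotypes(
                pool, freqs, {"east": 5}, linkage_pairs=[("F02", "F03")], seed=0
            )

    def test_unknown_allele_in_table_is_rejected(self):
        pool = simulate_allele_pool(2, 0, seed=1)
        with pytest.raises(ValueError, match="unknown allele"):
            simulate_genotypes(pool, {"east": [{"F09": 1.0}]}, {"east": 2}, seed=0)

    def test_carrier_proportions_match_binomial_sampling(self):
        # carrier probability at one locus with haplotype frequency f is
        # 1 - (1-f)^2; realized carrier counts must fall in the exact
        # binomial 99% interval for both subpopulations
        pool = simulate_allele_pool(2, 0, seed=3)
        n = 200
        freqs = {
            "east": [{"F01": 0.9, "F02": 0.1}],
            "north": [{"F01": 0.1, "F02": 0.9}],
        }
        truth = simulate_genotypes(pool, freqs, {"east": n, "north": n}, seed=9)
        for sp, f in (("east", 0.9), ("north", 0.1)):
            carriers = sum(
                1 for ind in truth.individuals
                if ind.subpop == sp and "F01" in ind.alleles
            )
            p_carrier = 1 - (1 - f) ** 2
            lo = stats.binom.ppf(0.005, n, p_carrier)
            hi = stats.binom.ppf(0.995, n, p_carrier)
            assert lo <= carriers <= hi


class TestClones:
    def test_noise_free_clones_equal_true_alleles(self, study_cohort):
        pool, truth, _ = study_cohort
        sim = simulate_clones(truth, error_rate=0.0, chimera_rate=0.0, seed=3)
        truth_by_ind = {
            ind.individual_id: {pool.seq_of(a) for a in ind.alleles}
            for ind in truth.individuals
        }
        for c in sim.clone_set.clones:
            assert c.seq in truth_by_ind[c.individual_id]
        assert set(sim.provenance.values()) == {FAITHFUL}

    def test_total_clone_count_tracks_poisson_mean(self, study_cohort):
        _, truth, sim = study_cohort
        total = len(sim.clone_set)
        assert abs(total - 26.9 * 32) <= 0.10 * 861

    def test_chimeric_fraction_matches_rate(self):
        # two-allele individuals, many clones: chimera fraction ~ rate
        pool = simulate_allele_pool(2, 0, target_divergence=0.05, seed=5)
        truth = simulate_genotypes(
            pool, {"east": [{("F01", "F02"): 1.0}]}, {"east": 100}, seed=0
        )
        sim = simulate_clones(truth, mean_clones=100, error_rate=0.0,
                              chimera_rate=0.1, seed=1)
        counts = sim.provenance_counts()
        frac = counts[CHIMERA] / len(sim.clone_set)
        assert abs(frac - 0.1) <= 0.01

    def test_chimeras_are_single_crossovers_of_parental_alleles(self):
        pool = simulate_allele_pool(2, 0, target_divergence=0.1, seed=6)
        truth = simulate_genotypes(
            pool, {"east": [{("F01", "F02"): 1.0}]}, {"east": 5}, seed=0
        )
        sim = simulate_clones(truth, mean_clones=50, error_rate=0.0,
                              chimera_rate=0.5, seed=2)
        a, b = pool.functional_alleles
        possible = {a, b}
        for k in range(1, len(a)):
            possible.add(a[:k] + b[k:])
            possible.add(b[:k] + a[k:])
        for c in sim.clone_set.clones:
            assert c.seq in possible

    def test_chimera_with_one_allele_degrades_to_faithful_and_logs(self):
        pool = simulate_allele_pool(1, 0, seed=7)
        truth = simulate_genotypes(pool, {"east": [{"F01": 1.0}]}, {"east": 3}, seed=0)
        sim = simulate_clones(truth, mean_clones=30, chimera_rate=1.0,
                              error_rate=0.0, seed=0)
        assert set(sim.provenance.values()) == {FAITHFUL}
        assert sim.log and "one allele" in sim.log[0]

    def test_provenance_partitions_the_clone_set(self, study_cohort):
        _, _, sim = study_cohort
        counts = sim.provenance_counts()
        assert counts[FAITHFUL] + counts[POINT_ERROR] + counts[CHIMERA] == len(
            sim.clone_set
        )
        assert set(sim.provenance) == {
            (c.individual_id, c.clone_id) for c in sim.clone_set.clones
        }

    def test_identical_seeds_reproduce_identical_fasta(self, tmp_path):
        from drbkit.io import write_clones_fasta

        out = []
        for run in range(2):
            _, _, sim = simulate_study_cohort(seed=42)
            path = tmp_path / f"clones{run}.fasta"
            write_clones_fasta(sim.clone_set, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]
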