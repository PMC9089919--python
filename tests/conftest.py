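import numpy as np
import pytest

from drbkit import datasets, simulate
from drbkit.sitemodels import CodonSiteModel


@pytest.fixture(scope="session")
def table1():
    """The packaged published genotype table (32 individuals, 14 alleles)."""
    return datasets.load_table1_fixture()


@pytest.fixture(scope="session")
def study_cohort():
    """One study-shaped synthetic cohort with ground truth."""
    return simulate.simulate_study_cohort(seed=11)


@pytest.fixture(scope="session")
def mixed_selection_fit():
    """A simulated alignment with a positively selected site class, fitted
    under all four site models; shared across the model-comparison tests."""
    tree = "((A:0.25,B:0.25):0.15,(C:0.25,D:0.25):0.15,(E:0.25,F:0.25):0.15);"
    rng = np.random.default_rng(7)
    omegas = np.where(rng.random(80) < 0.2, 4.0, 0.2)
    aln = simulate.simulate_codon_alignment(tree, 80, omegas, kappa=2.0, seed=7)
    fits = {
        m: CodonSiteModel(aln, model=m, codon_freq="equal").fit(restarts=2, seed=1)
        for m in ("M0", "M1a", "M2a", "M7", "M8")
    }
    return {"alignment": aln, "tree": tree, "omegas": omegas, "fits": fits}
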