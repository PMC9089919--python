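"""Synthetic-data generation with full ground truth.

Emulates the raw material of a clone-based MHC genotyping study: a pool of
divergent functional alleles plus one-base-deletion pseudogenes over an
80-codon exon fragment, multi-locus genotypes across two subpopulations with
divergent allele frequencies (including a perfectly linked allele pair), and
per-individual plasmid-clone sets carrying realistic PCR artifacts (point
errors from polymerase misincorporation, single-crossover chimeras between
co-amplified templates).  Every clone records its provenance so recovery by
the calling pipeline can be scored against truth.

A small Goldman–Yang codon-alignment simulator for the site-model
parameter-recovery tests lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from . import codons
from .calling import CloneRecord, CloneSet
from .phylo import PhyloTree
from .sitemodels import codon_rate_matrix, N_STATES

NT = "ACGT"
_NT_INDEX = {n: i for i, n in enumerate(NT)}

# defaults that emulate the study design (see docs/methods.md)
DEFAULT_N_CODONS = 80
DEFAULT_FRAME_OFFSET = 2
DEFAULT_MEAN_CLONES = 26.9
DEFAULT_ERROR_RATE = 2e-5
DEFAULT_CHIMERA_RATE = 0.005


# ---------------------------------------------------------------------------
# allele pool
# ---------------------------------------------------------------------------

@dataclass
class AllelePool:
    """Functional alleles (full amplicon length) and one-base-deletion
    pseudogenes, with name ↔ sequence bookkeeping."""

    functional_alleles: list[str]
    pseudogene_alleles: list[str]
    n_codons: int
    frame_offset: int = DEFAULT_FRAME_OFFSET

    def __post_init__(self):
        expected = 3 * self.n_codons + self.frame_offset
        for s in self.functional_alleles:
            if len(s) != expected:
                raise ValueError("functional allele of wrong length")
            if codons.premature_stops(s, self.frame_offset):
                raise ValueError("functional allele contains an in-frame stop")
        if len(set(self.functional_alleles)) != len(self.functional_alleles):
            raise ValueError("functional alleles are not unique")
        for s in self.pseudogene_alleles:
            if len(s) != expected - 1:
                raise ValueError("pseudogene allele must be one base shorter")

    @property
    def names(self) -> dict[str, str]:
        out = {f"F{i:02d}": s for i, s in enumerate(self.functional_alleles, 1)}
        out.update({f"P{i:02d}": s for i, s in enumerate(self.pseudogene_alleles, 1)})
        return out

    def seq_of(self, name: str) -> str:
        return self.names[name]

    def functional_names(self) -> list[str]:
        return [f"F{i:02d}" for i in range(1, len(self.functional_alleles) + 1)]

    def pseudogene_names(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, len(self.pseudogene_alleles) + 1)]

    def mean_pairwise_p_distance(self) -> float:
        seqs = self.functional_alleles
        if len(seqs) < 2:
            return 0.0
        tot = n = 0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                diff = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                tot += diff / len(seqs[i])
                n += 1
        return tot / n


def _k80_nucleotide_generator(kappa: float) -> np.ndarray:
    """4x4 K80 rate matrix normalized to one substitution per unit time."""
    Q = np.ones((4, 4))
    for i, a in enumerate(NT):
        for j, b in enumerate(NT):
            if i != j and ((a in "AG") == (b in "AG")):
                Q[i, j] = kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.mean(np.diag(Q))
    return Q / rate


def _divergence_for_target_p(target_p: float, kappa: float) -> float:
    """Total tip-to-tip distance D whose expected p-distance equals target."""
    Q = _k80_nucleotide_generator(kappa)

    def expected_p(D: float) -> float:
        P = linalg.expm(Q * D)
        return 1.0 - float(np.trace(P)) / 4.0

    return float(optimize.brentq(lambda D: expected_p(D) - target_p, 1e-9, 20.0))


def simulate_allele_pool(
    n_functional: int,
    n_pseudo: int = 0,
    n_codons: int = DEFAULT_N_CODONS,
    target_divergence: float = 0.05,
    kappa: float = 2.0,
    frame_offset: int = DEFAULT_FRAME_OFFSET,
    seed: int = 0,
) -> AllelePool:
    """Simulate an allele pool around a random stop-free root sequence.

    Each functional allele evolves independently from the root by K80
    substitution at half the target tip-to-tip divergence, resampling any
    codon that becomes an in-frame stop; pseudogenes are functional alleles
    with one random base deleted.  Mean pairwise p-distance tracks
    ``target_divergence`` (within ~20% relative for pools of >= 5 alleles).
    """
    if n_functional < 1:
        raise ValueError("need at least one functional allele")
    if not 0.0 <= target_divergence <= 0.5:
        raise ValueError("target_divergence must lie in [0, 0.5]")
    if target_divergence == 0.0 and n_functional > 1:
        raise ValueError(
            "unsatisfiable: divergence 0 cannot produce multiple unique alleles"
        )
    rng = np.random.default_rng(seed)

    # random stop-free root
    lead = "".join(rng.choice(list(NT), size=frame_offset))
    root_codons = []
    while len(root_codons) < n_codons:
        c = "".join(rng.choice(list(NT), size=3))
        if not codons.is_stop(c):
            root_codons.append(c)
    root = lead + "".join(root_codons)

    if n_functional == 1:
        return AllelePool([root], _make_pseudogenes([root], n_pseudo, rng),
                          n_codons, frame_offset)

    D = _divergence_for_target_p(target_divergence, kappa)
    P = linalg.expm(_k80_nucleotide_generator(kappa) * (D / 2.0))

    def evolve_tip() -> str:
        arr = [
            NT[rng.choice(4, p=P[_NT_INDEX[b]])] for b in root
        ]
        seq = "".join(arr)
        # stop-avoidance resampling per codon
        for _ in range(1000):
            stops = codons.premature_stops(seq, frame_offset)
            if not stops:
                return seq
            chars = list(seq)
            for s1 in stops:
                start = frame_offset + 3 * (s1 - 1)
                for k in range(start, start + 3):
                    chars[k] = NT[rng.choice(4, p=P[_NT_INDEX[root[k]]])]
            seq = "".join(chars)
        raise RuntimeError("stop-avoidance resampling failed to converge")

    alleles: list[str] = []
    attempts = 0
    while len(alleles) < n_functional:
        tip = evolve_tip()
        if tip not in alleles:
            alleles.append(tip)
        attempts += 1
        if attempts > 200 * n_functional:
            raise ValueError(
                "unsatisfiable: cannot draw enough unique alleles at this divergence"
            )
    return AllelePool(alleles, _make_pseudogenes(alleles, n_pseudo, rng),
                      n_codons, frame_offset)


def _make_pseudogenes(functional: list[str], n_pseudo: int, rng) -> list[str]:
    out: list[str] = []
    attempts = 0
    while len(out) < n_pseudo:
        parent = functional[rng.integers(len(functional))]
        pos = int(rng.integers(len(parent)))
        ps = parent[:pos] + parent[pos + 1 :]
        if ps not in out:
            out.append(ps)
        attempts += 1
        if attempts > 1000:
            raise ValueError("unsatisfiable: cannot draw unique pseudogenes")
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

Haplotype = tuple[str, ...]  # allele names carried together; () is a null


@dataclass
class Individual:
    individual_id: str
    subpop: str
    alleles: frozenset[str]


@dataclass
class CohortTruth:
    """Ground-truth genotypes: who carries which alleles, plus the linked
    pairs that co-occur by construction."""

    individuals: list[Individual]
    linkage_pairs: list[tuple[str, str]]
    pool: AllelePool

    def labels(self) -> dict[str, str]:
        return {ind.individual_id: ind.subpop for ind in self.individuals}

    def allele_carriers(self, name: str) -> int:
        return sum(1 for ind in self.individuals if name in ind.alleles)

    def check_linkage(self) -> bool:
        for a, b in self.linkage_pairs:
            for ind in self.individuals:
                if (a in ind.alleles) != (b in ind.alleles):
                    return False
        return True


def _normalize_hap(key) -> Haplotype:
    if key is None:
        return ()
    if isinstance(key, str):
        return (key,)
    return tuple(key)


def simulate_genotypes(
    pool: AllelePool,
    subpop_allele_freqs: dict[str, list[dict]],
    n_per_subpop: dict[str, int],
    linkage_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
) -> CohortTruth:
    """Draw diploid multi-locus genotypes from per-subpopulation haplotype
    frequency tables.

    ``subpop_allele_freqs[subpop]`` is a list over loci; each locus is a
    mapping from a haplotype (an allele name, a tuple of linked allele
    names, or None for a null haplotype) to its frequency (summing to 1).
    Linked allele pairs must appear only as joint haplotypes, which makes
    their perfect co-occurrence structural.  Each individual receives two
    haplotypes per locus; its allele set is the union.  Individuals drawing
    no functional allele at all are redrawn (every genotyped animal in a
    study like this amplified at least one template).
    """
    linkage_pairs = list(linkage_pairs or [])
    known = set(pool.names)
    rng = np.random.default_rng(seed)

    tables: dict[str, list[tuple[list[Haplotype], np.ndarray]]] = {}
    for subpop, loci in subpop_allele_freqs.items():
        tabs = []
        for locus in loci:
            haps = [_normalize_hap(k) for k in locus.keys()]
            freqs = np.array(list(locus.values()), dtype=float)
            for h in haps:
                for a in h:
                    if a not in known:
                        raise ValueError(f"frequency table references unknown allele {a!r}")
            if abs(freqs.sum() - 1.0) > 1e-6:
                raise ValueError(f"frequencies at a locus of {subpop!r} do not sum to 1")
            tabs.append((haps, freqs / freqs.sum()))
        tables[subpop] = tabs
    for a, b in linkage_pairs:
        for subpop, tabs in tables.items():
            for haps, _ in tabs:
                for h in haps:
                    if (a in h) != (b in h):
                        raise ValueError(
                            f"linked pair ({a},{b}) split across haplotype {h} in {subpop!r}"
                        )

    functional = set(pool.functional_names())
    individuals: list[Individual] = []
    idx = 0
    for subpop, n in n_per_subpop.items():
        if subpop not in tables:
            raise ValueError(f"no frequency table for subpopulation {subpop!r}")
        for _ in range(n):
            idx += 1
            for _attempt in range(1000):
                alleles: set[str] = set()
                for haps, freqs in tables[subpop]:
                    for _copy in range(2):
                        h = haps[rng.choice(len(haps), p=freqs)]
                        alleles.update(h)
                if alleles & functional:
                    break
            individuals.append(
                Individual(f"IND{idx}", subpop, frozenset(alleles))
            )
    return CohortTruth(individuals, linkage_pairs, pool)


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------

FAITHFUL = "faithful"
POINT_ERROR = "point_error"
CHIMERA = "chimera"


@dataclass
class CloneSimResult:
    clone_set: CloneSet
    provenance: dict[tuple[str, str], str]
    log: list[str] = field(default_factory=list)

    def provenance_counts(self) -> dict[str, int]:
        out = {FAITHFUL: 0, POINT_ERROR: 0, CHIMERA: 0}
        for v in self.provenance.values():
            out[v] += 1
        return out


def simulate_clones(
    truth: CohortTruth,
    mean_clones: float = DEFAULT_MEAN_CLONES,
    error_rate: float = DEFAULT_ERROR_RATE,
    chimera_rate: float = DEFAULT_CHIMERA_RATE,
    seed: int = 0,
) -> CloneSimResult:
    """Simulate plasmid-clone sequencing of each individual's amplicon mix.

    Clone counts are Poisson(mean_clones) with a floor of 1.  Each clone
    starts from a uniformly chosen true allele of its individual; with
    probability ``chimera_rate`` it is instead a single-crossover recombinant
    of two distinct alleles of the same individual (uniform breakpoint);
    point errors then hit every base independently with ``error_rate``.
    Provenance records the generating mechanism (chimera wins over
    point_error; a chimera request in a one-allele individual degrades to a
    faithful clone and is logged).
    """
    if mean_clones <= 0:
        raise ValueError("mean_clones must be positive")
    if not (0 <= error_rate <= 1 and 0 <= chimera_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[CloneRecord] = []
    provenance: dict[tuple[str, str], str] = {}
    log: list[str] = []
    for ind in truth.individuals:
        alleles = sorted(ind.alleles)
        seqs = [truth.pool.seq_of(a) for a in alleles]
        n = max(1, int(rng.poisson(mean_clones)))
        for k in range(1, n + 1):
            source = FAITHFUL
            if rng.random() < chimera_rate:
                if len(seqs) >= 2:
                    i, j = rng.choice(len(seqs), size=2, replace=False)
                    a, b = seqs[i], seqs[j]
                    cut = int(rng.integers(1, min(len(a), len(b))))
                    seq = a[:cut] + b[cut:]
                    source = CHIMERA
                else:
                    seq = seqs[0]
                    log.append(
                        f"{ind.individual_id}: chimera requested with one allele; "
                        "emitted faithful clone"
                    )
            else:
                seq = seqs[rng.integers(len(seqs))]
            if error_rate > 0:
                n_err = rng.binomial(len(seq), error_rate)
                if n_err:
                    pos = rng.choice(len(seq), size=n_err, replace=False)
                    chars = list(seq)
                    for p in pos:
                        chars[p] = rng.choice([x for x in NT if x != chars[p]])
                    seq = "".join(chars)
                    if source == FAITHFUL:
                        source = POINT_ERROR
            clone_id = f"clone{k}"
            records.append(CloneRecord(ind.individual_id, clone_id, seq))
            provenance[(ind.individual_id, clone_id)] = source
    return CloneSimResult(CloneSet(records), provenance, log)


# ---------------------------------------------------------------------------
# study-shaped cohort defaults
# ---------------------------------------------------------------------------

def study_frequency_tables() -> dict[str, list[dict]]:
    """Per-subpopulation haplotype frequency tables shaped like the study:
    a near-fixed common allele in the north, a linked pair near fixation in
    the east but rare in the north, a tail of rare alleles, one pseudogene
    fixed everywhere and two rare ones.  Haplotype frequencies are back-
    calculated from the carrier proportions the study reports."""
    east = [
        {"F01": 0.44, None: 0.56},
        {("F02", "F03"): 0.90, None: 0.10},
        {"F04": 0.054, "F06": 0.027, "F07": 0.027, "F08": 0.027,
         "F09": 0.027, "F10": 0.027, None: 0.811},
        {"P01": 1.0},
        {"P02": 0.027, "P03": 0.054, None: 0.919},
    ]
    north = [
        {"F01": 0.85, None: 0.15},
        {("F02", "F03"): 0.17, None: 0.83},
        {"F04": 0.04, "F05": 0.077, "F06": 0.04, "F11": 0.04, None: 0.803},
        {"P01": 1.0},
        {None: 1.0},
    ]
    return {"east": east, "north": north, "admixed": north}


def simulate_study_cohort(
    seed: int = 0,
    n_functional: int = 11,
    n_pseudo: int = 3,
    n_codons: int = DEFAULT_N_CODONS,
    target_divergence: float = 0.05,
    mean_clones: float = DEFAULT_MEAN_CLONES,
    error_rate: float = DEFAULT_ERROR_RATE,
    chimera_rate: float = DEFAULT_CHIMERA_RATE,
    n_per_subpop: dict[str, int] | None = None,
    require_all_carried: bool = True,
) -> tuple[AllelePool, CohortTruth, CloneSimResult]:
    """End-to-end study-shaped simulation: pool -> genotypes -> clones.

    With ``require_all_carried`` (default) the cohort is redrawn until every
    pool allele has at least one carrier: an observed allele catalog is by
    definition the set of alleles the cohort actually carries, so a cohort
    emulating a study with an 11+3 catalog must carry all 14.
    """
    pool = simulate_allele_pool(
        n_functional, n_pseudo, n_codons=n_codons,
        target_divergence=target_divergence, seed=seed,
    )
    tables = study_frequency_tables()
    counts = n_per_subpop or {"east": 19, "north": 11, "admixed": 2}
    truth = None
    for attempt in range(1000):
        cand = simulate_genotypes(
            pool, tables, counts, linkage_pairs=[("F02", "F03")],
            seed=seed + 1 + 7919 * attempt,
        )
        if not require_all_carried or all(
            cand.allele_carriers(a) >= 1 for a in pool.names
        ):
            truth = cand
            break
    if truth is None:
        raise RuntimeError("could not draw a cohort carrying every allele")
    clones = simulate_clones(
        truth, mean_clones=mean_clones, error_rate=error_rate,
        chimera_rate=chimera_rate, seed=seed + 2,
    )
    return pool, truth, clones


# ---------------------------------------------------------------------------
# codon-alignment simulation (GY94) for parameter-recovery tests
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: PhyloTree | str,
    n_sites: int,
    site_omegas,
    kappa: float = 2.0,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a codon alignment along ``tree`` under the Goldman–Yang model.

    ``site_omegas`` is either a scalar or a length-``n_sites`` vector of
    per-site omega values; branch lengths are expected substitutions per
    codon under the site-averaged rate.  Codon frequencies are equal.
    """
    if isinstance(tree, str):
        tree = PhyloTree.from_newick(tree)
    rng = np.random.default_rng(seed)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    omegas = np.broadcast_to(np.asarray(site_omegas, dtype=float), (n_sites,)).copy()
    uniq = np.unique(omegas)
    rates = {w: codon_rate_matrix(kappa, w, pi)[1] for w in uniq}
    scale = float(np.mean([rates[w] for w in omegas]))

    Ps_cache: dict[tuple[float, float], np.ndarray] = {}

    def P_of(w: float, t: float) -> np.ndarray:
        key = (w, t)
        if key not in Ps_cache:
            Q, _ = codon_rate_matrix(kappa, w, pi)
            Ps_cache[key] = linalg.expm(Q * t / scale)
        return Ps_cache[key]

    root_state = rng.choice(N_STATES, size=n_sites, p=pi)

    out: dict[str, str] = {}

    def descend(node, state):
        for ch in node.children:
            child_state = state.copy()
            for w in uniq:
                mask = omegas == w
                P = P_of(float(w), float(ch.length))
                for s in np.nonzero(mask)[0]:
                    child_state[s] = rng.choice(N_STATES, p=P[state[s]])
            if ch.is_tip():
                out[ch.name] = "".join(codons.SENSE_CODONS[i] for i in child_state)
            else:
                descend(ch, child_state)

    descend(tree.root, root_state)
    return out
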