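"""Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction, partitioned into
antigen-binding sites (ABS), non-ABS, and overall codons.

Synonymous and nonsynonymous site counts come from single-nucleotide
mutation fates under the standard genetic code, with mutations to stop
codons excluded from the denominator at each codon position.  Differences
between codons that differ at more than one position are averaged over all
minimal substitution paths, excluding paths that pass through a stop codon
(unweighted pathway averaging).  Proportions are corrected with
d = -(3/4)·ln(1 - 4p/3) and flagged undefined at saturation (p >= 3/4).
Across an allele set, rates are means over all unordered sequence pairs;
standard errors come from a seeded codon-column bootstrap.

For MHC exon 2 the expectation under balancing/positive selection is
omega > 1 at the ABS codons and omega < 1 at the structurally constrained
remainder.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from math import log

import numpy as np

from . import codons


# ---------------------------------------------------------------------------
# ABS mask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsMask:
    """1-based codon indices of presumed antigen-binding sites."""

    positions: frozenset[int]
    n_codons: int

    def __post_init__(self):
        bad = [p for p in self.positions if not 1 <= p <= self.n_codons]
        if bad:
            raise ValueError(f"mask positions out of range 1..{self.n_codons}: {sorted(bad)}")

    def complement(self) -> frozenset[int]:
        return frozenset(range(1, self.n_codons + 1)) - self.positions

    def __len__(self) -> int:
        return len(self.positions)


def load_abs_mask(source=None, n_codons: int = 80) -> AbsMask:
    """Load an ABS mask from a file (one 1-based codon index per line, '#'
    comments) or the packaged default (18 positions over 80 codons inferred
    from the human HLA-DR peptide-contact residues)."""
    if source is None:
        text = (
            resources.files("drbkit.data").joinpath("abs_mask_default.txt").read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    positions = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            positions.add(int(line))
    return AbsMask(frozenset(positions), n_codons)


# ---------------------------------------------------------------------------
# per-codon counts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of a sense codon; s + n = 3."""
    if codons.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in codons.CODON_INDEX:
        raise ValueError(f"not a valid codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for mpos, _old, _new, mutant in codons.single_step_neighbors(codon):
            if mpos != pos:
                continue
            if codons.is_stop(mutant):
                continue
            nonstop += 1
            if codons.AMINO_ACID[mutant] == codons.AMINO_ACID[codon]:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal substitution paths that avoid stop codons.

    If every minimal path crosses a stop codon (possible only for some
    3-step pairs), paths through stops are admitted as a fallback.
    """
    for c in (codon_a, codon_b):
        if codons.is_stop(c):
            raise ValueError(f"stop codon {c!r} in comparison")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if codons.is_stop(nxt):
                return None
            if codons.AMINO_ACID[cur] == codons.AMINO_ACID[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        # fallback: count through-stop paths rather than fail
        valid = []
        for order in itertools.permutations(diff_pos):
            cur = codon_a
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                same = (not codons.is_stop(cur) and not codons.is_stop(nxt)
                        and codons.AMINO_ACID[cur] == codons.AMINO_ACID[nxt])
                sd, nd = (sd + 1.0, nd) if same else (sd, nd + 1.0)
                cur = nxt
            valid.append((sd, nd))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC-corrected rate and a defined-flag (False at saturation p >= 3/4)."""
    if p >= 0.75:
        return float("nan"), False
    return -0.75 * log(1.0 - 4.0 * p / 3.0), True


# ---------------------------------------------------------------------------
# pairwise and partitioned estimates
# ---------------------------------------------------------------------------

@dataclass
class PairwiseNG:
    Nd: float
    Sd: float
    N: float
    S: float
    pN: float | None
    pS: float | None
    dN: float
    dS: float
    dN_defined: bool
    dS_defined: bool


def _codon_lists(seq_a: str, seq_b: str, frame_offset: int = 0) -> tuple[list[str], list[str]]:
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    ca = codons.codons_of(seq_a, frame_offset)
    cb = codons.codons_of(seq_b, frame_offset)
    return ca, cb


def pairwise_dnds(
    seq_a: str,
    seq_b: str,
    mask: AbsMask | None = None,
    mask_mode: str = "within",
    frame_offset: int = 0,
) -> PairwiseNG:
    """NG86 estimate for one sequence pair, optionally restricted to the
    mask's codon positions (``mask_mode='within'``) or their complement
    (``'outside'``)."""
    ca, cb = _codon_lists(seq_a, seq_b, frame_offset)
    if mask is not None:
        keep = mask.positions if mask_mode == "within" else mask.complement()
        ca = [c for i, c in enumerate(ca, 1) if i in keep]
        cb = [c for i, c in enumerate(cb, 1) if i in keep]
    S = N = Sd = Nd = 0.0
    for a, b in zip(ca, cb):
        sa, na = ng_site_counts(a)
        sb, nb = ng_site_counts(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_pair_differences(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS, dS_ok = jukes_cantor(pS) if pS is not None else (float("nan"), False)
    dN, dN_ok = jukes_cantor(pN) if pN is not None else (float("nan"), False)
    return PairwiseNG(Nd=Nd, Sd=Sd, N=N, S=S, pN=pN, pS=pS,
                      dN=dN, dS=dS, dN_defined=dN_ok, dS_defined=dS_ok)


@dataclass
class SelectionEstimate:
    partition: str
    n_codons: int
    dN: float
    dN_se: float
    dS: float
    dS_se: float
    omega: float | None  # dN/dS, None when dS is 0 or undefined
    n_pairs: int
    n_pairs_undefined: int


def _pair_column_stats(seqs: list[list[str]]) -> np.ndarray:
    """Per (pair, codon column) tensor of (Sd, Nd, S, N) contributions."""
    n = len(seqs)
    C = len(seqs[0])
    pairs = list(itertools.combinations(range(n), 2))
    out = np.zeros((len(pairs), C, 4))
    for k, (i, j) in enumerate(pairs):
        for c in range(C):
            a, b = seqs[i][c], seqs[j][c]
            sd, nd = codon_pair_differences(a, b)
            sa, na = ng_site_counts(a)
            sb, nb = ng_site_counts(b)
            out[k, c] = (sd, nd, (sa + sb) / 2.0, (na + nb) / 2.0)
    return out


def _rates_from_sums(sums: np.ndarray) -> tuple[float, float, int]:
    """Mean-of-pairs dN and dS from (pairs, 4) sums; returns the number of
    pairs dropped for saturation/zero-site reasons."""
    dNs, dSs = [], []
    dropped = 0
    for sd, nd, S, N in sums:
        if S <= 0 or N <= 0:
            dropped += 1
            continue
        pS, pN = sd / S, nd / N
        if pS >= 0.75 or pN >= 0.75:
            dropped += 1
            continue
        dSs.append(-0.75 * log(1 - 4 * pS / 3))
        dNs.append(-0.75 * log(1 - 4 * pN / 3))
    if not dNs:
        return float("nan"), float("nan"), dropped
    return float(np.mean(dNs)), float(np.mean(dSs)), dropped


def partitioned_rates(
    alignment: dict[str, str],
    mask: AbsMask | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    frame_offset: int = 0,
) -> dict[str, SelectionEstimate]:
    """Mean-of-pairs NG86 rates for the overall / ABS / non-ABS partitions
    with codon-bootstrap standard errors.

    dN and dS are means over all unordered pairs; the SE of each is the
    standard deviation of that mean over ``bootstrap_reps`` resamplings of
    codon columns (within the partition) with replacement.
    """
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    seq_codons = [codons.codons_of(alignment[n], frame_offset) for n in names]
    C = len(seq_codons[0])
    if any(len(s) != C for s in seq_codons):
        raise ValueError("aligned sequences must have equal codon counts")
    if mask is None:
        mask = AbsMask(frozenset(), C)
    stats_tensor = _pair_column_stats(seq_codons)  # (pairs, C, 4)
    rng = np.random.default_rng(seed)

    partitions = {
        "overall": np.arange(C),
        "ABS": np.array(sorted(i - 1 for i in mask.positions), dtype=int),
        "nonABS": np.array(sorted(i - 1 for i in mask.complement() if i <= C), dtype=int),
    }
    out = {}
    n_pairs = stats_tensor.shape[0]
    for part, cols in partitions.items():
        if len(cols) == 0:
            out[part] = SelectionEstimate(part, 0, float("nan"), float("nan"),
                                          float("nan"), float("nan"), None, n_pairs, n_pairs)
            continue
        sums = stats_tensor[:, cols, :].sum(axis=1)
        dN, dS, dropped = _rates_from_sums(sums)
        # codon bootstrap within the partition
        boot_dN = np.empty(bootstrap_reps)
        boot_dS = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            idx = rng.choice(cols, size=len(cols), replace=True)
            bsums = stats_tensor[:, idx, :].sum(axis=1)
            boot_dN[r], boot_dS[r], _ = _rates_from_sums(bsums)
        omega = dN / dS if (dS and np.isfinite(dS) and dS > 0) else None
        out[part] = SelectionEstimate(
            partition=part,
            n_codons=len(cols),
            dN=dN,
            dN_se=float(np.nanstd(boot_dN, ddof=1)),
            dS=dS,
            dS_se=float(np.nanstd(boot_dS, ddof=1)),
            omega=omega,
            n_pairs=n_pairs,
            n_pairs_undefined=dropped,
        )
    return out


def rates_table(estimates: dict[str, SelectionEstimate]) -> str:
    """Human-readable partition table (position, codons, dN±SE, dS±SE, omega)."""
    lines = ["partition\tn_codons\tdN\tdN_se\tdS\tdS_se\tomega"]
    for part in ("overall", "ABS", "nonABS"):
        if part not in estimates:
            continue
        e = estimates[part]
        om = f"{e.omega:.3f}" if e.omega is not None else "NA"
        lines.append(
            f"{e.partition}\t{e.n_codons}\t{e.dN:.3f}\t{e.dN_se:.3f}"
            f"\t{e.dS:.3f}\t{e.dS_se:.3f}\t{om}"
        )
    return "\n".join(lines)
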