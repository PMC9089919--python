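"""Subpopulation statistics on the genotype matrix: allele carrier counts,
a two-sided Fisher exact test (hypergeometric probability-mass rule, the R
convention), Welch's unequal-variance t-test, and per-individual diversity
summaries with the minimum-locus-number bound.

The study design this serves: individuals from two regional subpopulations
(plus a couple of admixed animals merged into one of them by geography),
scored for presence/absence of each allele; the questions are whether
carrier frequencies and per-individual allele counts differ between the
subpopulations, and how many loci the maximum per-individual allele count
implies (ceil(max/2) for a diploid)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import GenotypeMatrix


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows subpopulations, columns trait yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (with the R implementation's 1+1e-7 relative slack).
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    t = ContingencyTable2x2(a, b, c, d)  # validates
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("degenerate: zero variance in both groups")
    sx, sy = vx / len(x), vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def _merged_subpop(matrix: GenotypeMatrix, merge_admixed_into: str = "north") -> pd.Series:
    sub = matrix.subpop.copy()
    return sub.replace({"admixed": merge_admixed_into})


def carrier_counts(
    matrix: GenotypeMatrix,
    allele_set,
    mode: str = "all",
    merge_admixed_into: str = "north",
) -> dict[str, tuple[int, int]]:
    """Per-subpopulation (carriers, n) for a trait defined over alleles.

    mode='all': individual carries every allele in the set; 'any': at least
    one; 'exactly_one_functional': the individual's whole genotype holds
    exactly one functional allele (the allele set is ignored).  Admixed
    individuals are merged into ``merge_admixed_into`` first.
    """
    allele_set = list(allele_set)
    unknown = [a for a in allele_set if a not in matrix.presence.columns]
    if unknown:
        raise ValueError(f"unknown allele name(s): {unknown}")
    sub = _merged_subpop(matrix, merge_admixed_into)
    if mode == "all":
        hit = matrix.presence[allele_set].all(axis=1) if allele_set else pd.Series(
            True, index=matrix.presence.index
        )
    elif mode == "any":
        hit = matrix.presence[allele_set].any(axis=1) if allele_set else pd.Series(
            False, index=matrix.presence.index
        )
    elif mode == "exactly_one_functional":
        hit = matrix.presence[matrix.functional_alleles()].sum(axis=1) == 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for sp in sorted(sub.unique()):
        sel = sub == sp
        out[sp] = (int(hit[sel].sum()), int(sel.sum()))
    return out


@dataclass
class DiversitySummary:
    mean_functional_per_individual: dict[str, float]
    mean_pseudogene_per_individual: dict[str, float]
    max_alleles_one_individual: int
    locus_lower_bound: int
    carrier_frequencies: pd.DataFrame  # alleles x subpops, proportions

    def display(self) -> str:
        lines = ["Diversity summary"]
        for sp, m in self.mean_functional_per_individual.items():
            ps = self.mean_pseudogene_per_individual[sp]
            lines.append(f"  {sp}: mean {m:.1f} functional alleles ({ps:.1f} pseudogenes)")
        lines.append(
            f"  max alleles in one individual: {self.max_alleles_one_individual}"
            f" -> at least {self.locus_lower_bound} functional loci per haploid genome"
        )
        return "\n".join(lines)


def summarize_diversity(
    matrix: GenotypeMatrix, merge_admixed_into: str = "north"
) -> DiversitySummary:
    """Mean functional/pseudogene alleles per individual per subpopulation
    (full precision; rounding is display-only), the maximum per-individual
    functional allele count, and the implied minimum number of loci."""
    if matrix.presence.empty:
        raise ValueError("empty genotype matrix")
    sub = _merged_subpop(matrix, merge_admixed_into)
    func = matrix.functional_alleles()
    pseudo = matrix.pseudogene_alleles()
    n_func = matrix.presence[func].sum(axis=1)
    n_pseudo = matrix.presence[pseudo].sum(axis=1)
    mean_f, mean_p = {}, {}
    freq = {}
    for sp in sorted(sub.unique()):
        sel = sub == sp
        mean_f[sp] = float(n_func[sel].mean())
        mean_p[sp] = float(n_pseudo[sel].mean())
        freq[sp] = matrix.presence.loc[sel].mean(axis=0)
    mx = int(n_func.max())
    return DiversitySummary(
        mean_functional_per_individual=mean_f,
        mean_pseudogene_per_individual=mean_p,
        max_alleles_one_individual=mx,
        locus_lower_bound=math.ceil(mx / 2),
        carrier_frequencies=pd.DataFrame(freq),
    )


def subpopulation_report(
    matrix: GenotypeMatrix, merge_admixed_into: str = "north"
) -> dict:
    """The full statistics stage: carrier contrasts, Fisher tests on the
    linked-pair and single-allele contrasts, the Welch t-test on
    per-individual functional allele counts, and the diversity summary."""
    sub = _merged_subpop(matrix, merge_admixed_into)
    func = matrix.functional_alleles()
    div = summarize_diversity(matrix, merge_admixed_into)

    def fisher_for(mode: str, alleles) -> dict:
        cc = carrier_counts(matrix, alleles, mode=mode, merge_admixed_into=merge_admixed_into)
        sps = sorted(cc)
        if len(sps) != 2:
            return {"carriers": cc, "p": None}
        (c1, n1), (c2, n2) = cc[sps[0]], cc[sps[1]]
        p = fisher_exact_two_sided([[c1, n1 - c1], [c2, n2 - c2]])
        return {"carriers": {sp: list(cc[sp]) for sp in sps}, "p": p}

    counts_by_sub = {
        sp: [int(v) for v in matrix.presence.loc[sub == sp, func].sum(axis=1)]
        for sp in sorted(sub.unique())
    }
    t = df = p_t = None
    sps = sorted(counts_by_sub)
    if len(sps) == 2:
        t, df, p_t = welch_t_test(counts_by_sub[sps[0]], counts_by_sub[sps[1]])
    report = {
        "n_individuals": int(len(matrix.individuals)),
        "subpop_sizes": {sp: int((sub == sp).sum()) for sp in sorted(sub.unique())},
        "mean_functional": div.mean_functional_per_individual,
        "mean_pseudogene": div.mean_pseudogene_per_individual,
        "max_alleles_one_individual": div.max_alleles_one_individual,
        "locus_lower_bound": div.locus_lower_bound,
        "welch_t": {"t": t, "df": df, "p": p_t},
        "per_allele_carriers": {
            a: {
                sp: int(matrix.presence.loc[sub == sp, a].sum())
                for sp in sorted(sub.unique())
            }
            for a in matrix.alleles
        },
        "single_functional_contrast": fisher_for("exactly_one_functional", []),
    }
    return report
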