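# Methods

This note documents the models and procedures implemented in `drbkit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Study design the package serves

A multi-locus MHC class II *DRB* exon-2 fragment (242 nt: a 2-nt partial
codon followed by 80 complete codons) is PCR-amplified from each
individual, cloned into plasmids, and sequenced — roughly 27 clones per
individual. Because several duplicated loci co-amplify, genotypes are
recorded as presence/absence of each distinct sequence per individual, not
as two alleles of one locus. The analysis questions are: which sequences
are real alleles; which are functional versus pseudogenes; how allele
carriage differs between two subpopulations; and whether the gene shows the
balancing/positive selection and trans-species polymorphism typical of MHC.

## Allele calling

**Validation rule.** A distinct clone sequence is accepted only if detected
at least twice — twice in one individual or once each in at least two
individuals. Singletons are discarded as likely PCR artifacts. The rule is
applied globally; a validated allele is then assigned to every individual
in which it was observed at least once (per-individual assignment
thresholds are not part of the rule).

*Limitation (quantified):* the rule cannot exclude artifacts that recur.
Two single-crossover chimeras of the same ordered parent pair whose
breakpoints fall in the same inter-SNP interval are byte-identical and
pass validation. At a chimera rate of 0.5% per clone in a cohort of ~860
clones this happens with expectation of order 0.02 per cohort — rare but
not impossible, and the package's own recovery tests have observed exactly
one such false call in 20 simulated cohorts. Wet-lab studies close this gap
with database verification of each validated sequence, which is outside
this package's scope.

**Functional/pseudogene classification.** A sequence is functional iff it
has the expected amplicon length (242 nt by default) and its translation
after the frame offset contains no stop codon; a 1–6-nt length deviation is
treated as a germline indel (pseudogene), and larger deviations are
rejected as non-target amplicons. Only the length test and the stop scan
decide status; a global pairwise alignment (match +1, mismatch −1, gap −2)
against the closest validated functional allele merely localizes the
deletion for reporting. The frame offset defaults to 2 nt so that 242 nt
yield exactly 80 complete codons; it is configurable.

**Naming.** Functional alleles are numbered `*01, *02, …` by descending
carrier count (ties by first observation), pseudogenes `*PS01, …` likewise.

## Subpopulation statistics

Admixed individuals are merged into the northern subpopulation by default
(their geographic origin in the motivating study); the merge target is
configurable. The Fisher exact test is two-sided by the probability-mass
rule — the p-value is the sum of hypergeometric probabilities, over all
2×2 tables with the observed margins, that do not exceed the observed
table's probability (with the 1+1e-7 relative slack R uses) — so its
output matches `fisher.test` in R. Welch's t-test uses the
Welch–Satterthwaite degrees of freedom. Per-individual means are kept at
full precision and rounded only for display. The minimum number of loci is
⌈max alleles in one individual / 2⌉ for a diploid genome.

## Counting-based selection (NG86)

Synonymous/nonsynonymous sites per codon come from single-nucleotide
mutation fates under the standard genetic code, with mutations to stop
codons excluded from the denominator at each position. Differences between
codons differing at k positions are averaged over the k! minimal
substitution paths, excluding paths through stop codons (unweighted
pathway averaging; if every path crosses a stop, through-stop paths are
admitted rather than failing). Proportions are corrected with
d = −(3/4)·ln(1 − 4p/3) and flagged undefined at p ≥ 3/4. Across an allele
set, dN and dS are means over all unordered pairs (mean-of-pairs, not
concatenation), and standard errors come from a 1000-replicate seeded
bootstrap of codon columns within each partition. These are the canonical
NG86 choices; counting variants that weight pathways or correct site
counts for transition bias will differ by a few percent at MHC-typical
divergences, so partition-level ω values should be compared across methods
only to about ±0.05.

**ABS mask.** The antigen-binding-site partition defaults to 18 of the 80
codons, inferred by mapping the crystallographic peptide-contact residues
of the human HLA-DR β1 domain onto the fragment (amplicon codon k ↔ β1
residue k+8). The true contact set of a non-human DR β chain is an
inference from human structure, not an observation; the mask ships as a
plain-text file and any user mask can be supplied.

## Likelihood-based selection (codon site models)

The substitution process follows the Goldman–Yang parameterization: the
rate between sense codons differing at one position is
π_target × κ^[transition] × ω^[nonsynonymous], zero otherwise, over the 61
sense codons; branch lengths are expected substitutions per codon under
the fitted site-class mixture. Codon frequencies default to F3x4 (empirical
position-specific nucleotide frequencies), with equal-frequency and F1x4
options. Site-to-site variation in ω uses the standard mixture family:

| model | ω distribution across sites | free class parameters |
|-------|-----------------------------|-----------------------|
| M0    | single ω                    | ω |
| M1a   | ω0 < 1, ω1 = 1              | p0, ω0 |
| M2a   | M1a + ω2 ≥ 1                | p0, p1, ω0, ω2 |
| M7    | beta(p, q) on (0, 1)        | p, q |
| M8    | p0·beta(p, q) + p1·ωs ≥ 1   | p0, p, q, ωs |

The beta is discretized into K = 10 equal-probability categories
represented by their category means (quantile edges). Likelihoods are
computed by Felsenstein pruning with per-node scaling; transition matrices
come from the symmetric eigendecomposition of the reversible generator,
and the implementation is verified against dense `expm` oracles to 1e-8
in the test suite.

**Optimization.** Multi-start (default 5 seeded restarts) bounded L-BFGS-B
with κ ∈ [0.1, 20], ω ∈ [1e-4, 50], beta shapes ∈ [0.005, 99], and
three-class proportions on the simplex via an unconstrained softmax
transform; relative tolerance 1e-8. Branch lengths are handled in one of
three modes: `full` (co-estimated per branch), `fixed`, or the default
`scale`, which estimates branch lengths once under M0 and co-estimates a
single tree-scale factor with each site model's parameters. The scale mode
keeps every fit at seconds on desk-scale alignments while preserving the
nested-model log-likelihood ordering, because all models share the same
branch-length treatment; `full` is available when absolute lnL values
matter.

**Tree.** No tree is prescribed by the genotyping protocol, so the default
is the neighbor-joining tree from K80 distances among the alleles; any
newick tree can be supplied. Absolute log-likelihoods depend on the tree
and frequency model and are not comparable across programs; the LRT
statistics (differences of lnL between nested models sharing everything
else) are the robust quantity.

**LRTs and site identification.** M1a vs M2a and M7 vs M8 are compared by
2ΔlnL against χ² with 2 degrees of freedom (for df = 2 the upper tail is
exactly e^(−x/2)). Sites are flagged when the posterior probability of the
ω > 1 class exceeds a threshold (default 0.95). The default posterior is
naive empirical Bayes (computed at the MLEs). Bayes empirical Bayes, which
averages over uncertainty in the positive-class parameters, is implemented
over a 10-point-per-dimension uniform grid: for M2a over (p0, p1) on the
triangle, ω0 on (0, 1) and ω2 on (1, 11); for M8 over p0 and ωs with the
beta shape fixed at its MLE. κ and branch lengths stay at their MLEs in
both schemes.

## Trans-species polymorphism

K80 distances d = −½·ln((1−2P−Q)·√(1−2Q)) with P and Q the transition and
transversion proportions over gap-free, unambiguous columns; saturated
pairs are flagged infinite; an optional gamma shape parameter applies the
K80+Γ correction. Trees are built by standard neighbor joining, with
negative branch-length estimates clamped to zero and the deficit moved to
the sibling branch. A species is monophyletic iff some bipartition of the
unrooted tree separates exactly its tips; TSP is reported when any species
with ≥ 2 tips fails this, or when an identical-sequence group spans
species. Identical-allele grouping has two rules: `full` (exact equality)
and `trimmed`, which also merges records of different lengths when the
shorter is a contiguous window of the longer (the common case of archival
records truncated to 185 nt), taking the transitive closure so the result
is a partition.

Distance-based NJ replaces Bayesian tree inference deliberately: the TSP
statements need topology (monophyly, sharing), not posterior
probabilities, and NJ is exact on additive distances and deterministic.
Gamma rate heterogeneity is off by default because no shape estimate is
available from the genotyping pipeline itself.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the observable structure of the motivating study:

* **Allele pool** — 11 functional alleles of 242 nt and 3 pseudogenes of
  241 nt (each exactly one deletion from a functional allele), evolved
  independently from a random stop-free root by K80 substitution (κ = 2)
  with per-codon stop-avoidance resampling; the tip-to-tip divergence is
  calibrated so the mean pairwise p-distance matches the target (default
  0.05, typical of *DRB* exon-2 allele sets).
* **Genotypes** — per-subpopulation haplotype frequency tables over 5 loci
  (common allele near fixation in the north; a linked pair — one haplotype
  carrying two alleles, hence perfect co-occurrence by construction — near
  fixation in the east and rare in the north; a tail of rare alleles; one
  pseudogene fixed everywhere). Haplotype frequencies are back-calculated
  from the study's carrier proportions. Two haplotypes are drawn per locus
  per individual (19 east, 11 north, 2 admixed by default). The cohort is
  redrawn until every pool allele has a carrier, because an observed
  catalog is by definition the set of alleles the sampled cohort carries.
* **Clones** — Poisson(26.9) clones per individual (floor 1); each clone
  is a uniformly chosen true allele, replaced with probability
  `chimera_rate` by a single-crossover recombinant (uniform breakpoint) of
  two distinct alleles of the same individual, then hit by independent
  per-base substitution errors. Defaults: error rate 2e-5/base (a
  proofreading polymerase accumulating ~1e-6 errors/base/cycle over ~30
  cycles), chimera rate 0.005 (low because the amplicon is short and
  extension time generous). Provenance (faithful / point_error / chimera)
  is recorded per clone and always partitions the clone set.

Not emulated: chromatogram/quality artifacts, direction-reconciliation of
reads (inputs are assumed forward/reverse-matched upstream), sequencing
error profiles, indel PCR errors (the simulated indels are germline), and
any coalescent demography of the allele pool. Consequently, passing
recovery tests show that the calling rules behave correctly for the
artifact model stated above — not that real chromatogram-level error modes
are handled.

A small Goldman–Yang codon-alignment simulator (arbitrary per-site ω
vector on an arbitrary tree) supports the site-model parameter-recovery
tests; its power/size checks use 6-taxon trees of total length ≈ 1.95 and
80 codons — the fragment length of the motivating design — which keeps the
full 20-replicate battery under three minutes on one core.

## Numerical and degenerate-input conventions

* Fisher's test errors on an all-zero table; Welch's test errors when both
  groups are degenerate at different means and returns (0, 1) when the
  groups are identical.
* NG86 pairs are dropped from partition means when pN or pS reaches the
  Jukes–Cantor pole (≥ 3/4); ω is reported as undefined when dS ≤ 0.
* NJ requires ≥ 3 taxa; 2-taxon site-model trees are legal (only the path
  length is identifiable, which is harmless for likelihoods).
* All randomness flows through seeded `numpy` generators; identical seeds
  give byte-identical FASTA/JSON outputs.
* Site-pattern compression and per-node scaling keep likelihoods exact and
  finite on desk-scale alignments.

## Known limitations

* The ABS mask is a cross-species structural inference; partition-level ω
  conclusions inherit that uncertainty.
* The validation rule's blindness to recurrent chimeras (quantified above)
  means a zero-false-positive guarantee is unattainable in principle
  without sequence-database verification.
* BEB here marginalizes only over the positive-class parameter grid, not
  over κ or branch lengths, and M8's beta shape stays at its MLE.
* The NG86 estimator ignores transition/transversion bias in site
  counting; with κ > 1 it mildly underestimates ω (the neutral-simulation
  calibration in the tests uses κ = 1 for exactness of the assumption).
* Branch-length `scale` mode trades absolute lnL fidelity for speed;
  use `full` when absolute likelihood values are the object of interest.
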