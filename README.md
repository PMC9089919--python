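# drbkit

Clone-based genotyping and molecular-evolution analysis of MHC class II
*DRB* exon 2, built for studies of immune-gene diversity in small or
bottlenecked wildlife populations (the shipped fixtures and defaults follow
a survey of Finnish wolverines, *Gulo gulo*).

When a multi-locus MHC gene family is amplified from genomic DNA, cloned,
and Sanger-sequenced, the raw data are plasmid clones per individual, a mix
of true alleles and PCR artifacts. `drbkit` implements the complete desk
side of such a study:

* **Allele calling** — collapse clones to distinct sequences and keep a
  sequence only if it was detected at least twice (twice in one individual,
  or once each in at least two individuals); classify each validated
  sequence as a *functional allele* (intact open reading frame) or a
  *pseudogene* (indel and/or premature stop codon); name alleles and build
  an individuals × alleles genotype matrix.
* **Subpopulation statistics** — carrier counts, a two-sided Fisher exact
  test (hypergeometric probability-mass rule, the R convention), Welch's
  unequal-variance *t*-test, per-individual allele means, and the
  minimum-locus bound ⌈max alleles / 2⌉ for a diploid.
* **Selection, counting-based** — Nei–Gojobori (1986) *d*N/*d*S with
  Jukes–Cantor correction, ω = *d*N/*d*S partitioned into antigen-binding
  sites (ABS, inferred from the human HLA-DR structure; 18 of 80 codons by
  default), non-ABS, and overall, with codon-bootstrap standard errors.
* **Selection, likelihood-based** — codon site models M0, M1a (nearly
  neutral), M2a (positive selection), M7 (beta), M8 (beta & ω) on a fixed
  tree, with likelihood-ratio tests of M1a vs M2a and M7 vs M8
  (2ΔlnL ~ χ²₂) and per-site identification of positively selected codons
  by naive or Bayes empirical Bayes posteriors of the ω > 1 class.
* **Trans-species polymorphism (TSP)** — K80 distances, neighbor-joining
  trees, identical-allele sharing across species (including
  different-length records compared over their overlap), and per-species
  monophyly tests; shared or interleaved alleles across species are the
  classic signature of long-term balancing selection on the MHC.
* **Synthetic data** — a fully ground-truthed simulator of allele pools,
  two-subpopulation multi-locus genotypes (with a perfectly linked allele
  pair), and clone sets with point errors and single-crossover PCR
  chimeras, used to validate the whole pipeline by recovery.

## Worked example

The package ships a transcription of the study's published genotype table
(32 individuals from two regional subpopulations, 11 functional alleles,
3 pseudogenes):

```python
from drbkit import load_table1_fixture, fisher_exact_two_sided, summarize_diversity
from drbkit.popstats import carrier_counts

matrix = load_table1_fixture()
print(summarize_diversity(matrix).display())

cc = carrier_counts(matrix, ["Gugu-DRB*02", "Gugu-DRB*03"], mode="all")
(ec, en), (nc, nn) = cc["east"], cc["north"]
p = fisher_exact_two_sided([[ec, en - ec], [nc, nn - nc]])
print(f"DRB*02+*03 carriers: east {ec}/{en}, north {nc}/{nn} "
      f"(Fisher exact P = {p:.2e})")
```

prints

```
Diversity summary
  east: mean 3.1 functional alleles (1.2 pseudogenes)
  north: mean 2.0 functional alleles (1.0 pseudogenes)
  max alleles in one individual: 5 -> at least 3 functional loci per haploid genome
DRB*02+*03 carriers: east 19/19, north 4/13 (Fisher exact P = 2.55e-05)
```

— the eastern subpopulation carries more functional alleles per individual
than the northern one, the linked allele pair is essentially fixed in the
east but rare in the north (a highly significant contrast), and the
five-allele maximum implies at least three *DRB* loci per haploid genome.

The same analyses run from the shell:

```sh
drbkit simulate --seed 1 --outdir sim           # ground-truthed cohort
drbkit call-alleles --clones sim/clones.fasta --labels sim/labels.tsv --outdir out
drbkit stats --matrix out/genotype_matrix.tsv
drbkit dnds --alleles out/alleles.fasta --frame-offset 2 --boot 1000 --seed 1
drbkit sitemodels --alleles out/alleles.fasta --frame-offset 2 --models M1a,M2a,M7,M8
drbkit run --clones sim/clones.fasta --labels sim/labels.tsv --outdir report
```

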