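# Default antigen-binding-site (ABS) mask: 18 codon positions over the
# 80-codon exon-2 fragment of the MHC class II DR beta chain.
#
# The positions are inferred from the peptide-contact residues of the human
# HLA-DR beta-1 domain determined crystallographically (Brown et al. 1993,
# Nature 364:33-39), mapped onto the fragment with amplicon codon k
# corresponding to beta-1 residue k+8.  The exact ABS set of a non-human
# mustelid DR beta chain is an inference, not an observation; override with
# --mask / load_abs_mask(path) to supply your own.
#
# amplicon codon  (beta-1 residue)
3    # 11
5    # 13
20   # 28
22   # 30
24   # 32
29   # 37
30   # 38
39   # 47
48   # 56
52   # 60
53   # 61
57   # 65
60   # 68
62   # 70
63   # 71
66   # 74
70   # 78
74   # 82
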