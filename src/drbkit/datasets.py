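"""Packaged fixtures: the published per-individual genotype table
(32 wolverines × 14 allele columns, hand-transcribed) and the default
antigen-binding-site mask."""

from __future__ import annotations

import hashlib
from importlib import resources

from .calling import GenotypeMatrix
from .ng import AbsMask, load_abs_mask

# guards the hand transcription against accidental edits
_TABLE1_SHA256 = "0a533bb5203f36be252d8c27776951d7c2932f617817ba6bc1c3cc37842fd3a4"


def load_table1_fixture() -> GenotypeMatrix:
    """The published genotype table: 32 individuals (19 eastern, 11 northern,
    2 admixed), 11 functional alleles and 3 pseudogenes."""
    res = resources.files("drbkit.data").joinpath("table1_genotypes.tsv")
    text = res.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError(
            "genotype fixture checksum mismatch — the packaged transcription "
            "has been modified"
        )
    with resources.as_file(res) as path:
        return GenotypeMatrix.from_tsv(path)


def load_default_abs_mask(n_codons: int = 80) -> AbsMask:
    return load_abs_mask(None, n_codons=n_codons)
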