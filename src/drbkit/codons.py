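"""Shared codon-level utilities: the standard genetic code, sense-codon
indexing, transition/transversion classification, and translation helpers
used by the simulator, the ORF classifier, NG86 counting, and the codon
substitution models."""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

#: the 61 sense codons of the standard code, in fixed TCAG-major order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AMINO_ACID: dict[str, str] = {c: _standard.forward_table[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def codons_of(seq: str, frame_offset: int = 0) -> list[str]:
    """Split ``seq`` into complete codons, skipping ``frame_offset`` leading nt."""
    body = seq[frame_offset:]
    return [body[i : i + 3] for i in range(0, len(body) - len(body) % 3, 3)]


def premature_stops(seq: str, frame_offset: int = 0) -> list[int]:
    """1-based codon indices of in-frame stop codons after the frame offset."""
    return [i + 1 for i, c in enumerate(codons_of(seq, frame_offset)) if is_stop(c)]


def translate(seq: str, frame_offset: int = 0) -> str:
    return "".join(
        "*" if is_stop(c) else AMINO_ACID[c] for c in codons_of(seq, frame_offset)
    )


@lru_cache(maxsize=None)
def single_step_neighbors(codon: str) -> tuple[tuple[int, str, str, str], ...]:
    """All 9 single-nucleotide mutations of ``codon``.

    Returns tuples (position 0-2, old base, new base, mutant codon); mutants
    may be stop codons — callers filter as appropriate.
    """
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                mutant = codon[:pos] + nt + codon[pos + 1 :]
                out.append((pos, codon[pos], nt, mutant))
    return tuple(out)
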