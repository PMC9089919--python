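"""Thin pairwise-alignment helpers (Biopython PairwiseAligner) used to
localize germline deletions in pseudogene candidates."""

from __future__ import annotations

from Bio import Align


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def closest_reference(seq: str, references: list[str]) -> str:
    """The reference with the highest global alignment score against seq."""
    if not references:
        raise ValueError("no references supplied")
    a = _aligner()
    return max(references, key=lambda r: a.score(r, seq))


def global_align(ref: str, seq: str) -> tuple[str, str, int | None]:
    """Globally align ``seq`` against ``ref``.

    Returns the two gapped strings and the 1-based position (in ref
    coordinates) of the first gap opened in ``seq`` — the inferred deletion
    site — or None when the alignment is gap-free.
    """
    aln = _aligner().align(ref, seq)[0]
    ref_gapped, seq_gapped = str(aln[0]), str(aln[1])
    ref_pos = 0
    gap_pos = None
    for r, s in zip(ref_gapped, seq_gapped):
        if r != "-":
            ref_pos += 1
        if s == "-" and gap_pos is None:
            gap_pos = ref_pos
            break
    return ref_gapped, seq_gapped, gap_pos
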