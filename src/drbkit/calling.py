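"""Clone-based allele calling for multi-locus MHC amplicon data.

Plasmid clones sequenced from one PCR per individual are collapsed to
distinct candidate sequences, validated by replication (a sequence must be
seen at least twice — twice in one individual, or once each in at least two
individuals — to exclude PCR chimeras and polymerase errors), classified as
functional alleles or pseudogenes by an open-reading-frame test, named, and
assembled into an individuals × alleles genotype matrix.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from . import codons
from .align import closest_reference, global_align

logger = logging.getLogger(__name__)

FUNCTIONAL = "functional"  # intact ORF

PSEUDOGENE = "pseudogene"

SUBPOPULATIONS = ("north", "east", "admixed")


@dataclass(frozen=True)
class CloneRecord:
    """One plasmid-derived sequence read from one individual."""

    individual_id: str
    clone_id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for clone {self.individual_id}|{self.clone_id}")


@dataclass
class CloneSet:
    """All clones of a cohort, keyed by (individual_id, clone_id)."""

    clones: list[CloneRecord]

    def __post_init__(self):
        keys = [(c.individual_id, c.clone_id) for c in self.clones]
        dupes = [k for k, n in Counter(keys).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate clone identifiers: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.clones)

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clones:
            seen.setdefault(c.individual_id, None)
        return list(seen)

    def by_individual(self) -> dict[str, list[CloneRecord]]:
        out: dict[str, list[CloneRecord]] = defaultdict(list)
        for c in self.clones:
            out[c.individual_id].append(c)
        return dict(out)


@dataclass
class CandidateSequence:
    """A distinct clone sequence with its per-individual support counts."""

    seq: str
    support: dict[str, int] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class OrfReport:
    length: int
    frame_offset: int
    indel_detected: bool
    premature_stop_positions: list[int]
    closest_functional: str | None = None
    indel_position: int | None = None


@dataclass
class AlleleCall:
    name: str
    seq: str
    status: str  # FUNCTIONAL | PSEUDOGENE
    orf_report: OrfReport
    support: dict[str, int] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class GenotypeMatrix:
    """Boolean individuals × alleles presence table with subpopulation labels.

    ``presence`` rows are individuals, columns allele names; ``subpop`` maps
    each individual to one of north/east/admixed; ``status`` maps each allele
    to functional/pseudogene.
    """

    presence: pd.DataFrame
    subpop: pd.Series
    status: dict[str, str]

    def __post_init__(self):
        bad = set(self.subpop) - set(SUBPOPULATIONS)
        if bad:
            raise ValueError(f"unknown subpopulation labels: {sorted(bad)}")
        if list(self.presence.index) != list(self.subpop.index):
            raise ValueError("presence rows and subpopulation labels disagree")

    @property
    def individuals(self) -> list[str]:
        return list(self.presence.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.presence.columns)

    def functional_alleles(self) -> list[str]:
        return [a for a in self.alleles if self.status[a] == FUNCTIONAL]

    def pseudogene_alleles(self) -> list[str]:
        return [a for a in self.alleles if self.status[a] == PSEUDOGENE]

    def to_tsv(self, path) -> None:
        df = self.presence.astype(int).copy()
        df.insert(0, "subpop", self.subpop)
        df.insert(
            1, "_status", ""
        )  # placeholder column removed on write; statuses go in a header comment
        df = df.drop(columns="_status")
        with open(path, "w") as fh:
            fh.write(
                "# status: "
                + ",".join(f"{a}={self.status[a]}" for a in self.alleles)
                + "\n"
            )
            df.to_csv(fh, sep="\t", index_label="individual_id")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# status:"):
                raise ValueError(f"{path}: missing '# status:' header line")
            status = dict(
                kv.split("=") for kv in first.split(":", 1)[1].strip().split(",")
            )
            df = pd.read_csv(fh, sep="\t", index_col="individual_id")
        df.index = df.index.astype(str)
        subpop = df.pop("subpop")
        return cls(presence=df.astype(bool), subpop=subpop, status=status)


def collapse_clones(clones: CloneSet) -> list[CandidateSequence]:
    """Collapse clones into one candidate per distinct sequence.

    Candidates are returned in order of first observation; supports sum to
    the total clone count.
    """
    candidates: dict[str, CandidateSequence] = {}
    for c in clones.clones:
        cand = candidates.setdefault(c.seq, CandidateSequence(seq=c.seq))
        cand.support[c.individual_id] = cand.support.get(c.individual_id, 0) + 1
    return list(candidates.values())


def validate_candidates(
    candidates: list[CandidateSequence],
) -> tuple[list[CandidateSequence], list[CandidateSequence]]:
    """Apply the replication rule: keep a candidate iff it was detected at
    least twice — twice in one individual or once each in ≥ 2 individuals.
    Single, unique sequences are rejected as likely PCR artifacts."""
    validated, rejected = [], []
    for cand in candidates:
        (validated if cand.total_support >= 2 else rejected).append(cand)
    return validated, rejected


def classify_sequence(
    seq: str,
    n_codons: int = 80,
    frame_offset: int = 2,
    expected_length: int | None = None,
    references: list[str] | None = None,
) -> tuple[str, OrfReport]:
    """Classify a candidate as a functional allele or a pseudogene.

    A sequence is functional iff it has the expected amplicon length (an
    intact reading frame) and its translation after ``frame_offset`` nt
    contains no stop codon. Length deviations of 1–6 nt are indels
    (germline frameshifts → pseudogene); deviations beyond ±6 nt are
    rejected as non-target amplicons. When ``references`` (validated
    functional sequences) are supplied, the closest one is aligned to
    localize the indel; only the length test decides the status.
    """
    if expected_length is None:
        expected_length = 3 * n_codons + frame_offset
    length = len(seq)
    if abs(length - expected_length) > 6:
        raise ValueError(
            f"sequence length {length} deviates more than 6 nt from the "
            f"expected amplicon length {expected_length}: non-target amplicon"
        )
    stops = codons.premature_stops(seq, frame_offset)
    indel = length != expected_length
    report = OrfReport(
        length=length,
        frame_offset=frame_offset,
        indel_detected=indel,
        premature_stop_positions=stops,
    )
    if indel and references:
        ref = closest_reference(seq, references)
        report.closest_functional = ref
        _, _, gap_pos = global_align(ref, seq)
        report.indel_position = gap_pos
    status = FUNCTIONAL if (not indel and not stops) else PSEUDOGENE
    return status, report


def name_alleles(calls: list[AlleleCall], prefix: str = "Gugu") -> list[AlleleCall]:
    """Assign names: functional alleles ``<prefix>-DRB*01..`` by descending
    carrier count (ties broken by first-observation order), pseudogenes
    ``<prefix>-DRB*PS01..`` the same way."""

    def carriers(call: AlleleCall) -> int:
        return sum(1 for n in call.support.values() if n > 0)

    functional = [c for c in calls if c.status == FUNCTIONAL]
    pseudo = [c for c in calls if c.status == PSEUDOGENE]
    # stable sort keeps first-observation order among ties
    functional.sort(key=lambda c: -carriers(c))
    pseudo.sort(key=lambda c: -carriers(c))
    for i, call in enumerate(functional, 1):
        call.name = f"{prefix}-DRB*{i:02d}"
    for i, call in enumerate(pseudo, 1):
        call.name = f"{prefix}-DRB*PS{i:02d}"
    return functional + pseudo


def build_genotype_matrix(
    alleles: list[AlleleCall],
    clones: CloneSet,
    labels: dict[str, str],
) -> GenotypeMatrix:
    """Presence(ind, allele) = the globally validated allele was observed in
    at least one clone of that individual."""
    for ind in clones.individuals():
        if ind not in labels:
            raise ValueError(f"individual {ind!r} has no subpopulation label")
    seq_to_name = {a.seq: a.name for a in alleles}
    individuals = clones.individuals()
    presence = pd.DataFrame(
        False, index=individuals, columns=[a.name for a in alleles]
    )
    for c in clones.clones:
        name = seq_to_name.get(c.seq)
        if name is not None:
            presence.loc[c.individual_id, name] = True
    empty = presence.index[~presence.any(axis=1)]
    for ind in empty:
        logger.warning(
            "individual %s carries no validated allele (all clones rejected)", ind
        )
    subpop = pd.Series({ind: labels[ind] for ind in individuals}, name="subpop")
    status = {a.name: a.status for a in alleles}
    return GenotypeMatrix(presence=presence, subpop=subpop.loc[individuals], status=status)


def call_alleles(
    clones: CloneSet,
    labels: dict[str, str],
    n_codons: int = 80,
    frame_offset: int = 2,
    expected_length: int | None = None,
    prefix: str = "Gugu",
) -> tuple[list[AlleleCall], GenotypeMatrix, dict]:
    """Full calling pipeline: collapse → validate → classify → name → matrix.

    Returns the named allele calls, the genotype matrix, and a report dict
    (counts of candidates, rejected singletons, off-target sequences).
    """
    if expected_length is None:
        expected_length = 3 * n_codons + frame_offset
    candidates = collapse_clones(clones)
    validated, rejected = validate_candidates(candidates)

    # classify in two passes so indel localization can use the functional set
    prelim: list[tuple[CandidateSequence, str, OrfReport]] = []
    off_target = 0
    for cand in validated:
        try:
            status, report = classify_sequence(
                cand.seq, n_codons, frame_offset, expected_length
            )
        except ValueError:
            off_target += 1
            continue
        prelim.append((cand, status, report))
    functional_seqs = [c.seq for c, s, _ in prelim if s == FUNCTIONAL]
    calls = []
    for cand, status, report in prelim:
        if status == PSEUDOGENE and report.indel_detected and functional_seqs:
            _, report = classify_sequence(
                cand.seq, n_codons, frame_offset, expected_length, functional_seqs
            )
        calls.append(
            AlleleCall(
                name="", seq=cand.seq, status=status, orf_report=report,
                support=dict(cand.support),
            )
        )
    named = name_alleles(calls, prefix=prefix)
    matrix = build_genotype_matrix(named, clones, labels)
    report = {
        "n_clones": len(clones),
        "n_candidates": len(candidates),
        "n_validated": len(validated),
        "n_rejected_singletons": len(rejected),
        "n_off_target": off_target,
        "n_functional": sum(1 for a in named if a.status == FUNCTIONAL),
        "n_pseudogene": sum(1 for a in named if a.status == PSEUDOGENE),
    }
    return named, matrix, report
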