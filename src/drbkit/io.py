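"""File I/O: FASTA (clones, alleles, multi-species panels), TSV label and
genotype tables, and the flat key=value configuration format.

Clone FASTA headers are ``>IND<id>|clone<k>``; species-panel headers are
``>Species|Allele|Accession`` (accession optional).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CloneRecord, CloneSet


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Errors on duplicate identifiers and on empty files; the underlying
    parser reports malformed records with their position.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta-2line",
    )


def parse_clone_header(header: str) -> tuple[str, str]:
    parts = header.split("|")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(
            f"clone header {header!r} is not of the form 'IND<id>|clone<k>'"
        )
    return parts[0], parts[1]


def read_clones_fasta(path) -> CloneSet:
    recs = read_fasta(path)
    return CloneSet(
        [CloneRecord(*parse_clone_header(h), seq=s) for h, s in recs.items()]
    )


def write_clones_fasta(clones: CloneSet, path) -> None:
    write_fasta(
        {f"{c.individual_id}|{c.clone_id}": c.seq for c in clones.clones}, path
    )


def read_species_panel(path) -> tuple[dict[str, str], dict[str, str]]:
    """Multi-species allele FASTA -> (allele label -> sequence,
    allele label -> species)."""
    recs = read_fasta(path)
    seqs: dict[str, str] = {}
    species: dict[str, str] = {}
    for header, seq in recs.items():
        parts = header.split("|")
        if len(parts) < 2:
            raise ValueError(
                f"panel header {header!r} is not 'Species|Allele[|Accession]'"
            )
        label = parts[1]
        if label in seqs:
            label = f"{parts[0]}|{parts[1]}"
        seqs[label] = seq
        species[label] = parts[0]
    return seqs, species


def read_labels_tsv(path) -> dict[str, str]:
    """Two-column TSV (individual_id, subpop), '#' comments allowed."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if parts[0] == "individual_id":  # optional header
            continue
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
        if parts[0] in out:
            raise ValueError(f"{path}:{ln}: duplicate individual {parts[0]!r}")
        out[parts[0]] = parts[1]
    if not out:
        raise ValueError(f"{path}: no labels found")
    return out


def write_labels_tsv(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tsubpop\n")
        for ind, sp in labels.items():
            fh.write(f"{ind}\t{sp}\n")


def read_config_file(path) -> dict[str, str]:
    """Flat ``key = value`` configuration; '#' comments; keys lowercase."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        k, v = (s.strip() for s in line.split("=", 1))
        out[k.lower()] = v
    return out
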