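"""Pipeline orchestration: call-alleles → stats → dN/dS → site models
(→ TSP when a species panel is given), with a machine-readable JSON report.

Every stage is also available on its own through the library modules; the
pipeline wires them with one validated configuration and one seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .calling import FUNCTIONAL, CloneSet, call_alleles
from .io import (
    read_clones_fasta,
    read_labels_tsv,
    read_species_panel,
    write_fasta,
)
from .ng import load_abs_mask, partitioned_rates, rates_table
from .phylo import (
    DistanceMatrix,
    identical_allele_groups,
    neighbor_joining,
    species_monophyly,
)
from .popstats import subpopulation_report
from .sitemodels import CodonSiteModel, likelihood_ratio_test


@dataclass
class PipelineConfig:
    """Validated pipeline settings; defaults reproduce the study's design
    (242-nt amplicon, 80 codons after a 2-nt frame offset, admixed
    individuals merged into the northern subpopulation)."""

    frame_offset: int = 2
    n_codons: int = 80
    expected_length: int | None = None
    merge_admixed_into: str = "north"
    mask_path: str | None = None
    bootstrap_reps: int = 1000
    models: tuple[str, ...] = ("M1a", "M2a", "M7", "M8")
    restarts: int = 3
    codon_freq: str = "f3x4"
    seed: int = 0
    allele_prefix: str = "Gugu"
    outdir: str | None = None

    def __post_init__(self):
        if self.expected_length is None:
            self.expected_length = 3 * self.n_codons + self.frame_offset
        if self.frame_offset < 0 or self.n_codons < 1:
            raise ValueError("invalid frame_offset / n_codons")
        if self.merge_admixed_into not in ("north", "east"):
            raise ValueError("merge_admixed_into must be 'north' or 'east'")
        unknown = set(self.models) - {"M0", "M1a", "M2a", "M7", "M8"}
        if unknown:
            raise ValueError(f"unknown site models: {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        kwargs = {}
        fields = cls.__dataclass_fields__
        for k, v in mapping.items():
            if k not in fields:
                raise ValueError(f"unknown configuration key {k!r}")
            if v is None:
                continue
            typ = fields[k].type
            if k == "models" and isinstance(v, str):
                v = tuple(s.strip() for s in v.split(","))
            elif typ.startswith("int"):
                v = int(v)
            kwargs[k] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    clones: CloneSet | str,
    labels: dict[str, str] | str,
    species_panel: str | None = None,
) -> dict:
    """Execute the staged analysis and return the report bundle (a JSON-
    serializable dict); per-stage tables are written under config.outdir
    when set.  Any stage error aborts with a stage-tagged message."""
    report: dict = {
        "tool": {"name": "drbkit", "version": __version__},
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    with stage("call-alleles"):
        if isinstance(clones, str):
            clones = read_clones_fasta(clones)
        if isinstance(labels, str):
            labels = read_labels_tsv(labels)
        calls, matrix, call_report = call_alleles(
            clones,
            labels,
            n_codons=config.n_codons,
            frame_offset=config.frame_offset,
            expected_length=config.expected_length,
            prefix=config.allele_prefix,
        )
        report["call_alleles"] = call_report
        report["alleles"] = {
            a.name: {"status": a.status, "carriers": len(a.support),
                     "total_support": a.total_support}
            for a in calls
        }
        if outdir:
            write_fasta({a.name: a.seq for a in calls}, outdir / "alleles.fasta")
            matrix.to_tsv(outdir / "genotype_matrix.tsv")

    with stage("stats"):
        report["stats"] = subpopulation_report(
            matrix, merge_admixed_into=config.merge_admixed_into
        )

    functional = {a.name: a.seq for a in calls if a.status == FUNCTIONAL}
    trimmed = {
        n: s[config.frame_offset : config.frame_offset + 3 * config.n_codons]
        for n, s in functional.items()
    }

    if len(trimmed) >= 2:
        with stage("dnds"):
            mask = load_abs_mask(config.mask_path, n_codons=config.n_codons)
            est = partitioned_rates(
                trimmed, mask, bootstrap_reps=config.bootstrap_reps, seed=config.seed
            )
            report["dnds"] = {
                part: {
                    "n_codons": e.n_codons,
                    "dN": e.dN, "dN_se": e.dN_se,
                    "dS": e.dS, "dS_se": e.dS_se,
                    "omega": e.omega,
                }
                for part, e in est.items()
            }
            if outdir:
                (outdir / "dnds.tsv").write_text(rates_table(est) + "\n")

    if len(trimmed) >= 3 and config.models:
        with stage("sitemodels"):
            fits = {}
            for m in config.models:
                fits[m] = CodonSiteModel(
                    trimmed, model=m, codon_freq=config.codon_freq
                ).fit(restarts=config.restarts, seed=config.seed)
            report["site_models"] = {m: f.to_dict() for m, f in fits.items()}
            lrts = {}
            for null, alt in (("M1a", "M2a"), ("M7", "M8")):
                if null in fits and alt in fits:
                    r = likelihood_ratio_test(fits[null], fits[alt])
                    lrts[f"{null}_vs_{alt}"] = {
                        "delta": r.delta, "df": r.df, "p": r.p
                    }
            report["lrt"] = lrts
            sel = {}
            for m in ("M2a", "M8"):
                if m in fits:
                    df = fits[m].selected_sites(threshold=0.95)
                    sel[m] = {int(i): float(p) for i, p in df["posterior"].items()}
            report["selected_sites"] = sel

    if species_panel:
        with stage("tsp"):
            seqs, species = read_species_panel(species_panel)
            groups = identical_allele_groups(seqs, species, overlap_rule="trimmed")
            report["tsp_identical_groups"] = groups
            same_len = {n: s for n, s in seqs.items() if len(s) == len(next(iter(seqs.values())))}
            if len(same_len) >= 3:
                tree = neighbor_joining(DistanceMatrix.from_sequences(same_len))
                mono = species_monophyly(tree, {n: species[n] for n in same_len})
                report["tsp_monophyly"] = mono
                if outdir:
                    (outdir / "tsp_tree.nwk").write_text(tree.newick() + "\n")

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
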