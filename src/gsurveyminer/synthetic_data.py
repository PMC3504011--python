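"""Synthetic survey libraries with fully known planted structure.

The generator emulates the shape of a 454-style low-coverage survey
library *after* assembly: contigs with read counts, not raw reads
(assembly is outside the pipeline's contract).  Background contigs are
i.i.d. sequence at a configurable GC content with clipped-read-scale
lengths (mean 272 bp, sd 80, floor 100).  On top of that it plants

* tandem repeats (motif x n_units, optional per-base substitution
  noise) on dedicated contigs with primer-amenable GC-balanced flanks,
* contaminant reads per category (virus, prokaryote, rRNA,
  transposable element, mitochondrial) at configurable read fractions;
  rRNA and mitochondrial reads are packed into few multi-read contigs
  to mimic over-represented multi-copy loci, the rest stay single
  reads,
* fabricated homology-hit tables whose titles, lineages and e-values
  deterministically trigger the true category, with optional decoy
  rows (exclusion terms, near-threshold e-values) that are designed to
  be missed.

Everything is deterministic given the seed, and the emitted truth
covers every contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import HolobiontSets, HomologyHit
from .seq_model import Contig, Library
from .tandem_repeat import RepeatMatch

BASES = np.array(list("ACGT"))

CONTAMINANT_ORDER = (
    "virus", "prokaryote", "transposable_element", "rrna", "mitochondrial",
)

#: Categories whose reads are packed into few multi-read contigs
#: (over-represented multi-copy loci); the others stay single reads.
MULTICOPY_CATEGORIES = frozenset({"rrna", "mitochondrial"})


@dataclass(frozen=True)
class PlantedRepeat:
    motif: str
    n_units: int
    mutation_rate: float = 0.0
    on_single_read_contig: bool = True


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library."""

    seed: int
    n_contigs: int = 200
    length_mean: float = 272.0
    length_sd: float = 80.0
    length_min: int = 100
    gc_content: float = 0.40
    flank_bp: int = 140
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    contaminant_fractions: Mapping[str, float] = field(default_factory=dict)
    multiread_fraction: float = 0.25
    multiread_geom_p: float = 0.6

    def __post_init__(self) -> None:
        total = sum(self.contaminant_fractions.values())
        if not all(0 <= f <= 1 for f in self.contaminant_fractions.values()):
            raise ValueError("contaminant fractions must be in [0, 1]")
        if total >= 1:
            raise ValueError("contaminant fractions must sum to < 1")
        unknown = set(self.contaminant_fractions) - set(CONTAMINANT_ORDER)
        if unknown:
            raise ValueError(f"unknown contaminant categories {unknown}")


@dataclass(frozen=True)
class TruthRecord:
    contig_id: str
    category: str  # "target" or a contaminant category
    n_reads: int
    repeat: RepeatMatch | None = None


@dataclass
class SimTruth:
    """Planted ground truth for one simulated library."""

    records: dict[str, TruthRecord]
    planned_total_reads: int
    category_read_counts: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(r.n_reads for r in self.records.values())

    def read_fraction(self, category: str) -> float:
        return self.category_read_counts.get(category, 0) / self.total_reads

    def planted_repeats(self) -> list[RepeatMatch]:
        return [
            r.repeat for r in self.records.values() if r.repeat is not None
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            rep = rec.repeat
            rows.append(
                {
                    "contig_id": rec.contig_id,
                    "category": rec.category,
                    "n_reads": rec.n_reads,
                    "repeat_start": rep.start if rep else "",
                    "repeat_end": rep.end if rep else "",
                    "repeat_motif": rep.motif if rep else "",
                    "repeat_perfection": (
                        f"{rep.perfection:.2f}" if rep else ""
                    ),
                }
            )
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_library(cfg: SimConfig, library_id: str = "sim") -> tuple[Library, SimTruth]:
    """Generate a library plus its planted truth, deterministically."""
    rng = np.random.default_rng(cfg.seed)
    contigs: list[Contig] = []
    records: dict[str, TruthRecord] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{library_id}_c{counter:06d}"

    def add(seq: str, n_reads: int, category: str,
            repeat: RepeatMatch | None = None) -> None:
        cid = next_id()
        contigs.append(
            Contig(id=cid, sequence=seq, n_reads=n_reads,
                   library_id=library_id)
        )
        records[cid] = TruthRecord(
            contig_id=cid, category=category, n_reads=n_reads, repeat=repeat
        )

    # --- background target contigs -------------------------------------
    background_reads = 0
    for _ in range(cfg.n_contigs):
        length = max(
            cfg.length_min,
            int(round(rng.normal(cfg.length_mean, cfg.length_sd))),
        )
        if rng.random() < cfg.multiread_fraction:
            n_reads = 2 + int(rng.geometric(cfg.multiread_geom_p) - 1)
        else:
            n_reads = 1
        background_reads += n_reads
        add(_random_seq(rng, length, cfg.gc_content), n_reads, "target")

    # --- planted repeat contigs (primer-amenable balanced flanks) ------
    for plant in cfg.planted_repeats:
        tract = plant.motif * plant.n_units
        max_len = 2 * cfg.flank_bp + len(tract)
        if len(tract) + 2 * 18 > max_len:
            raise ValueError(
                f"planted repeat {plant.motif!r} x {plant.n_units} does not "
                "leave room for flanks"
            )
        tract = _mutate(tract, plant.mutation_rate, rng)
        left = _random_seq(rng, cfg.flank_bp, 0.5)
        right = _random_seq(rng, cfg.flank_bp, 0.5)
        u = len(plant.motif)
        # break the repeat at the flank boundaries so the planted
        # coordinates are exactly recoverable
        if left and left[-1] == tract[u - 1]:
            left = left[:-1] + ("G" if tract[u - 1] != "G" else "C")
        if right and right[0] == tract[len(tract) - u]:
            right = ("G" if tract[len(tract) - u] != "G" else "C") + right[1:]
        seq = left + tract + right
        n_cols = len(tract) - u
        mismatches = sum(
            1 for i in range(n_cols) if tract[i] != tract[i + u]
        )
        n_match = n_cols - mismatches
        perfection = 100.0 * n_match / n_cols if n_cols else 100.0
        repeat = RepeatMatch(
            contig_id="",  # patched below via record id
            start=cfg.flank_bp,
            end=cfg.flank_bp + len(tract),
            unit_length=u,
            motif=min(
                plant.motif[i:] + plant.motif[:i]
                for i in range(len(plant.motif))
            ),
            score=float(n_match + (-5.0) * mismatches),
            n_match=n_match,
            n_mismatch=mismatches,
            n_gap=0,
            perfection=perfection,
        )
        n_reads = 1 if plant.on_single_read_contig else 2
        background_reads += n_reads
        cid = f"{library_id}_c{counter + 1:06d}"
        repeat = RepeatMatch(**{**repeat.__dict__, "contig_id": cid})
        add(seq, n_reads, "target", repeat=repeat)

    # --- contaminant reads ---------------------------------------------
    frac_total = sum(cfg.contaminant_fractions.values())
    planned_total = (
        int(np.ceil(background_reads / (1 - frac_total)))
        if frac_total > 0
        else background_reads
    )
    category_reads: dict[str, int] = {}
    for category in CONTAMINANT_ORDER:
        frac = cfg.contaminant_fractions.get(category, 0.0)
        if frac <= 0:
            continue
        n_reads_cat = int(rng.binomial(planned_total, frac))
        category_reads[category] = n_reads_cat
        remaining = n_reads_cat
        while remaining > 0:
            if category in MULTICOPY_CATEGORIES:
                # over-represented locus: many reads collapse into one contig
                n_reads = min(remaining, 1 + int(rng.poisson(19)))
            else:
                n_reads = 1
            length = max(
                cfg.length_min,
                int(round(rng.normal(cfg.length_mean, cfg.length_sd))),
            )
            add(_random_seq(rng, length, cfg.gc_content), n_reads, category)
            remaining -= n_reads

    lib = Library(
        id=library_id,
        contigs=contigs,
        n_raw_reads=background_reads + sum(category_reads.values()),
        raw_read_bp=sum(len(c) * c.n_reads for c in contigs),
    )
    truth = SimTruth(
        records=records,
        planned_total_reads=planned_total,
        category_read_counts=category_reads,
    )
    return lib, truth


# ---------------------------------------------------------------------------
# fabricated homology hits

_HIT_TEMPLATES: dict[str, dict[str, str]] = {
    "virus": {
        "title": "White spot syndrome virus VP28 envelope protein",
        "lineage": "Viruses; Naldaviricetes; Nimaviridae; Whispovirus",
        "species": "White spot syndrome virus",
        "db": "viral_refseq",
        "evalue": "1e-70",
    },
    "prokaryote": {
        "title": "Psychromonas ingrahamii 37, complete genome",
        "lineage": "Bacteria; Proteobacteria; Gammaproteobacteria; "
                   "Psychromonadaceae; Psychromonas",
        "species": "Psychromonas ingrahamii",
        "db": "nt",
        "evalue": "1e-25",
    },
    "rrna": {
        "title": "Hyas araneus 18S ribosomal RNA gene, partial sequence",
        "lineage": "Eukaryota; Metazoa; Arthropoda; Crustacea",
        "species": "Hyas araneus",
        "db": "nt",
        "evalue": "1e-40",
    },
    "transposable_element": {
        "title": "Xiphophorus maculatus Rex3 retrotransposon, complete "
                 "sequence",
        "lineage": "Eukaryota; Metazoa; Chordata; Actinopterygii",
        "species": "Xiphophorus maculatus",
        "db": "nt",
        "evalue": "1e-30",
    },
    "mitochondrial": {
        "title": "Metopaulias depressus mitochondrion, partial genome",
        "lineage": "Eukaryota; Metazoa; Arthropoda; Decapoda",
        "species": "Metopaulias depressus",
        "db": "mito_ref",
        "evalue": "1e-20",
    },
    "target": {
        "title": "Cancer pagurus genomic scaffold, whole genome shotgun "
                 "sequence",
        "lineage": "Eukaryota; Metazoa; Arthropoda; Decapoda",
        "species": "Cancer pagurus",
        "db": "nt",
        "evalue": "1e-15",
    },
}

_DECOYS: dict[str, dict[str, str]] = {
    # flanking-region clone of a transposon: the exclusion rule must veto it
    "transposable_element": {
        "title": "Tc1 transposon flanking region clone 7",
        "lineage": "Eukaryota; Metazoa; Nematoda",
        "species": "Caenorhabditis elegans",
        "db": "nt",
        "evalue": "1e-30",
    },
    # just above the conservative viral threshold
    "virus": {
        "title": "White spot syndrome virus VP28 envelope protein",
        "lineage": "Viruses; Naldaviricetes; Nimaviridae; Whispovirus",
        "species": "White spot syndrome virus",
        "db": "viral_refseq",
        "evalue": "1e-59",
    },
    # just above the general homology threshold
    "prokaryote": {
        "title": "Psychromonas ingrahamii 37, complete genome",
        "lineage": "Bacteria; Proteobacteria; Gammaproteobacteria; "
                   "Psychromonadaceae; Psychromonas",
        "species": "Psychromonas ingrahamii",
        "db": "nt",
        "evalue": "1e-11",
    },
    "rrna": {
        "title": "Hyas araneus 18S ribosomal RNA gene, partial sequence",
        "lineage": "Eukaryota; Metazoa; Arthropoda; Crustacea",
        "species": "Hyas araneus",
        "db": "nt",
        "evalue": "1e-11",
    },
    "mitochondrial": {
        "title": "Metopaulias depressus mitochondrion, partial genome",
        "lineage": "Eukaryota; Metazoa; Arthropoda; Decapoda",
        "species": "Metopaulias depressus",
        "db": "mito_ref",
        "evalue": "1e-11",
    },
}


def fabricate_hit_table(
    truth: SimTruth,
    decoy_fraction: float = 0.0,
    target_hit_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[HomologyHit], set[str]]:
    """One deterministic hit per contig, triggering its true category.

    A ``decoy_fraction`` of contaminant contigs instead receives a
    decoy row (exclusion term or near-threshold e-value) engineered to
    be *missed* by the rules; their ids are returned so recovery tests
    can score them separately.  Target contigs get a neutral metazoan
    hit with probability ``target_hit_fraction`` and no hit otherwise.
    """
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    decoy_ids: set[str] = set()
    acc = 0
    for rec in truth.records.values():
        if rec.category == "target":
            if rng.random() >= target_hit_fraction:
                continue
            template = _HIT_TEMPLATES["target"]
        elif (
            rec.category in _DECOYS and rng.random() < decoy_fraction
        ):
            template = _DECOYS[rec.category]
            decoy_ids.add(rec.contig_id)
        else:
            template = _HIT_TEMPLATES[rec.category]
        acc += 1
        s_start = int(rng.integers(0, 1000))
        span = int(rng.integers(50, 300))
        hits.append(
            HomologyHit(
                query_id=rec.contig_id,
                subject_accession=f"SYN{acc:07d}",
                evalue=float(template["evalue"]),
                bitscore=200.0,
                q_start=0,
                q_end=span,
                s_start=s_start,
                s_end=s_start + span,
                subject_title=template["title"],
                lineage=template["lineage"],
                species_field=template["species"],
                db_tag=template["db"],
            )
        )
    return hits, decoy_ids


def fabricate_holobiont_table(
    n_plastid: int = 10,
    n_symbiont: int = 14,
    n_host: int = 393,
    n_conflict: int = 17,
    seed: int = 0,
) -> tuple[list[HomologyHit], HolobiontSets]:
    """Hit table for a coral-plus-dinoflagellate tissue extraction.

    Builds the stated numbers of contigs with plastid-only,
    symbiont-nuclear-only, host-only and multi-category hits; the
    multi-category contigs model conflicting database annotations.
    """
    sets = HolobiontSets(
        host_taxa=frozenset({"Faviinae", "Cnidaria"}),
        symbiont_taxa=frozenset({"Dinoflagellata", "Symbiodinium"}),
    )
    rng = np.random.default_rng(seed)
    host_hit = dict(
        subject_title="Favia fragum genomic clone",
        lineage="Eukaryota; Metazoa; Cnidaria; Anthozoa; Faviinae",
        species_field="Favia fragum",
    )
    sym_hit = dict(
        subject_title="Symbiodinium minutum nuclear genome scaffold",
        lineage="Eukaryota; Alveolata; Dinoflagellata; Symbiodinium",
        species_field="Symbiodinium minutum",
    )
    plastid_hit = dict(
        subject_title="Symbiodinium plastid minicircle psbA gene",
        lineage="Eukaryota; Alveolata; Dinoflagellata; Symbiodinium",
        species_field="Symbiodinium sp.",
    )
    hits: list[HomologyHit] = []
    counter = 0

    def emit(cid: str, template: dict) -> None:
        nonlocal counter
        counter += 1
        hits.append(
            HomologyHit(
                query_id=cid,
                subject_accession=f"HOLO{counter:06d}",
                evalue=10.0 ** -float(rng.integers(13, 60)),
                bitscore=float(rng.integers(100, 500)),
                db_tag="nt",
                **template,
            )
        )

    idx = 0
    for _ in range(n_plastid):
        idx += 1
        emit(f"holo_c{idx:05d}", plastid_hit)
    for _ in range(n_symbiont):
        idx += 1
        emit(f"holo_c{idx:05d}", sym_hit)
    for _ in range(n_host):
        idx += 1
        emit(f"holo_c{idx:05d}", host_hit)
    pairs = [
        (host_hit, sym_hit), (host_hit, plastid_hit),
        (sym_hit, plastid_hit),
    ]
    for i in range(n_conflict):
        idx += 1
        for template in pairs[i % len(pairs)]:
            emit(f"holo_c{idx:05d}", template)
    return hits, sets


# ---------------------------------------------------------------------------
# recovery scoring


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter / shorter if shorter > 0 else 0.0


def repeat_recovery(
    detected: Sequence[RepeatMatch],
    planted: Sequence[RepeatMatch],
    min_overlap: float = 0.5,
) -> dict[str, float]:
    """Sensitivity/precision of repeat detection by >= 50% interval overlap."""
    def hit(d: RepeatMatch, p: RepeatMatch) -> bool:
        return (
            d.contig_id == p.contig_id
            and _overlap_fraction((d.start, d.end), (p.start, p.end))
            >= min_overlap
        )

    tp_planted = sum(1 for p in planted if any(hit(d, p) for d in detected))
    tp_detected = sum(1 for d in detected if any(hit(d, p) for p in planted))
    sensitivity = tp_planted / len(planted) if planted else float("nan")
    precision = (
        tp_detected / len(detected) if detected else float("nan")
    )
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_planted": len(planted),
        "n_detected": len(detected),
    }


def classification_recovery(
    labels: Mapping[str, "object"],
    truth: SimTruth,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Confusion matrix (truth x predicted) over classified contigs.

    Target contigs whose fabricated hit is a neutral metazoan record
    are, by design, classified as other eukaryote, so their truth row
    is reported as ``eukaryote_other``.
    """
    excluded = set(exclude)
    rows = []
    for cid, label in labels.items():
        if cid in excluded or cid not in truth.records:
            continue
        truth_cat = truth.records[cid].category
        if truth_cat == "target":
            truth_cat = "eukaryote_other"
        rows.append(
            {
                "truth": truth_cat,
                "predicted": getattr(label, "category", str(label)),
            }
        )
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return pd.crosstab(df["truth"], df["predicted"])
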