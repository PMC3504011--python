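"""Contig classification from tabular homology hits.

The triage consumes pre-computed homology hits (BLAST-style tabular
rows extended with the subject definition line and a semicolon-joined
taxonomic lineage) and applies keyword, e-value and taxonomy rules to
sort contigs into rRNA, transposable-element, prokaryote, virus and
mitochondrial bins, to build contamination-free datasets, and to
partition a holobiont library between host, symbiont-nuclear and
plastid genomes.

Matching conventions: terms are case-insensitive; terms of three
characters or fewer ("SSU", "5S", ...) must match as whole tokens so
that "5S" does not fire inside "S5"; longer terms match as substrings,
mirroring free-text search over definition lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_model import Library

logger = logging.getLogger(__name__)

#: General homology significance threshold (nucleotide collection,
#: Swiss-Prot and mitochondrial-reference searches).
GENERAL_EVALUE_MAX = 1e-12
#: Conservative threshold for calling viral origin from hits against
#: viral reference proteins.
VIRAL_EVALUE_MAX = 1e-60

RRNA_TERMS = (
    "rRNA", "18S", "28S", "5S", "5,8S", "5.8S", "23S", "25S", "17S",
    "ribosomal RNA", "rDNA", "SSU", "LSU", "internal transcribed spacer",
    "ITS1", "ITS2", "external transcribed spacer",
)

TE_TITLE_TERMS = (
    "transposon", "retrotransposon", "transposable element",
    "interspersed element", "interspersed repeated mobile element",
    "SINE sequence", "SINE Alu", "SINE family", "LINE family",
    "LINE sequence", "Alu repeat",
)
TE_SPECIES_TERMS = ("transposon", "retroposon")
TE_EXCLUSION_TERMS = ("flanking region", "flank_region", "flanking end")

PROKARYOTE_ROOTS = frozenset({"bacteria", "archaea"})

CATEGORY_PRECEDENCE = (
    "virus",
    "prokaryote",
    "transposable_element",
    "rrna",
    "mitochondrial",
)

CONTAMINANT_CATEGORIES = frozenset(
    {"virus", "prokaryote", "transposable_element"}
)


@dataclass(frozen=True)
class HomologyHit:
    """One row of an extended tabular homology result."""

    query_id: str
    subject_accession: str
    evalue: float
    bitscore: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    subject_title: str = ""
    lineage: str = ""
    species_field: str = ""
    db_tag: str = "nt"  # nt | swissprot | viral_refseq | mito_ref

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


@dataclass(frozen=True)
class AnnotationLabel:
    contig_id: str
    category: str
    evidence: str = ""


def _term_matches(term: str, text: str) -> bool:
    if len(term) <= 3:
        pattern = r"(?<![A-Za-z0-9])" + re.escape(term) + r"(?![A-Za-z0-9])"
        return re.search(pattern, text, flags=re.IGNORECASE) is not None
    return term.lower() in text.lower()


def _first_matching_term(terms: Sequence[str], text: str) -> str | None:
    for term in terms:
        if _term_matches(term, text):
            return term
    return None


def classify_rrna(hit: HomologyHit) -> bool:
    """True when the hit's definition line names an rRNA feature."""
    return _first_matching_term(RRNA_TERMS, hit.subject_title) is not None


def classify_te(hit: HomologyHit) -> bool:
    """True for transposable-element hits, minus flanking-region decoys.

    Title terms and the species-field terms both count; any exclusion
    term in the definition line vetoes the hit (mobile-element entries
    are often deposited as "<element> flanking region" clones whose
    sequence is the host flank, not the element).
    """
    if _first_matching_term(TE_EXCLUSION_TERMS, hit.subject_title):
        return False
    if _first_matching_term(TE_TITLE_TERMS, hit.subject_title):
        return True
    return (
        _first_matching_term(TE_SPECIES_TERMS, hit.species_field) is not None
    )


def classify_prokaryote(hit: HomologyHit) -> bool:
    """True when the taxonomic lineage is rooted in Bacteria/Archaea."""
    if not hit.lineage:
        logger.warning(
            "hit %s -> %s has no lineage; not classified as prokaryote",
            hit.query_id, hit.subject_accession,
        )
        return False
    root = hit.lineage.split(";")[0].strip().lower()
    return root in PROKARYOTE_ROOTS


def classify_virus(hit: HomologyHit) -> bool:
    """True for hits against viral reference proteins at e <= 1e-60."""
    if hit.db_tag != "viral_refseq":
        return False
    return hit.evalue <= VIRAL_EVALUE_MAX


def best_hit(hits: Iterable[HomologyHit]) -> HomologyHit:
    """Lowest e-value; ties by higher bitscore, then accession order."""
    return min(
        hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_accession)
    )


_RULES = {
    "virus": classify_virus,
    "prokaryote": classify_prokaryote,
    "transposable_element": classify_te,
    "rrna": classify_rrna,
    "mitochondrial": lambda h: h.db_tag == "mito_ref",
}


def classify_contig(
    hits: Sequence[HomologyHit],
    precedence: Sequence[str] = CATEGORY_PRECEDENCE,
) -> AnnotationLabel:
    """Single category for one contig's hits via rule precedence.

    Hits from the general databases must clear the 1e-12 threshold;
    viral-protein hits are judged by the viral rule's own 1e-60 cut.
    A contig whose surviving hits trigger no rule is ``eukaryote_other``
    if any hit survives and ``unassigned`` otherwise.
    """
    if not hits:
        return AnnotationLabel("", "unassigned")
    contig_id = hits[0].query_id
    if any(h.query_id != contig_id for h in hits):
        raise ValueError("hits must share one query_id")
    surviving = [
        h
        for h in hits
        if (h.db_tag == "viral_refseq") or h.evalue <= GENERAL_EVALUE_MAX
    ]
    for category in precedence:
        rule = _RULES[category]
        triggering = [h for h in surviving if rule(h)]
        if triggering:
            top = best_hit(triggering)
            return AnnotationLabel(
                contig_id,
                category,
                evidence=f"{category}:{top.subject_accession}",
            )
    # viral-db hits above the viral threshold carry no other information
    informative = [h for h in surviving if h.db_tag != "viral_refseq"]
    if informative:
        top = best_hit(informative)
        return AnnotationLabel(
            contig_id, "eukaryote_other",
            evidence=f"best:{top.subject_accession}",
        )
    return AnnotationLabel(contig_id, "unassigned")


def classify_library(
    hits: Iterable[HomologyHit],
    precedence: Sequence[str] = CATEGORY_PRECEDENCE,
) -> dict[str, AnnotationLabel]:
    """Classify every contig that has at least one hit."""
    by_contig: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_contig.setdefault(h.query_id, []).append(h)
    return {
        cid: classify_contig(rows, precedence)
        for cid, rows in by_contig.items()
    }


def contamination_free(
    lib: Library, labels: Mapping[str, AnnotationLabel]
) -> Library:
    """Remove contigs labelled viral, prokaryotic or mobile-element."""
    drop = {
        cid
        for cid, label in labels.items()
        if label.category in CONTAMINANT_CATEGORIES
    }
    keep = [c.id for c in lib.contigs if c.id not in drop]
    return lib.subset(keep)


# ---------------------------------------------------------------------------
# holobiont partition


@dataclass(frozen=True)
class HolobiontSets:
    """Lineage tokens assigning hits to the co-extracted genomes."""

    host_taxa: frozenset[str]
    symbiont_taxa: frozenset[str]
    plastid_terms: tuple[str, ...] = ("plastid", "chloroplast")


def _hit_holobiont_category(
    hit: HomologyHit, sets: HolobiontSets
) -> str | None:
    lineage_tokens = {t.strip().lower() for t in hit.lineage.split(";")}
    is_symbiont = bool(
        lineage_tokens & {t.lower() for t in sets.symbiont_taxa}
    )
    if is_symbiont:
        title = hit.subject_title.lower()
        if any(term in title for term in sets.plastid_terms):
            return "plastid"
        return "symbiont_nuclear"
    if lineage_tokens & {t.lower() for t in sets.host_taxa}:
        return "host"
    return None


def holobiont_partition(
    hits: Iterable[HomologyHit], sets: HolobiontSets
) -> dict[str, AnnotationLabel]:
    """Partition contigs between host, symbiont nucleus and plastid.

    A contig with hits in exactly one category gets that category; hits
    in more than one category mean conflicting database annotations and
    the contig is labelled ``conflict``.
    """
    by_contig: dict[str, set[str]] = {}
    for h in hits:
        cat = _hit_holobiont_category(h, sets)
        if cat is not None:
            by_contig.setdefault(h.query_id, set()).add(cat)
    labels = {}
    for cid, cats in by_contig.items():
        category = cats.pop() if len(cats) == 1 else "conflict"
        labels[cid] = AnnotationLabel(cid, category)
    return labels


# ---------------------------------------------------------------------------
# mitochondrial presence


def _merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mito_presence(
    hits: Iterable[HomologyHit],
    gene_table: Mapping[str, tuple[int, int]],
    full_threshold: float = 0.95,
    contig_lengths: Mapping[str, int] | None = None,
) -> tuple[dict[str, str], int]:
    """Presence matrix of mitochondrial genes plus recovered mito bp.

    ``gene_table`` maps gene name to its (start, end) on the reference
    mitogenome; hits must carry subject coordinates on that reference.
    A gene covered at >= ``full_threshold`` of its length (after
    merging hit intervals) is ``full``, any coverage is ``partial``,
    none is ``absent``.  ``total_mito_bp`` sums the lengths of the
    distinct contigs with significant mito hits (or their merged query
    spans when lengths are not provided).
    """
    mito_hits = [
        h
        for h in hits
        if h.db_tag == "mito_ref" and h.evalue <= GENERAL_EVALUE_MAX
    ]
    presence: dict[str, str] = {}
    for gene, (g_start, g_end) in gene_table.items():
        spans = []
        for h in mito_hits:
            s, e = sorted((h.s_start, h.s_end))
            s, e = max(s, g_start), min(e, g_end)
            if e > s:
                spans.append((s, e))
        covered = sum(e - s for s, e in _merge_intervals(spans))
        frac = covered / (g_end - g_start) if g_end > g_start else 0.0
        if frac >= full_threshold:
            presence[gene] = "full"
        elif frac > 0:
            presence[gene] = "partial"
        else:
            presence[gene] = "absent"
    total_bp = 0
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for h in mito_hits:
        qs, qe = sorted((h.q_start, h.q_end))
        by_contig.setdefault(h.query_id, []).append((qs, qe))
    for cid, spans in by_contig.items():
        if contig_lengths is not None and cid in contig_lengths:
            total_bp += contig_lengths[cid]
        else:
            total_bp += sum(e - s for s, e in _merge_intervals(spans))
    return presence, total_bp


# ---------------------------------------------------------------------------
# tabular I/O

HIT_COLUMNS = [
    "query_id", "subject_accession", "evalue", "bitscore",
    "q_start", "q_end", "s_start", "s_end",
    "subject_title", "lineage", "species_field", "db_tag",
]


def read_hit_table(path) -> list[HomologyHit]:
    """Read an extended BLAST-tabular TSV (header = HIT_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HomologyHit(
                query_id=row.query_id,
                subject_accession=row.subject_accession,
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                q_start=int(row.q_start),
                q_end=int(row.q_end),
                s_start=int(row.s_start),
                s_end=int(row.s_end),
                subject_title=row.subject_title,
                lineage=row.lineage,
                species_field=row.species_field,
                db_tag=row.db_tag,
            )
        )
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path) -> None:
    rows = [[getattr(h, c) for c in HIT_COLUMNS] for h in hits]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def labels_to_tsv(labels: Mapping[str, AnnotationLabel], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tcategory\tevidence\n")
        for cid in sorted(labels):
            lab = labels[cid]
            fh.write(f"{cid}\t{lab.category}\t{lab.evidence}\n")


def contamination_report(
    lib: Library, labels: Mapping[str, AnnotationLabel]
) -> pd.DataFrame:
    """Per-category contig/read/bp inventory (zero rows included)."""
    categories = list(CATEGORY_PRECEDENCE) + [
        "eukaryote_other", "unassigned",
    ]
    by_id = {c.id: c for c in lib.contigs}
    rows = []
    for cat in categories:
        cids = [
            cid
            for cid, lab in labels.items()
            if lab.category == cat and cid in by_id
        ]
        contigs = [by_id[c] for c in cids]
        rows.append(
            {
                "category": cat,
                "n_contigs": len(contigs),
                "n_reads": sum(c.n_reads for c in contigs),
                "total_contig_bp": sum(len(c) for c in contigs),
            }
        )
    unlabelled = [c for c in lib.contigs if c.id not in labels]
    rows.append(
        {
            "category": "no_hit",
            "n_contigs": len(unlabelled),
            "n_reads": sum(c.n_reads for c in unlabelled),
            "total_contig_bp": sum(len(c) for c in unlabelled),
        }
    )
    return pd.DataFrame(rows)
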