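"""Read-weighted redundancy resolution for KEGG BRITE class assignments.

One orthology record can map to several BRITE classes.  To keep the
per-library functional profile additive in sequencing effort, each
class assigned to a contig receives ``n_reads / n_classes`` for that
contig, so before any exclusion the class scores sum exactly to the
number of reads of the scored contigs.  Classes too imprecise for
survey data ("Organismal Systems", "Human Diseases", "Enzyme
Families") are dropped from the report *after* aggregation, leaving
the divisor untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"Organismal Systems", "Human Diseases", "Enzyme Families"}
)


@dataclass(frozen=True)
class OrthologyAssignment:
    contig_id: str
    n_reads: int
    classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def brite_scores(
    assignments: Iterable[OrthologyAssignment],
    excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
    divide_before_exclusion: bool = True,
) -> dict[str, float]:
    """Aggregate read-weighted scores per BRITE class.

    Contigs with an empty class set are skipped with a warning.  With
    ``divide_before_exclusion`` (the default) the per-contig divisor is
    the full class count and the exclusion only hides classes from the
    output; the alternative renormalises over the surviving classes.
    """
    scores: dict[str, float] = {}
    for a in assignments:
        classes = a.classes
        if not classes:
            logger.warning("contig %s has no BRITE classes; skipped",
                           a.contig_id)
            continue
        if divide_before_exclusion:
            share = a.n_reads / len(classes)
            for cls in classes:
                scores[cls] = scores.get(cls, 0.0) + share
        else:
            kept = classes - excluded_classes
            if not kept:
                continue
            share = a.n_reads / len(kept)
            for cls in kept:
                scores[cls] = scores.get(cls, 0.0) + share
    return {
        cls: score
        for cls, score in scores.items()
        if cls not in excluded_classes
    }


def read_orthology_table(path) -> list[OrthologyAssignment]:
    """Read a ``contig_id<TAB>n_reads<TAB>class;class;...`` table."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        names=["contig_id", "n_reads", "classes"], header=0,
    )
    out = []
    for row in df.itertuples(index=False):
        classes = frozenset(
            c.strip() for c in row.classes.split(";") if c.strip()
        )
        out.append(
            OrthologyAssignment(
                contig_id=row.contig_id,
                n_reads=int(row.n_reads),
                classes=classes,
            )
        )
    return out


def scores_to_tsv(scores: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tscore\n")
        for cls in sorted(scores, key=lambda c: (-scores[c], c)):
            fh.write(f"{cls}\t{scores[cls]:.4f}\n")
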