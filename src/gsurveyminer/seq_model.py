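"""Contigs, libraries and genome-size records shared by every pipeline stage.

A *contig* here is any unique sequence in an assembled 454-style survey
library, including unassembled single reads (``n_reads == 1``).  The read
count is first-class metadata: the marker pipeline restricts final
candidates to single-read contigs, and the functional weighting divides
read counts over orthology classes, so every stage needs it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: Standard C-value conversion: 1 pg of DNA corresponds to 978 Mbp.
BP_PER_PG = 978e6


@dataclass(frozen=True)
class Contig:
    """One unique library sequence together with its assembly read count."""

    id: str
    sequence: str
    n_reads: int = 1
    library_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        if self.n_reads < 1:
            raise ValueError(f"contig {self.id!r}: n_reads must be >= 1")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)}; "
                "only A, C, G, T, N are accepted"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_single_read(self) -> bool:
        return self.n_reads == 1


@dataclass
class Library:
    """An ordered collection of contigs plus raw-read bookkeeping.

    ``n_raw_reads``/``raw_read_bp`` describe the unassembled library the
    contigs were built from; they are carried for coverage and
    per-category read fractions but are never derived from the contigs.
    """

    id: str
    contigs: list[Contig] = field(default_factory=list)
    n_raw_reads: int = 0
    raw_read_bp: int = 0

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_contig_bp(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def total_reads(self) -> int:
        """Sum of per-contig read counts (assembled reads)."""
        return sum(c.n_reads for c in self.contigs)

    @property
    def mean_contig_length(self) -> float:
        if not self.contigs:
            raise ValueError(f"library {self.id!r} is empty")
        return self.total_contig_bp / len(self.contigs)

    def subset(self, contig_ids: Iterable[str]) -> "Library":
        wanted = set(contig_ids)
        return replace(
            self, contigs=[c for c in self.contigs if c.id in wanted]
        )


@dataclass(frozen=True)
class GenomeSizeRecord:
    """Haploid genome size of a (related) species, as a C-value in pg."""

    species: str
    c_value_pg: float
    conversion: float = BP_PER_PG

    def __post_init__(self) -> None:
        if self.c_value_pg <= 0 or self.conversion <= 0:
            raise ValueError("C-value and conversion must be positive")

    @property
    def genome_bp(self) -> float:
        return self.c_value_pg * self.conversion


def read_counts_table(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``contig_id<TAB>n_reads`` table."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated "
                    f"columns, got {len(parts)}"
                )
            cid, raw = parts
            try:
                n = int(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: read count {raw!r} is not an "
                    "integer"
                ) from exc
            if n < 1:
                raise ValueError(
                    f"{path}: line {lineno}: read count must be >= 1"
                )
            counts[cid] = n
    return counts


def read_fasta(
    path: str | os.PathLike,
    counts_path: str | os.PathLike | None = None,
    library_id: str | None = None,
) -> Library:
    """Load a library from FASTA, optionally attaching per-contig read counts.

    Contigs missing from the counts table default to single reads.
    Duplicate record ids and empty records are hard errors.
    """
    counts = read_counts_table(counts_path) if counts_path else {}
    lib_id = library_id if library_id is not None else os.path.basename(
        os.fspath(path)
    )
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: contig {rec.id!r} has no sequence")
        contigs.append(
            Contig(
                id=rec.id,
                sequence=seq,
                n_reads=counts.get(rec.id, 1),
                library_id=lib_id,
            )
        )
    return Library(id=lib_id, contigs=contigs)


def write_fasta(lib: Library, path: str | os.PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in lib.contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_counts_table(lib: Library, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in lib.contigs:
            fh.write(f"{c.id}\t{c.n_reads}\n")


def read_genome_sizes(path: str | os.PathLike) -> dict[str, GenomeSizeRecord]:
    """Read a ``species<TAB>c_value_pg`` table."""
    out: dict[str, GenomeSizeRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns"
                )
            species, pg = parts
            out[species] = GenomeSizeRecord(species=species, c_value_pg=float(pg))
    return out
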