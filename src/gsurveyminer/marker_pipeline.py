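"""Candidate-locus filtering cascade for micro-/minisatellite markers.

Stages, in order: contig length floor (100 bp) -> repeat search under a
named profile -> optional 100%-perfection filter -> primer feasibility
with all repeats on the contig masked -> cryptic-simplicity screen of
every primer -> optional single-read-contig restriction.  The stages
are independent predicates, so the order only affects how much work is
wasted, not the final set.

A pair is "clean" when neither of its primers is significantly simple;
the chosen pair is the first clean one, otherwise the best-penalty pair
is kept but the candidate fails the ``not_simple`` filter.  Each repeat
match yields one candidate, so a contig carrying several repeats can
contribute several loci.
"""

from __future__ import annotations

from dataclasses import dataclass

from .primer_design import PrimerPair, PrimerParams, design_primer_pairs
from .seq_model import Library
from .simplicity import SimplicityParams, simplicity_test
from .tandem_repeat import (
    RepeatMatch,
    SearchProfile,
    find_tandem_repeats,
    perfect_only,
)

MIN_CONTIG_BP = 100

FILTER_NAMES = (
    "min_length",
    "perfection",
    "has_primers",
    "not_simple",
    "single_read",
)


@dataclass(frozen=True)
class MarkerCandidate:
    contig_id: str
    repeat: RepeatMatch
    primer_pairs: tuple[PrimerPair, ...]
    chosen_pair: PrimerPair | None
    filters_passed: dict[str, bool]
    retained: bool


@dataclass
class FunnelReport:
    """Counts surviving each stage of the cascade.

    Locus counts and contig counts are both reported: a contig with
    several repeats contributes several loci but one contig.
    """

    profile: str
    n_contigs: int = 0
    n_contigs_min_length: int = 0
    n_repeats: int = 0
    n_after_perfection: int = 0
    n_with_primers: int = 0
    n_not_simple: int = 0
    n_retained: int = 0
    n_contigs_retained: int = 0

    def stage_counts(self) -> list[tuple[str, int]]:
        return [
            ("contigs", self.n_contigs),
            ("contigs_min_length", self.n_contigs_min_length),
            ("repeats", self.n_repeats),
            ("after_perfection", self.n_after_perfection),
            ("with_primers", self.n_with_primers),
            ("not_simple", self.n_not_simple),
            ("retained", self.n_retained),
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in self.stage_counts():
                fh.write(f"{stage}\t{count}\n")
            fh.write(f"contigs_retained\t{self.n_contigs_retained}\n")


def retention_percent(n_retained: int, n_initial: int) -> float:
    """Retained candidates as a percentage (2 decimals, half-up)."""
    from .summary_stats import round_half_up

    if n_initial <= 0:
        raise ValueError("n_initial must be positive")
    return round_half_up(100.0 * n_retained / n_initial, 2)


def run_marker_pipeline(
    lib: Library,
    profile: SearchProfile,
    primer_params: PrimerParams | None = None,
    simplicity_params: SimplicityParams | None = None,
    require_perfect: bool = True,
    single_read_only: bool = True,
    min_contig_bp: int = MIN_CONTIG_BP,
) -> tuple[list[MarkerCandidate], FunnelReport]:
    """Run the full filtering cascade over a library.

    Returns every candidate (retained or not, with its per-filter
    verdicts) plus the funnel counts.
    """
    primer_params = primer_params or PrimerParams()
    simplicity_params = simplicity_params or SimplicityParams()
    report = FunnelReport(profile=profile.name, n_contigs=len(lib.contigs))
    candidates: list[MarkerCandidate] = []
    retained_contigs: set[str] = set()

    for contig in lib.contigs:
        if len(contig) < min_contig_bp:
            continue
        report.n_contigs_min_length += 1
        matches = find_tandem_repeats(
            contig.sequence, profile, contig_id=contig.id
        )
        report.n_repeats += len(matches)
        if require_perfect:
            kept = perfect_only(matches)
        else:
            kept = matches
        report.n_after_perfection += len(kept)
        all_intervals = [(m.start, m.end) for m in matches]
        for m in kept:
            filters = {name: False for name in FILTER_NAMES}
            filters["min_length"] = True
            filters["perfection"] = True
            pairs = design_primer_pairs(
                contig.sequence,
                excluded=all_intervals,
                params=primer_params,
                target=(m.start, m.end),
            )
            chosen: PrimerPair | None = None
            if pairs:
                filters["has_primers"] = True
                report.n_with_primers += 1
                for pair in pairs:
                    left = simplicity_test(pair.left_seq, simplicity_params)
                    right = simplicity_test(pair.right_seq, simplicity_params)
                    if not (left.is_simple or right.is_simple):
                        chosen = pair
                        filters["not_simple"] = True
                        break
                if chosen is None:
                    # all pairs significantly simple: keep best for the
                    # record but fail the filter
                    chosen = pairs[0]
                if filters["not_simple"]:
                    report.n_not_simple += 1
            filters["single_read"] = (
                contig.is_single_read if single_read_only else True
            )
            retained = all(filters.values())
            if retained:
                report.n_retained += 1
                retained_contigs.add(contig.id)
            candidates.append(
                MarkerCandidate(
                    contig_id=contig.id,
                    repeat=m,
                    primer_pairs=tuple(pairs),
                    chosen_pair=chosen,
                    filters_passed=filters,
                    retained=retained,
                )
            )
    report.n_contigs_retained = len(retained_contigs)
    return candidates, report


def candidates_to_tsv(candidates, path) -> None:
    cols = (
        "contig_id\tstart\tend\tunit_length\tmotif\tperfection\t"
        "left_primer\tright_primer\tproduct_size\t"
        + "\t".join(FILTER_NAMES)
        + "\tretained\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in candidates:
            m = c.repeat
            pair = c.chosen_pair
            left = pair.left_seq if pair else ""
            right = pair.right_seq if pair else ""
            size = pair.product_size if pair else ""
            flags = "\t".join(
                str(int(c.filters_passed[n])) for n in FILTER_NAMES
            )
            fh.write(
                f"{c.contig_id}\t{m.start}\t{m.end}\t{m.unit_length}\t"
                f"{m.motif}\t{m.perfection:.2f}\t{left}\t{right}\t{size}\t"
                f"{flags}\t{int(c.retained)}\n"
            )
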