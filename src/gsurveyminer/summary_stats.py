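"""Coverage estimates, library percentages, correlation and report tables.

Genome coverage is estimated from C-values: a survey of ``total_bp``
sequenced base pairs covers ``100 * total_bp / (c_value_pg * 978 Mbp)``
percent of a genome of the given C-value.  Report rounding follows the
library-table conventions: percentages half-up to 2 decimals, mean
lengths to 1 decimal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .seq_model import GenomeSizeRecord, Library


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (report parity; bankers' rounding would
    disagree on exact .5 boundaries)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LibrarySummary:
    library_id: str
    n_reads: int
    read_bp: int
    n_contigs: int
    contig_bp: int
    mean_contig_length: float


def library_summary(lib: Library) -> LibrarySummary:
    """Contig counts, bp totals and mean contig length (1 decimal)."""
    if not lib.contigs:
        raise ValueError(f"library {lib.id!r} is empty")
    contig_bp = lib.total_contig_bp
    return LibrarySummary(
        library_id=lib.id,
        # fall back on assembled-read totals when raw-read bookkeeping
        # was not supplied with the FASTA
        n_reads=lib.n_raw_reads or lib.total_reads,
        read_bp=lib.raw_read_bp or sum(len(c) * c.n_reads for c in lib.contigs),
        n_contigs=len(lib.contigs),
        contig_bp=contig_bp,
        mean_contig_length=round_half_up(contig_bp / len(lib.contigs), 1),
    )


def genome_coverage(total_bp: float, gsr: GenomeSizeRecord) -> float:
    """Percent of the genome covered by ``total_bp``, 2 decimals."""
    if total_bp < 0:
        raise ValueError("total_bp must be non-negative")
    return round_half_up(100.0 * total_bp / gsr.genome_bp, 2)


def percent_of_library(n_part: float, n_total: float) -> float:
    """Share of a library as a percentage, 2 decimals half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_part <= n_total):
        raise ValueError("need 0 <= n_part <= n_total")
    return round_half_up(100.0 * n_part / n_total, 2)


def correlate_mt_recovery(
    pairs: Sequence[tuple[float, float]], method: str = "spearman"
) -> dict[str, float]:
    """Correlation between library size and recovered mitochondrial bp.

    ``pairs`` holds (library_contig_bp, mito_bp) per library; both
    Spearman and Pearson are offered with two-sided p-values.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 libraries")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("constant input has no defined correlation")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p)}


def build_reports(
    lib: Library,
    out_dir: str | os.PathLike,
    labels: Mapping | None = None,
    funnel=None,
    densities: Mapping[str, Mapping[str, float]] | None = None,
    brite: Mapping[str, float] | None = None,
    genome_size: GenomeSizeRecord | None = None,
) -> dict[str, str]:
    """Write deterministic TSV report tables for completed stages.

    Returns a mapping of report name to file path.  Only reports whose
    inputs were supplied are produced; reruns on identical inputs are
    byte-identical.
    """
    from .annotation import contamination_report

    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}

    s = library_summary(lib)
    path = os.path.join(out_dir, "library_summary.tsv")
    row = {
        "library_id": s.library_id,
        "n_reads": s.n_reads,
        "read_bp": s.read_bp,
        "n_contigs": s.n_contigs,
        "contig_bp": s.contig_bp,
        "mean_contig_length": f"{s.mean_contig_length:.1f}",
    }
    if genome_size is not None:
        row["coverage_reads_pct"] = f"{genome_coverage(s.read_bp, genome_size):.2f}"
        row["coverage_contigs_pct"] = f"{genome_coverage(s.contig_bp, genome_size):.2f}"
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
    written["library_summary"] = path

    if labels is not None:
        path = os.path.join(out_dir, "contamination_report.tsv")
        df = contamination_report(lib, labels)
        total_reads = lib.total_reads
        df["pct_of_reads"] = [
            f"{percent_of_library(n, total_reads):.2f}" for n in df["n_reads"]
        ]
        df["pct_of_contigs"] = [
            f"{percent_of_library(n, len(lib.contigs)):.2f}"
            for n in df["n_contigs"]
        ]
        df.to_csv(path, sep="\t", index=False)
        written["contamination_report"] = path

    if funnel is not None:
        path = os.path.join(out_dir, "marker_funnel.tsv")
        funnel.to_tsv(path)
        written["marker_funnel"] = path

    if densities is not None:
        path = os.path.join(out_dir, "repeat_density.tsv")
        with open(path, "w") as fh:
            fh.write("profile\trepeat_bp\tbp_per_mbp\tpercent_of_sequence\n")
            for profile in sorted(densities):
                d = densities[profile]
                fh.write(
                    f"{profile}\t{d['repeat_bp']:.0f}\t"
                    f"{d['bp_per_mbp']:.1f}\t"
                    f"{round_half_up(d['percent_of_sequence'], 2):.2f}\n"
                )
        written["repeat_density"] = path

    if brite is not None:
        from .brite_weighting import scores_to_tsv

        path = os.path.join(out_dir, "brite_scores.tsv")
        scores_to_tsv(brite, path)
        written["brite_scores"] = path

    return written
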