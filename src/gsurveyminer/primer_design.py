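"""Primer-pair feasibility search on tandem-repeat flanks.

A deterministic, exhaustive re-check of the constraint set used for
marker primer design: every 18-27-mer window in the left and right
flank is screened structurally (poly-X runs, ambiguous bases, GC
content) and thermodynamically (nearest-neighbour melting temperature),
then windows are paired so that the product spans the masked repeat
without either primer touching a masked region.  Pairs are ranked by a
penalty that measures distance from the optimal melting temperature
and primer length.

Melting temperatures use the SantaLucia unified nearest-neighbour
parameter set (50 mM monovalent salt, 50 nM oligo).  Dimer and hairpin
thermodynamics are deliberately not modelled; the checker answers
"does a structurally and thermally sound pair exist", and a full
designer can be swapped in behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

Interval = tuple[int, int]


@dataclass(frozen=True)
class PrimerParams:
    """Constraint set for primer feasibility.

    ``product_size_range``, ``max_tm_diff``, ``max_poly_x``, ``max_n``
    and ``n_return`` follow the marker-design settings; primer length,
    melting temperature and GC bounds are the designer's conventional
    defaults and stay configurable.
    """

    product_size_range: tuple[int, int] = (100, 300)
    max_tm_diff: float = 8.0
    max_poly_x: int = 4
    max_n: int = 1
    n_return: int = 3
    primer_length_range: tuple[int, int] = (18, 27)
    tm_range: tuple[float, float] = (57.0, 63.0)
    tm_target: float = 60.0
    gc_range: tuple[float, float] = (20.0, 80.0)
    optimal_length: int = 20


@dataclass(frozen=True)
class PrimerPair:
    """One feasible pair; right primer is the reverse complement of its
    genomic window ``[right_start, right_start + len)``."""

    left_seq: str
    right_seq: str
    left_start: int
    right_start: int
    product_size: int
    left_tm: float
    right_tm: float
    penalty: float


def melting_temperature(seq: str) -> float:
    """Nearest-neighbour Tm, SantaLucia unified parameters.

    Ambiguous bases are approximated as A (a destabilising choice).
    """
    seq = seq.upper().replace("N", "A")
    return float(
        _mt.Tm_NN(Seq(seq), nn_table=_mt.DNA_NN3, Na=50, dnac1=50, dnac2=0)
    )


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _gc_percent(seq: str) -> float:
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def _window_ok(window: str, params: PrimerParams) -> bool:
    if window.count("N") > params.max_n:
        return False
    if _max_homopolymer(window) > params.max_poly_x:
        return False
    lo, hi = params.gc_range
    return lo <= _gc_percent(window) <= hi


def _overlaps(start: int, end: int, intervals: Sequence[Interval]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def _candidate_windows(
    seq: str,
    lo_bound: int,
    hi_bound: int,
    excluded: Sequence[Interval],
    params: PrimerParams,
) -> list[tuple[int, int, float, float]]:
    """Feasible (start, length, tm, penalty) windows within bounds."""
    lmin, lmax = params.primer_length_range
    tlo, thi = params.tm_range
    out = []
    for start in range(lo_bound, hi_bound):
        for length in range(lmin, lmax + 1):
            end = start + length
            if end > hi_bound:
                break
            if _overlaps(start, end, excluded):
                continue
            window = seq[start:end]
            if not _window_ok(window, params):
                continue
            tm = melting_temperature(window)
            if not (tlo <= tm <= thi):
                continue
            pen = abs(tm - params.tm_target) + abs(
                length - params.optimal_length
            )
            out.append((start, length, tm, pen))
    return out


def design_primer_pairs(
    contig_seq: str,
    excluded: Sequence[Interval],
    params: PrimerParams | None = None,
    target: Interval | None = None,
) -> list[PrimerPair]:
    """Search both flanks for up to ``n_return`` feasible primer pairs.

    ``excluded`` are masked intervals (tandem repeats) no primer may
    overlap; ``target`` is the interval the product must span and
    defaults to the hull of the excluded intervals.  Returns pairs
    best-penalty first; an infeasible contig yields an empty list.
    """
    params = params or PrimerParams()
    contig_seq = contig_seq.upper()
    n = len(contig_seq)
    for s, e in excluded:
        if not (0 <= s <= e <= n):
            raise ValueError(f"excluded interval ({s}, {e}) outside contig")
    if target is None:
        if not excluded:
            raise ValueError("need a target interval or excluded regions")
        target = (min(s for s, _ in excluded), max(e for _, e in excluded))
    t_start, t_end = target

    lefts = _candidate_windows(contig_seq, 0, t_start, excluded, params)
    rights = _candidate_windows(contig_seq, t_end, n, excluded, params)
    if not lefts or not rights:
        return []

    p_lo, p_hi = params.product_size_range
    la = np.asarray(lefts, dtype=float)  # columns: start, length, tm, pen
    ra = np.asarray(rights, dtype=float)
    product = (ra[:, 0] + ra[:, 1])[None, :] - la[:, 0][:, None]
    ok = (product >= p_lo) & (product <= p_hi)
    ok &= (
        np.abs(la[:, 2][:, None] - ra[:, 2][None, :]) <= params.max_tm_diff
    )
    li, ri = np.nonzero(ok)
    if li.size == 0:
        return []
    penalty = la[li, 3] + ra[ri, 3]
    order = np.lexsort((ra[ri, 0], la[li, 0], penalty))[: params.n_return]
    out = []
    for k in order:
        ls, llen = int(la[li[k], 0]), int(la[li[k], 1])
        rs, rlen = int(ra[ri[k], 0]), int(ra[ri[k], 1])
        out.append(
            PrimerPair(
                left_seq=contig_seq[ls : ls + llen],
                right_seq=str(
                    Seq(contig_seq[rs : rs + rlen]).reverse_complement()
                ),
                left_start=ls,
                right_start=rs,
                product_size=rs + rlen - ls,
                left_tm=float(la[li[k], 2]),
                right_tm=float(ra[ri[k], 2]),
                penalty=float(penalty[k]),
            )
        )
    return out


def pairs_to_tsv(contig_id: str, pairs: Sequence[PrimerPair], fh) -> None:
    for p in pairs:
        fh.write(
            f"{contig_id}\t{p.left_seq}\t{p.right_seq}\t{p.left_start}\t"
            f"{p.right_start}\t{p.product_size}\t{p.left_tm:.2f}\t"
            f"{p.right_tm:.2f}\n"
        )
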