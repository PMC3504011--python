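"""Exact and imperfect tandem-repeat detection under named search profiles.

The detector models a tandem repeat of unit length ``u`` as a gapless
local self-alignment at lag ``u``: position ``i`` is compared with
position ``i + u``, a match scores +1 and a mismatch scores the profile
penalty (default -5).  A run of ``L`` scoring columns starting at ``a``
describes a repeat region ``[a, a + L + u)`` — the aligned columns plus
one trailing unit.  A perfect repeat of region length ``R`` therefore
scores ``R - u``, which makes the published minimum scores act as
effective minimum lengths (e.g. ``s = 12`` admits a perfect
dinucleotide only from 14 bp up).

Candidate segments must start and end on a matching column, meet the
profile's minimum score (and minimum region length, where set), and are
reduced to a pairwise non-overlapping set by a deterministic greedy
rule: highest score first, ties broken by smaller unit, then leftmost
start, then smaller end.  Indels inside a repeat array shift its lag;
they are picked up as neighbouring-lag segments rather than as gapped
columns, so ``n_gap`` is always 0 in reported matches.

``N`` matches nothing, including another ``N``, and scores as a
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SearchProfile",
    "RepeatMatch",
    "BUILTIN_PROFILES",
    "find_tandem_repeats",
    "perfect_only",
    "perfection_filter",
    "repeat_density",
    "canonical_rotation",
]


@dataclass(frozen=True)
class SearchProfile:
    """One named set of repeat-search parameters."""

    name: str
    mode: str  # "exact" or "imperfect"
    unit_min: int
    unit_max: int
    min_score: float
    mismatch_penalty: float = -5.0
    gap_penalty: float = -5.0
    min_region_bp: int | None = None
    perfection_min: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "imperfect"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if not (1 <= self.unit_min <= self.unit_max):
            raise ValueError("need 1 <= unit_min <= unit_max")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


#: The published search profiles.  ``mayer_micro``/``mayer_mini`` are the
#: imperfect micro- and minisatellite searches; ``santana_mono`` and
#: ``santana_2_6`` the exact mono- and di-to-hexanucleotide searches;
#: ``gardner`` the most restrictive exact di-to-hexa search.
BUILTIN_PROFILES: dict[str, SearchProfile] = {
    "mayer_micro": SearchProfile(
        name="mayer_micro", mode="imperfect", unit_min=1, unit_max=6,
        min_score=12,
    ),
    "mayer_mini": SearchProfile(
        name="mayer_mini", mode="imperfect", unit_min=7, unit_max=50,
        min_score=12, min_region_bp=30,
    ),
    "santana_mono": SearchProfile(
        name="santana_mono", mode="exact", unit_min=1, unit_max=1,
        min_score=11,
    ),
    "santana_2_6": SearchProfile(
        name="santana_2_6", mode="exact", unit_min=2, unit_max=6,
        min_score=8, min_region_bp=5,
    ),
    "gardner": SearchProfile(
        name="gardner", mode="exact", unit_min=2, unit_max=6, min_score=8,
    ),
}


@dataclass(frozen=True)
class RepeatMatch:
    """A located tandem repeat (0-based, half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    unit_length: int
    motif: str
    score: float
    n_match: int
    n_mismatch: int
    n_gap: int
    perfection: float

    @property
    def region_bp(self) -> int:
        return self.end - self.start


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_BASE_CODE[b] for b in seq), dtype=np.int8, count=len(seq)
        )
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None


def _match_vector(codes: np.ndarray, u: int) -> np.ndarray:
    """Boolean lag-u match vector; N (code 4) never matches."""
    left, right = codes[:-u], codes[u:]
    return (left == right) & (left != 4)


def _best_segment(
    S: np.ndarray,
    start_ok: np.ndarray,
    end_ok: np.ndarray,
    lo: int,
    hi: int,
    lmin: int,
) -> tuple[float, int, int] | None:
    """Best-scoring segment [a, b) within window [lo, hi).

    ``S`` is the full prefix-sum array (S[b] - S[a] = segment score);
    segments must start on a column with ``start_ok[a]``, end on one
    with ``end_ok[b - 1]`` and have length >= lmin.  Ties resolve to
    the smallest start, then the smallest end.
    """
    length = hi - lo
    if length < lmin:
        return None
    s = S[lo : hi + 1]
    starts = np.where(start_ok[lo:hi], s[:-1], np.inf)
    # running minimum of admissible prefix values, earliest index wins
    run_min = np.minimum.accumulate(starts)
    prev = np.concatenate(([np.inf], run_min[:-1]))
    idx = np.where(starts < prev, np.arange(length), -1)
    run_idx = np.maximum.accumulate(idx)
    # candidate segment ends b (window-local), need b - a >= lmin
    b = np.arange(lmin, length + 1)
    amax = b - lmin  # largest admissible prefix position for each b
    mins = run_min[amax]
    valid = end_ok[lo + b - 1] & np.isfinite(mins)
    if not valid.any():
        return None
    scores = s[b] - mins
    scores[~valid] = -np.inf
    best = scores.max()
    if not np.isfinite(best):
        return None
    cand = np.flatnonzero(scores == best)
    a_for_b = run_idx[amax[cand]]
    order = np.lexsort((b[cand], a_for_b))[0]
    return float(best), lo + int(a_for_b[order]), lo + int(b[cand[order]])


def _consensus_unit(seq: str, start: int, end: int, u: int) -> str:
    """Majority base per unit column over the repeat region."""
    bases = []
    for j in range(u):
        col = seq[start + j : end : u]
        counts: dict[str, int] = {}
        for b in col:
            if b != "N":
                counts[b] = counts.get(b, 0) + 1
        if counts:
            bases.append(min(counts, key=lambda k: (-counts[k], k)))
        else:
            bases.append("N")
    return "".join(bases)


def find_tandem_repeats(
    seq: str,
    profile: SearchProfile,
    contig_id: str = "",
) -> list[RepeatMatch]:
    """Detect tandem repeats in ``seq`` under ``profile``.

    Returns non-overlapping matches sorted by start position.  A
    sequence too short to hold any repeat yields an empty list.
    """
    seq = seq.upper()
    n = len(seq)
    codes = _encode(seq)
    penalty = profile.mismatch_penalty
    min_region = profile.min_region_bp or 0

    # per-lag column values and prefix sums; exact mode forbids
    # mismatching columns outright
    lag_data: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    windows: list[list[int]] = []  # [u, lo, hi]
    for u in range(profile.unit_min, min(profile.unit_max, n - 1) + 1):
        m = _match_vector(codes, u)
        if profile.mode == "exact":
            vals = np.where(m, 1.0, -float(n + 1))
        else:
            vals = np.where(m, 1.0, penalty)
        S = np.concatenate(([0.0], np.cumsum(vals)))
        lag_data[u] = (m, S)
        windows.append([u, 0, n - u])

    cache: dict[tuple[int, int, int], tuple[float, int, int] | None] = {}

    def window_best(u: int, lo: int, hi: int):
        key = (u, lo, hi)
        if key not in cache:
            m, S = lag_data[u]
            lmin = max(1, min_region - u)
            cache[key] = _best_segment(S, m, m, lo, hi, lmin)
        return cache[key]

    accepted: list[tuple[int, int, int, float]] = []  # (a, b, u, score)
    while True:
        best_key = None
        best_seg = None
        for u, lo, hi in windows:
            seg = window_best(u, lo, hi)
            if seg is None or seg[0] < profile.min_score:
                continue
            score, a, b = seg
            key = (-score, u, a, b)
            if best_key is None or key < best_key:
                best_key = key
                best_seg = (a, b, u, score)
        if best_seg is None:
            break
        a, b, u, score = best_seg
        ra, rb = a, b + u  # blocked sequence region
        accepted.append((a, b, u, score))
        new_windows: list[list[int]] = []
        for w in windows:
            wu, lo, hi = w
            if hi + wu <= ra or lo >= rb:  # sequence spans disjoint
                new_windows.append(w)
                continue
            left_hi = min(hi, ra - wu)
            if left_hi - lo >= 1:
                new_windows.append([wu, lo, left_hi])
            right_lo = max(lo, rb)
            if hi - right_lo >= 1:
                new_windows.append([wu, right_lo, hi])
        windows = new_windows

    matches: list[RepeatMatch] = []
    for a, b, u, score in sorted(accepted):
        m, _ = lag_data[u]
        n_match = int(m[a:b].sum())
        n_mismatch = (b - a) - n_match
        perfection = 100.0 * n_match / (n_match + n_mismatch)
        unit = _consensus_unit(seq, a, b + u, u)
        matches.append(
            RepeatMatch(
                contig_id=contig_id,
                start=a,
                end=b + u,
                unit_length=u,
                motif=canonical_rotation(unit),
                score=float(score),
                n_match=n_match,
                n_mismatch=n_mismatch,
                n_gap=0,
                perfection=perfection,
            )
        )
    return matches


def perfect_only(matches: Iterable[RepeatMatch]) -> list[RepeatMatch]:
    """Keep only 100%-perfect repeats (no interruptions)."""
    return [m for m in matches if m.perfection == 100.0]


def perfection_filter(
    matches: Iterable[RepeatMatch], threshold: float
) -> list[RepeatMatch]:
    """Keep repeats with perfection >= threshold (inclusive)."""
    return [m for m in matches if m.perfection >= threshold]


def repeat_density(
    matches: Sequence[RepeatMatch], total_bp: int
) -> dict[str, float]:
    """Repeat coverage as bp/Mbp and as percent of the sequence scanned.

    Assumes matches are already non-overlapping (as produced by
    :func:`find_tandem_repeats`).
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    repeat_bp = sum(m.region_bp for m in matches)
    bp_per_mbp = 1e6 * repeat_bp / total_bp
    return {
        "repeat_bp": float(repeat_bp),
        "bp_per_mbp": bp_per_mbp,
        "percent_of_sequence": bp_per_mbp / 1e4,
    }


def repeats_to_tsv(matches: Iterable[RepeatMatch], path) -> None:
    header = (
        "contig_id\tstart\tend\tunit_length\tmotif\tscore\t"
        "n_match\tn_mismatch\tn_gap\tperfection\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for m in matches:
            fh.write(
                f"{m.contig_id}\t{m.start}\t{m.end}\t{m.unit_length}\t"
                f"{m.motif}\t{m.score:g}\t{m.n_match}\t{m.n_mismatch}\t"
                f"{m.n_gap}\t{m.perfection:.2f}\n"
            )


def repeats_to_gff3(matches: Iterable[RepeatMatch], path) -> None:
    """GFF3 output (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in matches:
            attrs = (
                f"motif={m.motif};unit_length={m.unit_length};"
                f"perfection={m.perfection:.2f}"
            )
            fh.write(
                f"{m.contig_id}\tgsurveyminer\ttandem_repeat\t"
                f"{m.start + 1}\t{m.end}\t{m.score:g}\t+\t.\t{attrs}\n"
            )
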