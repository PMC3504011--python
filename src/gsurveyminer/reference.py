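"""Brute-force reference implementations used to validate the fast paths.

These routines restate the detector semantics as literal enumeration:
every admissible segment is scored one column at a time and the
non-overlapping set is selected by explicit greedy sorting.  They share
no code with the production implementations and are deliberately slow;
they exist so that the optimised detectors can be checked against an
exhaustive second opinion on small inputs.
"""

from __future__ import annotations

from .tandem_repeat import SearchProfile


def brute_force_tandem_repeats(
    seq: str, profile: SearchProfile
) -> list[tuple[int, int, int, float]]:
    """Enumerate-and-greedy tandem repeat search.

    Returns ``(start, end, unit_length, score)`` tuples for the final
    non-overlapping set, sorted by start.  ``end`` is the region end
    (aligned columns plus one unit), matching the fast detector.
    """
    seq = seq.upper()
    n = len(seq)
    min_region = profile.min_region_bp or 0
    candidates: list[tuple[float, int, int, int]] = []  # (score, u, a, b)
    for u in range(profile.unit_min, min(profile.unit_max, n - 1) + 1):
        cols = []
        for i in range(n - u):
            x, y = seq[i], seq[i + u]
            cols.append(x == y and x != "N")
        for a in range(n - u):
            if not cols[a]:
                continue
            score = 0.0
            n_mis = 0
            for b in range(a + 1, n - u + 1):
                if cols[b - 1]:
                    score += 1.0
                else:
                    n_mis += 1
                    score += profile.mismatch_penalty
                if not cols[b - 1]:
                    continue
                if profile.mode == "exact" and n_mis:
                    break
                region = (b - a) + u
                if score >= profile.min_score and region >= min_region:
                    candidates.append((score, u, a, b))
    # greedy: highest score, then smaller unit, then leftmost, then
    # smaller end; accepted regions block all overlapping candidates
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    chosen: list[tuple[int, int, int, float]] = []
    occupied: list[tuple[int, int]] = []
    for score, u, a, b in candidates:
        ra, rb = a, b + u
        if any(ra < e and s < rb for s, e in occupied):
            continue
        occupied.append((ra, rb))
        chosen.append((a, b + u, u, score))
    chosen.sort()
    return chosen


def brute_force_simplicity_score(
    seq: str,
    motif_weights: dict[int, float],
    half_window: int,
) -> float:
    """Literal triple loop over (i, j, k) position pairs and motif sizes."""
    n = len(seq)
    total = 0.0
    for i in range(n):
        for d in range(1, half_window + 1):
            j = i + d
            if j >= n:
                break
            for k, w in motif_weights.items():
                if j + k > n:
                    continue
                if seq[i : i + k] == seq[j : j + k]:
                    total += w
    return total
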