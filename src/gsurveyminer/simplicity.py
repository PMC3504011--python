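"""Shuffle-null test for cryptic simplicity in primer regions.

Short-motif repetitiveness that is not an obvious clean tandem repeat
("cryptic simplicity") makes priming regions unreliable.  The score
counts, over every ordered position pair at distance 1..half_window,
the motif lengths 1-4 whose copies at the two positions agree; the null
distribution comes from composition-preserving single-nucleotide
shuffles of the same sequence, so base composition alone can never make
a sequence significant.  Significance uses the add-one permutation
p-value (1 + #{null >= observed}) / (1 + n_shuffles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WEIGHTS = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}


@dataclass(frozen=True)
class SimplicityParams:
    """Parameters of the simplicity test.

    Defaults follow the conventional settings for DNA: equal weights
    for mono- to tetranucleotide motifs, half-window 4, 50 shuffled
    sequences, alpha 0.05.
    """

    motif_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    half_window: int = 4
    n_shuffles: int = 50
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class SimplicityVerdict:
    observed_score: float
    null_scores: tuple[float, ...]
    rsf: float  # relative simplicity factor: observed / mean(null)
    p_value: float
    is_simple: bool


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (_CODE[b] for b in seq.upper()), dtype=np.int8, count=len(seq)
    )


def _scores_2d(codes: np.ndarray, params: SimplicityParams) -> np.ndarray:
    """Simplicity scores for each row of a 2D code array."""
    n = codes.shape[1]
    out = np.zeros(codes.shape[0])
    for d in range(1, params.half_window + 1):
        if d >= n:
            break
        eq = (codes[:, :-d] == codes[:, d:]).astype(np.int64)
        csum = np.concatenate(
            [np.zeros((codes.shape[0], 1), dtype=np.int64),
             np.cumsum(eq, axis=1)],
            axis=1,
        )
        for k, w in params.motif_weights.items():
            limit = n - d - k  # largest admissible start position
            if limit < 0:
                continue
            wins = csum[:, k : k + limit + 1] - csum[:, : limit + 1]
            out += w * (wins == k).sum(axis=1)
    return out


def simplicity_score(seq: str, params: SimplicityParams | None = None) -> float:
    """Deterministic repetitiveness score of one sequence."""
    params = params or SimplicityParams()
    if len(seq) < 2:
        return 0.0
    return float(_scores_2d(_encode(seq)[None, :], params)[0])


def simplicity_test(
    seq: str, params: SimplicityParams | None = None
) -> SimplicityVerdict:
    """Score ``seq`` against composition-preserving shuffles.

    Deterministic for a given ``params.seed``.
    """
    params = params or SimplicityParams()
    codes = _encode(seq)
    observed = float(_scores_2d(codes[None, :], params)[0])
    rng = np.random.default_rng(params.seed)
    shuffled = np.stack(
        [rng.permutation(codes) for _ in range(params.n_shuffles)]
    )
    null = _scores_2d(shuffled, params)
    p = (1 + int((null >= observed).sum())) / (1 + params.n_shuffles)
    mean_null = float(null.mean())
    rsf = observed / mean_null if mean_null > 0 else float("nan")
    return SimplicityVerdict(
        observed_score=observed,
        null_scores=tuple(float(x) for x in null),
        rsf=rsf,
        p_value=p,
        is_simple=p <= params.alpha,
    )
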