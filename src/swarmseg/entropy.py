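"""Kapur maximum-entropy thresholding over gray-level histograms.

The Kapur criterion partitions the gray levels at ``k`` thresholds and
scores a candidate by the sum of the Shannon entropies (in nats) of the
within-class intensity distributions; the maximizing threshold set is the
segmentation.  A single threshold ``t`` assigns levels ``[0..t]`` to the
lower class and ``[t+1..n_bins-1]`` to the upper class.

Conventions, fixed so results are bit-exact:

* a class with zero probability mass makes the candidate infeasible and
  scores ``-inf`` (this forbids degenerate "everything is background"
  optima);
* ``0 * ln 0 == 0``;
* ties are broken toward the lexicographically smallest threshold vector.

Two search routes are provided: :func:`exhaustive_threshold_search`, a
brute-force oracle, and :func:`pso_threshold_search`, which relaxes the
discrete problem to a continuous box and runs the shrinkage-factor PSO,
decoding positions by round-then-sort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from . import pso

__all__ = [
    "Histogram",
    "ThresholdSet",
    "DegenerateHistogramError",
    "compute_histogram",
    "kapur_objective",
    "exhaustive_threshold_search",
    "pso_threshold_search",
]

#: Guard on the brute-force oracle: refuse more than this many candidates.
MAX_EXHAUSTIVE_COMBINATIONS = 10**7


class DegenerateHistogramError(ValueError):
    """Histogram cannot support the requested number of thresholds.

    Raised when fewer than ``k + 1`` gray levels carry mass, so every
    candidate threshold set leaves some class empty (e.g. a constant image).
    """


@dataclass(frozen=True)
class Histogram:
    """Per-gray-level pixel counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D array with at least 2 bins")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.sum() <= 0:
            raise ValueError("histogram must contain at least one pixel")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing gray-level thresholds in ``[0, n_bins - 2]``."""

    thresholds: tuple[int, ...]

    def __post_init__(self) -> None:
        thresholds = tuple(int(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thresholds)
        if len(thresholds) < 1:
            raise ValueError("need at least one threshold")
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")
        if thresholds[0] < 0:
            raise ValueError(f"thresholds must be nonnegative, got {thresholds}")

    @property
    def k(self) -> int:
        return len(self.thresholds)

    def validate_for(self, hist: Histogram) -> None:
        if self.thresholds[-1] > hist.n_bins - 2:
            raise ValueError(
                f"threshold {self.thresholds[-1]} exceeds n_bins - 2 = {hist.n_bins - 2}"
            )


def compute_histogram(image: np.ndarray, n_bins: int = 256) -> Histogram:
    """Tabulate per-gray-level counts of a nonempty integer image."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    values = image.astype(np.int64, copy=False).ravel()
    lo, hi = int(values.min()), int(values.max())
    if lo < 0 or hi > n_bins - 1:
        bad = lo if lo < 0 else hi
        raise ValueError(f"pixel value {bad} outside [0, {n_bins - 1}]")
    return Histogram(np.bincount(values, minlength=n_bins))


def _entropy_tables(hist: Histogram) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative probability mass and cumulative  p*ln(p)  (0 ln 0 = 0)."""
    p = hist.counts / hist.total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return np.cumsum(p), np.cumsum(plogp)


def _score(cum_p: np.ndarray, cum_plogp: np.ndarray, thresholds: Sequence[int]) -> float:
    """Kapur score from precomputed cumulative tables; -inf if any class empty."""
    edges = [-1, *thresholds, cum_p.size - 1]
    score = 0.0
    for a, b in zip(edges, edges[1:]):
        omega = cum_p[b] - (cum_p[a] if a >= 0 else 0.0)
        if omega <= 0.0:
            return -math.inf
        s = cum_plogp[b] - (cum_plogp[a] if a >= 0 else 0.0)
        # -sum (p/w) ln (p/w)  ==  ln w - (sum p ln p)/w
        score += math.log(omega) - s / omega
    return score


def kapur_objective(hist: Histogram, thresholds: ThresholdSet | Sequence[int]) -> float:
    """Sum of within-class Shannon entropies (nats) at the given thresholds."""
    if not isinstance(thresholds, ThresholdSet):
        thresholds = ThresholdSet(tuple(thresholds))
    thresholds.validate_for(hist)
    cum_p, cum_plogp = _entropy_tables(hist)
    return _score(cum_p, cum_plogp, thresholds.thresholds)


def exhaustive_threshold_search(hist: Histogram, k: int = 1) -> tuple[ThresholdSet, float]:
    """Brute-force Kapur maximizer; the oracle for the PSO search.

    Enumerates all strictly increasing threshold vectors in lexicographic
    order and keeps the first maximizer, which realizes the
    lexicographically-smallest tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_candidates = hist.n_bins - 1
    if math.comb(n_candidates, k) > MAX_EXHAUSTIVE_COMBINATIONS:
        raise ValueError(
            f"C({n_candidates}, {k}) exceeds the exhaustive-search guard "
            f"of {MAX_EXHAUSTIVE_COMBINATIONS} combinations"
        )
    cum_p, cum_plogp = _entropy_tables(hist)
    best: tuple[int, ...] | None = None
    best_score = -math.inf
    for cand in combinations(range(n_candidates), k):
        score = _score(cum_p, cum_plogp, cand)
        if best is None or score > best_score:
            best, best_score = cand, score
    assert best is not None
    return ThresholdSet(best), best_score


def decode_position(position: np.ndarray) -> tuple[int, ...] | None:
    """Round-then-sort decoding of a continuous PSO position.

    Rounding is half-away-from-zero; duplicate thresholds after rounding
    decode to ``None`` (infeasible).
    """
    t = np.sort(np.floor(np.asarray(position, dtype=float) + 0.5).astype(int))
    if np.any(np.diff(t) == 0):
        return None
    return tuple(int(x) for x in t)


def pso_threshold_search(
    hist: Histogram,
    k: int = 1,
    config: pso.PSOConfig | None = None,
    on_step=None,
) -> tuple[ThresholdSet, float, pso.OptimizationResult]:
    """Kapur threshold search driven by the shrinkage-factor PSO.

    Particles move in the continuous box ``[0, n_bins - 2]^k``; positions
    decode by rounding to the nearest integer and sorting ascending, with
    duplicates scored ``-inf``.  Returns the decoded best threshold set,
    its Kapur score, and the optimizer trace.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if config is None:
        config = pso.PSOConfig()
    if int(np.count_nonzero(hist.counts)) < k + 1:
        raise DegenerateHistogramError(
            f"histogram has {int(np.count_nonzero(hist.counts))} occupied gray "
            f"levels; at least {k + 1} are needed for k={k} thresholds "
            "(every candidate leaves an empty class)"
        )
    cum_p, cum_plogp = _entropy_tables(hist)

    def objective(position: np.ndarray) -> float:
        decoded = decode_position(position)
        if decoded is None:
            return -math.inf
        return _score(cum_p, cum_plogp, decoded)

    bounds = pso.SearchBounds(np.zeros(k), np.full(k, hist.n_bins - 2, dtype=float))
    result = pso.optimize(objective, bounds, config, on_step=on_step)
    decoded = decode_position(result.best_position)
    if decoded is None:
        raise pso.EvaluationError(
            "optimizer best position decodes to duplicate thresholds; "
            "no feasible candidate was found"
        )
    thresholds = ThresholdSet(decoded)
    score = kapur_objective(hist, thresholds)
    return thresholds, score, result
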