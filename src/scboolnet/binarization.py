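"""Step-function binarization of expression vectors (BASC-style).

The expression values of one gene are sorted ascending into ``u1 <= ... <=
uN``.  For every discontinuity count j in {1, ..., N-2} the algorithm finds
the monotone step function with exactly j discontinuities minimizing the
total squared deviation from the sorted vector, with each level equal to
the mean of its interval (dynamic programming over breakpoint placements).
Each family member contributes the location of its strongest discontinuity
— the largest level jump, weighted by the inverse approximation error — and
the median of those locations fixes the binarization threshold t, placed at
the midpoint between the two sorted values flanking the median location.
A cell's bit is 1 iff its value is >= t.

Breakpoint convention: an integer d in {1, ..., N-1} denotes the
discontinuity between sorted ranks d and d+1 (1-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SortedVector",
    "StepFunction",
    "BinarizationResult",
    "DegenerateGeneError",
    "optimal_step_functions",
    "strongest_discontinuity",
    "compute_threshold",
    "binarize_matrix",
]

logger = logging.getLogger(__name__)

#: guards the jump/error score against division by zero on exact fits
SCORE_EPSILON = 1e-12


class DegenerateGeneError(ValueError):
    """Raised for constant vectors: no discontinuity exists to threshold on."""


@dataclass
class SortedVector:
    """Ascending expression values plus the permutation back to cell order."""

    values: np.ndarray
    original_order: np.ndarray  # original_order[k] = position of values[k] in the input

    @classmethod
    def from_raw(cls, raw) -> "SortedVector":
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 1:
            raise ValueError("expected a 1-D vector")
        if raw.size < 3:
            raise ValueError("need at least 3 values to estimate a threshold")
        order = np.argsort(raw, kind="stable")
        return cls(values=raw[order], original_order=order)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def unsort(self, sorted_bits: np.ndarray) -> np.ndarray:
        out = np.empty_like(sorted_bits)
        out[self.original_order] = sorted_bits
        return out


@dataclass
class StepFunction:
    """Monotone piecewise-constant fit: breakpoints, interval-mean levels, SSE."""

    breakpoints: tuple[int, ...]  # d in 1..N-1, strictly increasing
    levels: tuple[float, ...]
    error: float

    @property
    def n_discontinuities(self) -> int:
        return len(self.breakpoints)

    @property
    def n_steps(self) -> int:
        return len(self.breakpoints) + 1


@dataclass
class BinarizationResult:
    """Threshold, per-cell bits (original order) and family diagnostics."""

    threshold: float
    bits: np.ndarray
    strongest_discontinuities: list[tuple[int, float]]
    quality: float
    degenerate: bool = False


def _segment_cost_matrix(v: np.ndarray) -> np.ndarray:
    """cost[a, b] = SSE of v[a..b] around its mean (upper triangle)."""
    n = v.size
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])
    a = np.arange(n)[:, None]
    b = np.arange(n)[None, :]
    length = b - a + 1
    seg1 = s1[b + 1] - s1[a]
    seg2 = s2[b + 1] - s2[a]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = seg2 - seg1 * seg1 / np.maximum(length, 1)
    cost[length < 1] = np.inf
    return np.maximum(cost, 0.0)


def optimal_step_functions(v: SortedVector) -> list[StepFunction]:
    """Optimal monotone step functions for every discontinuity count N-2 .. 1.

    Each returned function minimizes total squared deviation among all
    placements of its breakpoint count; exact ties resolve to the
    lexicographically smallest breakpoint tuple.  Levels are interval means,
    hence non-decreasing on sorted input.
    """
    vals = v.values
    n = v.n
    if n < 3:
        raise ValueError("need at least 3 values")
    if vals[0] == vals[-1]:
        raise DegenerateGeneError("degenerate: no discontinuity (constant vector)")

    cost = _segment_cost_matrix(vals)
    max_segments = n - 1  # discontinuities up to N-2

    # Suffix DP: S[m, a] = min cost of splitting vals[a:] into m segments.
    # Forward reconstruction with first-occurrence argmin yields the
    # lexicographically smallest optimal breakpoint tuple.
    S = np.full((max_segments + 1, n + 1), np.inf)
    choice = np.zeros((max_segments + 1, n), dtype=int)
    S[1, :n] = cost[np.arange(n), n - 1]
    S[1, n] = np.inf
    for m in range(2, max_segments + 1):
        # candidate first-segment end b for start a: cost[a, b] + S[m-1, b+1]
        cand = cost + S[m - 1, 1:][None, :]  # cand[a, b]
        # restrict to b >= a handled by cost=inf below diagonal? cost is finite
        # below diagonal too (length<1 marked inf already)
        best_b = np.argmin(cand, axis=1)
        S[m, :n] = cand[np.arange(n), best_b]
        choice[m, :] = best_b

    family: list[StepFunction] = []
    for j in range(n - 2, 0, -1):  # discontinuities, descending step count
        m = j + 1
        bps: list[int] = []
        a = 0
        for seg in range(m, 1, -1):
            b = int(choice[seg, a]) if seg > 1 else n - 1
            bps.append(b + 1)  # 1-based rank before the discontinuity
            a = b + 1
        levels = []
        bounds = [0] + [d for d in bps] + [n]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            levels.append(float(vals[lo:hi].mean()))
        family.append(StepFunction(breakpoints=tuple(bps),
                                   levels=tuple(levels),
                                   error=float(S[m, 0])))
    return family


def strongest_discontinuity(f: StepFunction, v: SortedVector) -> tuple[int, float]:
    """Location and score of the strongest discontinuity of one step function.

    Score = level jump height / (approximation error + epsilon); ties go to
    the smallest location.  Adding a constant to all values changes neither
    jumps nor errors, so scores are shift-invariant.
    """
    if f.n_discontinuities < 1:
        raise ValueError("step function has no discontinuity")
    jumps = np.diff(f.levels)
    k = int(np.argmax(jumps))  # first occurrence = smallest location on ties
    score = float(jumps[k] / (f.error + SCORE_EPSILON))
    return f.breakpoints[k], score


def compute_threshold(raw, engine: str = "step") -> BinarizationResult:
    """Binarize one expression vector; bits returned in original cell order.

    The threshold location is the median (lower median on even counts) of
    the strongest-discontinuity locations across the step-function family;
    t is the midpoint of the two sorted values flanking that location.
    ``quality`` is the median absolute deviation of the locations divided by
    N-1 (0 = all family members agree on the cut).
    """
    if engine != "step":
        raise ValueError(f"unknown binarization engine {engine!r}")
    v = raw if isinstance(raw, SortedVector) else SortedVector.from_raw(raw)
    family = optimal_step_functions(v)
    strongest = [strongest_discontinuity(f, v) for f in family]
    locations = sorted(loc for loc, _ in strongest)
    med = locations[(len(locations) - 1) // 2]  # lower median
    t = float((v.values[med - 1] + v.values[med]) / 2.0)
    sorted_bits = (v.values >= t).astype(np.int8)
    mad = float(np.median(np.abs(np.asarray(locations) - med)))
    return BinarizationResult(
        threshold=t,
        bits=v.unsort(sorted_bits),
        strongest_discontinuities=strongest,
        quality=mad / (v.n - 1),
    )


def binarize_matrix(expr: pd.DataFrame, degenerate: str = "zero",
                    engine: str = "step") -> tuple[pd.DataFrame, dict[str, BinarizationResult]]:
    """Binarize every gene row independently; gene and cell order preserved.

    Constant rows carry no threshold information; they become all-0
    (``degenerate="zero"``, the default: a flat gene is called unexpressed)
    or are dropped (``degenerate="drop"``).
    """
    if degenerate not in ("zero", "drop"):
        raise ValueError(f"unknown degenerate policy {degenerate!r}")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    rows: dict[str, np.ndarray] = {}
    results: dict[str, BinarizationResult] = {}
    for gene, row in expr.iterrows():
        raw = row.to_numpy(dtype=float)
        try:
            res = compute_threshold(raw, engine=engine)
        except DegenerateGeneError:
            logger.warning("gene %s is constant: %s", gene,
                           "set to all-0" if degenerate == "zero" else "dropped")
            if degenerate == "drop":
                continue
            res = BinarizationResult(threshold=float("nan"),
                                     bits=np.zeros(raw.size, dtype=np.int8),
                                     strongest_discontinuities=[],
                                     quality=float("nan"), degenerate=True)
        rows[gene] = res.bits
        results[gene] = res
    bits = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns,
                                  dtype=np.int8)
    return bits, results


def thresholds_table(results: dict[str, BinarizationResult]) -> pd.DataFrame:
    """Per-gene threshold/quality/degenerate-flag table (for the thresholds CSV)."""
    return pd.DataFrame(
        {"gene": list(results),
         "threshold": [r.threshold for r in results.values()],
         "quality": [r.quality for r in results.values()],
         "degenerate": [r.degenerate for r in results.values()]}
    ).set_index("gene")
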