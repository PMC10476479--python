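"""Maximum-entropy (Kapur) segmentation criterion.

For a normalized gray-level histogram ``q`` over ``Z`` levels, the image
entropy is ``J = -sum_o q_o log(q_o)`` (with ``0 log 0 = 0``).  A threshold
vector ``u_1 < ... < u_m`` splits the gray range into ``m+1`` classes; class
``i`` spans ``[u_i, u_{i+1})`` with mass ``e_i = sum q_o`` over its levels and
within-class entropy

    ``J_i = -sum (q_o / e_i) log(q_o / e_i)``.

The Kapur objective is ``J(u) = sum_i J_i``, and the optimal threshold vector
maximizes it.  A vector inducing a zero-mass class is *infeasible* (returned
as ``None``) rather than scored: otherwise the criterion degenerately rewards
piling all mass into one class.

The log base (2, e or 10) rescales values by a constant, so the argmax is
base-invariant; base 2 (bits) is the default reporting unit.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .imaging import DomainError, GrayHistogram, ThresholdVector

__all__ = [
    "total_entropy",
    "class_entropy",
    "kapur_objective",
    "objective_landscape",
    "GuardExceededError",
    "KapurEvaluator",
    "resolve_base",
]

DEFAULT_ENUMERATION_GUARD = 2_000_000


class GuardExceededError(RuntimeError):
    """Exhaustive enumeration would exceed the configured evaluation budget."""


def resolve_base(base: float | str) -> float:
    """Normalize a log base given as 2, 10, e, or the strings "2"/"e"/"10"."""
    if isinstance(base, str):
        if base.strip().lower() == "e":
            return math.e
        try:
            base = float(base)
        except ValueError:
            raise DomainError(f"unsupported log base {base!r}") from None
    base = float(base)
    if base <= 0 or base == 1.0:
        raise DomainError(f"log base must be positive and != 1, got {base}")
    return base


def total_entropy(hist: GrayHistogram, base: float | str = 2) -> float:
    """Shannon entropy of the full histogram, in units of ``log base``."""
    b = resolve_base(base)
    q = hist.probs
    return float(-xlogy(q, q).sum() / math.log(b))


def class_entropy(
    hist: GrayHistogram, lo: int, hi: int, base: float | str = 2
) -> float | None:
    """Entropy of the normalized sub-histogram over levels ``[lo, hi)``.

    Returns ``None`` (infeasible) when the class carries zero mass.
    """
    if not (0 <= lo < hi <= hist.n_levels):
        raise DomainError(
            f"class range [{lo}, {hi}) invalid for Z={hist.n_levels}"
        )
    b = resolve_base(base)
    q = hist.probs[lo:hi]
    e = float(q.sum())
    if e <= 0.0:
        return None
    r = q / e
    return float(-xlogy(r, r).sum() / math.log(b))


def kapur_objective(
    hist: GrayHistogram, thresholds: ThresholdVector, base: float | str = 2
) -> float | None:
    """Total within-class entropy ``sum_i J_i`` for the classes induced by ``thresholds``.

    ``None`` when any induced class has zero mass.
    """
    if thresholds.n_levels != hist.n_levels:
        raise DomainError(
            f"thresholds are for Z={thresholds.n_levels}, histogram has Z={hist.n_levels}"
        )
    return _objective_from_cuts(hist.probs, thresholds.cuts, resolve_base(base))


def _objective_from_cuts(
    q: np.ndarray, cuts: Iterable[int], base: float
) -> float | None:
    """Direct (normalized-sum) evaluation; exact 0.0 for single-level classes."""
    ln_b = math.log(base)
    bounds = [0, *cuts, q.size]
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = q[lo:hi]
        e = float(seg.sum())
        if e <= 0.0:
            return None
        r = seg / e
        total += float(-xlogy(r, r).sum())
    return total / ln_b


class KapurEvaluator:
    """Vectorized prefix-sum evaluation of the Kapur objective.

    For batches of candidate cut vectors (as used by the population optimizer
    and the exhaustive oracle at large Z) each class entropy is computed as
    ``log(e) - (sum q log q over the class) / e`` from two cumulative arrays,
    giving O(m) work per candidate.  Mathematically identical to
    :func:`kapur_objective`; last-ulp rounding may differ, so final reported
    optima are re-evaluated with :func:`kapur_objective`.
    """

    def __init__(self, hist: GrayHistogram, base: float | str = 2):
        self.base = resolve_base(base)
        q = hist.probs
        self.n_levels = q.size
        self._S = np.concatenate(([0.0], np.cumsum(q)))
        self._C = np.concatenate(([0.0], np.cumsum(xlogy(q, q))))
        self._ln_b = math.log(self.base)

    def evaluate_batch(self, cuts_matrix: np.ndarray) -> np.ndarray:
        """Objective values for a ``(n, m)`` integer array of sorted cut vectors.

        Infeasible vectors (any zero-mass class) map to ``-inf``.
        """
        cuts_matrix = np.asarray(cuts_matrix)
        n, m = cuts_matrix.shape
        bounds = np.empty((n, m + 2), dtype=np.int64)
        bounds[:, 0] = 0
        bounds[:, 1:-1] = cuts_matrix
        bounds[:, -1] = self.n_levels
        e = self._S[bounds[:, 1:]] - self._S[bounds[:, :-1]]
        dc = self._C[bounds[:, 1:]] - self._C[bounds[:, :-1]]
        feasible = (e > 0.0).all(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_class = np.log(np.where(e > 0, e, 1.0)) - dc / np.where(e > 0, e, 1.0)
        values = per_class.sum(axis=1) / self._ln_b
        values[~feasible] = -np.inf
        return values


def _enumerate_cuts(n_levels: int, m: int) -> Iterable[tuple[int, ...]]:
    """All strictly increasing cut vectors in [1, Z-1], lexicographic order."""
    import itertools

    return itertools.combinations(range(1, n_levels), m)


def n_candidate_vectors(n_levels: int, m: int) -> int:
    return math.comb(n_levels - 1, m)


def objective_landscape(
    hist: GrayHistogram,
    m: int,
    base: float | str = 2,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> pd.DataFrame:
    """Exhaustive table of every candidate threshold vector and its objective.

    Columns ``u_1..u_m``, ``J`` (NaN for infeasible vectors) and ``feasible``.
    Raises :class:`GuardExceededError` when ``C(Z-1, m)`` exceeds ``guard``.
    """
    if m < 1:
        raise DomainError("m must be >= 1")
    z = hist.n_levels
    n_cand = n_candidate_vectors(z, m)
    if n_cand > guard:
        z_hint = max(2, int(math.ceil((guard * math.factorial(m)) ** (1.0 / m))))
        raise GuardExceededError(
            f"C({z - 1}, {m}) = {n_cand} candidate vectors exceed the guard of {guard}; "
            f"reduce the gray resolution (Z around {z_hint} or below) or m"
        )
    b = resolve_base(base)
    rows = []
    for cuts in _enumerate_cuts(z, m):
        j = _objective_from_cuts(hist.probs, cuts, b)
        rows.append((*cuts, math.nan if j is None else j, j is not None))
    cols = [f"u_{i + 1}" for i in range(m)] + ["J", "feasible"]
    return pd.DataFrame(rows, columns=cols)
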