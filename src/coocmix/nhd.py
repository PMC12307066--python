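"""Fisher's non-central hypergeometric distribution (NHD) for species pairs.

The number of sites of co-occurrence ``n_AB`` for a species pair (A, B),
conditional on each species' occupancy (``n_A``, ``n_B``) and the total
number of sites (``n_A + n_notA``), follows the NHD

    f(n | theta) = C(n_A, n) * C(n_notA, n_B - n) * exp(n * theta) / P0(theta)

over the finite support ``max(0, n_B - n_notA) <= n <= min(n_A, n_B)``.
``theta = log(psi)`` is the log odds ratio quantifying how the presence of
one species changes the odds of occurrence of the other: ``theta > 0`` is
spatial aggregation, ``theta < 0`` segregation, ``theta = 0`` independence
(the centred hypergeometric).

All probability arithmetic is carried out in log space using log-gamma
binomial coefficients and log-sum-exp; the support is finite, so the
normalizer is exact rather than truncated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "PairCounts",
    "Boundary",
    "ThetaEstimate",
    "support",
    "log_normalizer",
    "logpmf",
    "pmf_vector",
    "mode",
    "mean",
    "sample",
    "theta_mle",
    "theta_from_conditional_probs",
]

THETA_BRACKET = 50.0
MLE_TOL = 1e-8


@dataclass(frozen=True)
class PairCounts:
    """2x2 occupancy contingency for one species pair.

    ``n_a`` / ``n_nota`` are the numbers of sites with species A present /
    absent, ``n_b`` the occupancy of species B and ``n_ab`` the observed
    number of co-occurrences (optional; required only for estimation).
    """

    n_a: int
    n_nota: int
    n_b: int
    n_ab: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_a", "n_nota", "n_b"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_b > self.n_a + self.n_nota:
            raise ValueError(
                f"n_b={self.n_b} exceeds total sites {self.n_a + self.n_nota}"
            )
        if self.n_ab is not None:
            lo, hi = support(self)
            if not (isinstance(self.n_ab, (int, np.integer)) and lo <= self.n_ab <= hi):
                raise ValueError(
                    f"n_ab={self.n_ab} outside support [{lo}, {hi}] for {self}"
                )

    @property
    def total_sites(self) -> int:
        return self.n_a + self.n_nota

    def swapped(self) -> "PairCounts":
        """The same pair with the A/B labels exchanged."""
        return PairCounts(self.n_b, self.total_sites - self.n_b, self.n_a, self.n_ab)


class Boundary(enum.Enum):
    FINITE = "finite"
    NEG_INFINITE = "neg_infinite"
    POS_INFINITE = "pos_infinite"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class ThetaEstimate:
    """Single-pair conditional MLE of the log odds ratio.

    ``theta`` is NaN whenever ``boundary`` is not FINITE: boundary estimates
    are carried as flags, never as floating infinities that could leak into
    downstream arithmetic.
    """

    theta: float
    boundary: Boundary
    loglik_at_max: float

    @property
    def is_finite(self) -> bool:
        return self.boundary is Boundary.FINITE


def support(counts: PairCounts) -> tuple[int, int]:
    """Support bounds of the co-occurrence count: (max(0, n_B - n_notA), min(n_A, n_B))."""
    lo = max(0, counts.n_b - counts.n_nota)
    hi = min(counts.n_a, counts.n_b)
    return lo, hi


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return theta


def _log_terms(counts: PairCounts) -> tuple[np.ndarray, np.ndarray]:
    """Support values n and log[C(n_A, n) C(n_notA, n_B - n)] for each."""
    lo, hi = support(counts)
    n = np.arange(lo, hi + 1)
    logc = (
        gammaln(counts.n_a + 1)
        - gammaln(n + 1)
        - gammaln(counts.n_a - n + 1)
        + gammaln(counts.n_nota + 1)
        - gammaln(counts.n_b - n + 1)
        - gammaln(counts.n_nota - counts.n_b + n + 1)
    )
    return n, logc


def log_normalizer(counts: PairCounts, theta: float) -> float:
    """log P0(theta), the exact log-sum-exp over the finite support."""
    theta = _check_theta(theta)
    n, logc = _log_terms(counts)
    return float(logsumexp(logc + n * theta))


def logpmf(n: int, counts: PairCounts, theta: float) -> float:
    """Log NHD pmf at ``n``; -inf (not an exception) outside the support."""
    theta = _check_theta(theta)
    lo, hi = support(counts)
    if not (lo <= n <= hi):
        return -math.inf
    logc = (
        gammaln(counts.n_a + 1)
        - gammaln(n + 1)
        - gammaln(counts.n_a - n + 1)
        + gammaln(counts.n_nota + 1)
        - gammaln(counts.n_b - n + 1)
        - gammaln(counts.n_nota - counts.n_b + n + 1)
    )
    return float(logc + n * theta - log_normalizer(counts, theta))


def pmf_vector(counts: PairCounts, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """(support values, probabilities) — exponentials normalized over the support."""
    theta = _check_theta(theta)
    n, logc = _log_terms(counts)
    w = logc + n * theta
    w -= logsumexp(w)
    return n, np.exp(w)


def mode(counts: PairCounts, theta: float) -> int:
    """Argmax of the pmf over the support; ties broken toward the smaller n.

    Exact ties occur at theta values where adjacent pmf ratios equal 1;
    log-gamma rounding can perturb them by an ulp, so any value within 1e-9
    (log scale) of the maximum counts as tied.
    """
    n, logc = _log_terms(counts)
    w = logc + n * float(_check_theta(theta))
    return int(n[np.flatnonzero(w >= w.max() - 1e-9)[0]])


def mean(counts: PairCounts, theta: float) -> float:
    """E[n_AB | theta]; strictly increasing in theta when the support has >1 point."""
    n, p = pmf_vector(counts, theta)
    return float(np.dot(n, p))


def sample(counts: PairCounts, theta: float, rng: np.random.Generator, size=None):
    """Exact draws by inverse CDF over the finite support."""
    n, p = pmf_vector(counts, theta)
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    u = rng.random(size)
    idx = np.searchsorted(cdf, u, side="right")
    out = n[np.minimum(idx, len(n) - 1)]
    return int(out) if size is None else out


def theta_mle(counts: PairCounts) -> ThetaEstimate:
    """Conditional MLE of theta for one observed table.

    Solves the score equation E[n_AB | theta] = n_AB by bracketed
    root-finding (the conditional mean is monotone in theta). Tables whose
    observed count sits on a support bound have no finite maximizer and are
    flagged NEG_INFINITE / POS_INFINITE; single-point supports carry no
    information about theta and are flagged UNDEFINED.
    """
    if counts.n_ab is None:
        raise ValueError("theta_mle requires observed n_ab")
    lo, hi = support(counts)
    if lo == hi:
        return ThetaEstimate(math.nan, Boundary.UNDEFINED, 0.0)
    if counts.n_ab == lo:
        return ThetaEstimate(math.nan, Boundary.NEG_INFINITE, 0.0)
    if counts.n_ab == hi:
        return ThetaEstimate(math.nan, Boundary.POS_INFINITE, 0.0)

    target = counts.n_ab

    def f(theta: float) -> float:
        return mean(counts, theta) - target

    theta_hat = brentq(f, -THETA_BRACKET, THETA_BRACKET, xtol=MLE_TOL)
    return ThetaEstimate(
        float(theta_hat), Boundary.FINITE, logpmf(counts.n_ab, counts, theta_hat)
    )


def theta_from_conditional_probs(p_b_given_a: float, p_b_given_nota: float) -> float:
    """theta = log odds ratio from the two conditional occupancy probabilities."""
    for name, p in (("p_b_given_a", p_b_given_a), ("p_b_given_nota", p_b_given_nota)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}={p} implies infinite odds; must lie in (0, 1)")
    return math.log(p_b_given_a * (1.0 - p_b_given_nota)) - math.log(
        (1.0 - p_b_given_a) * p_b_given_nota
    )


# ---------------------------------------------------------------------------
# Vectorised support tables used by the hierarchical model. Pairs are packed
# into a ragged (n_pairs, max_support) array padded with -inf log-coefficients
# so a whole assemblage's log-likelihood is one numpy pass.
# ---------------------------------------------------------------------------


class SupportTable:
    """Precomputed log binomial-coefficient table for a batch of pairs."""

    __slots__ = (
        "lo", "hi", "y", "logc", "nvals", "size", "n_pairs",
        "starts", "seg", "flat_n", "flat_logc", "_ylogc",
    )

    def __init__(self, n_a, n_nota, n_b, n_ab=None):
        n_a = np.asarray(n_a, dtype=np.int64)
        n_nota = np.asarray(n_nota, dtype=np.int64)
        n_b = np.asarray(n_b, dtype=np.int64)
        lo = np.maximum(0, n_b - n_nota)
        hi = np.minimum(n_a, n_b)
        if n_ab is not None:
            n_ab = np.asarray(n_ab, dtype=np.int64)
            if np.any(n_ab < lo) or np.any(n_ab > hi):
                raise ValueError("observed n_ab outside the NHD support for some pair")
        self.n_pairs = len(n_a)
        self.lo = lo
        self.hi = hi
        self.size = hi - lo + 1
        self.y = n_ab
        k = int(self.size.max())
        offs = np.arange(k)
        nvals = lo[:, None] + offs[None, :]
        valid = offs[None, :] < self.size[:, None]
        nv = np.where(valid, nvals, 0)
        logc = (
            gammaln(n_a + 1)[:, None]
            - gammaln(nv + 1)
            - gammaln(n_a[:, None] - nv + 1)
            + gammaln(n_nota + 1)[:, None]
            - gammaln(n_b[:, None] - nv + 1)
            - gammaln(n_nota[:, None] - n_b[:, None] + nv + 1)
        )
        self.logc = np.where(valid, logc, -np.inf)
        self.nvals = np.where(valid, nvals, 0)
        # flat segmented layout for the hot log-likelihood path: one entry
        # per (pair, support point), avoiding the padding waste of the
        # rectangular table when most supports are tiny
        self.starts = np.concatenate([[0], np.cumsum(self.size)[:-1]])
        seg = np.repeat(np.arange(self.n_pairs), self.size)
        self.seg = seg
        self.flat_n = (nvals[valid]).astype(np.float64)
        self.flat_logc = logc[valid]
        # log coefficient at the observed count, cached
        self._ylogc = None

    def probs(self, theta: np.ndarray) -> np.ndarray:
        """Row-normalized pmf over the padded support at per-pair theta."""
        a = self.logc + self.nvals * np.asarray(theta, float)[:, None]
        m = a.max(axis=1, keepdims=True)
        w = np.exp(a - m)
        return w / w.sum(axis=1, keepdims=True)

    def sample(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One exact inverse-CDF draw of the co-occurrence count per pair."""
        cdf = np.cumsum(self.probs(theta), axis=1)
        u = rng.random(self.n_pairs)
        idx = (u[:, None] > cdf).sum(axis=1)
        return self.lo + np.minimum(idx, self.size - 1)

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        """Pointwise log pmf of each pair's observed count at its theta."""
        if self.y is None:
            raise ValueError("no observed counts attached to this table")
        a = self.flat_logc + self.flat_n * theta[self.seg]
        m = np.maximum.reduceat(a, self.starts)
        np.subtract(a, m[self.seg], out=a)
        np.exp(a, out=a)
        log_p0 = m + np.log(np.add.reduceat(a, self.starts))
        if self._ylogc is None:
            idx = self.y - self.lo
            self._ylogc = self.logc[np.arange(self.n_pairs), idx]
        return self._ylogc + self.y * theta - log_p0
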