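"""Pairwise association measures for feature matrices.

Two families of measures are provided for building weighted association
networks from an ``n x p`` matrix of continuous measurements:

* correlation — Pearson's and Spearman's coefficients;
* mutual information (MI) — computed on discretized data through
  ``MI(X, Y) = H(X) + H(Y) - H(X, Y)`` with a choice of four entropy
  estimators (plug-in/empirical, Miller–Madow, James–Stein shrinkage,
  Schurmann–Grassberger).

All entropies and MI values are in nats. Continuous variables are binned
before MI estimation, by default into ``ceil(n**(1/3))`` equal-frequency
bins; the same binning is shared by marginal and joint tabulations so that
``MI(x, x) = H(x)`` holds exactly for the empirical estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import rankdata

__all__ = [
    "ESTIMATORS",
    "MEASURES",
    "AssociationError",
    "DiscretizedVariable",
    "EntropyEstimate",
    "AssociationMatrix",
    "pearson",
    "spearman",
    "discretize",
    "default_n_bins",
    "entropy",
    "mutual_information",
    "mi_from_joint_counts",
    "association_matrix",
]

ESTIMATORS = ("empirical", "miller_madow", "shrinkage", "schurmann_grassberger")
MEASURES = ("pearson", "spearman", "mi")


class AssociationError(ValueError):
    """Invalid input to an association computation."""


# ---------------------------------------------------------------------------
# correlation measures
# ---------------------------------------------------------------------------

def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise AssociationError(f"{name} is empty")
    return a


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson's sample correlation coefficient, cov(X, Y) / (S_X S_Y).

    Raises :class:`AssociationError` on length mismatch or zero-variance
    input, for which the coefficient is undefined.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise AssociationError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise AssociationError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise AssociationError("correlation undefined for zero-variance input")
    return float(np.corrcoef(xa, ya)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: Pearson applied to average ranks."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise AssociationError(f"length mismatch: {xa.size} vs {ya.size}")
    return pearson(rankdata(xa), rankdata(ya))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizedVariable:
    """Binned version of a continuous variable.

    ``labels`` are 1-based bin indices of length n; ``n_bins`` is the number
    of requested bins (occupied bins may be fewer, e.g. for ties or constant
    input).
    """

    labels: np.ndarray
    n_bins: int
    scheme: str

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def counts(self) -> np.ndarray:
        """Occupancy of each bin 1..n_bins."""
        return np.bincount(self.labels - 1, minlength=self.n_bins)

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


def default_n_bins(n: int) -> int:
    """Default bin count ceil(n**(1/3)) (cube-root rule)."""
    return int(np.ceil(n ** (1.0 / 3.0) - 1e-9))


def discretize(
    x: Sequence[float],
    n_bins: Optional[int] = None,
    scheme: str = "equal_frequency",
) -> DiscretizedVariable:
    """Bin a continuous variable into ``n_bins`` categories.

    ``equal_frequency`` places bin edges at empirical quantiles so occupancies
    differ by at most one when values are distinct; tied values always share a
    bin. ``equal_width`` uses equally spaced edges between min and max.
    Constant input collapses to a single occupied bin.
    """
    xa = _as_1d(x, "x")
    n = xa.size
    if n < 2:
        raise AssociationError("need at least 2 observations to discretize")
    if n_bins is None:
        n_bins = default_n_bins(n)
    n_bins = int(n_bins)
    if n_bins < 1:
        raise AssociationError("n_bins must be positive")
    if n_bins > n:
        raise AssociationError(f"n_bins={n_bins} exceeds sample size {n}")
    if scheme not in ("equal_frequency", "equal_width"):
        raise AssociationError(f"unknown binning scheme {scheme!r}")

    if np.ptp(xa) == 0 or n_bins == 1:
        labels = np.ones(n, dtype=np.int64)
    elif scheme == "equal_frequency":
        edges = np.quantile(xa, np.arange(1, n_bins) / n_bins)
        labels = np.searchsorted(edges, xa, side="left") + 1
    else:
        edges = np.linspace(xa.min(), xa.max(), n_bins + 1)[1:-1]
        labels = np.searchsorted(edges, xa, side="right") + 1
    return DiscretizedVariable(labels=labels, n_bins=n_bins, scheme=scheme)


# ---------------------------------------------------------------------------
# entropy estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntropyEstimate:
    """An entropy value in nats together with estimator metadata."""

    value: float
    estimator: str
    n: int
    n_bins: int
    lambda_star: Optional[float] = None
    prior_N: Optional[float] = None


def _entropy_rows(
    counts: np.ndarray,
    estimator: str,
    prior_N: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized entropy of each row of a count table.

    ``counts`` is an (m, B) nonnegative array; returns ``(values, extra)``
    where ``extra`` holds the shrinkage intensity lambda* per row (NaN for the
    other estimators). Every estimator treats the set of occupied (nonzero)
    bins as the support.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim == 1:
        c = c[None, :]
    if np.any(c < 0):
        raise AssociationError("counts must be nonnegative")
    n = c.sum(axis=1)
    if np.any(n <= 0):
        raise AssociationError("all-zero count table")
    occ = c > 0
    k = occ.sum(axis=1).astype(float)  # |x|, occupied bins
    p = c / n[:, None]
    extra = np.full(c.shape[0], np.nan)

    def plugin(prob: np.ndarray) -> np.ndarray:
        safe = np.where(occ, prob, 1.0)
        return -(np.where(occ, prob * np.log(safe), 0.0)).sum(axis=1)

    if estimator == "empirical":
        h = plugin(p)
    elif estimator == "miller_madow":
        h = plugin(p) + (k - 1.0) / (2.0 * n)
    elif estimator == "shrinkage":
        # James-Stein intensity toward the uniform target 1/|x|
        target = np.where(occ, 1.0 / k[:, None], 0.0)
        num = 1.0 - (p ** 2).sum(axis=1)
        den = (n - 1.0) * (np.where(occ, target - p, 0.0) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(den > 0, num / den, 1.0)
        lam = np.clip(lam, 0.0, 1.0)
        p_shrunk = lam[:, None] * target + (1.0 - lam[:, None]) * p
        h = plugin(p_shrunk)
        extra = lam
    elif estimator == "schurmann_grassberger":
        # Dirichlet prior weight N, default 1/|x|
        N = np.full(c.shape[0], prior_N, dtype=float) if prior_N is not None \
            else 1.0 / k
        tot = n + k * N
        outer = digamma(tot + 1.0)[:, None]
        inner = digamma(np.where(occ, c, 0.0) + N[:, None] + 1.0)
        h = (np.where(occ, (c + N[:, None]) * (outer - inner), 0.0)).sum(axis=1) / tot
    else:
        raise AssociationError(f"unknown entropy estimator {estimator!r}")
    return h, extra


def entropy(
    counts: Sequence[int],
    estimator: str = "empirical",
    prior_N: Optional[float] = None,
) -> EntropyEstimate:
    """Entropy (nats) of an occupancy table under the chosen estimator.

    ``counts`` may be any array of nonnegative integers (a joint table is
    flattened). ``prior_N`` is only meaningful for the Schurmann–Grassberger
    estimator and defaults to 1/|x| with |x| the number of occupied bins.
    """
    c = np.asarray(counts, dtype=float).ravel()
    h, extra = _entropy_rows(c, estimator, prior_N=prior_N)
    k = int(np.count_nonzero(c))
    return EntropyEstimate(
        value=float(h[0]),
        estimator=estimator,
        n=int(c.sum()),
        n_bins=k,
        lambda_star=float(extra[0]) if estimator == "shrinkage" else None,
        prior_N=(float(prior_N) if prior_N is not None
                 else (1.0 / k if estimator == "schurmann_grassberger" else None)),
    )


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def mi_from_joint_counts(
    joint: np.ndarray,
    estimator: str = "empirical",
    prior_N: Optional[float] = None,
) -> float:
    """MI (nats) from a pre-binned joint count table via H(X)+H(Y)-H(X,Y)."""
    j = np.asarray(joint, dtype=float)
    if j.ndim != 2:
        raise AssociationError("joint counts must be a 2-D table")
    hx = entropy(j.sum(axis=1), estimator, prior_N).value
    hy = entropy(j.sum(axis=0), estimator, prior_N).value
    hxy = entropy(j, estimator, prior_N).value
    return hx + hy - hxy


def mutual_information(
    x: Sequence[float],
    y: Sequence[float],
    estimator: str = "empirical",
    n_bins: Optional[int] = None,
    scheme: str = "equal_frequency",
    prior_N: Optional[float] = None,
) -> float:
    """MI (nats) between two continuous variables after shared discretization."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise AssociationError(f"length mismatch: {xa.size} vs {ya.size}")
    dx = discretize(xa, n_bins=n_bins, scheme=scheme)
    dy = discretize(ya, n_bins=n_bins, scheme=scheme)
    b = max(dx.n_bins, dy.n_bins)
    joint = np.zeros((b, b))
    np.add.at(joint, (dx.labels - 1, dy.labels - 1), 1.0)
    return mi_from_joint_counts(joint, estimator, prior_N)


# ---------------------------------------------------------------------------
# matrix-level kernels (shared with the permutation test)
# ---------------------------------------------------------------------------

def _label_matrix(X: np.ndarray, n_bins: Optional[int], scheme: str) -> tuple[np.ndarray, int]:
    """Column-wise discretization; returns (0-based label matrix, bin count)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    b = int(n_bins) if n_bins is not None else default_n_bins(n)
    L = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        L[:, j] = discretize(X[:, j], n_bins=b, scheme=scheme).labels - 1
    return L, b


def _mi_matrix_from_labels(
    L: np.ndarray,
    b: int,
    estimator: str,
    prior_N: Optional[float] = None,
) -> np.ndarray:
    """All-pairs MI from a 0-based label matrix, vectorized over pairs.

    The diagonal is set to zero: self-information is never used by the
    connectivity statistic downstream.
    """
    n, p = L.shape
    marg = np.zeros((p, b))
    np.add.at(marg, (np.arange(p)[None, :].repeat(n, 0), L), 1.0)
    hm, _ = _entropy_rows(marg, estimator, prior_N)

    iu, ju = np.triu_indices(p, 1)
    codes = L[:, iu] * b + L[:, ju]                      # (n, m)
    m = iu.size
    offsets = np.arange(m, dtype=np.int64) * (b * b)
    flat = np.bincount((codes + offsets[None, :]).ravel(), minlength=m * b * b)
    joint = flat.reshape(m, b * b)
    hj, _ = _entropy_rows(joint, estimator, prior_N)

    mi = hm[iu] + hm[ju] - hj
    A = np.zeros((p, p))
    A[iu, ju] = mi
    A[ju, iu] = mi
    return A


def _corr_matrix(X: np.ndarray, method: str) -> np.ndarray:
    """Correlation matrix with constant columns mapped to zero weight."""
    X = np.asarray(X, dtype=float)
    if method == "spearman":
        X = rankdata(X, axis=0)
    const = np.ptp(X, axis=0) == 0
    A = np.eye(X.shape[1])
    keep = ~const
    if keep.sum() >= 2:
        sub = np.corrcoef(X[:, keep], rowvar=False)
        A[np.ix_(keep, keep)] = sub
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) assigned zero association weight",
            stacklevel=3,
        )
        A[const, :] = 0.0
        A[:, const] = 0.0
        A[np.diag_indices_from(A)] = 1.0
    return A


# ---------------------------------------------------------------------------
# association matrix
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """Symmetric p x p weighted adjacency with measure metadata."""

    weights: np.ndarray
    measure: str
    feature_names: tuple[str, ...]
    estimator: Optional[str] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise AssociationError("weights must be a square matrix")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise AssociationError("weights must be symmetric")
        self.feature_names = tuple(self.feature_names)
        if len(self.feature_names) != self.weights.shape[0]:
            raise AssociationError("feature_names length must match matrix size")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.feature_names,
                            columns=self.feature_names)


def _coerce_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    a = np.asarray(X, dtype=float)
    if a.ndim != 2:
        raise AssociationError("feature matrix must be 2-D (samples x features)")
    return a, tuple(f"V{i + 1}" for i in range(a.shape[1]))


def association_matrix(
    X,
    measure: str = "pearson",
    estimator: Optional[str] = None,
    n_bins: Optional[int] = None,
    scheme: str = "equal_frequency",
    prior_N: Optional[float] = None,
) -> AssociationMatrix:
    """Weighted adjacency matrix of all pairwise associations in ``X``.

    ``X`` is samples x features (ndarray or DataFrame). For ``measure="mi"``
    the ``estimator`` chooses the entropy estimator (default empirical).
    Constant features receive zero weight against all partners, with a
    warning, rather than aborting.
    """
    A, names = _coerce_matrix(X)
    n, p = A.shape
    if p < 2:
        raise AssociationError("need at least 2 features")
    if n < 3:
        raise AssociationError("need at least 3 samples")
    if measure not in MEASURES:
        raise AssociationError(f"unknown measure {measure!r}")

    if measure in ("pearson", "spearman"):
        W = _corr_matrix(A, measure)
        est = None
    else:
        est = estimator or "empirical"
        if est not in ESTIMATORS:
            raise AssociationError(f"unknown entropy estimator {est!r}")
        const = np.ptp(A, axis=0) == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant feature(s) assigned zero association weight",
                stacklevel=2,
            )
        L, b = _label_matrix(A, n_bins, scheme)
        W = _mi_matrix_from_labels(L, b, est, prior_N)
        # a constant column occupies one bin: MI against anything is already 0
    return AssociationMatrix(weights=W, measure=measure, feature_names=names,
                             estimator=est)
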