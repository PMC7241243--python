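"""Structured random correlation matrices and Gaussian sampling.

Three families of p x p correlation structures are provided for simulating
multivariate normal feature data with known dependence:

* Toeplitz / AR(1): entry (i, j) equals rho**|i-j|, correlation decaying
  exponentially with index distance;
* hub: within each block one node (the hub) is correlated with every other
  member with polynomially attenuating strength, blocks mutually
  independent;
* average ("vine"): a fully random correlation matrix built from partial
  correlations sampled from a Beta distribution via the recursive C-vine
  construction, calibrated so the mean absolute off-diagonal correlation
  hits a target value.

Matrices can be roughened with the Hardin et al. unit-vector perturbation
(small eps-scaled inner products of random unit vectors added off-diagonal),
which keeps the diagonal at one and, for eps below the smallest eigenvalue,
preserves positive definiteness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import toeplitz as _sp_toeplitz

from .association import AssociationError

__all__ = [
    "CorrelationModel",
    "CalibrationError",
    "toeplitz_matrix",
    "perturb_hardin",
    "hub_matrix",
    "hub_correlation",
    "beta_shape_from_moments",
    "vine_matrix",
    "average_abs_correlation",
    "calibrate_mu",
    "sample_gaussian",
]

_PD_TOL = 1e-10


class CalibrationError(RuntimeError):
    """The scalar calibration could not bracket its target."""


@dataclass
class CorrelationModel:
    """A structured correlation matrix plus the parameters that built it."""

    kind: str
    rho: float
    p: int
    matrix: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12):
            raise AssociationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise AssociationError("correlation matrix must have unit diagonal")
        if self.min_eigenvalue <= _PD_TOL:
            raise AssociationError("correlation matrix is not positive definite")


def _ensure_pd(matrix: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clip and re-normalise to a valid correlation matrix.

    Fallback only; emits a warning whenever it actually changes the input.
    """
    w, v = np.linalg.eigh(matrix)
    if w[0] > _PD_TOL:
        return matrix
    warnings.warn("clipping eigenvalues to restore positive definiteness",
                  stacklevel=3)
    w = np.clip(w, clip, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2.0


def toeplitz_matrix(p: int, rho: float) -> CorrelationModel:
    """AR(1) correlation matrix with entries rho**|i-j|."""
    if p < 2:
        raise AssociationError("p must be >= 2")
    if not 0.0 <= rho < 1.0:
        raise AssociationError("rho must be in [0, 1) (singular at 1)")
    first = rho ** np.arange(p)
    return CorrelationModel(kind="toeplitz", rho=float(rho), p=p,
                            matrix=_sp_toeplitz(first))


def perturb_hardin(
    model: CorrelationModel,
    eps_noise: float = 0.01,
    edim: int = 2,
    rng: Optional[np.random.Generator] = None,
) -> CorrelationModel:
    """Add the Hardin unit-vector noise R + eps * (U U^T - I) off-diagonal.

    Rows of U are independent uniform unit vectors in ``edim`` dimensions, so
    each off-diagonal shift is an eps-scaled inner product bounded by eps in
    magnitude; the diagonal stays exactly one. Requires
    ``eps_noise < lambda_min(R)`` so the result remains positive definite.
    """
    if eps_noise < 0:
        raise AssociationError("eps_noise must be nonnegative")
    if eps_noise == 0:
        return model
    lam = model.min_eigenvalue
    if eps_noise >= lam:
        raise AssociationError(
            f"eps_noise={eps_noise} must be below the smallest eigenvalue {lam:.4g}"
        )
    rng = rng or np.random.default_rng()
    u = rng.standard_normal((model.p, edim))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    m = model.matrix + eps_noise * (u @ u.T - np.eye(model.p))
    m = _ensure_pd(m)
    params = dict(model.params, eps_noise=eps_noise, edim=edim)
    return CorrelationModel(kind=model.kind, rho=model.rho, p=model.p,
                            matrix=m, params=params)


def hub_correlation(i: int, g: int, rho: float, rho_min: float = 0.0,
                    gamma: float = 2.0) -> float:
    """Hub-to-member correlation of member ``i`` (2..g) in a block of size g:
    ``rho - ((i-2)/(g-2))**gamma * (rho - rho_min)``, hitting exactly ``rho``
    at i=2 and ``rho_min`` at i=g."""
    if g < 3:
        raise AssociationError("hub group needs at least 3 members")
    if not 2 <= i <= g:
        raise AssociationError("member index must be in 2..g")
    return rho - ((i - 2) / (g - 2)) ** gamma * (rho - rho_min)


def hub_matrix(
    group_sizes: Sequence[int] = (15, 5),
    rho: float = 0.7,
    rho_min: float = 0.0,
    gamma: float = 2.0,
) -> CorrelationModel:
    """Block-diagonal hub structure.

    Within a block of size g, member i = 2..g correlates with the hub (the
    first member) as ``rho - ((i-2)/(g-2))**gamma * (rho - rho_min)``, so the
    first member after the hub gets exactly ``rho`` and the last exactly
    ``rho_min``. Non-hub pairs and cross-block pairs are uncorrelated.
    """
    if not 0.0 <= rho <= 1.0:
        raise AssociationError("rho must be in [0, 1]")
    if rho_min > rho:
        raise AssociationError("rho_min must not exceed rho")
    if gamma <= 0:
        raise AssociationError("gamma must be positive")
    sizes = [int(g) for g in group_sizes]
    if any(g < 3 for g in sizes):
        raise AssociationError("each hub group needs at least 3 members")
    p = sum(sizes)
    m = np.eye(p)
    start = 0
    for g in sizes:
        for i in range(2, g + 1):  # member index within the block, 1-based
            r = hub_correlation(i, g, rho, rho_min, gamma)
            m[start, start + i - 1] = m[start + i - 1, start] = r
        start += g  # blocks independent: nothing to fill across blocks
    m = _ensure_pd(m)
    return CorrelationModel(kind="hub", rho=float(rho), p=p, matrix=m,
                            params={"group_sizes": tuple(sizes),
                                    "rho_min": rho_min, "gamma": gamma})


def beta_shape_from_moments(mu: float, sigma2: float) -> tuple[float, float]:
    """Invert the Beta mean/variance to shape parameters (alpha, beta)."""
    if not 0.0 < mu < 1.0:
        raise AssociationError("mu must be in (0, 1)")
    if not 0.0 < sigma2 < mu * (1.0 - mu):
        raise AssociationError(
            f"sigma2 must be in (0, mu(1-mu)) = (0, {mu * (1 - mu):.4g})"
        )
    alpha = mu * (mu * (1.0 - mu) / sigma2 - 1.0)
    beta = alpha * (1.0 / mu - 1.0)
    return float(alpha), float(beta)


def vine_matrix(
    p: int,
    alpha: float,
    beta: float,
    rng: Optional[np.random.Generator] = None,
    support: tuple[float, float] = (-1.0, 1.0),
) -> CorrelationModel:
    """Random correlation matrix from Beta-distributed partial correlations.

    Partial correlations are drawn i.i.d. from Beta(alpha, beta) affinely
    mapped onto ``support`` and converted to a full correlation matrix with
    the recursive C-vine construction, which is positive definite by
    construction for partials strictly inside (-1, 1).
    """
    if p < 2:
        raise AssociationError("p must be >= 2")
    if alpha <= 0 or beta <= 0:
        raise AssociationError("Beta shapes must be positive")
    lo, hi = support
    if not (-1.0 <= lo < hi <= 1.0):
        raise AssociationError("support must be within [-1, 1]")
    rng = rng or np.random.default_rng()
    # keep partials strictly inside (-1, 1) for numerical stability
    draw = lambda: float(np.clip(lo + (hi - lo) * rng.beta(alpha, beta),
                                 -1.0 + 1e-12, 1.0 - 1e-12))
    P = np.zeros((p, p))
    R = np.eye(p)
    for k in range(p - 1):
        for i in range(k + 1, p):
            P[k, i] = draw()
            r = P[k, i]
            for l in range(k - 1, -1, -1):
                r = r * np.sqrt((1.0 - P[l, i] ** 2) * (1.0 - P[l, k] ** 2)) \
                    + P[l, i] * P[l, k]
            R[k, i] = R[i, k] = r
    return CorrelationModel(kind="average", rho=float("nan"), p=p, matrix=R,
                            params={"alpha": alpha, "beta": beta,
                                    "support": support})


def average_abs_correlation(model) -> float:
    """Mean absolute off-diagonal correlation 2/(p^2-p) * sum_{i>j} |rho_ij|."""
    m = model.matrix if isinstance(model, CorrelationModel) else np.asarray(model)
    p = m.shape[0]
    if p < 2:
        raise AssociationError("p must be >= 2")
    iu = np.triu_indices(p, 1)
    return float(np.abs(m[iu]).mean())


def calibrate_mu(
    target_rho: float,
    p: int = 20,
    sigma2: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    n_matrices: int = 40,
    tol: float = 0.02,
) -> float:
    """Find the Beta mean mu whose vine matrices average |rho| = target.

    The Monte-Carlo response (mean of :func:`average_abs_correlation` over
    ``n_matrices`` vine draws) is made a deterministic function of mu through
    common random numbers, then inverted by bracketed root finding. Partial
    correlations are drawn on the positive support (0, 1), under which the
    response is monotone increasing in mu and the realised matrices have the
    predominantly positive entries of an "average correlation rho" model.
    """
    if not 0.0 < target_rho < 1.0:
        raise AssociationError("target_rho must be in (0, 1)")
    rng = rng or np.random.default_rng()
    crn_seed = int(rng.integers(2 ** 31 - 1))

    # admissible mu interval: sigma2 < mu(1-mu)
    disc = 1.0 - 4.0 * sigma2
    if disc <= 0:
        raise AssociationError("sigma2 too large for any valid Beta mean")
    lo = (1.0 - np.sqrt(disc)) / 2.0 + 1e-4
    hi = (1.0 + np.sqrt(disc)) / 2.0 - 1e-4

    def response(mu: float) -> float:
        a, b = beta_shape_from_moments(mu, sigma2)
        sub = np.random.default_rng(crn_seed)
        vals = [average_abs_correlation(
                    vine_matrix(p, a, b, sub, support=(0.0, 1.0)))
                for _ in range(n_matrices)]
        return float(np.mean(vals)) - target_rho

    f_lo, f_hi = response(lo), response(hi)
    if f_lo >= 0.0:
        if abs(f_lo) <= tol:
            return lo
        raise CalibrationError(
            f"target {target_rho} below attainable range (min approx {f_lo + target_rho:.3f})")
    if f_hi <= 0.0:
        if abs(f_hi) <= tol:
            return hi
        raise CalibrationError(
            f"target {target_rho} above attainable range (max approx {f_hi + target_rho:.3f})")
    from scipy.optimize import brentq
    return float(brentq(response, lo, hi, xtol=1e-3))


def sample_gaussian(
    model: CorrelationModel,
    n: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw an n x p matrix from N(0, Sigma) with Sigma the model matrix."""
    model.validate()
    rng = rng or np.random.default_rng()
    chol = np.linalg.cholesky(model.matrix)
    return rng.standard_normal((int(n), model.p)) @ chol.T
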