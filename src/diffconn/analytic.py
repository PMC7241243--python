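"""Closed-form relations among Pearson correlation, Spearman correlation,
and Gaussian mutual information.

For a bivariate normal pair with correlation rho the mutual information is

    MI(rho) = -(1/2) * ln(1 - rho**2)    [nats],

an even, strictly increasing function of |rho| that crosses the identity
MI = rho at a single positive correlation near 0.916: below it MI < rho,
above it MI > rho. In the absence of ties the expected Spearman correlation
of a bivariate normal sample of size n is

    rho_S = 6 / (pi * (n + 1)) * (arcsin(rho) + (n - 2) * arcsin(rho / 2)),

which maps 0 -> 0 and +/-1 -> +/-1 exactly and is biased towards zero in
between; the bias shrinks as n grows.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .association import AssociationError

__all__ = [
    "gaussian_mi",
    "mi_correlation_crossing",
    "spearman_of_pearson",
    "spearman_bias_argmax",
    "mi_curve",
]


def gaussian_mi(rho):
    """Mutual information (nats) of a bivariate Gaussian with correlation rho."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise AssociationError("|rho| must be < 1")
    out = -0.5 * np.log1p(-r ** 2)
    return float(out) if np.isscalar(rho) else out


def mi_correlation_crossing(xtol: float = 1e-6) -> float:
    """The positive rho where the Gaussian MI curve equals rho itself.

    Found by bracketed root finding of ``-0.5*ln(1-rho^2) - rho`` on
    (0.5, 0.99); MI < rho below the root and MI > rho above it.
    """
    return float(brentq(lambda r: gaussian_mi(r) - r, 0.5, 0.99, xtol=xtol))


def spearman_of_pearson(rho, n: int):
    """Expected no-ties Spearman correlation of a Gaussian sample of size n."""
    if n < 3:
        raise AssociationError("n must be >= 3")
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise AssociationError("|rho| must be <= 1")
    out = 6.0 / (np.pi * (n + 1.0)) * (np.arcsin(r) + (n - 2.0) * np.arcsin(r / 2.0))
    return float(out) if np.isscalar(rho) else out


def spearman_bias_argmax(n: Optional[int] = None, xtol: float = 1e-4):
    """Location and size of the maximal downward Spearman bias.

    Maximises ``gap(rho) = rho - rho_S(rho)`` over rho in [0, 1]. With
    ``n=None`` the large-sample limit ``rho - (6/pi) * arcsin(rho/2)`` is
    used, whose argmax has the closed form 2*sqrt(1 - 9/pi^2) ~= 0.5937.
    Returns ``(argmax, gap_at_argmax)``.
    """
    if n is None:
        gap = lambda r: r - 6.0 / np.pi * np.arcsin(r / 2.0)
    else:
        gap = lambda r: r - spearman_of_pearson(r, n)
    res = minimize_scalar(lambda r: -gap(r), bounds=(0.0, 1.0),
                          method="bounded", options={"xatol": xtol})
    return float(res.x), float(gap(res.x))


def mi_curve(
    rhos: Optional[np.ndarray] = None,
    n: int = 100,
) -> pd.DataFrame:
    """Tabulate (rho, Gaussian MI, expected Spearman) for plotting/export."""
    if rhos is None:
        rhos = np.linspace(-0.99, 0.99, 199)
    rhos = np.asarray(rhos, dtype=float)
    return pd.DataFrame({
        "rho": rhos,
        "gaussian_mi": gaussian_mi(rhos),
        "spearman": spearman_of_pearson(rhos, n),
    })
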