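"""Permutation significance test for differential connectivity.

The null distribution is built by independently permuting each and every
column of both group matrices, which preserves every column's marginal
(mean, variance, full multiset of values) while destroying all
between-feature associations. Each permutation replicate yields a
"permuted" differential connectivity for every feature; over ``n_perm``
replicates these form the null sample D_i against which the observed
delta_chi_i is compared:

    P_i = (1 + #{ |D_i| > |delta_chi_i| }) / n_perm,   clipped to 1.

The comparison is two-sided on magnitude (delta_chi can have either sign),
ties count as non-exceeding, and the smallest attainable p-value is
1/n_perm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import association as assoc
from .association import AssociationError
from .connectivity import _chi

__all__ = ["PermutationConfig", "DCResult", "permute_columns", "dc_test"]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation test."""

    n_perm: int = 1000
    alpha: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise AssociationError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise AssociationError("alpha must be in (0, 1)")


def permute_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each column of ``X`` (marginals preserved)."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise AssociationError("expected a 2-D matrix")
    idx = np.argsort(rng.random(X.shape), axis=0)
    return X[idx, np.arange(X.shape[1])]


@dataclass
class DCResult:
    """Results of a differential connectivity test.

    Carries the per-feature connectivities of both groups, their difference,
    permutation p-values and significance flags, plus the null standard
    deviation of each feature as a dispersion diagnostic.
    """

    feature_names: tuple[str, ...]
    chi_g1: np.ndarray
    chi_g2: np.ndarray
    delta_chi: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    config: PermutationConfig
    measure: str
    estimator: Optional[str] = None
    null_sd: Optional[np.ndarray] = None
    group_labels: tuple[str, str] = ("G1", "G2")

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-feature table."""
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "chi_g1": self.chi_g1,
                "chi_g2": self.chi_g2,
                "delta_chi": self.delta_chi,
                "p_value": self.p_values,
                "significant": self.significant,
            }
        )

    def adjusted_p_values(self, method: str = "fdr_bh") -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values (opt-in; raw p by default)."""
        if method != "fdr_bh":
            raise AssociationError(f"unsupported adjustment {method!r}")
        p = np.asarray(self.p_values)
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.clip(adj, 0.0, 1.0)
        return out

    def summary(self) -> str:
        """Human-readable summary table."""
        est = f" ({self.estimator})" if self.estimator else ""
        lines = [
            "Differential Connectivity Permutation Test",
            "=" * 58,
            f"measure: {self.measure}{est}   n_perm: {self.config.n_perm}"
            f"   alpha: {self.config.alpha}",
            f"features: {len(self.feature_names)}   "
            f"significant: {self.n_significant}",
            "-" * 58,
            f"{'feature':<16}{'chi_G1':>9}{'chi_G2':>9}"
            f"{'delta':>9}{'p':>9}  sig",
        ]
        for i, name in enumerate(self.feature_names):
            flag = "*" if self.significant[i] else ""
            lines.append(
                f"{name:<16}{self.chi_g1[i]:>9.3f}{self.chi_g2[i]:>9.3f}"
                f"{self.delta_chi[i]:>9.3f}{self.p_values[i]:>9.4f}  {flag}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


def _chi_function(measure, estimator, n_bins, scheme, prior_N, n, p):
    """Return (prepare, chi_of_prepared) for efficient repeated evaluation."""
    if measure in ("pearson", "spearman"):

        def prepare(X):
            X = np.asarray(X, dtype=float)
            if measure == "spearman":
                from scipy.stats import rankdata
                X = rankdata(X, axis=0)
            return X

        def chi(M):
            return _chi(assoc._corr_matrix(M, "pearson"))

        return prepare, chi

    est = estimator or "empirical"
    if est not in assoc.ESTIMATORS:
        raise AssociationError(f"unknown entropy estimator {est!r}")

    def prepare(X):
        L, b = assoc._label_matrix(np.asarray(X, dtype=float), n_bins, scheme)
        return L, b

    def chi(prepared):
        L, b = prepared
        return _chi(assoc._mi_matrix_from_labels(L, b, est, prior_N))

    return prepare, chi


def _permute_prepared(prepared, measure, rng):
    if measure in ("pearson", "spearman"):
        return permute_columns(prepared, rng)
    L, b = prepared
    return permute_columns(L, rng), b


def dc_test(
    X1,
    X2,
    measure: str = "pearson",
    estimator: Optional[str] = None,
    config: Optional[PermutationConfig] = None,
    n_bins: Optional[int] = None,
    scheme: str = "equal_frequency",
    prior_N: Optional[float] = None,
    group_labels: tuple[str, str] = ("G1", "G2"),
) -> DCResult:
    """Test each feature for differential connectivity between two groups.

    ``X1`` and ``X2`` are samples x features matrices over the same features
    (sample sizes may differ). Deterministic given ``config.seed``.
    """
    config = config or PermutationConfig()
    A1, names1 = assoc._coerce_matrix(X1)
    A2, names2 = assoc._coerce_matrix(X2)
    if A1.shape[1] != A2.shape[1]:
        raise AssociationError("groups have different numbers of features")
    if isinstance(X1, pd.DataFrame) and isinstance(X2, pd.DataFrame) \
            and names1 != names2:
        raise AssociationError("feature names differ between groups")
    if A1.shape[0] < 3 or A2.shape[0] < 3:
        raise AssociationError("need at least 3 samples per group")
    if measure not in assoc.MEASURES:
        raise AssociationError(f"unknown measure {measure!r}")

    p = A1.shape[1]
    rng = np.random.default_rng(config.seed)

    prep, chi = _chi_function(measure, estimator, n_bins, scheme, prior_N,
                              A1.shape[0], p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-column warnings per replicate
        P1, P2 = prep(A1), prep(A2)
        chi1, chi2 = chi(P1), chi(P2)
        delta = chi1 - chi2
        D = np.empty((config.n_perm, p))
        for b in range(config.n_perm):
            D[b] = chi(_permute_prepared(P1, measure, rng)) \
                - chi(_permute_prepared(P2, measure, rng))

    exceed = (np.abs(D) > np.abs(delta)[None, :]).sum(axis=0)
    pvals = np.minimum((1.0 + exceed) / config.n_perm, 1.0)

    return DCResult(
        feature_names=names1,
        chi_g1=chi1,
        chi_g2=chi2,
        delta_chi=delta,
        p_values=pvals,
        significant=pvals < config.alpha,
        config=config,
        measure=measure,
        estimator=(estimator or "empirical") if measure == "mi" else None,
        null_sd=D.std(axis=0, ddof=1) if config.n_perm > 1 else None,
        group_labels=group_labels,
    )
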