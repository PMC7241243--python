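"""Model-style entry point for differential connectivity analysis.

Usage mirrors the fit-and-summarise pattern of statistical modelling
packages::

    model = DifferentialConnectivity(X1, X2, measure="pearson")
    res = model.fit(n_perm=1000, alpha=0.05, seed=7)
    print(res.summary())
    res.to_frame()          # per-feature table

or from a single tidy table with a two-level group column::

    model = DifferentialConnectivity.from_dataframe(df, group_col="status")
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .association import AssociationError, association_matrix
from .significance import DCResult, PermutationConfig, dc_test

__all__ = ["DifferentialConnectivity"]


class DifferentialConnectivity:
    """Differential connectivity model for two groups of samples.

    Parameters
    ----------
    X1, X2 : array-like or DataFrame, samples x features
        The two condition/group matrices over the same features.
    measure : {"pearson", "spearman", "mi"}
        Association measure used to weight the network edges.
    estimator : {"empirical", "miller_madow", "shrinkage",
        "schurmann_grassberger"}, optional
        Entropy estimator, MI measure only.
    n_bins, scheme, prior_N
        Discretization and prior settings forwarded to the MI machinery.
    """

    def __init__(
        self,
        X1,
        X2,
        measure: str = "pearson",
        estimator: Optional[str] = None,
        n_bins: Optional[int] = None,
        scheme: str = "equal_frequency",
        prior_N: Optional[float] = None,
        group_labels: tuple[str, str] = ("G1", "G2"),
    ) -> None:
        self.X1 = X1
        self.X2 = X2
        self.measure = measure
        self.estimator = estimator
        self.n_bins = n_bins
        self.scheme = scheme
        self.prior_N = prior_N
        self.group_labels = group_labels

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        group_col: str,
        **kwargs,
    ) -> "DifferentialConnectivity":
        """Build the model from one table holding both groups.

        ``group_col`` must have exactly two levels; all remaining columns are
        treated as features.
        """
        if group_col not in data.columns:
            raise AssociationError(f"group column {group_col!r} not found")
        levels = pd.unique(data[group_col])
        if len(levels) != 2:
            raise AssociationError(
                f"group column must have exactly 2 levels, found {len(levels)}"
            )
        feats = data.drop(columns=[group_col])
        g1 = feats[data[group_col] == levels[0]]
        g2 = feats[data[group_col] == levels[1]]
        kwargs.setdefault("group_labels", (str(levels[0]), str(levels[1])))
        return cls(g1, g2, **kwargs)

    def association_matrices(self):
        """The two weighted adjacency matrices the statistic is built on."""
        kw = dict(measure=self.measure, estimator=self.estimator,
                  n_bins=self.n_bins, scheme=self.scheme, prior_N=self.prior_N)
        return association_matrix(self.X1, **kw), association_matrix(self.X2, **kw)

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: Optional[int] = None,
    ) -> DCResult:
        """Run the column-permutation test; returns a :class:`DCResult`."""
        cfg = PermutationConfig(n_perm=n_perm, alpha=alpha, seed=seed)
        return dc_test(
            self.X1, self.X2,
            measure=self.measure, estimator=self.estimator, config=cfg,
            n_bins=self.n_bins, scheme=self.scheme, prior_N=self.prior_N,
            group_labels=self.group_labels,
        )
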