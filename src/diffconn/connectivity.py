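"""Node connectivity and differential connectivity.

The connectivity of node *i* in a weighted network with adjacency ``A`` is
the sum of absolute association weights to all other nodes,

    chi_i = sum_{j != i} |a_ij|,

which reduces to the node degree for unweighted (0/1) networks. The
differential connectivity between two conditions is the elementwise
difference ``delta_chi = chi_G1 - chi_G2``.

The diagonal never contributes: a correlation self-weight of one would add
the same constant to every node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import AssociationError, AssociationMatrix

__all__ = ["ConnectivityProfile", "DifferentialConnectivityProfile",
           "node_connectivity", "differential_connectivity", "_chi"]


@dataclass(frozen=True)
class ConnectivityProfile:
    """Per-node connectivity chi for one group."""

    chi: np.ndarray
    measure: str
    feature_names: tuple[str, ...]
    group_label: str = ""


@dataclass(frozen=True)
class DifferentialConnectivityProfile:
    """Elementwise chi difference between two groups."""

    delta_chi: np.ndarray
    feature_names: tuple[str, ...]
    group_labels: tuple[str, str] = ("G1", "G2")


def _chi(weights: np.ndarray) -> np.ndarray:
    """Row sums of absolute off-diagonal weights."""
    a = np.abs(np.asarray(weights, dtype=float))
    return a.sum(axis=1) - np.diag(a)


def node_connectivity(A: AssociationMatrix, group_label: str = "") -> ConnectivityProfile:
    """Connectivity chi_i = sum_{j != i} |a_ij| of every node."""
    w = A.weights
    if w.shape[0] < 2:
        raise AssociationError("need at least 2 nodes")
    return ConnectivityProfile(chi=_chi(w), measure=A.measure,
                               feature_names=A.feature_names,
                               group_label=group_label)


def differential_connectivity(
    A1: AssociationMatrix, A2: AssociationMatrix,
    group_labels: tuple[str, str] = ("G1", "G2"),
) -> DifferentialConnectivityProfile:
    """delta_chi_i = chi_i^G1 - chi_i^G2; antisymmetric under group swap."""
    if A1.feature_names != A2.feature_names:
        raise AssociationError("feature names differ between groups")
    if A1.measure != A2.measure:
        raise AssociationError("association measures differ between groups")
    d = _chi(A1.weights) - _chi(A2.weights)
    return DifferentialConnectivityProfile(delta_chi=d,
                                           feature_names=A1.feature_names,
                                           group_labels=group_labels)
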