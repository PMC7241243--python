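"""Scripted simulation grids: type-I error, power, and kinetic perturbation.

Each experiment sweeps a grid of simulation cells, runs the differential
connectivity permutation test in every cell for a number of replicates, and
returns a long-format table with one row per cell carrying the median
significant-feature count and (where both groups are exchangeable) the
empirical type-I-error rate. All randomness flows from one master seed.

Measures are written as strings: ``"pearson"``, ``"spearman"``, or
``"mi:<estimator>"`` (e.g. ``"mi:miller_madow"``; plain ``"mi"`` means the
empirical estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import AssociationError
from .corr_structures import (
    calibrate_mu,
    beta_shape_from_moments,
    hub_matrix,
    perturb_hardin,
    sample_gaussian,
    toeplitz_matrix,
    vine_matrix,
)
from .kinetic import KineticModel, KineticPopulationSpec, generate_group, goodwin_oscillator
from .significance import DCResult, PermutationConfig, dc_test

__all__ = [
    "DEFAULT_EPSILONS",
    "OverlapCounts",
    "parse_measure",
    "type1_experiment",
    "power_experiment",
    "kinetic_experiment",
    "overlap_summary",
]

DEFAULT_EPSILONS = (1 / 10, 1 / 5, 1 / 3, 1 / 2, 1 / 1.5, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0)


def parse_measure(spec: str) -> tuple[str, Optional[str]]:
    """Split a measure string into (measure, estimator)."""
    if ":" in spec:
        measure, estimator = spec.split(":", 1)
    else:
        measure, estimator = spec, None
    if measure == "mi" and estimator is None:
        estimator = "empirical"
    return measure, estimator


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31 - 1))


def _run_cell(X1, X2, measure_spec: str, n_perm: int, alpha: float, seed: int) -> DCResult:
    measure, estimator = parse_measure(measure_spec)
    cfg = PermutationConfig(n_perm=n_perm, alpha=alpha, seed=seed)
    return dc_test(X1, X2, measure=measure, estimator=estimator, config=cfg)


def type1_experiment(
    n_values: Sequence[int] = (25, 100, 500),
    p: int = 20,
    replicates: int = 100,
    measures: Sequence[str] = ("pearson",),
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Type-I-error calibration: both groups i.i.d. N(0, I_p).

    The reported ``type1_rate`` is the fraction of feature/replicate tests
    declared significant at ``alpha``; under a calibrated test it should sit
    near ``alpha`` for every sample size.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        for m in measures:
            counts = []
            for _ in range(replicates):
                X1 = rng.standard_normal((n, p))
                X2 = rng.standard_normal((n, p))
                res = _run_cell(X1, X2, m, n_perm, alpha, _child_seed(rng))
                counts.append(res.n_significant)
            counts = np.asarray(counts)
            rows.append({
                "experiment": "type1", "measure": m, "n": n, "p": p,
                "replicates": replicates,
                "median_significant": float(np.median(counts)),
                "type1_rate": float(counts.mean() / p),
            })
    return pd.DataFrame(rows)


def _structured_model(structure: str, rho: float, p: int, rng,
                      sigma2: float, mu_cache: dict,
                      hub_group_sizes, eps_noise: float, edim: int):
    if structure == "toeplitz":
        model = toeplitz_matrix(p, rho)
        if eps_noise > 0:
            if eps_noise < model.min_eigenvalue:
                model = perturb_hardin(model, eps_noise, edim, rng)
            else:
                warnings.warn(
                    f"skipping Hardin perturbation at rho={rho}: eps_noise "
                    "not below the smallest eigenvalue")
        return model
    if structure == "hub":
        sizes = hub_group_sizes or (15, 5)
        if sum(sizes) != p:
            raise AssociationError("hub group sizes must sum to p")
        model = hub_matrix(sizes, rho=rho, rho_min=0.0, gamma=2.0)
        if 0 < eps_noise < model.min_eigenvalue:
            model = perturb_hardin(model, eps_noise, edim, rng)
        return model
    if structure == "average":
        if rho not in mu_cache:
            mu_cache[rho] = calibrate_mu(rho, p=p, sigma2=sigma2, rng=rng)
        a, b = beta_shape_from_moments(mu_cache[rho], sigma2)
        return vine_matrix(p, a, b, rng, support=(0.0, 1.0))
    raise AssociationError(f"unknown structure {structure!r}")


def power_experiment(
    structure: str = "toeplitz",
    rho_values: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_values: Sequence[int] = (10, 25, 50, 100, 250, 500),
    measures: Sequence[str] = ("pearson",),
    replicates: int = 10,
    p: int = 20,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    null_comparison: bool = True,
    sigma2: float = 0.1,
    hub_group_sizes: Optional[Sequence[int]] = None,
    eps_noise: float = 0.01,
    edim: int = 2,
) -> pd.DataFrame:
    """Power grid: group 1 structured, group 2 uncorrelated (or, with
    ``null_comparison=False``, a second draw from the same structure)."""
    rng = np.random.default_rng(seed)
    mu_cache: dict = {}
    rows = []
    for rho in rho_values:
        for n in n_values:
            for m in measures:
                counts = []
                for _ in range(replicates):
                    model = _structured_model(structure, rho, p, rng, sigma2,
                                              mu_cache, hub_group_sizes,
                                              eps_noise, edim)
                    X1 = sample_gaussian(model, n, rng)
                    X2 = (rng.standard_normal((n, p)) if null_comparison
                          else sample_gaussian(model, n, rng))
                    res = _run_cell(X1, X2, m, n_perm, alpha, _child_seed(rng))
                    counts.append(res.n_significant)
                counts = np.asarray(counts)
                rows.append({
                    "experiment": "power", "structure": structure,
                    "measure": m, "rho": rho, "n": n, "p": p,
                    "replicates": replicates,
                    "median_significant": float(np.median(counts)),
                    "mean_significant": float(counts.mean()),
                })
    return pd.DataFrame(rows)


def kinetic_experiment(
    epsilons: Sequence[float] = DEFAULT_EPSILONS,
    n_values: Sequence[int] = (10, 25, 50, 100, 250, 500),
    measures: Sequence[str] = ("pearson",),
    replicates: int = 5,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    model: Optional[KineticModel] = None,
    t_sample: float = 200.0,
    pool_size: int = 1000,
) -> pd.DataFrame:
    """Kinetic-model grid: group 1 perturbed by epsilon, group 2 at
    epsilon = 1.

    For each epsilon a pool of ``pool_size`` individuals is simulated once
    (as is one reference pool at epsilon = 1) and replicate data sets of each
    size are drawn from the pools without replacement.
    """
    model = model or goodwin_oscillator()
    rng = np.random.default_rng(seed)
    if pool_size < max(n_values):
        raise AssociationError("pool_size must be at least max(n_values)")

    def pool(eps: float) -> pd.DataFrame:
        spec = KineticPopulationSpec(model=model, n=pool_size, epsilon=eps,
                                     t_sample=t_sample, seed=_child_seed(rng))
        return generate_group(spec)

    ref = pool(1.0)
    rows = []
    for eps in epsilons:
        grp = ref if eps == 1.0 else pool(eps)
        for n in n_values:
            for m in measures:
                counts = []
                for _ in range(replicates):
                    i1 = rng.choice(pool_size, size=n, replace=False)
                    i2 = rng.choice(pool_size, size=n, replace=False)
                    X1 = grp.iloc[i1].reset_index(drop=True)
                    X2 = ref.iloc[i2].reset_index(drop=True)
                    res = _run_cell(X1, X2, m, n_perm, alpha, _child_seed(rng))
                    counts.append(res.n_significant)
                counts = np.asarray(counts)
                rows.append({
                    "experiment": "kinetic", "measure": m, "epsilon": eps,
                    "n": n, "p": model.p, "replicates": replicates,
                    "median_significant": float(np.median(counts)),
                    "mean_significant": float(counts.mean()),
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapCounts:
    """Set arithmetic on the significant-feature sets of two results."""

    only_in_a: int
    only_in_b: int
    overlap: int
    total_a: int
    total_b: int


def overlap_summary(result_a: DCResult, result_b: DCResult) -> OverlapCounts:
    """Counts of features significant only in a, only in b, and in both."""
    if result_a.feature_names != result_b.feature_names:
        raise AssociationError("results cover different feature sets")
    sa = set(np.flatnonzero(result_a.significant))
    sb = set(np.flatnonzero(result_b.significant))
    return OverlapCounts(
        only_in_a=len(sa - sb),
        only_in_b=len(sb - sa),
        overlap=len(sa & sb),
        total_a=len(sa),
        total_b=len(sb),
    )
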