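"""Population snapshots from a kinetic ODE model.

A population of in-silico individuals is generated from one kinetic model
by (i) jittering every rate constant, Michaelis constant, and nonzero
initial concentration independently and uniformly within +/- 10 % of its
reference value (per-individual biological variability), (ii) optionally
multiplying every parameter of every individual by one global perturbation
factor epsilon (the "perturbed condition"), and (iii) integrating each
individual's ODE system and recording the concentration vector at a single
sampling time. Rows of the resulting feature matrix are individuals,
columns are species.

The packaged model is a five-species negative-feedback (Goodwin-type)
oscillator: production of S1 is repressed by S5 through a steep Hill term,
S1..S4 convert linearly down the chain, and S5 is removed by a saturable
Michaelis-Menten reaction that closes the loop with relaxation-type limit
cycles. The parameters were chosen so that epsilon > 1 accelerates the
oscillation (more zero crossings per unit time) and epsilon < 1 slows it,
while a sustained limit cycle persists across epsilon in [1/3, 10].
Because individuals differ slightly in period, a late sampling time spreads
them over the limit cycle, producing the strongly nonlinear cross-sectional
associations this generator exists to emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .association import AssociationError

__all__ = [
    "KineticModel",
    "IndividualParameters",
    "KineticPopulationSpec",
    "SimulationError",
    "goodwin_oscillator",
    "draw_individual",
    "apply_perturbation",
    "simulate_individual",
    "simulate_trajectory",
    "generate_group",
    "load_sbml_model",
]


class SimulationError(RuntimeError):
    """ODE integration failed for one individual."""


@dataclass(frozen=True)
class KineticModel:
    """A kinetic ODE system with named parameters.

    ``rhs(t, state, k, Km)`` returns the derivative vector; ``k`` and ``Km``
    are the dictionaries of rate and Michaelis-type constants, ``c0`` the
    reference initial concentrations (one per species).
    """

    species: tuple[str, ...]
    k: dict
    Km: dict
    c0: np.ndarray
    rhs: Callable

    def __post_init__(self) -> None:
        object.__setattr__(self, "c0", np.asarray(self.c0, dtype=float))
        if self.c0.size != len(self.species):
            raise AssociationError("c0 must have one entry per species")
        if any(v < 0 for v in self.k.values()) or any(v < 0 for v in self.Km.values()) \
                or np.any(self.c0 < 0):
            raise AssociationError("kinetic parameters must be nonnegative")

    @property
    def p(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class IndividualParameters:
    """One individual's realised parameter set."""

    k: dict
    Km: dict
    c0: np.ndarray


def _goodwin_rhs(t, x, k, Km):
    # S5 represses production of S1 (Hill, h=8); linear chain S1->...->S5;
    # Michaelis-Menten removal of S5 closes the negative-feedback loop.
    h = 8.0
    prod = k["v0"] / (1.0 + (max(x[4], 0.0) / Km["K_inh"]) ** h)
    return (
        prod - k["k1"] * x[0],
        k["k1"] * x[0] - k["k2"] * x[1],
        k["k2"] * x[1] - k["k3"] * x[2],
        k["k3"] * x[2] - k["k4"] * x[3],
        k["k4"] * x[3] - k["k5"] * x[4] / (Km["Km5"] + x[4]),
    )


def goodwin_oscillator() -> KineticModel:
    """The packaged five-species negative-feedback oscillator."""
    return KineticModel(
        species=("S1", "S2", "S3", "S4", "S5"),
        k={"v0": 1.0, "k1": 0.3, "k2": 0.3, "k3": 0.3, "k4": 0.3, "k5": 0.6},
        Km={"K_inh": 0.3, "Km5": 0.2},
        c0=np.array([1.0, 0.5, 0.0, 0.0, 0.0]),
        rhs=_goodwin_rhs,
    )


@dataclass(frozen=True)
class KineticPopulationSpec:
    """Settings of one simulated population (one group/condition)."""

    model: KineticModel
    n: int
    epsilon: float = 1.0
    jitter_fraction: float = 0.10
    t_sample: float = 200.0
    seed: Optional[int] = None
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise AssociationError("epsilon must be positive")
        if not 0.0 <= self.jitter_fraction < 1.0:
            raise AssociationError("jitter_fraction must be in [0, 1)")
        if self.t_sample <= 0:
            raise AssociationError("t_sample must be positive")
        if self.n < 1:
            raise AssociationError("population size must be >= 1")


def draw_individual(
    model: KineticModel,
    jitter_fraction: float = 0.10,
    rng: Optional[np.random.Generator] = None,
) -> IndividualParameters:
    """Draw one individual: every parameter uniform in base * (1 -/+ f).

    Only species with nonzero reference initial concentration are jittered
    (a zero base gives a degenerate interval and stays zero).
    """
    if not 0.0 <= jitter_fraction < 1.0:
        raise AssociationError("jitter_fraction must be in [0, 1)")
    rng = rng or np.random.default_rng()
    f = jitter_fraction

    def u(base: float) -> float:
        return float(rng.uniform((1.0 - f) * base, (1.0 + f) * base)) if base > 0 else float(base)

    k = {name: u(v) for name, v in model.k.items()}
    km = {name: u(v) for name, v in model.Km.items()}
    c0 = np.array([u(v) for v in model.c0])
    return IndividualParameters(k=k, Km=km, c0=c0)


def apply_perturbation(params: IndividualParameters, epsilon: float) -> IndividualParameters:
    """Multiply every rate constant, Michaelis constant, and initial
    concentration by the global factor epsilon."""
    if epsilon <= 0:
        raise AssociationError("epsilon must be positive")
    return IndividualParameters(
        k={n: epsilon * v for n, v in params.k.items()},
        Km={n: epsilon * v for n, v in params.Km.items()},
        c0=epsilon * params.c0,
    )


def simulate_trajectory(
    model: KineticModel,
    params: Optional[IndividualParameters] = None,
    t_max: float = 300.0,
    n_points: int = 3000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one parameter set on a dense grid; returns (t, states).

    ``states`` has shape (n_points, p). Intended for inspecting dynamics
    (periods, amplitudes); population snapshots use
    :func:`simulate_individual`.
    """
    if params is None:
        params = IndividualParameters(k=dict(model.k), Km=dict(model.Km),
                                      c0=model.c0.copy())
    t = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(model.rhs, (0.0, t_max), params.c0, t_eval=t,
                    args=(params.k, params.Km), method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    return t, sol.y.T


def simulate_individual(
    model: KineticModel,
    params: IndividualParameters,
    t_sample: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    label: str = "",
) -> np.ndarray:
    """Concentration vector of one individual at the sampling time.

    Tiny negative values from integration error are clipped to zero.
    """
    if t_sample <= 0:
        raise AssociationError("t_sample must be positive")
    sol = solve_ivp(model.rhs, (0.0, t_sample), params.c0,
                    t_eval=[t_sample], args=(params.k, params.Km),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        who = f" for individual {label}" if label else ""
        raise SimulationError(f"integration failed{who}: {sol.message}")
    state = sol.y[:, -1]
    return np.clip(state, 0.0, None)


def generate_group(spec: KineticPopulationSpec) -> pd.DataFrame:
    """Simulate a population; rows are individuals, columns species.

    Each row is an independent individual: jitter, global epsilon scaling,
    integration to ``spec.t_sample``. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = np.empty((spec.n, spec.model.p))
    for j in range(spec.n):
        ind = draw_individual(spec.model, spec.jitter_fraction, rng)
        ind = apply_perturbation(ind, spec.epsilon)
        out[j] = simulate_individual(spec.model, ind, spec.t_sample,
                                     rtol=spec.rtol, atol=spec.atol,
                                     label=str(j))
    return pd.DataFrame(out, columns=list(spec.model.species))


def load_sbml_model(path: str) -> KineticModel:
    """Load a kinetic model from an SBML file (optional interface).

    Requires the ``python-libsbml`` package; only mass-action and
    Michaelis-Menten style rate laws expressible through the
    :class:`KineticModel` container are supported.
    """
    try:
        import libsbml  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "SBML loading requires the optional python-libsbml package"
        ) from exc
    raise NotImplementedError(
        "generic SBML kinetics are not mapped onto KineticModel; "
        "construct a KineticModel directly instead"
    )  # pragma: no cover
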