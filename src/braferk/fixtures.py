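"""Tiny synthetic reaction networks with independent reference solutions.

These fixtures exercise the mass-action machinery and the stiff integrator on
problems whose answers are known in closed form (or by an algebraic
equilibrium condition), independently of the 36-species cascade:

``single_binding``
    A + B ⇌ A·B.  Second-order reversible kinetics has an explicit solution:
    with K = d/a and roots r1 < r2 of x² − (A0 + B0 + K)x + A0·B0 = 0, the
    complex follows x(t) = r1·r2·(1 − E)/(r2 − r1·E), E = exp(−a(r2 − r1)t),
    relaxing to the equilibrium x(∞) = r1.

``michaelis_menten``
    E + pS ⇌ E·pS → E + S, a single dephosphorylation cycle.  With enzyme
    scarce relative to substrate, the quasi-steady-state velocity is
    V = k·E0·[pS]/(K_m + [pS]) with K_m = (d + k)/a.

``two_step``
    A + B ⇌ A·B, A·B + C ⇌ A·B·C — ordered assembly of a ternary complex.
    The reference is the pair of equilibrium conditions a1[A][B] = d1[A·B]
    and a2[A·B][C] = d2[A·B·C], which the relaxed system must satisfy.

Matching these references is the integrator's acceptance gate before the full
cascade is trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping

import numpy as np

from .network import ReactionNetwork, Reaction, Species

__all__ = ["FixtureNetwork", "make_fixture_network"]


@dataclass(frozen=True)
class FixtureNetwork:
    """A toy network bundled with its reference-solution contract."""

    network: ReactionNetwork
    constants: Mapping[str, float]
    initial: Mapping[str, float]
    description: str
    #: closed-form trajectory of a named species, or None
    closed_form: Callable[[np.ndarray], np.ndarray] | None = None
    closed_form_species: str | None = None
    #: expected equilibrium concentrations, or None
    equilibrium: Mapping[str, float] | None = None
    #: residual function on a state dict -> max relative equilibrium error
    equilibrium_check: Callable[[Mapping[str, float]], float] | None = None


def _single_binding(a: float = 1.0, d: float = 1.0,
                    A0: float = 1.0, B0: float = 1.0) -> FixtureNetwork:
    species = (Species("A", "substrate"), Species("B", "substrate"),
               Species("A·B", "complex", constituents=("A", "B")))
    net = ReactionNetwork(
        species=species,
        reactions=(Reaction("F.1", "binding", ("A", "B"), ("A·B",), "a1", "d1"),),
        include_dbf=False, include_tmt=False)
    K = d / a if a > 0 else np.inf
    # roots of x^2 - (A0+B0+K) x + A0 B0
    s = A0 + B0 + K
    disc = np.sqrt(s * s - 4 * A0 * B0)
    r1, r2 = (s - disc) / 2, (s + disc) / 2

    def x_of_t(t: np.ndarray) -> np.ndarray:
        E = np.exp(-a * (r2 - r1) * np.asarray(t, float))
        return r1 * r2 * (1 - E) / (r2 - r1 * E)

    return FixtureNetwork(
        network=net, constants={"a1": a, "d1": d},
        initial={"A": A0, "B": B0},
        description=f"reversible binding, a={a}, d={d}, A0={A0}, B0={B0}",
        closed_form=x_of_t, closed_form_species="A·B",
        equilibrium={"A·B": r1, "A": A0 - r1, "B": B0 - r1})


def _michaelis_menten(a: float = 10.0, d: float = 5.0, k: float = 5.0,
                      E0: float = 0.01, S0: float = 10.0) -> FixtureNetwork:
    species = (Species("E", "phosphatase"), Species("pS", "substrate", phospho_count=1),
               Species("S", "substrate"),
               Species("E·pS", "complex", constituents=("E", "pS")))
    net = ReactionNetwork(
        species=species,
        reactions=(
            Reaction("F.1", "binding", ("E", "pS"), ("E·pS",), "a1", "d1"),
            Reaction("F.2", "catalysis", ("E·pS",), ("E", "S"), "k3"),
        ),
        include_dbf=False, include_tmt=False)
    km = (d + k) / a

    def qss_velocity(s_free: float) -> float:
        return k * E0 * s_free / (km + s_free)

    fx = FixtureNetwork(
        network=net, constants={"a1": a, "d1": d, "k3": k},
        initial={"E": E0, "pS": S0},
        description=f"Michaelis-Menten dephosphorylation, Km={km}, E0={E0}, S0={S0}")
    object.__setattr__(fx, "qss_velocity", qss_velocity)  # extra contract hook
    object.__setattr__(fx, "km", km)
    return fx


def _two_step(a1: float = 2.0, d1: float = 1.0, a2: float = 1.0, d2: float = 3.0,
              A0: float = 1.0, B0: float = 1.5, C0: float = 2.0) -> FixtureNetwork:
    species = (Species("A", "substrate"), Species("B", "substrate"),
               Species("C", "substrate"),
               Species("A·B", "complex", constituents=("A", "B")),
               Species("A·B·C", "complex", constituents=("A", "B", "C")))
    net = ReactionNetwork(
        species=species,
        reactions=(
            Reaction("F.1", "binding", ("A", "B"), ("A·B",), "a1", "d1"),
            Reaction("F.2", "binding", ("A·B", "C"), ("A·B·C",), "a2", "d2"),
        ),
        include_dbf=False, include_tmt=False)

    def equilibrium_check(state: Mapping[str, float]) -> float:
        r1 = a1 * state["A"] * state["B"] / (d1 * state["A·B"])
        r2 = a2 * state["A·B"] * state["C"] / (d2 * state["A·B·C"])
        return float(max(abs(r1 - 1.0), abs(r2 - 1.0)))

    return FixtureNetwork(
        network=net, constants={"a1": a1, "d1": d1, "a2": a2, "d2": d2},
        initial={"A": A0, "B": B0, "C": C0},
        description="ordered two-step assembly of a ternary complex",
        equilibrium_check=equilibrium_check)


_KINDS = {"single_binding": _single_binding,
          "michaelis_menten": _michaelis_menten,
          "two_step": _two_step}


def make_fixture_network(kind: Literal["single_binding", "michaelis_menten", "two_step"],
                         **params) -> FixtureNetwork:
    """Build one of the toy oracle networks (see module docstring)."""
    try:
        factory = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {sorted(_KINDS)}") from None
    return factory(**params)
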