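"""Mass-action kinetics: ODE right-hand side, stoichiometry, conservation laws.

The law of mass action turns each reaction into a flux equal to its rate
constant times the product of reactant concentrations; a species' time
derivative is the signed sum of the fluxes of the reactions that produce and
consume it.  For a reversible binding ``X + Y <-> X·Y`` with constants
``(a, d)`` the net flux is ``a[X][Y] - d[X·Y]``; a catalytic step contributes
``k[complex]``.

Working units are nM for concentrations and hours for time throughout.

Because every reaction conserves the protein, drug and adenine-nucleotide
moieties, the network carries one linear conservation law per free moiety:
total BRAF, MEK, ERK, phosph1, phosph2, DBF and TMT (each counted across free,
bound and phosphorylated forms) are constant along any exact solution, as is
the pooled ATP + ADP count.  These laws are exposed as integer weight vectors
lying in the left null space of the stoichiometric matrix and are used to
verify integration accuracy a posteriori.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, TYPE_CHECKING

import numpy as np

from .network import ReactionNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Trajectory

__all__ = [
    "RateConstants",
    "ConfigurationError",
    "MassActionRHS",
    "derive_rhs",
    "stoichiometric_matrix",
    "conservation_weights",
    "ConservedTotals",
    "conserved_totals",
    "conservation_residuals",
    "CONSERVED_MOIETIES",
]

#: Moieties whose totals the cascade conserves (the seven protein/drug laws).
CONSERVED_MOIETIES = ("BRAF", "MEK", "ERK", "phosph1", "phosph2", "DBF", "TMT")


class ConfigurationError(ValueError):
    """A reaction references a rate constant the parameter set does not define."""


@dataclass(frozen=True)
class RateConstants:
    """The cascade's kinetic constants.

    ``a1``..``a8`` are forward (association) constants in 1/(nM·h),
    ``d1``..``d8`` reverse (dissociation) constants in 1/h, and the four
    catalytic constants ``k12``, ``k3``, ``k56``, ``k7`` (1/h) are shared by
    the two phosphorylation steps of the BRAF tier, the phosphatase-1 steps,
    the two phosphorylation steps of the MEK tier and the phosphatase-2 steps
    respectively.  By default all forward constants are equal (``a_j = a_1``),
    which leaves the Michaelis constants ``K_mi = (d_i + k_i)/a_i`` as the
    governing ratios.
    """

    a: tuple[float, ...]
    d: tuple[float, ...]
    k: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.a) != 8 or len(self.d) != 8:
            raise ValueError("need eight forward and eight reverse constants")
        vals = list(self.a) + list(self.d) + list(self.k.values())
        if any(v < 0 for v in vals):
            raise ValueError("rate constants must be nonnegative")
        bad = set(self.k) - {"k12", "k3", "k56", "k7"}
        if bad:
            raise ValueError(f"unknown catalytic constants: {sorted(bad)}")

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "RateConstants":
        a = tuple(float(values[f"a{i}"]) for i in range(1, 9))
        d = tuple(float(values[f"d{i}"]) for i in range(1, 9))
        k = {name: float(values[name]) for name in ("k12", "k3", "k56", "k7")}
        return cls(a=a, d=d, k=k)

    @classmethod
    def defaults(cls) -> "RateConstants":
        from .config import default_rate_constants

        return default_rate_constants()

    def __getitem__(self, ref: str) -> float:
        if ref in self.k:
            return float(self.k[ref])
        if len(ref) >= 2 and ref[0] in "ad" and ref[1:].isdigit():
            i = int(ref[1:])
            if 1 <= i <= 8:
                return float((self.a if ref[0] == "a" else self.d)[i - 1])
        raise KeyError(ref)

    def as_dict(self) -> dict[str, float]:
        out = {f"a{i+1}": self.a[i] for i in range(8)}
        out.update({f"d{i+1}": self.d[i] for i in range(8)})
        out.update({k: float(v) for k, v in self.k.items()})
        return out

    # pairing of catalytic constants with binding families, used for K_m
    _K_PAIR = {1: None, 2: "k12", 3: "k3", 4: None, 5: None, 6: "k56", 7: "k7", 8: None}

    def michaelis_constants(self) -> dict[int, float]:
        """``K_mi = (d_i + k_i)/a_i`` per binding family (``k_i = 0`` where the
        family has no catalytic step, reducing to the dissociation constant)."""
        out = {}
        for i in range(1, 9):
            if self.a[i - 1] > 0:
                ki = self.k[self._K_PAIR[i]] if self._K_PAIR[i] else 0.0
                out[i] = (self.d[i - 1] + ki) / self.a[i - 1]
        return out


def _rate_for(constants: RateConstants | Mapping[str, float], ref: str, rid: str) -> float:
    try:
        return float(constants[ref])
    except KeyError:
        raise ConfigurationError(
            f"reaction {rid} references unknown rate constant {ref!r}") from None


class MassActionRHS:
    """Compiled mass-action derivative function for a network.

    Callable with the scipy signature ``f(t, x)``; the system is autonomous so
    ``t`` is ignored.  An analytic Jacobian is provided for stiff integrators.
    A nonnegative state always maps to a derivative that is nonnegative in
    every coordinate that is zero, because each consuming flux contains the
    species itself as a factor.
    """

    def __init__(self, network: ReactionNetwork,
                 constants: RateConstants | Mapping[str, float]):
        self.network = network
        idx = network.species_index()
        n_r = network.n_reactions
        self.n_species = network.n_species
        # per-reaction compiled structure (forward direction)
        self._r1 = np.zeros(n_r, dtype=np.intp)
        self._r2 = np.full(n_r, -1, dtype=np.intp)   # -1: unary (catalysis)
        self._rev = np.zeros(n_r, dtype=np.intp)     # complex index for bindings
        self._kf = np.zeros(n_r)
        self._kr = np.zeros(n_r)
        self.stoichiometry = stoichiometric_matrix(network)
        self._N = self.stoichiometry.astype(float)
        for j, r in enumerate(network.reactions):
            self._kf[j] = _rate_for(constants, r.fwd_rate, r.rid)
            self._r1[j] = idx[r.reactants[0]]
            if r.kind == "binding":
                self._r2[j] = idx[r.reactants[1]]
                self._rev[j] = idx[r.products[0]]
                self._kr[j] = _rate_for(constants, r.rev_rate, r.rid)  # type: ignore[arg-type]
        self._has_second = self._r2 >= 0
        self._r2safe = np.where(self._has_second, self._r2, 0)

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        """Net flux per reaction (forward minus reverse) at state ``x``."""
        fwd = self._kf * x[self._r1]
        fwd = np.where(self._has_second, fwd * x[self._r2safe], fwd)
        rev = self._kr * x[self._rev]
        return fwd - rev

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        return self._N @ self.fluxes(np.asarray(x, dtype=float))

    def jacobian(self, t: float, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        n_r = len(self._kf)
        D = np.zeros((n_r, self.n_species))
        rows = np.arange(n_r)
        partner = np.where(self._has_second, x[self._r2safe], 1.0)
        np.add.at(D, (rows, self._r1), self._kf * partner)
        two = self._has_second
        np.add.at(D, (rows[two], self._r2[two]), self._kf[two] * x[self._r1[two]])
        np.add.at(D, (rows, self._rev), -self._kr)
        return self._N @ D


def derive_rhs(network: ReactionNetwork,
               constants: RateConstants | Mapping[str, float]) -> MassActionRHS:
    """Compile the mass-action right-hand side for ``network``.

    Raises :class:`ConfigurationError` if a reaction references a rate
    constant that ``constants`` does not define.
    """
    return MassActionRHS(network, constants)


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer net-stoichiometry matrix (species × reactions, forward sense).

    Entry ``(s, r)`` is the net production of species ``s`` by one forward
    event of reaction ``r``; the derivative vector equals this matrix times
    the net flux vector at every state.
    """
    idx = network.species_index()
    N = np.zeros((network.n_species, network.n_reactions), dtype=np.int64)
    for j, r in enumerate(network.reactions):
        for n in r.reactants:
            N[idx[n], j] -= 1
        for n in r.products:
            N[idx[n], j] += 1
    return N


def conservation_weights(network: ReactionNetwork,
                         include_adenosine_pool: bool = True) -> dict[str, np.ndarray]:
    """Integer weight vectors of the linear conservation laws.

    One law per conserved moiety present in the network (species weighted by
    how many copies of the moiety they contain), plus — optionally — the
    pooled ATP + ADP law.  Every returned vector lies exactly in the left
    null space of :func:`stoichiometric_matrix`.
    """
    moieties = [m for m in CONSERVED_MOIETIES]
    counts = [network.moiety_counts(s.name) for s in network.species]
    present = {m for c in counts for m in c}
    out: dict[str, np.ndarray] = {}
    for m in moieties:
        if m in present:
            out[f"{m}_tot"] = np.array([c.get(m, 0) for c in counts], dtype=np.int64)
    if include_adenosine_pool and {"ATP", "ADP"} & present:
        out["adenosine_pool"] = np.array(
            [c.get("ATP", 0) + c.get("ADP", 0) for c in counts], dtype=np.int64)
    # generic fallback for toy networks that use none of the cascade moieties
    if not out:
        for m in sorted(present):
            out[f"{m}_tot"] = np.array([c.get(m, 0) for c in counts], dtype=np.int64)
    return out


@dataclass(frozen=True)
class ConservedTotals:
    """The seven conserved totals (nM), each summed over free and bound forms."""

    BRAF_tot: float = 0.0
    MEK_tot: float = 0.0
    ERK_tot: float = 0.0
    phosph1_tot: float = 0.0
    phosph2_tot: float = 0.0
    DBF_tot: float = 0.0
    TMT_tot: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f"{m}_tot": getattr(self, f"{m}_tot") for m in CONSERVED_MOIETIES}


def conserved_totals(network: ReactionNetwork, state: np.ndarray) -> ConservedTotals:
    """Constituent-weighted totals of the seven conserved moieties at ``state``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(f"state has shape {state.shape}, expected ({network.n_species},)")
    weights = conservation_weights(network, include_adenosine_pool=False)
    vals = {}
    for m in CONSERVED_MOIETIES:
        w = weights.get(f"{m}_tot")
        vals[f"{m}_tot"] = float(w @ state) if w is not None else 0.0
    return ConservedTotals(**vals)


def conservation_residuals(network: ReactionNetwork, trajectory: "Trajectory",
                           floor: float = 1e-6,
                           include_adenosine_pool: bool | None = None) -> dict[str, float]:
    """Per-law maximum relative drift along a trajectory.

    For each law the residual is ``max_t |total(t) - total(0)| /
    max(total(0), floor)``; the floor (nM) keeps zero-dose laws well defined.
    The pooled ATP + ADP law is skipped when the trajectory was run with ATP
    clamped, since clamping deliberately breaks it.
    """
    if include_adenosine_pool is None:
        include_adenosine_pool = not trajectory.clamp_atp
    weights = conservation_weights(network, include_adenosine_pool=include_adenosine_pool)
    out = {}
    for name, w in weights.items():
        totals = trajectory.y @ w.astype(float)
        out[name] = float(np.max(np.abs(totals - totals[0])) / max(totals[0], floor))
    return out
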