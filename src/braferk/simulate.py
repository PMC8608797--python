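"""Time integration of the cascade ODEs and the treatment-response readouts.

The readout of record is *activated ERK*, the fraction of the total ERK pool
that is doubly phosphorylated::

    activated ERK(t) = [ppERK](t) / ERK_tot,     ERK_tot = [ERK](0)

which lies in [0, 1] because the ERK moiety is conserved.  For comparison with
clinical phospho-ERK measurements a second readout reports the change of
([pERK] + [ppERK]) at a given time relative to a drug-free baseline run, as a
signed percentage.

Concentrations span roughly six orders of magnitude (nM proteins against mM
ATP), so the system is stiff and is integrated with an implicit BDF method
using the analytic Jacobian.  Conservation of the moiety totals is verified
a posteriori on every run; a run whose totals drift beyond tolerance is an
error, never silently accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import RateConstants, conservation_residuals, derive_rhs
from .network import ReactionNetwork, build_cascade_network

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "SimulationError",
    "ConservationError",
    "simulate",
    "activated_erk",
    "phospho_erk_change",
    "CascadeModel",
    "trajectory_to_csv",
]

logger = logging.getLogger("braferk")

NM_PER_UM = 1e3
NM_PER_MM = 1e6


class SimulationError(RuntimeError):
    """Integrator failure; carries the offending doses/parameters for diagnosis."""


class ConservationError(SimulationError):
    """A conserved total drifted beyond tolerance along the trajectory."""


@dataclass(frozen=True)
class SimulationSettings:
    """Solver and output-grid configuration.

    Times are hours.  ``readout_times`` are merged into the uniform output
    grid; ``rtol``/``atol`` feed the stiff integrator (atol in nM).  With
    ``clamp_atp`` the free-ATP pool is held constant, a convenience for
    exploring the negligible-depletion regime; the default integrates the
    literal reaction system, in which ATP is slowly consumed.
    """

    t_end: float = 24.0
    readout_times: tuple[float, ...] = (8.0, 16.0, 24.0)
    n_grid: int = 193
    rtol: float = 1e-8
    atol: float = 1e-12
    clamp_atp: bool = False
    pre_equilibrate: bool = False
    pre_equilibrate_hours: float = 120.0
    conservation_tol: float = 1e-6
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")
        if any(t < 0 or t > self.t_end for t in self.readout_times):
            raise ValueError("readout times must lie within [0, t_end]")

    def grid(self) -> np.ndarray:
        t = np.linspace(0.0, self.t_end, self.n_grid)
        return np.unique(np.concatenate([t, np.asarray(self.readout_times, float)]))


@dataclass(frozen=True)
class Trajectory:
    """Integrated concentrations: time grid plus a (time × species) matrix (nM)."""

    t: np.ndarray
    y: np.ndarray
    species: tuple[str, ...]
    doses: Mapping[str, float]
    clamp_atp: bool = False
    provenance: Mapping[str, object] = field(default_factory=dict)
    residuals: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[:, self.species.index(name)]

    def at(self, time: float, name: str) -> float:
        i = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[i] - time) > 1e-9:
            raise KeyError(f"time {time} h is not on the output grid")
        return float(self.y[i, self.species.index(name)])

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.species))
        df.insert(0, "time_h", self.t)
        return df

    def tidy_frame(self) -> pd.DataFrame:
        wide = self.frame()
        tidy = wide.melt(id_vars="time_h", var_name="species", value_name="concentration")
        tidy["units"] = "nM"
        return tidy


def _compose_initial_state(network: ReactionNetwork,
                           initial_state: Mapping[str, float] | np.ndarray,
                           doses: Mapping[str, float] | None) -> np.ndarray:
    names = network.species_names
    if isinstance(initial_state, np.ndarray):
        x0 = np.array(initial_state, dtype=float)
        if x0.shape != (len(names),):
            raise ValueError("initial state vector has the wrong length")
    else:
        unknown = set(initial_state) - set(names)
        if unknown:
            raise ValueError(f"initial concentrations for unknown species: {sorted(unknown)}")
        x0 = np.zeros(len(names))
        for n, v in initial_state.items():
            x0[names.index(n)] = float(v)
    doses = dict(doses or {})
    dbf_uM = float(doses.get("dbf_uM", 0.0))
    tmt_uM = float(doses.get("tmt_uM", 0.0))
    if dbf_uM < 0 or tmt_uM < 0:
        raise ValueError("doses must be nonnegative")
    for drug, dose in (("DBF", dbf_uM), ("TMT", tmt_uM)):
        if dose > 0 and drug not in names:
            raise ValueError(f"{drug} dose given but the network excludes {drug}")
        if drug in names:
            x0[names.index(drug)] = dose * NM_PER_UM
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    return x0


def simulate(network: ReactionNetwork,
             constants: RateConstants,
             initial_state: Mapping[str, float] | np.ndarray,
             doses: Mapping[str, float] | None = None,
             settings: SimulationSettings | None = None) -> Trajectory:
    """Integrate the cascade from an all-free, unphosphorylated initial state.

    ``initial_state`` maps species names to nM (unlisted species start at 0);
    ``doses`` supplies ``dbf_uM``/``tmt_uM``, placed as free drug at t = 0
    (treatment and pathway start together unless ``settings.pre_equilibrate``
    asks for a drug-free steady state first).  The returned trajectory is on
    the settings' output grid, has verified conservation residuals, and has
    tiny negative solver undershoots clipped to zero.
    """
    settings = settings or SimulationSettings()
    rhs = derive_rhs(network, constants)
    x0 = _compose_initial_state(network, initial_state, doses)

    names = network.species_names
    atp_idx = names.index("ATP") if (settings.clamp_atp and "ATP" in names) else None

    def f(t, x):
        dx = rhs(t, x)
        if atp_idx is not None:
            dx[atp_idx] = 0.0
        return dx

    def jac(t, x):
        J = rhs.jacobian(t, x)
        if atp_idx is not None:
            J[atp_idx, :] = 0.0
        return J

    if settings.pre_equilibrate and doses:
        x0 = _pre_equilibrate(network, constants, x0, settings)
        for drug, key in (("DBF", "dbf_uM"), ("TMT", "tmt_uM")):
            if drug in names:
                x0[names.index(drug)] = float((doses or {}).get(key, 0.0)) * NM_PER_UM

    t_eval = settings.grid()
    sol = solve_ivp(f, (0.0, settings.t_end), x0, method=settings.method,
                    t_eval=t_eval, jac=jac, rtol=settings.rtol, atol=settings.atol)
    if not sol.success:
        raise SimulationError(f"integrator failed ({sol.message}); doses={dict(doses or {})}")
    y = sol.y.T

    # tiny undershoots are solver noise; anything larger is a real failure
    clip_floor = -10.0 * settings.atol
    worst = float(y.min(initial=0.0))
    if worst < clip_floor:
        raise SimulationError(
            f"negative concentration {worst:.3e} nM below the clipping floor "
            f"{clip_floor:.1e}; doses={dict(doses or {})}")

    traj = Trajectory(t=sol.t, y=y, species=names, doses=dict(doses or {}),
                      clamp_atp=settings.clamp_atp,
                      provenance={
                          "rtol": settings.rtol, "atol": settings.atol,
                          "method": settings.method, "clamp_atp": settings.clamp_atp,
                          "pre_equilibrate": settings.pre_equilibrate,
                          "n_steps": int(sol.t.size), "nfev": int(sol.nfev),
                          "njev": int(sol.njev),
                      })
    residuals = conservation_residuals(network, traj)
    worst_law = max(residuals, key=residuals.get) if residuals else None
    logger.debug("simulate doses=%s nfev=%d max residual %s=%.2e",
                 dict(doses or {}), sol.nfev,
                 worst_law, residuals.get(worst_law, 0.0) if worst_law else 0.0)
    if worst_law and residuals[worst_law] > settings.conservation_tol:
        raise ConservationError(
            f"conservation law {worst_law} drifted by {residuals[worst_law]:.2e} "
            f"(tolerance {settings.conservation_tol:.1e}); doses={dict(doses or {})}")
    y = y.copy()
    y[y < 0] = 0.0
    return replace(traj, y=y, residuals=residuals)


def _pre_equilibrate(network, constants, x0, settings):
    eq = replace(settings, pre_equilibrate=False, t_end=settings.pre_equilibrate_hours,
                 readout_times=(), n_grid=33)
    names = network.species_names
    x = np.array(x0, dtype=float)
    for drug in ("DBF", "TMT"):
        if drug in names:
            x[names.index(drug)] = 0.0
    traj = simulate(network, constants, x, doses=None, settings=eq)
    return traj.y[-1].copy()


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def _erk_moiety_weights(species: Sequence[str]) -> np.ndarray:
    """Copies of the ERK moiety carried by each species (complexes included)."""
    erk_forms = {"ERK", "pERK", "ppERK"}
    return np.array([sum(part in erk_forms for part in name.split("·"))
                     for name in species], dtype=float)


def activated_erk(trajectory: Trajectory) -> np.ndarray:
    """Activated-ERK fraction [ppERK](t)/ERK_tot, element-wise over the grid.

    ERK_tot is the conserved ERK-moiety total at t = 0, which equals [ERK](0)
    for the standard all-free, unphosphorylated initial condition.
    """
    if "ppERK" not in trajectory.species:
        raise ValueError("trajectory has no ppERK species")
    erk_tot = float(_erk_moiety_weights(trajectory.species) @ trajectory.y[0])
    if erk_tot <= 0:
        raise ValueError("ERK_tot is zero; activated ERK is undefined")
    return trajectory["ppERK"] / erk_tot


def phospho_erk_change(trajectory_drug: Trajectory, trajectory_baseline: Trajectory,
                       t: float) -> float:
    """Percent change of phospho-ERK ([pERK] + [ppERK]) at ``t`` hours versus
    the drug-free baseline; −100 means complete loss of phospho-ERK."""
    drug = trajectory_drug.at(t, "pERK") + trajectory_drug.at(t, "ppERK")
    base = trajectory_baseline.at(t, "pERK") + trajectory_baseline.at(t, "ppERK")
    if base <= 0:
        raise ValueError(f"baseline phospho-ERK is zero at t={t} h; "
                         "relative change is undefined")
    return 100.0 * (drug - base) / base


# ---------------------------------------------------------------------------
# convenience front end
# ---------------------------------------------------------------------------

class CascadeModel:
    """Bundles network, constants, baseline concentrations and settings.

    The therapy-experiment drivers use this as their single entry point; each
    call re-simulates from the standard all-free initial condition with the
    requested doses and optional BRAF/ATP overrides.
    """

    def __init__(self,
                 network: ReactionNetwork | None = None,
                 constants: RateConstants | None = None,
                 initial: Mapping[str, float] | None = None,
                 settings: SimulationSettings | None = None):
        from .config import default_initial_concentrations

        self.network = network or build_cascade_network(True, True)
        self.constants = constants or RateConstants.defaults()
        self.initial = dict(initial) if initial is not None \
            else default_initial_concentrations()
        self.settings = settings or SimulationSettings()

    def initial_state(self, braf_nM: float | None = None,
                      atp_mM: float | None = None) -> dict[str, float]:
        x = dict(self.initial)
        if braf_nM is not None:
            x["BRAF"] = float(braf_nM)
        if atp_mM is not None:
            x["ATP"] = float(atp_mM) * NM_PER_MM
        return x

    def simulate(self, dbf_uM: float = 0.0, tmt_uM: float = 0.0,
                 braf_nM: float | None = None, atp_mM: float | None = None,
                 settings: SimulationSettings | None = None,
                 t_end: float | None = None) -> Trajectory:
        settings = settings or self.settings
        if t_end is not None:
            readouts = tuple(t for t in settings.readout_times if t <= t_end)
            settings = replace(settings, t_end=t_end, readout_times=readouts)
        return simulate(self.network, self.constants,
                        self.initial_state(braf_nM, atp_mM),
                        doses={"dbf_uM": dbf_uM, "tmt_uM": tmt_uM},
                        settings=settings)

    def activated_erk_at(self, times: Sequence[float], **kwargs) -> np.ndarray:
        """Activated ERK at the requested hours (single simulation)."""
        t_end = max(times)
        traj = self.simulate(t_end=max(t_end, 1e-6), **kwargs)
        frac = activated_erk(traj)
        out = []
        for t in times:
            i = int(np.argmin(np.abs(traj.t - t)))
            out.append(float(frac[i]))
        return np.array(out)


def trajectory_to_csv(trajectory: Trajectory, path, tidy: bool = False) -> None:
    """Write a trajectory as CSV: wide matrix by default, tidy long format on
    request (columns time, species, concentration, units)."""
    df = trajectory.tidy_frame() if tidy else trajectory.frame()
    df.to_csv(path, index=False)
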