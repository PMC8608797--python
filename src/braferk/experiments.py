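"""In silico therapy experiments: dose scans, combination surfaces, isobole
synergy, resistance thresholds, and clinical dose-unit conversion.

All drivers operate on a :class:`~braferk.simulate.CascadeModel` and report
the activated-ERK fraction at fixed readout times (default 8, 16 and 24 h)
with ATP fixed at 1 mM and BRAF at 3 nM unless a scan varies them.

Synergy follows the isobologram construction: the two monotherapy doses D*
and T* that alone bring activated ERK down to a target level (0.5 by default)
are joined by a straight segment in linear dose space; a dose combination
strictly below that segment which also achieves the level is classified
synergistic, because it reaches the target effect with less than the
dose-additive requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .simulate import CascadeModel

__all__ = [
    "ScanSpec",
    "ResponseSurface",
    "SynergyResult",
    "NoAnchorError",
    "NotReached",
    "NOT_REACHED",
    "monotherapy_scan",
    "combination_grid",
    "monotherapy_anchor",
    "isobole_synergy",
    "min_resistance_threshold",
    "dbf_dose_convert",
    "DBF_MOLECULAR_WEIGHT",
    "DEFAULT_DBF_DOSES_UM",
    "DEFAULT_TMT_DOSES_UM",
]

logger = logging.getLogger("braferk")

#: Dabrafenib molecular weight, g/mol, for the µM <-> ng/mL conversion.
DBF_MOLECULAR_WEIGHT = 519.6

#: Default log-spaced dose grids (µM), spanning the clinically relevant range.
#: These are configuration choices, not measured values.
DEFAULT_DBF_DOSES_UM = tuple(np.round(np.logspace(-3, 1, 7), 6))
DEFAULT_TMT_DOSES_UM = tuple(np.round(np.logspace(-3, 0.5, 7), 6))

BASELINE_BRAF_NM = 3.0
BASELINE_ATP_MM = 1.0


@dataclass(frozen=True)
class ScanSpec:
    """A one-axis scan: vary ``axis`` over ``values`` at fixed co-factors.

    ``axis`` is one of ``braf_tot`` (nM), ``atp_tot`` (mM), ``dbf_dose`` or
    ``tmt_dose`` (µM); ``doses`` lists the monotherapy doses to overlay (µM).
    """

    axis: Literal["braf_tot", "atp_tot", "dbf_dose", "tmt_dose"]
    values: tuple[float, ...]
    doses: tuple[float, ...] = (0.0,)
    times: tuple[float, ...] = (8.0, 16.0, 24.0)
    braf_nM: float = BASELINE_BRAF_NM
    atp_mM: float = BASELINE_ATP_MM

    def __post_init__(self) -> None:
        if not self.values or any(v <= 0 for v in self.values):
            raise ValueError("axis values must be positive")
        if list(self.values) != sorted(self.values):
            raise ValueError("axis values must be sorted ascending")


def monotherapy_scan(model: CascadeModel, spec: ScanSpec,
                     drug: Literal["dbf", "tmt"]) -> pd.DataFrame:
    """Activated ERK over one varying axis for each monotherapy dose and time.

    Returns a tidy frame with columns ``axis``, ``axis_value``, ``dose_uM``,
    ``time_h`` and ``activated_erk`` (one simulation per grid point).
    """
    rows = []
    for dose in spec.doses:
        for v in spec.values:
            kw = {"braf_nM": spec.braf_nM, "atp_mM": spec.atp_mM,
                  "dbf_uM": dose if drug == "dbf" else 0.0,
                  "tmt_uM": dose if drug == "tmt" else 0.0}
            if spec.axis == "braf_tot":
                kw["braf_nM"] = v
            elif spec.axis == "atp_tot":
                kw["atp_mM"] = v
            elif spec.axis == "dbf_dose":
                kw["dbf_uM"] = v
            else:
                kw["tmt_uM"] = v
            try:
                fracs = model.activated_erk_at(spec.times, **kw)
            except Exception as exc:
                raise RuntimeError(f"simulation failed at {spec.axis}={v}, "
                                   f"{drug} dose {dose} µM") from exc
            for t, f in zip(spec.times, fracs):
                rows.append({"axis": spec.axis, "axis_value": v, "dose_uM": dose,
                             "time_h": t, "activated_erk": f})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResponseSurface:
    """Activated ERK over a DBF × TMT dose grid at one or more times.

    ``values[time]`` is a matrix with TMT doses down the rows and DBF doses
    across the columns; ``context`` records the fixed BRAF/ATP levels.
    """

    dbf_doses: tuple[float, ...]
    tmt_doses: tuple[float, ...]
    times: tuple[float, ...]
    values: Mapping[float, np.ndarray]
    context: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, m in self.values.items():
            if m.shape != (len(self.tmt_doses), len(self.dbf_doses)):
                raise ValueError(f"surface at t={t} has shape {m.shape}")

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.times:
            m = self.values[t]
            for i, tmt in enumerate(self.tmt_doses):
                for j, dbf in enumerate(self.dbf_doses):
                    rows.append({"time_h": t, "dbf_uM": dbf, "tmt_uM": tmt,
                                 "activated_erk": m[i, j]})
        return pd.DataFrame(rows)


def combination_grid(model: CascadeModel,
                     dbf_doses: Sequence[float] = DEFAULT_DBF_DOSES_UM,
                     tmt_doses: Sequence[float] = DEFAULT_TMT_DOSES_UM,
                     context: Mapping[str, float] | None = None,
                     times: Sequence[float] = (8.0, 16.0, 24.0)) -> ResponseSurface:
    """Full-factorial DBF × TMT simulation; one surface per readout time."""
    dbf_doses = tuple(dbf_doses)
    tmt_doses = tuple(tmt_doses)
    if not dbf_doses or not tmt_doses:
        raise ValueError("dose lists must be nonempty")
    if list(dbf_doses) != sorted(dbf_doses) or list(tmt_doses) != sorted(tmt_doses):
        raise ValueError("dose lists must be sorted ascending")
    ctx = {"braf_nM": BASELINE_BRAF_NM, "atp_mM": BASELINE_ATP_MM, **(context or {})}
    times = tuple(times)
    mats = {t: np.zeros((len(tmt_doses), len(dbf_doses))) for t in times}
    for i, tmt in enumerate(tmt_doses):
        for j, dbf in enumerate(dbf_doses):
            try:
                fr = model.activated_erk_at(times, dbf_uM=dbf, tmt_uM=tmt, **ctx)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed at DBF={dbf} µM, TMT={tmt} µM") from exc
            for t, f in zip(times, fr):
                mats[t][i, j] = f
    return ResponseSurface(dbf_doses, tmt_doses, times, mats, ctx)


# ---------------------------------------------------------------------------
# isobole synergy
# ---------------------------------------------------------------------------

class NoAnchorError(RuntimeError):
    """A monotherapy axis never crosses the effect level within its dose range."""

    def __init__(self, axis: str, extreme_dose: float, extreme_value: float,
                 level: float):
        self.axis, self.extreme_dose = axis, extreme_dose
        self.extreme_value, self.level = extreme_value, level
        super().__init__(
            f"no monotherapy anchor on the {axis} axis: activated ERK at the "
            f"extreme dose {extreme_dose} µM is {extreme_value:.3f}, never "
            f"reaching level {level}")


def monotherapy_anchor(model: CascadeModel, drug: Literal["dbf", "tmt"],
                       level: float = 0.5, time: float = 8.0,
                       dose_range: tuple[float, float] = (1e-4, 30.0),
                       context: Mapping[str, float] | None = None,
                       erk_tol: float = 1e-3) -> float:
    """Monotherapy dose (µM) at which activated ERK equals ``level`` at ``time``.

    The dose axis is first bracketed on a coarse logarithmic scan (monotone
    interpolation supplies the starting guess), then refined by bisection on
    the simulator until activated ERK is within ``erk_tol`` of the level.
    Raises :class:`NoAnchorError` if the response never crosses the level.
    """
    ctx = dict(context or {})

    def erk_at(dose: float) -> float:
        kw = {"dbf_uM": dose if drug == "dbf" else 0.0,
              "tmt_uM": dose if drug == "tmt" else 0.0, **ctx}
        return float(model.activated_erk_at([time], **kw)[0])

    lo, hi = dose_range
    scan = np.logspace(np.log10(lo), np.log10(hi), 9)
    vals = np.array([erk_at(d) for d in scan])
    if vals.min() > level:
        raise NoAnchorError(drug, float(scan[-1]), float(vals[-1]), level)
    if vals[0] < level:  # already below the level at the smallest dose tested
        raise NoAnchorError(drug, float(scan[0]), float(vals[0]), level)
    k = int(np.argmax(vals <= level))  # first scanned dose at/below the level
    d_lo, d_hi = float(scan[k - 1]), float(scan[k])
    # monotone (PCHIP) interpolation of ERK vs log-dose for the starting guess
    try:
        interp = PchipInterpolator(np.log10(scan), vals)
        guesses = np.linspace(np.log10(d_lo), np.log10(d_hi), 64)
        g = float(10 ** guesses[int(np.argmin(np.abs(interp(guesses) - level)))])
    except ValueError:  # non-monotone scan data; fall back to the bracket mid
        g = float(np.sqrt(d_lo * d_hi))
    f_g = erk_at(g)
    for _ in range(60):
        if abs(f_g - level) <= erk_tol:
            return g
        if f_g > level:
            d_lo = g
        else:
            d_hi = g
        g = float(np.sqrt(d_lo * d_hi))
        f_g = erk_at(g)
    return g


@dataclass(frozen=True)
class SynergyResult:
    """Per-cell synergy classification against the straight-line isobole."""

    surface: ResponseSurface
    time: float
    level: float
    dbf_anchor: float
    tmt_anchor: float
    synergistic: np.ndarray  # bool, same shape as the surface matrices

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, tmt in enumerate(self.surface.tmt_doses):
            for j, dbf in enumerate(self.surface.dbf_doses):
                rows.append({"dbf_uM": dbf, "tmt_uM": tmt,
                             "activated_erk": self.surface.values[self.time][i, j],
                             "synergistic": bool(self.synergistic[i, j])})
        return pd.DataFrame(rows)


def isobole_synergy(model: CascadeModel, surface: ResponseSurface,
                    level: float = 0.5, time: float = 8.0,
                    anchor_dose_range: tuple[float, float] = (1e-4, 30.0)) -> SynergyResult:
    """Classify each grid cell as synergistic or not.

    The additive boundary is the straight segment between the monotherapy
    anchors (D*, 0) and (0, T*) in linear dose space.  A true combination
    (both doses positive) is synergistic iff it does not lie above the
    segment (d/D* + t/T* ≤ 1) and its activated ERK is at or below the
    level: it reaches the target effect with no more than the dose-additive
    budget.  The anchors themselves are monotherapy points on the line and
    are never classified synergistic.
    """
    if time not in surface.values:
        raise KeyError(f"surface has no readout at t={time} h")
    ctx = dict(surface.context)
    d_star = monotherapy_anchor(model, "dbf", level, time, anchor_dose_range, ctx)
    t_star = monotherapy_anchor(model, "tmt", level, time, anchor_dose_range, ctx)
    m = surface.values[time]
    dbf = np.asarray(surface.dbf_doses)
    tmt = np.asarray(surface.tmt_doses)
    not_above = (dbf[None, :] / d_star + tmt[:, None] / t_star) <= 1.0 + 1e-9
    combination = (dbf[None, :] > 0) & (tmt[:, None] > 0)
    synergistic = not_above & combination & (m <= level)
    logger.info("isobole anchors at t=%g h, level %.2f: D*=%.4g µM, T*=%.4g µM",
                time, level, d_star, t_star)
    return SynergyResult(surface, time, level, d_star, t_star, synergistic)


# ---------------------------------------------------------------------------
# resistance thresholds
# ---------------------------------------------------------------------------

class NotReached:
    """Tagged sentinel: the effect level is not reached below the cap."""

    _instance: "NotReached | None" = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_REACHED"


NOT_REACHED = NotReached()

_AXIS_DEFAULTS = {
    "braf": {"cap": 20.0, "unit": "nM", "tol": 0.01},
    "atp": {"cap": 20.0, "unit": "mM", "tol": 0.001},
}


def min_resistance_threshold(model: CascadeModel, dbf_uM: float, tmt_uM: float,
                             axis: Literal["braf", "atp"], level: float = 0.5,
                             time: float = 24.0, cap: float | None = None,
                             tol: float | None = None) -> float | NotReached:
    """Smallest BRAF (nM) or ATP (mM) level sustaining activated ERK > ``level``
    at ``time`` hours under the given dose pair.

    The response is numerically monotone in the axis variable, so the
    threshold is found by bisection to absolute tolerance ``tol``; if even the
    cap does not push activated ERK past the level, the tagged
    :data:`NOT_REACHED` sentinel is returned.  A non-monotone bracket detected
    on the coarse pre-scan triggers a grid-scan fallback with a warning.
    """
    spec = _AXIS_DEFAULTS[axis]
    cap = spec["cap"] if cap is None else cap
    tol = spec["tol"] if tol is None else tol

    def erk_at(v: float) -> float:
        kw = {"braf_nM": v} if axis == "braf" else {"atp_mM": v}
        return float(model.activated_erk_at([time], dbf_uM=dbf_uM, tmt_uM=tmt_uM,
                                            **kw)[0])

    if erk_at(cap) <= level:
        return NOT_REACHED
    lo = cap / 1e4
    if erk_at(lo) > level:
        return lo  # already over the level at the smallest value probed
    # coarse scan to locate (and sanity-check) the crossing
    grid = np.geomspace(lo, cap, 9)
    vals = np.array([erk_at(v) for v in grid])
    crossings = np.nonzero((vals[:-1] <= level) & (vals[1:] > level))[0]
    if len(crossings) != 1 or np.any(np.diff(vals) < -0.05):
        logger.warning("non-monotone %s response for doses (%g, %g); "
                       "falling back to first-crossing refinement",
                       axis, dbf_uM, tmt_uM)
    k = int(crossings[0]) if len(crossings) else int(np.argmax(vals > level)) - 1
    v_lo, v_hi = float(grid[k]), float(grid[k + 1])
    while v_hi - v_lo > tol:
        mid = 0.5 * (v_lo + v_hi)
        if erk_at(mid) > level:
            v_hi = mid
        else:
            v_lo = mid
    return v_hi


def dbf_dose_convert(value: float,
                     from_unit: Literal["uM", "ng_per_mL"]) -> float:
    """Convert a dabrafenib concentration between µM and ng/mL.

    ``ng/mL = µM × 519.6`` (dabrafenib's molecular weight in g/mol); the
    round trip recovers the input to machine precision.
    """
    if value < 0:
        raise ValueError("concentration must be nonnegative")
    if from_unit == "uM":
        return value * DBF_MOLECULAR_WEIGHT
    if from_unit == "ng_per_mL":
        return value / DBF_MOLECULAR_WEIGHT
    raise ValueError(f"unknown unit {from_unit!r}; use 'uM' or 'ng_per_mL'")
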