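"""Steady states and flux-feasibility thresholds of cycling motifs.

For the single irreversible reaction with background turnover the fixed
point is closed-form: with ``alpha = Vmax,Ea - kin``,

    m0* = alpha · kin · KM,E0 / [(Vmax,E0 − kin)(Vmax,Ea·Atot − kin(KM,Ea + Atot))]
    m1* = kin / kout
    a1* = kin · KM,Ea / (Vmax,Ea − kin),    a0* = Atot − a1*

and a positive steady state exists iff both

    kin < Vmax,E0        (primary-enzyme limit)
    kin < Atot·Vmax,Ea / (KM,Ea + Atot)     (co-substrate cycling limit).

The two limits act independently: the first depends only on the primary
enzyme, the second only on the pool size and its turnover kinetics.  For all
other motifs the fixed point is found numerically: integrate until the
relative derivative is small, then polish with a root finder on the
conservation-reduced system.
"""
from __future__ import annotations

import signal
import threading
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import MotifModel, ReactionSpec

__all__ = [
    "UnsupportedMotifError",
    "SteadyStateResult",
    "ThresholdResult",
    "FeasibilityMap",
    "analytic_single_steady_state",
    "feasibility_thresholds",
    "cosubstrate_steady_fractions",
    "numeric_steady_state",
    "classify_feasibility_grid",
]


class UnsupportedMotifError(ValueError):
    """The requested closed form only exists for the single-reaction motif."""


@dataclass(frozen=True)
class SteadyStateResult:
    """A fixed point (or the verdict that none exists).

    ``status`` is one of ``steady`` / ``diverging`` / ``undecided`` /
    ``infeasible``; ``feasible`` is True only for ``steady``.  ``residual``
    is ``max |dy/dt|`` at the reported state.
    """

    feasible: bool
    concentrations: np.ndarray | None
    residual: float | None
    method: str
    status: str
    alpha: float | None = None
    diverging_species: tuple[str, ...] = ()
    t_elapsed: float | None = None


@dataclass(frozen=True)
class ThresholdResult:
    """The two independent feasibility limits on the influx rate."""

    T_enzyme: float
    T_cosubstrate: float

    @property
    def binding(self) -> str:
        if self.T_enzyme < self.T_cosubstrate:
            return "enzyme"
        if self.T_cosubstrate < self.T_enzyme:
            return "cosubstrate"
        return "tie"

    @property
    def T_binding(self) -> float:
        return min(self.T_enzyme, self.T_cosubstrate)


@dataclass(frozen=True)
class FeasibilityMap:
    """Grid classification over (Atot, kin): 1 feasible, 0 infeasible,
    -1 boundary/undecided; ``m0_star`` is NaN where no steady state."""

    Atot: np.ndarray
    kin: np.ndarray
    status: np.ndarray      # shape (len(Atot), len(kin)), int8
    m0_star: np.ndarray     # same shape, float


# ---------------------------------------------------------------------------
# Single-reaction closed forms
# ---------------------------------------------------------------------------

def _single_reaction_params(model: MotifModel):
    """Extract (E0, Ea, pool, kin, kout) from a single-reaction motif."""
    ok = (model.n_metabolites == 2 and len(model.pools) == 1
          and len(model.reactions) == 2 and len(model.boundary.influxes) == 1
          and len(model.boundary.outfluxes) == 1)
    if ok:
        primary = next((r for r in model.reactions
                        if r.substrate == 0 and r.product == 1
                        and len(r.couplings) == 1
                        and r.couplings[0].direction == +1
                        and r.couplings[0].nu == 1), None)
        background = next((r for r in model.reactions
                           if r.substrate is None and r.product is None
                           and len(r.couplings) == 1
                           and r.couplings[0].direction == -1
                           and r.couplings[0].nu == 1), None)
        pool = model.pools[0]
        ok = (primary is not None and background is not None and pool.conserved
              and not primary.enzyme.reversible and not background.enzyme.reversible)
    if not ok:
        raise UnsupportedMotifError(
            "closed-form steady state exists only for the irreversible "
            "single-reaction motif with one conserved pool")
    kin = model.boundary.influxes[0][1]
    kout = model.boundary.outfluxes[0][1]
    return primary.enzyme, background.enzyme, pool, kin, kout


def feasibility_thresholds(model: MotifModel) -> ThresholdResult:
    """Both influx limits of the single-reaction motif and which binds."""
    e0, ea, pool, _, _ = _single_reaction_params(model)
    T_enzyme = e0.Vmax
    T_cosub = pool.Atot * ea.Vmax / (ea.KM_f + pool.Atot)
    return ThresholdResult(T_enzyme=T_enzyme, T_cosubstrate=T_cosub)


def analytic_single_steady_state(model: MotifModel,
                                 kin: float | None = None) -> SteadyStateResult:
    """Closed-form fixed point of the single-reaction motif.

    Uses the model's configured influx unless ``kin`` is given.  Returns
    ``feasible=False`` (status ``infeasible``) when either limit is violated.
    """
    e0, ea, pool, kin_model, kout = _single_reaction_params(model)
    if kin is None:
        kin = kin_model
    if kin < 0:
        raise ValueError("kin must be >= 0")
    thr = feasibility_thresholds(model)
    if kin == 0.0:
        y = np.array([0.0, 0.0, pool.Atot, 0.0])
        return SteadyStateResult(True, y, float(np.max(np.abs(model.rhs(0.0, y)))),
                                 "analytic", "steady", alpha=ea.Vmax)
    if not (kin < thr.T_enzyme and kin < thr.T_cosubstrate):
        return SteadyStateResult(False, None, None, "analytic", "infeasible")
    alpha = ea.Vmax - kin
    m0 = (alpha * kin * e0.KM_f
          / ((e0.Vmax - kin) * (ea.Vmax * pool.Atot - kin * (ea.KM_f + pool.Atot))))
    m1 = kin / kout
    a1 = kin * ea.KM_f / (ea.Vmax - kin)
    a0 = pool.Atot - a1
    y = np.array([m0, m1, a0, a1])
    model_at_kin = model.with_influx(model.boundary.influxes[0][0], kin)
    residual = float(np.max(np.abs(model_at_kin.rhs(0.0, y))))
    return SteadyStateResult(True, y, residual, "analytic", "steady", alpha=alpha)


def cosubstrate_steady_fractions(model: MotifModel,
                                 kin: float | None = None) -> tuple[float, float]:
    """Steady-state split ``(a0*, a1*)`` of the pool in the single-reaction
    motif; raises for infeasible influx (a1* would exceed Atot)."""
    e0, ea, pool, kin_model, _ = _single_reaction_params(model)
    if kin is None:
        kin = kin_model
    if kin == 0.0:
        return pool.Atot, 0.0
    if kin >= ea.Vmax:
        raise ValueError("infeasible influx: kin >= Vmax of the turnover enzyme")
    a1 = kin * ea.KM_f / (ea.Vmax - kin)
    if a1 > pool.Atot:
        raise ValueError("infeasible influx: required a1* exceeds the pool size")
    return pool.Atot - a1, a1


# ---------------------------------------------------------------------------
# Numeric steady state
# ---------------------------------------------------------------------------

def _reduced_system(model: MotifModel, y_template: np.ndarray):
    """Map between the full state and one with conserved pools eliminated.

    For each conserved pool only form 0 is free; form 1 is recovered as
    ``Atot - a0``, so the polish step enforces pool totals exactly.
    """
    n_met = model.n_metabolites
    free = list(range(n_met))
    for k, p in enumerate(model.pools):
        i0 = n_met + 2 * k
        if p.conserved:
            free.append(i0)
        else:
            free.extend((i0, i0 + 1))
    free_arr = np.array(free, dtype=int)

    def expand(x: np.ndarray) -> np.ndarray:
        y = np.empty(model.n_species)
        y[free_arr] = x
        for k, p in enumerate(model.pools):
            i0 = n_met + 2 * k
            if p.conserved:
                y[i0 + 1] = p.Atot - y[i0]
        return y

    def residual(x: np.ndarray) -> np.ndarray:
        return model.rhs(0.0, expand(x))[free_arr]

    return free_arr, expand, residual


class _ChunkTimeout(Exception):
    pass


@contextmanager
def _time_limit(seconds: float | None):
    """Abort a pathologically slow integration chunk (extreme stiffness at
    the feasibility boundary can stall the ODE solver).  Uses SIGALRM, so
    it is active only in the main thread; elsewhere it is a no-op."""
    if seconds is None or threading.current_thread() is not threading.main_thread():
        yield
        return

    def _raise(signum, frame):
        raise _ChunkTimeout

    old = signal.signal(signal.SIGALRM, _raise)
    signal.setitimer(signal.ITIMER_REAL, seconds)
    try:
        yield
    finally:
        signal.setitimer(signal.ITIMER_REAL, 0.0)
        signal.signal(signal.SIGALRM, old)


def _try_polish(model: MotifModel, y: np.ndarray, residual_tol: float):
    free, expand, fun = _reduced_system(model, y)
    try:
        sol = root(fun, y[free], method="hybr", tol=1e-13)
    except Exception:
        return None
    if not sol.success:
        return None
    y_full = expand(sol.x)
    if np.min(y_full) < -1e-9:
        return None
    y_full = np.maximum(y_full, 0.0)
    res = float(np.max(np.abs(model.rhs(0.0, y_full))))
    if res > residual_tol:
        return None
    return y_full, res


def numeric_steady_state(model: MotifModel,
                         y0: np.ndarray | None = None,
                         *,
                         conv_tol: float = 1e-9,
                         conv_floor: float = 1e-12,
                         residual_tol: float = 1e-8,
                         t_max: float = 1e6,
                         cap_factor: float = 1e6,
                         conc_floor: float = 1e-3,
                         rtol: float = 1e-8,
                         atol: float = 1e-10,
                         dt0: float = 50.0,
                         chunk_time_limit: float | None = 30.0,
                         polish: bool = True) -> SteadyStateResult:
    """Numeric fixed point of any motif, with divergence detection.

    Integrates in geometrically growing chunks; after each chunk a root
    polish on the conservation-reduced system is attempted (success =
    steady, with pool totals enforced exactly).  A species is classified
    diverging when it exceeds ``cap_factor`` times its initial scale with
    positive derivative, or — catching slow unbounded accumulation early —
    when it has risen monotonically and substantially over three
    consecutive chunks, is still rising, sits well above its initial
    scale, and no fixed point could be located from the trajectory.
    Reaching ``t_max`` (or an integrator breakdown) without a verdict
    gives the ``undecided`` status, not an exception.
    """
    y = model.initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()
    if y.shape != (model.n_species,):
        raise ValueError("y0 has wrong dimension")
    scale = np.maximum(np.abs(y), conc_floor)
    cap = cap_factor * scale
    t = 0.0
    dt = dt0
    growth_streak = np.zeros(model.n_species, dtype=int)
    while t < t_max:
        dt = min(dt, t_max - t)
        y_prev = y
        sol = None
        for method in ("LSODA", "BDF"):     # BDF retry when LSODA stalls
            try:
                with _time_limit(chunk_time_limit):
                    sol = solve_ivp(model.rhs, (t, t + dt), y, method=method,
                                    rtol=rtol, atol=atol, t_eval=(t + dt,))
                break
            except _ChunkTimeout:
                sol = None
            except Exception:
                return SteadyStateResult(False, None, None, "numeric",
                                         "undecided", t_elapsed=t)
        if sol is None:
            sol = type("_fail", (), {"success": False, "y": np.empty(0)})()
        if not sol.success or sol.y.size == 0:
            # integrator breakdown (extreme stiffness near the feasibility
            # boundary); try one last polish, else report undecided
            if polish:
                polished = _try_polish(model, y, residual_tol)
                if polished is not None:
                    return SteadyStateResult(True, polished[0], polished[1],
                                             "numeric", "steady", t_elapsed=t)
            return SteadyStateResult(False, None, None, "numeric", "undecided",
                                     t_elapsed=t)
        y = np.maximum(sol.y[:, -1], 0.0)
        t += dt
        dy = model.rhs(t, y)
        over = (y > cap) & (dy > 0)
        if np.any(over):
            names = tuple(model.species_names[i] for i in np.flatnonzero(over))
            return SteadyStateResult(False, None, None, "numeric", "diverging",
                                     diverging_species=names, t_elapsed=t)
        polished = _try_polish(model, y, residual_tol) if polish else None
        if polished is not None:
            return SteadyStateResult(True, polished[0], polished[1],
                                     "numeric", "steady", t_elapsed=t)
        rel = float(np.max(np.abs(dy) / np.maximum(np.abs(y), conv_floor)))
        if rel < conv_tol:
            res = float(np.max(np.abs(dy)))
            status_ok = res < residual_tol
            return SteadyStateResult(status_ok, y, res, "numeric",
                                     "steady" if status_ok else "undecided",
                                     t_elapsed=t)
        rising = (y > 1.2 * np.maximum(y_prev, conv_floor)) & (dy > 0) \
            & (y > 10.0 * scale)
        growth_streak = np.where(rising, growth_streak + 1, 0)
        if np.any(growth_streak >= 3):
            names = tuple(model.species_names[i]
                          for i in np.flatnonzero(growth_streak >= 3))
            return SteadyStateResult(False, None, None, "numeric", "diverging",
                                     diverging_species=names, t_elapsed=t)
        dt *= 4.0
        # land the next chunk end just past any predicted cap crossing, so
        # unbounded accumulation is caught at a chunk boundary
        growing = dy > 0
        if np.any(growing):
            t_to_cap = float(np.min((cap[growing] - y[growing]) / dy[growing]))
            dt = min(dt, max(dt0, 1.2 * t_to_cap))
    return SteadyStateResult(False, None, None, "numeric", "undecided", t_elapsed=t)


# ---------------------------------------------------------------------------
# Feasibility grid
# ---------------------------------------------------------------------------

def classify_feasibility_grid(model: MotifModel,
                              Atot_grid: np.ndarray,
                              kin_grid: np.ndarray,
                              *,
                              pool_id: str | None = None,
                              influx_species: int | None = None,
                              t_max: float = 1e6,
                              **options) -> FeasibilityMap:
    """Numeric feasibility and m0* over an (Atot, kin) grid.

    Each cell is classified with :func:`numeric_steady_state`; cells that
    remain undecided at ``t_max`` are flagged -1 (boundary).  For the
    single-reaction motif the 0/1 classification matches the analytic
    inequalities away from the boundary curves.
    """
    Atot_grid = np.asarray(Atot_grid, dtype=float)
    kin_grid = np.asarray(kin_grid, dtype=float)
    if np.any(Atot_grid <= 0) or np.any(kin_grid < 0):
        raise ValueError("grids must be positive (kin may include 0)")
    if pool_id is None:
        pool_id = model.pools[0].pool_id
    if influx_species is None:
        influx_species = model.boundary.influxes[0][0]
    options = {"rtol": 1e-7, "atol": 1e-9, "dt0": 200.0,
               "chunk_time_limit": 5.0, **options}
    status = np.full((Atot_grid.size, kin_grid.size), -1, dtype=np.int8)
    m0 = np.full(status.shape, np.nan)
    for i, Atot in enumerate(Atot_grid):
        m_a = model.with_pool_size(pool_id, Atot)
        for j, kin in enumerate(kin_grid):
            cell = m_a.with_influx(influx_species, kin)
            res = numeric_steady_state(cell, t_max=t_max, **options)
            if res.status == "steady":
                status[i, j] = 1
                m0[i, j] = res.concentrations[0]
            elif res.status == "diverging":
                status[i, j] = 0
    return FeasibilityMap(Atot_grid, kin_grid, status, m0)
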