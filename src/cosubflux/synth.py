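"""Synthetic inputs: physiologically ranged motif parameters, flux-survey
tables with planted structure, and stochastic influx schedules.

The survey generator emulates the structure of condition-resolved flux
screens of E. coli central carbon metabolism: ~45 reactions observed under
7 growth conditions, flux values from direct measurement or from flux
balance analysis (FBA), each reaction tied to an ATP, NADH or NADPH pool
whose size varies across conditions.  Structure is *planted* — a chosen
fraction of records sits below the enzyme kinetic limit E·kcat, and a
chosen subset of reactions has flux linear in pool size — so that the
screening stage can be tested by exact recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (EnzymeParams, PoolSpec, build_single_reaction_model,
                    build_branched_model, build_coupled_model,
                    build_linear_pathway_model, MotifModel)
from .survey import FluxRecord

__all__ = [
    "ParamRanges",
    "SurveyPlan",
    "InfluxNoiseProcess",
    "InfluxSchedule",
    "REFERENCE_SINGLE",
    "sample_model_params",
    "build_model_from_params",
    "generate_survey_dataset",
    "generate_influx_schedule",
]

#: Reference single-reaction parameter set (mM, s): primary enzyme
#: Etot = 0.01 mM, kcat = 100 /s, KM = 0.05 (composite, mM²); outflux
#: 0.1 /s; background turnover enzyme at 1.2x the primary Vmax.
REFERENCE_SINGLE = {
    "Etot": 0.01, "kcat": 100.0, "KM": 0.05, "kout": 0.1,
    "background_factor": 1.2, "Atot": 1.0,
}


@dataclass(frozen=True)
class ParamRanges:
    """Log-uniform sampling ranges for motif kinetic parameters.

    Defaults span roughly two orders of magnitude around the reference
    values above; they are package conventions for a physiological range,
    chosen once (enzyme concentrations 1 µM – 0.1 mM, turnover numbers
    1–1000 /s, Michaelis constants 1 µM – 1 mM, pools 10 µM – 10 mM).
    """

    Etot: tuple[float, float] = (1e-3, 0.1)
    kcat: tuple[float, float] = (1.0, 1000.0)
    KM: tuple[float, float] = (1e-3, 1.0)
    kout: tuple[float, float] = (0.01, 1.0)
    Atot: tuple[float, float] = (0.01, 10.0)

    def __post_init__(self) -> None:
        for name in ("Etot", "kcat", "KM", "kout", "Atot"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"range {name} must satisfy 0 < lo <= hi")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_model_params(ranges: ParamRanges, motif: str = "single", *,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        background_factor: float = 1.2,
                        kin_mode: str = "feasible") -> dict:
    """Draw one motif parameter configuration (log-uniform, seeded).

    The influx rate is placed relative to the binding feasibility limit:
    ``kin_mode='feasible'`` draws kin log-uniformly in [0.05, 0.90] of the
    limit, ``'infeasible'`` in [1.05, 2.0], ``'none'`` leaves kin at a
    nominal 0.1 of the enzyme limit.  Degenerate ranges (lo == hi) return
    that exact value, so collapsing all ranges onto the reference values
    reproduces the reference configuration.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = {
        "motif": motif,
        "Etot": _loguniform(rng, *ranges.Etot),
        "kcat": _loguniform(rng, *ranges.kcat),
        "KM": _loguniform(rng, *ranges.KM),
        "kout": _loguniform(rng, *ranges.kout),
        "Atot": _loguniform(rng, *ranges.Atot),
        "background_factor": background_factor,
    }
    Vmax = cfg["Etot"] * cfg["kcat"]
    Vmax_bg = background_factor * Vmax
    T_enzyme = Vmax
    T_cosub = cfg["Atot"] * Vmax_bg / (cfg["KM"] + cfg["Atot"])
    T = min(T_enzyme, T_cosub)
    if kin_mode == "feasible":
        cfg["kin"] = T * _loguniform(rng, 0.05, 0.90)
    elif kin_mode == "infeasible":
        cfg["kin"] = T * _loguniform(rng, 1.05, 2.0)
    elif kin_mode == "none":
        cfg["kin"] = 0.1 * T_enzyme
    else:
        raise ValueError(f"unknown kin_mode '{kin_mode}'")
    return cfg


def build_model_from_params(cfg: dict) -> MotifModel:
    """Instantiate the motif named in a sampled configuration."""
    motif = cfg.get("motif", "single")
    enz = EnzymeParams(kcat=cfg["kcat"], Etot=cfg["Etot"], KM_f=cfg["KM"])
    if motif == "single":
        bg = EnzymeParams(kcat=cfg["kcat"],
                          Etot=cfg["background_factor"] * cfg["Etot"],
                          KM_f=cfg["KM"])
        return build_single_reaction_model(
            enzyme_primary=enz, enzyme_background=bg,
            pool=PoolSpec("A", cfg["Atot"]), kin=cfg["kin"], kout=cfg["kout"])
    if motif == "linear":
        n = int(cfg.get("n", 4))
        return build_linear_pathway_model(
            n, [(2, min(n, 4), "A", 1)] if n >= 3 else [(1, n, "A", 1)],
            enzymes=enz, pools=[PoolSpec("A", cfg["Atot"])],
            kin=cfg["kin"], kout=cfg["kout"])
    if motif == "branched":
        return build_branched_model(Atot=cfg["Atot"],
                                    Btot=cfg.get("Btot", cfg["Atot"]),
                                    kin=cfg["kin"], kout=cfg["kout"])
    if motif == "coupled":
        return build_coupled_model(Atot=cfg["Atot"], kin1=cfg["kin"],
                                   kin2=cfg["kin"], kout=cfg["kout"])
    raise ValueError(f"unknown motif '{motif}'")


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------

_COSUBSTRATES = ("ATP", "NADH", "NADPH")


@dataclass(frozen=True)
class SurveyPlan:
    """Blueprint for a planted flux-survey table.

    Defaults mirror the structure of the condition-resolved E. coli screen:
    45 reactions × 7 conditions, ~80% of records below the enzyme limit,
    7 reactions with directly measured fluxes (49 measured records, the
    rest FBA-derived) including 3 whose flux is linear in pool size.
    """

    n_reactions: int = 45
    n_conditions: int = 7
    fraction_below_target: float = 0.8
    n_correlated: int = 3
    correlated_slope: float = 2.0
    correlated_noise_sd: float = 0.02
    n_measured_reactions: int = 7
    v_rel_sd: float = 0.1
    with_dG: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_below_target <= 1.0:
            raise ValueError("fraction_below_target must be in [0, 1]")
        if self.n_correlated > self.n_measured_reactions:
            raise ValueError("correlated reactions must be among the measured ones")
        if self.n_measured_reactions > self.n_reactions:
            raise ValueError("n_measured_reactions exceeds n_reactions")


def generate_survey_dataset(plan: SurveyPlan, seed: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> list[FluxRecord]:
    """Generate one planted survey table as a list of records.

    The realized below-the-enzyme-limit fraction equals
    ``round(target · N) / N`` exactly, for both the raw enzyme limit
    E·kcat·3600 and the substrate-saturation-corrected limit (records
    assigned "below" sit under the corrected limit; "above" records sit at
    or over the raw limit).  Correlated reactions get flux
    ``slope · pool · (1 + eps)``, eps ~ N(0, noise_sd), with enzyme levels
    raised so the planted linearity survives the below assignment.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_total = plan.n_reactions * plan.n_conditions
    n_below = int(round(plan.fraction_below_target * n_total))

    reaction_ids = [f"R{i + 1:02d}" for i in range(plan.n_reactions)]
    conditions = [f"C{j + 1}" for j in range(plan.n_conditions)]
    correlated = set(range(plan.n_correlated))
    measured = set(range(plan.n_measured_reactions))

    # Assign below/above per record; correlated reactions are forced below
    # (their planted line must not be clipped) and count toward the quota.
    n_forced = plan.n_correlated * plan.n_conditions
    if n_below < n_forced:
        raise ValueError("fraction_below_target too small to keep the "
                         "correlated reactions below the limit")
    other_cells = [(i, j) for i in range(plan.n_reactions) if i not in correlated
                   for j in range(plan.n_conditions)]
    pick = rng.choice(len(other_cells), size=n_below - n_forced, replace=False)
    below = {other_cells[k] for k in pick}
    below.update((i, j) for i in correlated for j in range(plan.n_conditions))

    records: list[FluxRecord] = []
    for i, rid in enumerate(reaction_ids):
        kcat = _loguniform(rng, 10.0, 1000.0)
        KM_sub = _loguniform(rng, 0.01, 1.0)
        E = _loguniform(rng, 1e-6, 1e-3)
        s_conc = np.array([_loguniform(rng, 0.05, 10.0)
                           for _ in range(plan.n_conditions)])
        pool = np.array([_loguniform(rng, 0.1, 10.0)
                         for _ in range(plan.n_conditions)])
        sat = s_conc / (KM_sub + s_conc)

        if i in correlated:
            v = plan.correlated_slope * pool * (
                1.0 + plan.correlated_noise_sd * rng.standard_normal(plan.n_conditions))
            v = np.abs(v)
            # raise E so every planted point is under the corrected limit
            E = 2.0 * float(np.max(v / (kcat * 3600.0 * sat)))
            limit = E * kcat * 3600.0
        else:
            limit = E * kcat * 3600.0
            v = np.empty(plan.n_conditions)
            for j in range(plan.n_conditions):
                if (i, j) in below:
                    v[j] = rng.uniform(0.05, 0.95) * limit * sat[j]
                else:
                    v[j] = limit * (1.0 + rng.uniform(0.05, 0.5))

        source = "measured" if i in measured else "FBA"
        cosub = _COSUBSTRATES[i % len(_COSUBSTRATES)]
        for j, cond in enumerate(conditions):
            records.append(FluxRecord(
                reaction_id=rid, condition=cond, source=source,
                v=float(v[j]), v_sd=float(plan.v_rel_sd * v[j]),
                E=float(E), kcat=float(kcat), KM_sub=float(KM_sub),
                s_conc=float(s_conc[j]), cosubstrate=cosub,
                pool=float(pool[j]), pool_sd=float(0.1 * pool[j]),
                dG_prime=float(rng.normal(-20.0, 15.0)) if plan.with_dG else None,
            ))
    return records


# ---------------------------------------------------------------------------
# Influx noise schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfluxNoiseProcess:
    """Piecewise-constant two-channel influx noise.

    Waiting times between switches are Exponential with mean ``tau`` (s).
    At each switch the log ratio of the two influxes is drawn from a
    standard normal, z ~ N(0, 1), and the pair is scaled so its mean stays
    at ``mean_kin``: arithmetic constraint kin1 + kin2 = 2·mean_kin (the
    default), or geometric constraint sqrt(kin1·kin2) = mean_kin.
    """

    tau: float
    mean_kin: float = 0.1
    seed: int | None = None
    mean_mode: str = "arithmetic"

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not self.mean_kin > 0:
            raise ValueError("mean_kin must be > 0")
        if self.mean_mode not in ("arithmetic", "geometric"):
            raise ValueError("mean_mode must be 'arithmetic' or 'geometric'")


@dataclass(frozen=True)
class InfluxSchedule:
    """Switch times with the (kin1, kin2) pair adopted at each switch.

    The influxes start symmetric at ``initial`` until the first switch.
    """

    initial: tuple[float, float]
    times: np.ndarray
    kin1: np.ndarray
    kin2: np.ndarray

    def __len__(self) -> int:
        return self.times.size


def _pair_from_z(z: float, mean_kin: float, mode: str) -> tuple[float, float]:
    if mode == "arithmetic":
        k1 = 2.0 * mean_kin * math.exp(z) / (1.0 + math.exp(z))
        return k1, 2.0 * mean_kin - k1
    return mean_kin * math.exp(z / 2.0), mean_kin * math.exp(-z / 2.0)


def generate_influx_schedule(process: InfluxNoiseProcess, t_max: float,
                             rng: np.random.Generator | None = None
                             ) -> InfluxSchedule:
    """Draw the event schedule for one noisy-influx simulation.

    The number of switches in [0, t_max] is Poisson with mean t_max / tau.
    A fixed seed gives a bit-reproducible schedule.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if rng is None:
        rng = np.random.default_rng(process.seed)
    times, k1s, k2s = [], [], []
    t = rng.exponential(process.tau)
    while t < t_max:
        z = rng.standard_normal()
        k1, k2 = _pair_from_z(z, process.mean_kin, process.mean_mode)
        times.append(t)
        k1s.append(k1)
        k2s.append(k2)
        t += rng.exponential(process.tau)
    return InfluxSchedule(initial=(process.mean_kin, process.mean_kin),
                          times=np.array(times), kin1=np.array(k1s),
                          kin2=np.array(k2s))
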