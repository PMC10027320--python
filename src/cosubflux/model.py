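"""Reaction-motif models of co-substrate (conserved-moiety) cycling.

A *co-substrate* is a metabolite such as ATP/ADP or NAD(P)H/NAD(P)+ that is
interconverted between two forms by different reactions.  When its synthesis
and degradation are slow, the total concentration across both forms — the
*pool size* ``Atot`` — is a conserved moiety of the kinetic model, and the
cycling couples otherwise unrelated reactions.

This module defines the domain types (enzymes, pools, reactions, boundary
fluxes), Michaelis–Menten rate laws on composite substrate concentrations,
and builders for the four canonical motifs:

* a single irreversible reaction with background co-substrate turnover,
* a linear pathway with intra-pathway cycling,
* two branches from one precursor, each coupled to its own pool,
* two independent pathways coupled through one shared pool.

State ordering is ``[m0 .. mn, a0, a1, b0, b1, ...]``: pathway metabolites
first, then the two forms of each pool in declaration order.  Concentrations
are in mM, time in s, rates in mM/s throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "EnzymeParams",
    "PoolSpec",
    "PoolCoupling",
    "ReactionSpec",
    "BoundarySpec",
    "MotifModel",
    "mm_rate",
    "composite_mm_rate",
    "reversible_mm_rate",
    "build_single_reaction_model",
    "build_linear_pathway_model",
    "build_branched_model",
    "build_coupled_model",
    "model_rhs",
    "validate_model",
]


class ConfigError(ValueError):
    """A model configuration violates an invariant of the motif family."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic constants of one enzyme.

    ``Vmax = kcat * Etot`` (mM/s).  ``KM_f`` is the (possibly composite)
    Michaelis constant dividing the *product* of the forward substrate
    concentrations; for a reaction coupled to a pool it therefore carries
    units of mM².  Reverse-direction constants exist iff ``reversible``.
    """

    kcat: float
    Etot: float
    KM_f: float
    reversible: bool = False
    kcat_r: float | None = None
    KM_r: float | None = None

    def __post_init__(self) -> None:
        for name in ("kcat", "Etot", "KM_f"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"EnzymeParams.{name} must be > 0")
        if self.reversible:
            if self.kcat_r is None or self.KM_r is None:
                raise ConfigError("reversible enzyme requires kcat_r and KM_r")
            if not (self.kcat_r > 0 and self.KM_r > 0):
                raise ConfigError("kcat_r and KM_r must be > 0")
        elif self.kcat_r is not None or self.KM_r is not None:
            raise ConfigError("kcat_r/KM_r given but reversible=False")

    @property
    def Vmax(self) -> float:
        return self.kcat * self.Etot

    @property
    def Vmax_r(self) -> float:
        return self.kcat_r * self.Etot if self.reversible else 0.0

    @classmethod
    def from_vmax(cls, Vmax: float, KM_f: float, *, Etot: float = 1.0,
                  Vmax_r: float | None = None, KM_r: float | None = None) -> "EnzymeParams":
        """Convenience constructor when only Vmax (not kcat, Etot) matters."""
        if Vmax_r is None:
            return cls(kcat=Vmax / Etot, Etot=Etot, KM_f=KM_f)
        return cls(kcat=Vmax / Etot, Etot=Etot, KM_f=KM_f,
                   reversible=True, kcat_r=Vmax_r / Etot, KM_r=KM_r)


@dataclass(frozen=True)
class PoolSpec:
    """A cycled co-substrate with total size ``Atot`` split over two forms.

    With ``ksyn0 = ksyn1 = kdeg = 0`` the total ``a0 + a1`` is a conserved
    quantity of the ODE system.  With synthesis/degradation enabled the total
    relaxes to ``(ksyn0 + ksyn1) / kdeg``.
    """

    pool_id: str
    Atot: float
    init_fraction0: float = 0.5
    ksyn0: float = 0.0
    ksyn1: float = 0.0
    kdeg: float = 0.0

    def __post_init__(self) -> None:
        if not self.Atot > 0:
            raise ConfigError(f"pool '{self.pool_id}': Atot must be > 0")
        if not 0.0 <= self.init_fraction0 <= 1.0:
            raise ConfigError(f"pool '{self.pool_id}': init_fraction0 not in [0, 1]")
        if min(self.ksyn0, self.ksyn1, self.kdeg) < 0:
            raise ConfigError(f"pool '{self.pool_id}': negative synthesis/degradation rate")
        if (self.ksyn0 > 0 or self.ksyn1 > 0) and self.kdeg == 0:
            raise ConfigError(f"pool '{self.pool_id}': synthesis without degradation diverges")

    @property
    def conserved(self) -> bool:
        return self.ksyn0 == 0.0 and self.ksyn1 == 0.0 and self.kdeg == 0.0


@dataclass(frozen=True)
class PoolCoupling:
    """Coupling of a reaction to one pool.

    ``direction = +1``: each catalytic event converts ``nu`` molecules of
    form 0 into form 1 (the reaction *consumes* form 0); ``-1`` the reverse.
    """

    pool_id: str
    direction: int
    nu: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ConfigError("PoolCoupling.direction must be +1 or -1")
        if not (isinstance(self.nu, (int, np.integer)) and self.nu >= 1):
            raise ConfigError("PoolCoupling.nu must be an integer >= 1")


@dataclass(frozen=True)
class ReactionSpec:
    """One enzymatic conversion, optionally coupled to pools.

    ``substrate``/``product`` are pathway-metabolite indices or ``None``.
    A reaction with neither is a *background* pool-turnover reaction (it
    converts pool forms only).  At most two couplings are supported, which
    covers interlinked cycling of two pools by one background enzyme.
    """

    substrate: int | None
    product: int | None
    enzyme: EnzymeParams
    couplings: tuple[PoolCoupling, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "couplings", tuple(self.couplings))
        if self.substrate is not None and self.substrate == self.product:
            raise ConfigError("reaction substrate and product must differ")
        if self.substrate is None and self.product is None and not self.couplings:
            raise ConfigError("background reaction needs at least one pool coupling")
        if len(self.couplings) > 2:
            raise ConfigError("at most two pool couplings per reaction")


@dataclass(frozen=True)
class BoundarySpec:
    """Zeroth-order influxes (mM/s) and first-order outfluxes (1/s)."""

    influxes: tuple[tuple[int, float], ...]
    outfluxes: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "influxes", tuple((int(i), float(k)) for i, k in self.influxes))
        object.__setattr__(self, "outfluxes", tuple((int(i), float(k)) for i, k in self.outfluxes))
        if any(k < 0 for _, k in self.influxes):
            raise ConfigError("influx rate kin must be >= 0")
        if any(k < 0 for _, k in self.outfluxes):
            raise ConfigError("outflux rate kout must be >= 0")


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def mm_rate(enzyme: EnzymeParams, s: float) -> float:
    """Irreversible Michaelis–Menten rate ``Vmax s / (KM + s)`` in mM/s.

    ``s`` may be a single concentration or a composite concentration product.
    """
    if np.any(np.asarray(s) < 0):
        raise ValueError("negative concentration")
    return enzyme.Vmax * s / (enzyme.KM_f + s)


def composite_mm_rate(enzyme: EnzymeParams, a: float, m: float) -> float:
    """Rate ``Vmax·a·m/(KM + a·m)`` for a reaction consuming both a pool
    form ``a`` and a pathway metabolite ``m`` (KM composite, mM²)."""
    if np.any(np.asarray(a) < 0) or np.any(np.asarray(m) < 0):
        raise ValueError("negative concentration")
    return mm_rate(enzyme, a * m)


def reversible_mm_rate(enzyme: EnzymeParams, s_fwd: float, s_rev: float) -> float:
    """Net rate of a one-site reversible Michaelis–Menten conversion.

    ``(Vmax_f·s_fwd/KM_f − Vmax_r·s_rev/KM_r) / (1 + s_fwd/KM_f + s_rev/KM_r)``
    on the composite forward/reverse concentration products.  Reduces to the
    irreversible law as the reverse terms vanish.
    """
    if np.any(np.asarray(s_fwd) < 0) or np.any(np.asarray(s_rev) < 0):
        raise ValueError("negative concentration")
    rf = s_fwd / enzyme.KM_f
    if enzyme.reversible:
        rr = s_rev / enzyme.KM_r
        return (enzyme.Vmax * rf - enzyme.Vmax_r * rr) / (1.0 + rf + rr)
    return enzyme.Vmax * rf / (1.0 + rf)


# ---------------------------------------------------------------------------
# MotifModel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifModel:
    """A reaction network over pathway metabolites plus cycled pool forms."""

    n_metabolites: int
    pools: tuple[PoolSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    boundary: BoundarySpec
    species_names: tuple[str, ...] = ()
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        pool_ids = [p.pool_id for p in self.pools]
        if len(set(pool_ids)) != len(pool_ids):
            raise ConfigError("duplicate pool ids")
        for rxn in self.reactions:
            for c in rxn.couplings:
                if c.pool_id not in pool_ids:
                    raise ConfigError(f"coupling references unknown pool '{c.pool_id}'")
            for idx in (rxn.substrate, rxn.product):
                if idx is not None and not 0 <= idx < self.n_metabolites:
                    raise ConfigError(f"reaction metabolite index {idx} out of range")
        for idx, _ in (*self.boundary.influxes, *self.boundary.outfluxes):
            if not 0 <= idx < self.n_metabolites:
                raise ConfigError(f"boundary species index {idx} out of range")
        if not self.species_names:
            names = [f"M{i}" for i in range(self.n_metabolites)]
            for p in self.pools:
                names += [f"{p.pool_id}0", f"{p.pool_id}1"]
            object.__setattr__(self, "species_names", tuple(names))
        if len(self.species_names) != self.n_species:
            raise ConfigError("species_names length does not match state dimension")

    # -- structure ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.n_metabolites + 2 * len(self.pools)

    def pool_index(self, pool_id: str) -> int:
        """Index of form 0 of the pool in the state vector."""
        for k, p in enumerate(self.pools):
            if p.pool_id == pool_id:
                return self.n_metabolites + 2 * k
        raise KeyError(pool_id)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(name) from None

    def initial_state(self, metabolites: Sequence[float] | None = None) -> np.ndarray:
        """Default start: metabolites at 0, each pool split by init_fraction0."""
        y = np.zeros(self.n_species)
        if metabolites is not None:
            y[: self.n_metabolites] = np.asarray(metabolites, dtype=float)
        for k, p in enumerate(self.pools):
            i0 = self.n_metabolites + 2 * k
            y[i0] = p.Atot * p.init_fraction0
            y[i0 + 1] = p.Atot * (1.0 - p.init_fraction0)
        return y

    # -- variants for parameter scans --------------------------------------

    def with_pool_size(self, pool_id: str, Atot: float) -> "MotifModel":
        pools = tuple(replace(p, Atot=Atot) if p.pool_id == pool_id else p
                      for p in self.pools)
        return replace(self, pools=pools)

    def with_influx(self, species: int, kin: float) -> "MotifModel":
        influxes = tuple((i, kin if i == species else k) for i, k in self.boundary.influxes)
        return replace(self, boundary=replace(self.boundary, influxes=influxes))

    def with_influxes(self, values: Mapping[int, float]) -> "MotifModel":
        influxes = tuple((i, values.get(i, k)) for i, k in self.boundary.influxes)
        return replace(self, boundary=replace(self.boundary, influxes=influxes))

    # -- dynamics ----------------------------------------------------------

    def reaction_rate(self, rxn: ReactionSpec, y: np.ndarray) -> float:
        """Instantaneous net rate of one reaction at state ``y`` (mM/s)."""
        s_fwd = 1.0 if rxn.substrate is None else y[rxn.substrate]
        s_rev = 1.0 if rxn.product is None else y[rxn.product]
        for c in rxn.couplings:
            i0 = self.pool_index(c.pool_id)
            a0, a1 = y[i0], y[i0 + 1]
            consumed, produced = (a0, a1) if c.direction == +1 else (a1, a0)
            s_fwd *= consumed ** c.nu
            s_rev *= produced ** c.nu
        if rxn.enzyme.reversible:
            return reversible_mm_rate(rxn.enzyme, s_fwd, s_rev)
        return mm_rate(rxn.enzyme, s_fwd)

    def reaction_rates(self, y: np.ndarray) -> np.ndarray:
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return np.array([self.reaction_rate(r, y) for r in self.reactions])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivatives at state ``y``.

        Tiny negative excursions produced by the integrator are clipped to
        zero when evaluating rate laws; the derivative is returned for the
        state as given, so pool conservation holds to machine precision.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_species,):
            raise ValueError(f"state dimension {y.shape} != ({self.n_species},)")
        yc = np.maximum(y, 0.0)
        dy = np.zeros_like(yc)
        for rxn in self.reactions:
            rate = self.reaction_rate(rxn, yc)
            if rxn.substrate is not None:
                dy[rxn.substrate] -= rate
            if rxn.product is not None:
                dy[rxn.product] += rate
            for c in rxn.couplings:
                i0 = self.pool_index(c.pool_id)
                dy[i0] -= c.direction * c.nu * rate
                dy[i0 + 1] += c.direction * c.nu * rate
        for i, kin in self.boundary.influxes:
            dy[i] += kin
        for i, kout in self.boundary.outfluxes:
            dy[i] -= kout * yc[i]
        for k, p in enumerate(self.pools):
            if not p.conserved:
                i0 = self.n_metabolites + 2 * k
                dy[i0] += p.ksyn0 - p.kdeg * yc[i0]
                dy[i0 + 1] += p.ksyn1 - p.kdeg * yc[i0 + 1]
        return dy


def model_rhs(model: MotifModel, state: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Functional wrapper around :meth:`MotifModel.rhs`."""
    return model.rhs(t, state)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_single_reaction_model(*, enzyme_primary: EnzymeParams,
                                enzyme_background: EnzymeParams,
                                pool: PoolSpec,
                                kin: float, kout: float) -> MotifModel:
    """Single reaction M0 + A0 -> M1 + A1 with background turnover A1 -> A0.

    The primary enzyme (E0) acts on the composite concentration ``a0·m0``;
    the background enzyme (Ea) regenerates form 0 from form 1.  Influx of M0
    at ``kin`` (mM/s) and first-order outflux of M1 at ``kout`` (1/s).
    """
    reactions = (
        ReactionSpec(0, 1, enzyme_primary,
                     (PoolCoupling(pool.pool_id, +1),), name="primary"),
        ReactionSpec(None, None, enzyme_background,
                     (PoolCoupling(pool.pool_id, -1),), name="background"),
    )
    boundary = BoundarySpec(influxes=((0, kin),), outfluxes=((1, kout),))
    return MotifModel(2, (pool,), reactions, boundary,
                      metadata={"motif": "single", "primary_reaction": 0,
                                "background_reaction": 1})


def build_linear_pathway_model(n: int,
                               cycling: Sequence[tuple],
                               *,
                               enzymes: EnzymeParams | Sequence[EnzymeParams],
                               pools: Sequence[PoolSpec],
                               kin: float, kout: float,
                               background_turnover: Mapping[str, EnzymeParams] | None = None,
                               ) -> MotifModel:
    """Chain M0 -> M1 -> ... -> Mn with intra-pathway co-substrate cycling.

    ``cycling`` entries are ``(consume_step, regenerate_step, pool_id, nu)``
    with steps numbered 1..n (step i converts M_{i-1} to M_i).  The consuming
    step converts ``nu`` copies of form 0 to form 1 per event; the
    regenerating step does the reverse, so each entry closes the cycle.
    ``regenerate_step`` may be ``None`` only when a ``background_turnover``
    enzyme is supplied for that pool (pool regenerated outside the pathway).
    """
    if n < 1:
        raise ConfigError("linear pathway needs n >= 1")
    if isinstance(enzymes, EnzymeParams):
        enzymes = [enzymes] * n
    enzymes = list(enzymes)
    if len(enzymes) != n:
        raise ConfigError(f"expected {n} enzymes, got {len(enzymes)}")
    background_turnover = dict(background_turnover or {})
    pool_ids = {p.pool_id for p in pools}

    step_couplings: dict[int, list[PoolCoupling]] = {}
    balance: dict[str, int] = {p.pool_id: 0 for p in pools}
    for entry in cycling:
        consume, regen, pool_id, nu = entry
        if pool_id not in pool_ids:
            raise ConfigError(f"cycling references unknown pool '{pool_id}'")
        for step, direction in ((consume, +1), (regen, -1)):
            if step is None:
                continue
            if not 1 <= step <= n:
                raise ConfigError(f"cycling step {step} outside 1..{n}")
            step_couplings.setdefault(step, []).append(
                PoolCoupling(pool_id, direction, nu))
            balance[pool_id] += direction * nu
        if consume is not None and consume == regen:
            raise ConfigError("consume_step and regenerate_step must differ")
    for pool_id, net in balance.items():
        if net != 0 and pool_id not in background_turnover:
            raise ConfigError(
                f"pool '{pool_id}' not conserved: net cycling stoichiometry {net} "
                "with no background turnover")

    reactions = [
        ReactionSpec(i - 1, i, enzymes[i - 1],
                     tuple(step_couplings.get(i, ())), name=f"step{i}")
        for i in range(1, n + 1)
    ]
    for pool_id, enz in background_turnover.items():
        reactions.append(ReactionSpec(None, None, enz,
                                      (PoolCoupling(pool_id, -1),),
                                      name=f"background_{pool_id}"))
    boundary = BoundarySpec(influxes=((0, kin),), outfluxes=((n, kout),))
    first_cycling = min((s for s, cs in step_couplings.items()
                         if any(c.direction == +1 for c in cs)), default=None)
    return MotifModel(n + 1, tuple(pools), tuple(reactions), boundary,
                      metadata={"motif": "linear", "n": n,
                                "first_cycling_step": first_cycling})


_UNIT_ENZYME = EnzymeParams(kcat=1.0, Etot=1.0, KM_f=1.0)
_UNIT_ENZYME_REV = EnzymeParams(kcat=1.0, Etot=1.0, KM_f=1.0,
                                reversible=True, kcat_r=1.0, KM_r=1.0)


def build_branched_model(*, Atot: float, Btot: float, kin: float,
                         kout: float = 1.0,
                         enzyme_entry: EnzymeParams = _UNIT_ENZYME_REV,
                         enzyme_coupled: EnzymeParams = _UNIT_ENZYME,
                         background_Vmax: float = 10.0,
                         background_KM: float = 1.0) -> MotifModel:
    """Two branches from one precursor, each coupled to its own pool.

    Species: M0, M1_1, M2_1, M1_2, M2_2 plus pools A (branch 1) and
    B (branch 2).  M0 -> M1_i are uncoupled entry steps (reversible by
    default, so branch back-pressure can redistribute flux); M1_i -> M2_i
    consume form 0 of the branch's pool; a pathway-independent background
    enzyme regenerates each pool.  Influx into M0, outflux from M2_1, M2_2.
    """
    if Atot <= 0 or Btot <= 0:
        raise ConfigError("pool sizes Atot and Btot must be > 0")
    pool_a = PoolSpec("A", Atot)
    pool_b = PoolSpec("B", Btot)
    background = EnzymeParams.from_vmax(background_Vmax, background_KM)
    reactions = (
        ReactionSpec(0, 1, enzyme_entry, name="entry_1"),
        ReactionSpec(1, 2, enzyme_coupled, (PoolCoupling("A", +1),), name="commit_1"),
        ReactionSpec(0, 3, enzyme_entry, name="entry_2"),
        ReactionSpec(3, 4, enzyme_coupled, (PoolCoupling("B", +1),), name="commit_2"),
        ReactionSpec(None, None, background, (PoolCoupling("A", -1),), name="background_A"),
        ReactionSpec(None, None, background, (PoolCoupling("B", -1),), name="background_B"),
    )
    boundary = BoundarySpec(influxes=((0, kin),), outfluxes=((2, kout), (4, kout)))
    names = ("M0", "M1_1", "M2_1", "M1_2", "M2_2", "A0", "A1", "B0", "B1")
    return MotifModel(5, (pool_a, pool_b), reactions, boundary, names,
                      metadata={"motif": "branched",
                                "branch_reactions": (1, 3)})


def build_coupled_model(*, Atot: float, kin1: float, kin2: float,
                        kout: float = 1.0,
                        enzyme: EnzymeParams | None = None,
                        reversible: bool = True,
                        background_Vmax: float = 0.01,
                        background_KM: float = 1.0,
                        init_fraction0: float = 0.5) -> MotifModel:
    """Two pathways coupled through one shared co-substrate pool.

    Pathway 1 (M0_1 -> M1_1) converts form 1 back to form 0; pathway 2
    (M0_2 -> M1_2) converts form 0 to form 1, so at steady state with
    negligible background turnover the two pathway fluxes must match.
    A slow background enzyme interconverts the forms in both directions
    at ``background_Vmax`` (set 0 to disable).
    """
    if Atot <= 0:
        raise ConfigError("pool size Atot must be > 0")
    if enzyme is None:
        enzyme = _UNIT_ENZYME_REV if reversible else _UNIT_ENZYME
    pool = PoolSpec("A", Atot, init_fraction0=init_fraction0)
    reactions = [
        ReactionSpec(0, 1, enzyme, (PoolCoupling("A", -1),), name="pathway_1"),
        ReactionSpec(2, 3, enzyme, (PoolCoupling("A", +1),), name="pathway_2"),
    ]
    if background_Vmax > 0:
        if reversible:
            bg = EnzymeParams.from_vmax(background_Vmax, background_KM,
                                        Vmax_r=background_Vmax, KM_r=background_KM)
            reactions.append(ReactionSpec(None, None, bg,
                                          (PoolCoupling("A", -1),), name="background"))
        else:
            bg = EnzymeParams.from_vmax(background_Vmax, background_KM)
            reactions.append(ReactionSpec(None, None, bg,
                                          (PoolCoupling("A", -1),), name="background_10"))
            reactions.append(ReactionSpec(None, None, bg,
                                          (PoolCoupling("A", +1),), name="background_01"))
    boundary = BoundarySpec(influxes=((0, kin1), (2, kin2)),
                            outfluxes=((1, kout), (3, kout)))
    names = ("M0_1", "M1_1", "M0_2", "M1_2", "A0", "A1")
    return MotifModel(4, (pool,), tuple(reactions), boundary, names,
                      metadata={"motif": "coupled",
                                "influx_species": (0, 2),
                                "output_species": (1, 3)})


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: MotifModel) -> list[str]:
    """Structural diagnostics; returns a list of violations (empty = valid).

    Checks pool cycling balance, presence of boundary fluxes, and that every
    outflux species is reachable from an influx through the reaction graph.
    Reports, never raises.
    """
    violations: list[str] = []
    for p in model.pools:
        if not p.conserved:
            continue
        net = sum(c.direction * c.nu
                  for rxn in model.reactions for c in rxn.couplings
                  if c.pool_id == p.pool_id)
        if net != 0:
            violations.append(
                f"pool not conserved: '{p.pool_id}' has net cycling stoichiometry {net}")
    if not model.boundary.influxes:
        violations.append("no influx")
    if not model.boundary.outfluxes or all(k == 0 for _, k in model.boundary.outfluxes):
        violations.append("no outflux")

    # reachability of each outflux species from the influx set
    edges: dict[int, set[int]] = {}
    for rxn in model.reactions:
        if rxn.substrate is not None and rxn.product is not None:
            edges.setdefault(rxn.substrate, set()).add(rxn.product)
            if rxn.enzyme.reversible:
                edges.setdefault(rxn.product, set()).add(rxn.substrate)
    reached = {i for i, _ in model.boundary.influxes}
    frontier = list(reached)
    while frontier:
        node = frontier.pop()
        for nxt in edges.get(node, ()):
            if nxt not in reached:
                reached.add(nxt)
                frontier.append(nxt)
    for i, k in model.boundary.outfluxes:
        if k > 0 and i not in reached:
            violations.append(
                f"outflux species {model.species_names[i]} unreachable from influx")
    return violations
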