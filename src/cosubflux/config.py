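"""Model/plan configuration files (YAML or JSON) and unit handling.

Two config styles are accepted:

* motif shorthand — ``motif: single|linear|branched|coupled`` plus the
  builder's parameters; this is the usual entry point;
* generic — explicit ``species`` / ``pools`` / ``reactions`` / ``boundary``
  sections for arbitrary networks.

A top-level ``units`` block declares concentration and time units
(``{conc: mM|uM, time: s}``); values are converted to internal units
(mM, s) once, at the boundary.  The composite Michaelis constant of a
pool-coupled reaction divides a concentration *product*: by default a
declared KM value is taken as that composite constant directly
(``km_interpretation: composite``); with ``per_substrate`` it is taken as
a per-substrate constant and squared.
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import (BoundarySpec, ConfigError, EnzymeParams, MotifModel,
                    PoolCoupling, PoolSpec, ReactionSpec,
                    build_branched_model, build_coupled_model,
                    build_linear_pathway_model, build_single_reaction_model)

__all__ = ["parse_config", "load_config_dict", "build_model_from_config"]

_CONC_FACTORS = {"mM": 1.0, "uM": 1e-3, "μM": 1e-3, "M": 1e3}
_TIME_FACTORS = {"s": 1.0, "min": 60.0, "h": 3600.0}


def load_config_dict(path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return data


class _Units:
    def __init__(self, block: dict | None):
        block = block or {}
        conc = block.get("conc", "mM")
        time = block.get("time", "s")
        if conc not in _CONC_FACTORS:
            raise ConfigError(f"unknown concentration unit '{conc}' "
                              f"(expected one of {sorted(_CONC_FACTORS)})")
        if time not in _TIME_FACTORS:
            raise ConfigError(f"unknown time unit '{time}' "
                              f"(expected one of {sorted(_TIME_FACTORS)})")
        self.conc = _CONC_FACTORS[conc]
        self.time = _TIME_FACTORS[time]

    def c(self, v):          # concentration -> mM
        return None if v is None else v * self.conc

    def per_t(self, v):      # first-order rate -> 1/s
        return None if v is None else v / self.time

    def c_per_t(self, v):    # zeroth-order rate -> mM/s
        return None if v is None else v * self.conc / self.time


def _enzyme(block: dict, units: _Units, km_square: bool, where: str) -> EnzymeParams:
    def km(value):
        v = units.c(value)
        return v * v if (km_square and v is not None) else v
    try:
        return EnzymeParams(
            kcat=units.per_t(block["kcat"]),
            Etot=units.c(block["Etot"]),
            KM_f=km(block["KM_f"]),
            reversible=bool(block.get("reversible", False)),
            kcat_r=units.per_t(block.get("kcat_r")),
            KM_r=km(block.get("KM_r")),
        )
    except KeyError as e:
        raise ConfigError(f"{where}: missing enzyme parameter {e.args[0]!r}") from None


def _pool(block: dict, units: _Units, where: str) -> PoolSpec:
    try:
        return PoolSpec(
            pool_id=str(block["id"]),
            Atot=units.c(block["Atot"]),
            init_fraction0=float(block.get("init_fraction0", 0.5)),
            ksyn0=units.c_per_t(block.get("ksyn0", 0.0)),
            ksyn1=units.c_per_t(block.get("ksyn1", 0.0)),
            kdeg=units.per_t(block.get("kdeg", 0.0)),
        )
    except KeyError as e:
        raise ConfigError(f"{where}: missing pool field {e.args[0]!r}") from None


def build_model_from_config(cfg: dict, *, strict: bool = True) -> MotifModel:
    """Assemble a MotifModel from a parsed config dict."""
    units = _Units(cfg.get("units"))
    km_square = cfg.get("km_interpretation", "composite") == "per_substrate"

    if "motif" in cfg:
        return _build_motif_shorthand(cfg, units, km_square)

    for section in ("species", "pools", "reactions", "boundary"):
        if section not in cfg:
            raise ConfigError(f"missing config section '{section}'")
    known = {"units", "km_interpretation", "species", "pools", "reactions",
             "boundary"}
    unknown = set(cfg) - known
    if unknown and strict:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    species = list(cfg["species"])
    pools = tuple(_pool(p, units, f"pools[{i}]") for i, p in enumerate(cfg["pools"]))

    def sp_index(name):
        if name is None:
            return None
        try:
            return species.index(name)
        except ValueError:
            raise ConfigError(f"unknown species '{name}'") from None

    reactions = []
    for i, r in enumerate(cfg["reactions"]):
        where = f"reactions[{i}]"
        couplings = tuple(
            PoolCoupling(str(c["pool"]), int(c["direction"]), int(c.get("nu", 1)))
            for c in r.get("couplings", ()))
        reactions.append(ReactionSpec(
            substrate=sp_index(r.get("substrate")),
            product=sp_index(r.get("product")),
            enzyme=_enzyme(r, units, km_square and bool(couplings), where),
            couplings=couplings,
            name=str(r.get("name", f"reaction_{i}")),
        ))
    b = cfg["boundary"]
    boundary = BoundarySpec(
        influxes=tuple((sp_index(e["species"]), units.c_per_t(e["kin"]))
                       for e in b.get("influxes", ())),
        outfluxes=tuple((sp_index(e["species"]), units.per_t(e["kout"]))
                        for e in b.get("outfluxes", ())),
    )
    pool_names = [f"{p.pool_id}{f}" for p in pools for f in ("0", "1")]
    return MotifModel(len(species), pools, tuple(reactions), boundary,
                      tuple(species) + tuple(pool_names))


def _build_motif_shorthand(cfg: dict, units: _Units, km_square: bool) -> MotifModel:
    motif = cfg["motif"]

    def need(key):
        if key not in cfg:
            raise ConfigError(f"motif '{motif}': missing parameter '{key}'")
        return cfg[key]

    if motif == "single":
        enz = _enzyme(need("enzyme_primary"), units, km_square, "enzyme_primary")
        bg = _enzyme(need("enzyme_background"), units, False, "enzyme_background")
        pool = _pool(need("pool"), units, "pool")
        return build_single_reaction_model(
            enzyme_primary=enz, enzyme_background=bg, pool=pool,
            kin=units.c_per_t(need("kin")), kout=units.per_t(need("kout")))
    if motif == "linear":
        n = int(need("n"))
        enz_cfg = need("enzymes")
        if isinstance(enz_cfg, dict):
            enzymes = _enzyme(enz_cfg, units, km_square, "enzymes")
        else:
            enzymes = [_enzyme(e, units, km_square, f"enzymes[{i}]")
                       for i, e in enumerate(enz_cfg)]
        pools = [_pool(p, units, f"pools[{i}]")
                 for i, p in enumerate(need("pools"))]
        cycling = [tuple(entry) for entry in need("cycling")]
        background = {pid: _enzyme(e, units, False, f"background[{pid}]")
                      for pid, e in cfg.get("background_turnover", {}).items()}
        return build_linear_pathway_model(
            n, cycling, enzymes=enzymes, pools=pools,
            kin=units.c_per_t(need("kin")), kout=units.per_t(need("kout")),
            background_turnover=background or None)
    if motif == "branched":
        kwargs = {}
        if "background_Vmax" in cfg:
            kwargs["background_Vmax"] = units.c_per_t(cfg["background_Vmax"])
        if "kout" in cfg:
            kwargs["kout"] = units.per_t(cfg["kout"])
        return build_branched_model(Atot=units.c(need("Atot")),
                                    Btot=units.c(need("Btot")),
                                    kin=units.c_per_t(need("kin")), **kwargs)
    if motif == "coupled":
        kwargs = {}
        if "background_Vmax" in cfg:
            kwargs["background_Vmax"] = units.c_per_t(cfg["background_Vmax"])
        if "kout" in cfg:
            kwargs["kout"] = units.per_t(cfg["kout"])
        if "reversible" in cfg:
            kwargs["reversible"] = bool(cfg["reversible"])
        return build_coupled_model(Atot=units.c(need("Atot")),
                                   kin1=units.c_per_t(need("kin1")),
                                   kin2=units.c_per_t(need("kin2")), **kwargs)
    raise ConfigError(f"unknown motif '{motif}'")


def parse_config(path, *, strict: bool = True) -> MotifModel:
    """Load a config file and build the model it describes."""
    return build_model_from_config(load_config_dict(path), strict=strict)
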