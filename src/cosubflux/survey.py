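"""Screening condition-resolved reaction fluxes against enzyme kinetic limits.

At steady state a reaction's flux cannot exceed the capacity of its primary
enzyme, ``v <= E * kcat`` (the apparent catalytic rate kapp = v / E is bounded
by kcat), nor the substrate-saturation-corrected capacity
``E * kcat * s / (KM + s)``.  A flux sitting well below both limits under many
conditions suggests some other constraint — such as the turnover of the
co-substrate pool (ATP, NADH, NADPH) the reaction is coupled to.  This module
loads per-reaction, per-condition flux tables, computes both limits, the
fraction of records below them, per-reaction linear fits of flux against
co-substrate pool size (with Benjamini–Hochberg adjusted significance,
measured and FBA-derived fluxes never pooled), and the normalized-flux /
thermodynamics table.

Units: flux v in mmol gDW^-1 h^-1, enzyme abundance E in mmol gDW^-1,
kcat in s^-1 (hence the 3600 in the limit), concentrations in mM,
dG_prime in kJ/mol.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KNOWN_COSUBSTRATES",
    "SURVEY_COLUMNS",
    "FluxRecord",
    "ReactionFit",
    "SurveyResult",
    "FractionBelow",
    "LoadError",
    "load_flux_records",
    "records_to_frame",
    "write_flux_records",
    "enzyme_limit",
    "saturation_limit",
    "classify_below_limit",
    "fraction_below",
    "fit_flux_vs_pool",
    "correlation_table",
    "normalized_flux_table",
    "run_survey",
]

KNOWN_COSUBSTRATES = ("ATP", "NADH", "NADPH")
SURVEY_COLUMNS = ["reaction_id", "condition", "source", "v", "v_sd", "E",
                  "kcat", "KM_sub", "s_conc", "cosubstrate", "pool",
                  "pool_sd", "dG_prime"]
_SOURCES = ("measured", "FBA")


class LoadError(ValueError):
    """The survey CSV violates the schema."""


@dataclass(frozen=True)
class FluxRecord:
    """One reaction under one growth condition.

    Missing values are ``None``, never zero.  A record is *usable* for the
    enzyme-limit screen when v, E and kcat are all present.
    """

    reaction_id: str
    condition: str
    source: str
    v: float | None = None
    v_sd: float | None = None
    E: float | None = None
    kcat: float | None = None
    KM_sub: float | None = None
    s_conc: float | None = None
    cosubstrate: str | None = None
    pool: float | None = None
    pool_sd: float | None = None
    dG_prime: float | None = None

    @property
    def usable(self) -> bool:
        return self.v is not None and self.E is not None and self.kcat is not None


@dataclass(frozen=True)
class ReactionFit:
    """Ordinary least squares of flux against co-substrate pool size for one
    reaction; nRMSE is the fit RMSE normalized by the mean observed flux."""

    reaction_id: str
    source: str
    n: int
    slope: float | None = None
    intercept: float | None = None
    nrmse: float | None = None
    pearson_r: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    flag: str | None = None


class FractionBelow(NamedTuple):
    fraction: float
    n_below: int
    n_usable: int


@dataclass(frozen=True)
class SurveyResult:
    """Aggregate screen statistics over one flux table."""

    n_records_total: int
    n_records_usable: int
    n_excluded_missing_enzyme: int
    fraction_below_enzyme_limit: FractionBelow
    fraction_below_saturation_limit: FractionBelow | None
    fits: tuple[ReactionFit, ...]
    normalized_flux: pd.DataFrame

    def summary_dict(self) -> dict:
        out = {
            "n_records_total": self.n_records_total,
            "n_records_usable": self.n_records_usable,
            "n_excluded_missing_enzyme": self.n_excluded_missing_enzyme,
            "fraction_below_enzyme_limit": self.fraction_below_enzyme_limit.fraction,
            "n_below_enzyme_limit": self.fraction_below_enzyme_limit.n_below,
        }
        if self.fraction_below_saturation_limit is not None:
            out["fraction_below_saturation_limit"] = \
                self.fraction_below_saturation_limit.fraction
            out["n_below_saturation_limit"] = \
                self.fraction_below_saturation_limit.n_below
        return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _opt_float(value, *, row: int, col: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise LoadError(f"row {row}: column '{col}' is not numeric: {value!r}")


def load_flux_records(path) -> list[FluxRecord]:
    """Read a survey CSV into validated records.

    Rows with missing mandatory fields (v, E, kcat) are retained but
    flagged unusable.  Duplicate (reaction, condition, source) rows,
    unknown co-substrate labels, unknown flux sources and negative fluxes
    are load errors naming the offending row.
    """
    df = pd.read_csv(path, dtype={"reaction_id": str, "condition": str,
                                  "source": str, "cosubstrate": str})
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns and c != "dG_prime"]
    if missing:
        raise LoadError(f"missing required columns: {missing}")
    if "dG_prime" not in df.columns:
        df["dG_prime"] = np.nan

    keys = list(zip(df["reaction_id"], df["condition"], df["source"]))
    dupes = [k for k, c in Counter(keys).items() if c > 1]
    if dupes:
        raise LoadError(f"duplicate (reaction, condition, source) rows: {dupes[:3]}")

    records = []
    for idx, row in df.iterrows():
        src = row["source"]
        if src not in _SOURCES:
            raise LoadError(f"row {idx}: unknown flux source '{src}'")
        cosub = row["cosubstrate"]
        if isinstance(cosub, float) and np.isnan(cosub):
            cosub = None
        if cosub is not None and cosub not in KNOWN_COSUBSTRATES:
            raise LoadError(f"row {idx}: unknown cosubstrate label '{cosub}'")
        rec = FluxRecord(
            reaction_id=str(row["reaction_id"]), condition=str(row["condition"]),
            source=src,
            v=_opt_float(row["v"], row=idx, col="v"),
            v_sd=_opt_float(row["v_sd"], row=idx, col="v_sd"),
            E=_opt_float(row["E"], row=idx, col="E"),
            kcat=_opt_float(row["kcat"], row=idx, col="kcat"),
            KM_sub=_opt_float(row["KM_sub"], row=idx, col="KM_sub"),
            s_conc=_opt_float(row["s_conc"], row=idx, col="s_conc"),
            cosubstrate=cosub,
            pool=_opt_float(row["pool"], row=idx, col="pool"),
            pool_sd=_opt_float(row["pool_sd"], row=idx, col="pool_sd"),
            dG_prime=_opt_float(row["dG_prime"], row=idx, col="dG_prime"),
        )
        if rec.v is not None and rec.v < 0:
            raise LoadError(f"row {idx}: negative flux v={rec.v}")
        records.append(rec)
    return records


def records_to_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in SURVEY_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def write_flux_records(records: Iterable[FluxRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Limits and classification
# ---------------------------------------------------------------------------

def enzyme_limit(record: FluxRecord) -> float | None:
    """Primary-enzyme flux limit E·kcat·3600 (mmol gDW^-1 h^-1); None when
    the inputs are missing."""
    if record.E is None or record.kcat is None:
        return None
    if record.E <= 0 or record.kcat <= 0:
        raise ValueError(f"{record.reaction_id}/{record.condition}: "
                         "E and kcat must be > 0")
    return record.E * record.kcat * 3600.0


def saturation_limit(record: FluxRecord) -> float | None:
    """Enzyme limit corrected for primary-substrate saturation,
    E·kcat·3600·s/(KM+s); never exceeds the raw enzyme limit."""
    base = enzyme_limit(record)
    if base is None or record.KM_sub is None or record.s_conc is None:
        return None
    if record.KM_sub <= 0 or record.s_conc < 0:
        raise ValueError(f"{record.reaction_id}/{record.condition}: "
                         "KM_sub must be > 0 and s_conc >= 0")
    return base * record.s_conc / (record.KM_sub + record.s_conc)


_LIMITS = {"enzyme": enzyme_limit, "saturation": saturation_limit}


def classify_below_limit(record: FluxRecord, mode: str = "enzyme") -> bool | None:
    """True iff v is strictly below the chosen limit; ties count as
    not-below; None when the limit (or v) is not computable."""
    limit = _LIMITS[mode](record)
    if limit is None or record.v is None:
        return None
    return record.v < limit


def fraction_below(records: Sequence[FluxRecord], mode: str = "enzyme"
                   ) -> FractionBelow:
    """Fraction of usable records with flux below the limit."""
    flags = [classify_below_limit(r, mode) for r in records]
    usable = [f for f in flags if f is not None]
    if not usable:
        raise ValueError("no usable records for mode "
                         f"'{mode}' (all limits non-computable)")
    n_below = sum(usable)
    return FractionBelow(n_below / len(usable), n_below, len(usable))


# ---------------------------------------------------------------------------
# Flux vs pool-size fits
# ---------------------------------------------------------------------------

def fit_flux_vs_pool(records: Sequence[FluxRecord]) -> ReactionFit:
    """OLS of v against pool size across conditions for one reaction."""
    recs = [r for r in records if r.v is not None and r.pool is not None]
    if not recs:
        raise ValueError("no records given")
    rid = recs[0].reaction_id
    src = recs[0].source
    if any(r.reaction_id != rid or r.source != src for r in recs):
        raise ValueError("fit_flux_vs_pool expects one reaction and one source")
    if len(recs) < 3:
        return ReactionFit(rid, src, len(recs), flag="insufficient_data")
    v = np.array([r.v for r in recs])
    pool = np.array([r.pool for r in recs])
    if np.ptp(pool) == 0.0:
        return ReactionFit(rid, src, len(recs), flag="degenerate_regressor")
    res = stats.linregress(pool, v)
    pred = res.intercept + res.slope * pool
    rmse = float(np.sqrt(np.mean((v - pred) ** 2)))
    mean_v = float(np.mean(v))
    nrmse = rmse / mean_v if mean_v > 0 else float("inf")
    return ReactionFit(rid, src, len(recs), slope=float(res.slope),
                       intercept=float(res.intercept), nrmse=nrmse,
                       pearson_r=float(res.rvalue), p_value=float(res.pvalue))


def correlation_table(records: Sequence[FluxRecord]) -> list[ReactionFit]:
    """Per-reaction flux–pool fits with BH-adjusted q-values.

    Reactions are grouped by (source, reaction); the Benjamini–Hochberg
    adjustment is applied within each source group (measured and FBA
    records are never pooled).  Sorted by q, then p.
    """
    groups: dict[tuple[str, str], list[FluxRecord]] = {}
    for r in records:
        groups.setdefault((r.source, r.reaction_id), []).append(r)
    fits = [fit_flux_vs_pool(g) for g in groups.values()]
    out: list[ReactionFit] = []
    for source in sorted({f.source for f in fits}):
        valid = [f for f in fits if f.source == source and f.p_value is not None]
        rest = [f for f in fits if f.source == source and f.p_value is None]
        if valid:
            qs = stats.false_discovery_control([f.p_value for f in valid])
            valid = [replace(f, q_value=float(q)) for f, q in zip(valid, qs)]
        out.extend(valid + rest)
    return sorted(out, key=lambda f: (f.q_value is None,
                                      f.q_value if f.q_value is not None else 0.0,
                                      f.p_value if f.p_value is not None else 0.0))


def normalized_flux_table(records: Sequence[FluxRecord]) -> pd.DataFrame:
    """Dimensionless saturation ratio v/(E·kcat·3600) per record, paired
    with dG_prime; records with no computable limit are excluded."""
    rows = []
    for r in records:
        limit = enzyme_limit(r)
        if limit is None or r.v is None:
            continue
        rows.append({"reaction_id": r.reaction_id, "condition": r.condition,
                     "source": r.source, "cosubstrate": r.cosubstrate,
                     "normalized_flux": r.v / limit, "dG_prime": r.dG_prime})
    return pd.DataFrame(rows, columns=["reaction_id", "condition", "source",
                                       "cosubstrate", "normalized_flux",
                                       "dG_prime"])


def run_survey(records: Sequence[FluxRecord]) -> SurveyResult:
    """The full screen: counts, below-limit fractions, fits, normalized flux."""
    n_total = len(records)
    usable = [r for r in records if r.usable]
    frac_enz = fraction_below(records, "enzyme")
    try:
        frac_sat = fraction_below(records, "saturation")
    except ValueError:
        frac_sat = None
    return SurveyResult(
        n_records_total=n_total,
        n_records_usable=len(usable),
        n_excluded_missing_enzyme=n_total - len(usable),
        fraction_below_enzyme_limit=frac_enz,
        fraction_below_saturation_limit=frac_sat,
        fits=tuple(correlation_table(records)),
        normalized_flux=normalized_flux_table(records),
    )
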