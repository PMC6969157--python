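"""Horizon-year projections and the P-neutrality solver.

The baseline scenario holds wild harvest at its recent-window mean, scales
aquaculture to a production target, and converts it to phosphorus terms with
a recent-window aquaculture P concentration; P-input follows from an assumed
phosphorus-use efficiency. The neutrality solver returns the unique PUE at
which P-input equals total P-harvest (zero net flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import ConfigError

SOLVE_NEUTRAL = "solve-neutral"


@dataclass
class ScenarioSpec:
    wild_window: tuple[int, int] = (2005, 2014)
    aquaculture_target: float = 140.0  # Tg live weight at the horizon
    horizon: int = 2050
    pue_assumption: float | str = 0.20  # fraction, or "solve-neutral"
    aquaculture_conc: float | None = None  # Tg P per Tg biomass; None = derive

    def __post_init__(self):
        if self.aquaculture_target <= 0:
            raise ConfigError("aquaculture_target must be > 0")
        y0, y1 = self.wild_window
        if y1 < y0:
            raise ConfigError("wild_window must be a nonempty year range")
        if isinstance(self.pue_assumption, str):
            if self.pue_assumption != SOLVE_NEUTRAL:
                raise ConfigError(
                    f"pue_assumption must be a fraction or {SOLVE_NEUTRAL!r}")
        elif not 0 < self.pue_assumption:
            raise ConfigError("pue_assumption must be > 0")


def history_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse a record-level budget into the per-year history a scenario
    consumes: wild/aquaculture production and harvested P, plus P-input."""
    wild = records[records["source"] == "capture"]
    aqua = records[records["source"] == "aquaculture"]

    def yearly(df, col):
        return df.groupby("year")[col].sum()

    out = pd.DataFrame({
        "wild_production_tg": yearly(wild, "weight"),
        "aqua_production_tg": yearly(aqua, "weight"),
        "wild_p_harvest_tg": yearly(wild, "p_harvest_tg"),
        "aqua_p_harvest_tg": yearly(aqua, "p_harvest_tg"),
        "p_input_tg": yearly(records, "p_input_tg"),
    }).fillna(0.0)
    out.index.name = "year"
    return out.reset_index()


def project_baseline(history: pd.DataFrame | None = None,
                     spec: ScenarioSpec | None = None,
                     overrides: Mapping[str, float] | None = None) -> dict:
    """Single-point horizon projection of the global fishery P budget.

    With a history, wild terms are window means and the aquaculture P
    concentration defaults to the window's harvested-P / production ratio.
    ``overrides`` replaces any output fields before the net flux is formed,
    which allows reproducing published projections directly from their
    printed harvest/input numbers.
    """
    spec = spec or ScenarioSpec()
    overrides = dict(overrides or {})
    out: dict[str, float] = {"horizon": spec.horizon}

    if history is not None:
        y0, y1 = spec.wild_window
        win = history[(history["year"] >= y0) & (history["year"] <= y1)]
        if win.empty:
            raise ConfigError(
                f"history does not cover the wild window {spec.wild_window}")
        out["wild_production_tg"] = float(win["wild_production_tg"].mean())
        out["wild_p_harvest_tg"] = float(win["wild_p_harvest_tg"].mean())
        conc = spec.aquaculture_conc
        if conc is None:
            conc = float(win["aqua_p_harvest_tg"].sum()
                         / win["aqua_production_tg"].sum())
        out["aquaculture_production_tg"] = spec.aquaculture_target
        out["aquaculture_conc"] = conc
        out["aquaculture_p_harvest_tg"] = spec.aquaculture_target * conc
        out["p_harvest_tg"] = (out["wild_p_harvest_tg"]
                               + out["aquaculture_p_harvest_tg"])
        pue = spec.pue_assumption
        if pue == SOLVE_NEUTRAL:
            pue = out["aquaculture_p_harvest_tg"] / out["p_harvest_tg"]
        out["pue"] = float(pue)
        out["p_input_tg"] = out["aquaculture_p_harvest_tg"] / out["pue"]
    elif not overrides:
        raise ConfigError("either a history or overrides must be supplied")

    out.update(overrides)

    # derive the aquaculture harvested-P term when only printed totals are
    # given, using the assumed efficiency (harvest = input * PUE)
    if "aquaculture_p_harvest_tg" not in out and "p_input_tg" in out:
        pue = out.get("pue", spec.pue_assumption)
        if isinstance(pue, str):
            raise ConfigError("cannot solve-neutral from overrides alone")
        out["pue"] = float(pue)
        out["aquaculture_p_harvest_tg"] = out["p_input_tg"] * float(pue)

    if "p_harvest_tg" not in out or "p_input_tg" not in out:
        raise ConfigError("projection needs p_harvest_tg and p_input_tg")
    out["p_net_tg"] = out["p_harvest_tg"] - out["p_input_tg"]
    return out


def solve_neutral_pue(baseline: Mapping[str, float]) -> float:
    """PUE at which P-input equals P-harvest (P-net = 0).

    ``PUE* = aquaculture harvested P / total harvested P``; plugging it back
    into the projection yields a zero net flux by construction.
    """
    total = float(baseline["p_harvest_tg"])
    aqua = float(baseline["aquaculture_p_harvest_tg"])
    if total <= 0:
        raise ConfigError("total P-harvest must be > 0")
    if aqua <= 0:
        raise ConfigError("aquaculture P-harvest must be > 0")
    return aqua / total


def weighted_pue(shares: Mapping[str, float],
                 efficiencies: Mapping[str, float],
                 scheme: str = "arithmetic", *, tol: float = 1e-6) -> float:
    """Production-weighted efficiency under two aggregation schemes.

    ``arithmetic``: sum(share * eff). ``harmonic``: 1 / sum(share / eff) —
    the scheme implied by summing per-group input = harvest / efficiency.
    The arithmetic value always dominates the harmonic one (weighted AM-HM).
    """
    if set(shares) != set(efficiencies):
        raise ConfigError("shares and efficiencies must cover the same groups")
    total = sum(shares.values())
    if abs(total - 1.0) > tol:
        raise ConfigError(f"shares must sum to 1, got {total}")
    if any(e <= 0 for e in efficiencies.values()):
        raise ConfigError("efficiencies must be > 0")
    if scheme == "arithmetic":
        return float(sum(shares[k] * efficiencies[k] for k in shares))
    if scheme == "harmonic":
        return float(1.0 / sum(shares[k] / efficiencies[k] for k in shares))
    raise ConfigError(f"unknown scheme {scheme!r}")


def efficiency_percentiles(db, group: str | None = None,
                           q: float = 0.5) -> float:
    """Empirical quantile of an efficiency pool (linear interpolation).

    ``db`` is a PUE/PRE table (filtered by ``group`` when given, matching a
    ``group`` or ``group6`` column) or any array of values.
    """
    if isinstance(db, pd.DataFrame):
        sub = db
        if group is not None:
            col = "group" if "group" in db.columns else "group6"
            sub = db[db[col] == group]
        values = sub["value"].to_numpy(float)
    else:
        values = np.asarray(db, float)
    if values.size == 0:
        raise ConfigError("empty efficiency pool")
    return float(np.quantile(values, q))
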