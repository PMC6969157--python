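"""Stage 1: catch-reconstruction scaling, concentration pools, and P-harvest.

The harvested phosphorus flux for a set of production records is
``sum_i W_i * R_i`` with ``W_i`` the live biomass (Tg) and ``R_i`` the
wet-basis whole-body P mass fraction resolved for each species through a
taxonomic fallback chain: species -> order -> major group -> whole database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    MAJOR_GROUPS,
    NON_FISH_GROUPS,
    ConfigError,
    SchemaError,
    normalize_concentrations,
)

DEFAULT_CUTOFF = 1


@dataclass(frozen=True)
class ConcentrationPool:
    """The sampling pool resolved for one produced species.

    ``level`` records how far up the taxonomy the fallback chain went.
    ``rescaled`` pools keep the species' own mean but borrow the coefficient
    of variation of the wider pool: draws are normal(mean, mean * CV).
    """

    species: str
    level: str  # "species" | "order" | "group" | "database"
    mean: float
    sd: float
    members: np.ndarray = field(repr=False)
    rescaled: bool = False

    def __post_init__(self):
        if not self.mean > 0:
            raise SchemaError(f"pool for {self.species!r}: mean must be > 0")
        if self.sd < 0:
            raise SchemaError(f"pool for {self.species!r}: sd must be >= 0")


def filter_fish(production: pd.DataFrame) -> pd.DataFrame:
    """Drop groups outside the phosphorus budget (aquatic plants, mammals)."""
    return production[~production["group"].isin(NON_FISH_GROUPS)].reset_index(
        drop=True)


def scale_wild_production(production: pd.DataFrame, factors: pd.DataFrame,
                          marine_only: bool = False) -> pd.DataFrame:
    """Multiply wild-capture weights by country x year reconstruction factors.

    Aquaculture rows are never scaled. Years past the last factor year reuse
    each country's last available factor; a missing (country, year) pair falls
    back to that year's cross-country mean factor.
    """
    fac = factors.pivot_table(index="year", columns="country", values="factor",
                              aggfunc="mean").sort_index()
    year_mean = fac.mean(axis=1)
    last_year = int(fac.index.max())
    first_year = int(fac.index.min())

    def lookup(country: str, year: int) -> float:
        if country in fac.columns:
            col = fac[country].dropna()
            if len(col):
                if year in col.index:
                    return float(col.loc[year])
                if year > int(col.index.max()):
                    return float(col.loc[col.index.max()])
        if year in year_mean.index:
            return float(year_mean.loc[year])
        if year > last_year:
            return float(year_mean.loc[last_year])
        return float(year_mean.loc[first_year])

    mask = production["source"].eq("capture")
    if marine_only:
        mask &= production["environment"].eq("marine")
    out = production.copy()
    sub = out.loc[mask, ["country", "year"]]
    pairs = {t for t in sub.itertuples(index=False, name=None)}
    fmap = {(c, y): lookup(c, int(y)) for c, y in pairs}
    out.loc[mask, "weight"] = out.loc[mask, "weight"].to_numpy() * np.array(
        [fmap[t] for t in sub.itertuples(index=False, name=None)])
    return out


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def resolve_pool(species: str, concentrations: pd.DataFrame,
                 cutoff: int = DEFAULT_CUTOFF, *, order: str | None = None,
                 group: str | None = None) -> ConcentrationPool:
    """Resolve the concentration sampling pool for one species.

    ``concentrations`` must already be on wet basis. ``order``/``group`` come
    from the production table when available; otherwise they are taken from
    the concentration database rows of the species itself.

    Chain, with ``n`` the number of species-level records:

    * ``n > cutoff``: the species' own records.
    * ``0 < n <= cutoff``: keep the species mean but rescale the spread by the
      coefficient of variation of the order pool (or, if the order pool is
      itself no larger than the cutoff, of the major-group pool).
    * ``n == 0``: the order pool if it exceeds the cutoff, else the
      major-group pool.
    * Taxa outside the three major groups: the whole-database pool.
    """
    if cutoff < 0:
        raise ConfigError("cutoff must be >= 0")
    values = concentrations["value"].to_numpy(float)
    if values.size == 0:
        raise SchemaError("empty concentration database")

    sp_mask = concentrations["species"] == species
    sp_vals = values[sp_mask.to_numpy()]
    if sp_mask.any():
        db_rows = concentrations.loc[sp_mask]
        if order is None or (isinstance(order, float) and np.isnan(order)):
            order = db_rows["order"].dropna().iloc[0] if db_rows[
                "order"].notna().any() else None
        if group is None:
            group = db_rows["group"].iloc[0]

    if group not in MAJOR_GROUPS:
        return ConcentrationPool(species, "database", float(values.mean()),
                                 _sd(values), values)

    order_vals = np.empty(0)
    if order is not None and not (isinstance(order, float) and np.isnan(order)):
        order_vals = values[(concentrations["order"] == order).to_numpy()]
    group_vals = values[(concentrations["group"] == group).to_numpy()]

    n = sp_vals.size
    if n > cutoff:
        return ConcentrationPool(species, "species", float(sp_vals.mean()),
                                 _sd(sp_vals), sp_vals)
    if n >= 1:
        sp_mean = float(sp_vals.mean())
        if order_vals.size > cutoff:
            ref, level = order_vals, "order"
        elif group_vals.size > 0:
            ref, level = group_vals, "group"
        else:
            ref, level = values, "group"
        cv = _sd(ref) / float(ref.mean()) if ref.size > 1 else 0.0
        return ConcentrationPool(species, level, sp_mean, sp_mean * cv, ref,
                                 rescaled=True)
    if order_vals.size > cutoff:
        return ConcentrationPool(species, "order", float(order_vals.mean()),
                                 _sd(order_vals), order_vals)
    if group_vals.size > 0:
        return ConcentrationPool(species, "group", float(group_vals.mean()),
                                 _sd(group_vals), group_vals)
    # group entirely absent from the database: fall back to everything
    return ConcentrationPool(species, "group", float(values.mean()),
                             _sd(values), values)


def build_pools(production: pd.DataFrame, concentrations: pd.DataFrame,
                cutoff: int = DEFAULT_CUTOFF) -> dict[str, ConcentrationPool]:
    """Resolve one pool per species appearing in ``production``."""
    conc = concentrations
    if (conc["basis"] == "dry").any():
        conc = normalize_concentrations(conc)
    fish = filter_fish(production)
    cols = ["species", "group"] + (["order"] if "order" in fish.columns else [])
    taxa = fish[cols].drop_duplicates("species")
    pools: dict[str, ConcentrationPool] = {}
    for row in taxa.itertuples(index=False):
        order = getattr(row, "order", None)
        if isinstance(order, float) and np.isnan(order):
            order = None
        pools[row.species] = resolve_pool(
            row.species, conc, cutoff, order=order, group=row.group)
    return pools


def compute_p_harvest(production: pd.DataFrame,
                      pools: dict[str, ConcentrationPool]) -> pd.DataFrame:
    """Point-estimate P-harvest per record: ``weight * pool mean`` (Tg P).

    Returns the production table with a ``p_harvest_tg`` column appended.
    Grouping columns are preserved so totals can be taken at any level.
    """
    if production["group"].isin(NON_FISH_GROUPS).any():
        raise SchemaError(
            "production contains aquatic-plant/mammal rows; apply filter_fish"
        )
    missing = sorted(set(production["species"]) - set(pools))
    if missing:
        raise SchemaError(f"unresolved species (no concentration pool): {missing}")
    out = production.copy()
    means = out["species"].map({s: p.mean for s, p in pools.items()})
    out["p_harvest_tg"] = out["weight"].to_numpy(float) * means.to_numpy(float)
    return out


def total_p_harvest(harvest: pd.DataFrame, by: list[str] | None = None):
    """Sum ``p_harvest_tg``, optionally grouped (e.g. ``["year"]``)."""
    if by:
        return harvest.groupby(by, as_index=True)["p_harvest_tg"].sum()
    return float(harvest["p_harvest_tg"].sum())
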