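"""Monte Carlo propagation of concentration, biomass, and PUE uncertainty.

Each replicate redraws (i) one whole-body P concentration per species from
its resolved pool, shared across countries within the replicate, (ii) one
biomass perturbation per production record, uniform on
``[W(1 - level/2), W(1 + level/2)]``, and (iii) one PUE per six-group from
the empirical pool, then pushes the draws through stages 1-2. Central values
are replicate means; uncertainty bands are interquartile ranges with linear
quantile interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GROUP6, ConfigError, normalize_concentrations
from .harvest_flux import (
    ConcentrationPool,
    build_pools,
    compute_p_harvest,
    filter_fish,
    scale_wild_production,
)
from .input_flux import assign_group6, group_pue, pue_pool


@dataclass
class MonteCarloConfig:
    n_rep: int = 1000
    cutoff: int = 1
    biomass_level: float = 0.5  # total relative width of the uniform interval
    seed: int = 0
    marine_only_scaling: bool = False
    other_invertebrate_as: str = "finfish"

    def __post_init__(self):
        if self.n_rep < 1:
            raise ConfigError("n_rep must be >= 1")
        if self.biomass_level < 0:
            raise ConfigError("biomass_level must be >= 0")
        if self.cutoff < 0:
            raise ConfigError("cutoff must be >= 0")


@dataclass
class MonteCarloResult:
    """Replicate-level budget series.

    ``harvest``/``input_``/``net`` are ``(n_rep, n_years)`` arrays in Tg P;
    ``net == harvest - input_`` holds exactly per replicate. ``point`` is the
    deterministic point estimate (pool means, median PUE) for debugging.
    ``units`` optionally maps aggregation-unit labels to the same triplet.
    """

    years: np.ndarray
    harvest: np.ndarray
    input_: np.ndarray
    net: np.ndarray
    point: pd.DataFrame
    units: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def n_rep(self) -> int:
        return self.harvest.shape[0]


def draw_concentration(pool: ConcentrationPool, rng: np.random.Generator) -> float:
    """One wet-basis concentration draw from a resolved pool."""
    if pool.rescaled:
        if pool.sd == 0:
            return pool.mean
        v = rng.normal(pool.mean, pool.sd)
        while v <= 0:  # mass fractions are positive; redraw rather than clip
            v = rng.normal(pool.mean, pool.sd)
        return float(v)
    return float(rng.choice(pool.members))


def draw_biomass(weight: float, level: float, rng: np.random.Generator) -> float:
    """One biomass draw, uniform over an interval of total width ``level * W``."""
    if weight < 0:
        raise ConfigError("weight must be >= 0")
    if level == 0 or weight == 0:
        return float(weight)
    half = 0.5 * level
    return float(rng.uniform(weight * (1 - half), weight * (1 + half)))


def draw_pue(pue_db: pd.DataFrame, key: str, rng: np.random.Generator) -> float:
    """One PUE draw, uniform over the group's empirical pool."""
    return float(rng.choice(pue_pool(pue_db, key)))


def _conc_draws(pool: ConcentrationPool, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Vectorized equivalent of :func:`draw_concentration`."""
    if pool.rescaled:
        if pool.sd == 0:
            return np.full(n, pool.mean)
        v = rng.normal(pool.mean, pool.sd, size=n)
        bad = v <= 0
        while bad.any():
            v[bad] = rng.normal(pool.mean, pool.sd, size=int(bad.sum()))
            bad = v <= 0
        return v
    return rng.choice(pool.members, size=n)


def _prepare(production, concentrations, pue_db, factors, config):
    """Scale, resolve pools, and freeze the record arrays shared by the point
    estimate and all replicates."""
    prod = filter_fish(production)
    conc = normalize_concentrations(concentrations)
    if factors is not None:
        prod = scale_wild_production(prod, factors,
                                     marine_only=config.marine_only_scaling)
    pools = build_pools(prod, conc, config.cutoff)
    prod = prod.copy()
    prod["group6"] = assign_group6(
        prod, other_invertebrate_as=config.other_invertebrate_as)
    return prod, conc, pools


def point_budget(production, concentrations, pue_db, factors=None,
                 config: MonteCarloConfig | None = None) -> pd.DataFrame:
    """Deterministic record-level budget (pool means, median PUE).

    Returns the scaled production table with ``p_harvest_tg``, ``group6``,
    and ``p_input_tg`` columns; ``p_input_tg`` is zero for capture rows.
    """
    config = config or MonteCarloConfig()
    prod, conc, pools = _prepare(production, concentrations, pue_db, factors,
                                 config)
    records = compute_p_harvest(prod.drop(columns=["group6"]), pools)
    records["group6"] = prod["group6"].to_numpy()
    pue = {key: group_pue(pue_db, key)
           for key in sorted(records["group6"].dropna().unique())}
    p_input = np.zeros(len(records))
    aqua = records["group6"].notna()
    p_input[aqua.to_numpy()] = records.loc[aqua, "p_harvest_tg"].to_numpy(
        float) / records.loc[aqua, "group6"].map(pue).to_numpy(float)
    records["p_input_tg"] = p_input
    return records


def run_monte_carlo(production, concentrations, pue_db, factors=None,
                    config: MonteCarloConfig | None = None,
                    by: str | None = None) -> MonteCarloResult:
    """Run the full replicate set; deterministic given (seed, inputs).

    ``by`` optionally names a grouping column (e.g. ``"country"``) to track
    per-unit budgets alongside the global series.
    """
    config = config or MonteCarloConfig()
    prod, conc, pools = _prepare(production, concentrations, pue_db, factors,
                                 config)

    years = np.sort(prod["year"].unique())
    year_idx = pd.Index(years).get_indexer(prod["year"])
    species = sorted(pools)
    sp_idx = pd.Index(species).get_indexer(prod["species"])
    weights = prod["weight"].to_numpy(float)
    n_rec, n_years, n_rep = len(prod), len(years), config.n_rep

    group_keys = sorted(k for k in prod["group6"].dropna().unique())
    aqua_mask = prod["group6"].notna().to_numpy()
    aqua_rows = np.flatnonzero(aqua_mask)
    g6_idx = pd.Index(group_keys).get_indexer(
        prod.loc[aqua_mask, "group6"]) if len(aqua_rows) else np.empty(0, int)

    rng = np.random.default_rng(config.seed)

    # draw order is fixed (species sorted, then biomass, then PUE by key) so
    # the stream is reproducible independent of input row order
    conc_draws = np.empty((n_rep, len(species)))
    for j, sp in enumerate(species):
        conc_draws[:, j] = _conc_draws(pools[sp], n_rep, rng)

    if config.biomass_level == 0:
        biomass = weights[None, :]
    else:
        half = 0.5 * config.biomass_level
        biomass = rng.uniform(weights * (1 - half), weights * (1 + half),
                              size=(n_rep, n_rec))

    pue_draws = np.empty((n_rep, len(group_keys)))
    for j, key in enumerate(group_keys):
        pue_draws[:, j] = rng.choice(pue_pool(pue_db, key), size=n_rep)

    p_rec = conc_draws[:, sp_idx] * biomass  # (n_rep, n_rec)

    year_onehot = np.zeros((n_rec, n_years))
    year_onehot[np.arange(n_rec), year_idx] = 1.0
    harvest = p_rec @ year_onehot

    if len(aqua_rows):
        p_aqua = p_rec[:, aqua_rows] / pue_draws[:, g6_idx]
        input_ = p_aqua @ year_onehot[aqua_rows]
    else:
        p_aqua = np.zeros((n_rep, 0))
        input_ = np.zeros((n_rep, n_years))
    net = harvest - input_

    units = None
    if by is not None:
        labels = np.sort(prod[by].unique())
        u_idx = pd.Index(labels).get_indexer(prod[by])
        combo = np.zeros((n_rec, len(labels) * n_years))
        combo[np.arange(n_rec), u_idx * n_years + year_idx] = 1.0
        h_u = (p_rec @ combo).reshape(n_rep, len(labels), n_years)
        if len(aqua_rows):
            i_u = (p_aqua @ combo[aqua_rows]).reshape(n_rep, len(labels),
                                                      n_years)
        else:
            i_u = np.zeros_like(h_u)
        units = {
            str(lab): {"harvest": h_u[:, k], "input": i_u[:, k],
                       "net": h_u[:, k] - i_u[:, k]}
            for k, lab in enumerate(labels)
        }

    point_records = point_budget(production, concentrations, pue_db, factors,
                                 config)
    point = point_records.groupby("year")[["p_harvest_tg", "p_input_tg"]].sum()
    point["p_net_tg"] = point["p_harvest_tg"] - point["p_input_tg"]
    point = point.reindex(years).reset_index()

    return MonteCarloResult(years=years, harvest=harvest, input_=input_,
                            net=net, point=point, units=units)


def iqr_summary(values: np.ndarray, axis: int = 0):
    """Mean, 25th, and 75th percentiles (linear interpolation)."""
    values = np.asarray(values, float)
    return (values.mean(axis=axis),
            np.quantile(values, 0.25, axis=axis),
            np.quantile(values, 0.75, axis=axis))


def summarize(result: MonteCarloResult) -> pd.DataFrame:
    """Long-format summary: (unit, year, flux, mean, q25, q75)."""
    frames = []

    def block(unit, harvest, input_, net):
        for flux, arr in (("p_harvest", harvest), ("p_input", input_),
                          ("p_net", net)):
            mean, q25, q75 = iqr_summary(arr)
            frames.append(pd.DataFrame({
                "unit": unit, "year": result.years, "flux": flux,
                "mean": mean, "q25": q25, "q75": q75,
            }))

    block("global", result.harvest, result.input_, result.net)
    if result.units:
        for label, d in result.units.items():
            block(label, d["harvest"], d["input"], d["net"])
    return pd.concat(frames, ignore_index=True)
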