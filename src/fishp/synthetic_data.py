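"""Synthetic input tables with the statistical structure the pipeline assumes.

Generates all five input schemas (production, concentrations, PUE, PRE,
scaling factors) plus a region map, with known ground truth so every
downstream stage is testable offline: lognormal right-skewed efficiency
pools with finfish above crustacean, species-within-order-within-group
concentration hierarchy (including deliberately "thin" species with zero or
one record to exercise the fallback chain), wild capture that plateaus while
aquaculture takes off geometrically, and reconstruction factors declining
toward one. All randomness derives from a single seed; identical configs
produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .data_io import ConfigError, GROUP6, MAJOR_GROUPS

CONTINENTS = ("Asia", "Europe", "America", "Africa", "Oceania")

_DEF_CONC = {"finfish": 0.0065, "crustacean": 0.0045, "mollusk": 0.0035}
_DEF_PUE = {"finfish": 0.22, "crustacean": 0.14, "mollusk": 0.50}
_DEF_PRE = {"finfish": 0.37, "crustacean": 0.20, "mollusk": 0.21}

PUE_MIN, PUE_MAX = 0.01, 1.67


@dataclass
class SynthConfig:
    n_species: int = 60
    n_orders: int = 12
    n_countries: int = 8
    year_range: tuple[int, int] = (1950, 2016)
    group_mean_conc: dict = field(default_factory=lambda: dict(_DEF_CONC))
    order_cv: float = 0.20
    species_cv: float = 0.15
    pue_median: dict = field(default_factory=lambda: dict(_DEF_PUE))
    pue_sigma: float = 0.50
    wild_plateau_year: int = 1990
    aquaculture_takeoff_year: int = 1980
    seed: int = 0
    # concentration database shape
    records_per_species: float = 4.0
    thin_fraction: float = 0.30  # species with 0 or 1 records
    dry_fraction: float = 0.10
    missing_moisture_fraction: float = 0.0
    # production shape
    wild_start_frac: float = 0.35
    aqua_start_frac: float = 0.005
    aqua_growth_rate: float = 0.185
    cultured_fraction: float = 0.5
    production_scale: float = 0.5
    other_invert_share: float = 0.005
    # efficiency databases
    pue_per_group: int = 30
    freshwater_mollusk_n: int = 0
    pre_per_group: int = 60
    pre_median: dict = field(default_factory=lambda: dict(_DEF_PRE))
    pre_sigma: float = 0.45
    # catch reconstruction
    scaling_anchors: tuple = ((1950, 1.29), (2004, 1.06))
    scaling_last_year: int = 2014

    def __post_init__(self):
        if not (self.n_species >= self.n_orders >= 3):
            raise ConfigError("need n_species >= n_orders >= 3")
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        if self.year_range[1] < self.year_range[0]:
            raise ConfigError("year_range must be nonempty")
        for name, frac in (("thin_fraction", self.thin_fraction),
                           ("dry_fraction", self.dry_fraction),
                           ("cultured_fraction", self.cultured_fraction)):
            if not 0 <= frac <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for mapping in (self.group_mean_conc, self.pue_median, self.pre_median):
            for k, v in mapping.items():
                if not 0 < v <= 1:
                    raise ConfigError(f"fraction for {k!r} must be in (0, 1]")
        for name, cv in (("order_cv", self.order_cv),
                         ("species_cv", self.species_cv),
                         ("pue_sigma", self.pue_sigma),
                         ("pre_sigma", self.pre_sigma)):
            if cv < 0:
                raise ConfigError(f"{name} must be >= 0")


def _ln_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_factors(rng, cv: float, size) -> np.ndarray:
    """Lognormal multiplicative factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = _ln_sigma(cv)
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _country_names(n: int) -> list[str]:
    return [f"country_{i:02d}" for i in range(n)]


def generate_taxonomy(config: SynthConfig) -> pd.DataFrame:
    """Species -> order -> major-group table; every order nonempty and all
    three major groups covered."""
    n_ord = config.n_orders
    n_fin = max(1, round(n_ord * 0.6))
    n_cru = max(1, round(n_ord * 0.25))
    if n_fin + n_cru >= n_ord:  # keep at least one mollusk order
        n_fin = n_ord - n_cru - 1 if n_ord - n_cru - 1 >= 1 else 1
        n_cru = max(1, n_ord - n_fin - 1)
    order_group = (["finfish"] * n_fin + ["crustacean"] * n_cru
                   + ["mollusk"] * (n_ord - n_fin - n_cru))
    orders = [f"order_{i:03d}" for i in range(n_ord)]
    rows = []
    for i in range(config.n_species):
        j = i % n_ord  # round-robin guarantees every order is populated
        rows.append((f"sp_{i:04d}", orders[j], order_group[j]))
    return pd.DataFrame(rows, columns=["species", "order", "group"])


def generate_concentration_db(taxonomy: pd.DataFrame,
                              config: SynthConfig) -> pd.DataFrame:
    """Whole-body P concentration records, hierarchically dispersed.

    Species means sit lognormally around order means, which sit around the
    group means, all mean-preserving. A configurable fraction of species is
    "thin" (zero or one record); a configurable fraction of records is
    reported on dry basis with a moisture field.
    """
    rng = np.random.default_rng(config.seed + 1)
    orders = taxonomy["order"].unique()
    order_factor = dict(zip(
        orders, _mean_one_factors(rng, config.order_cv, len(orders))))
    sp_factor = _mean_one_factors(rng, config.species_cv, len(taxonomy))

    n_sp = len(taxonomy)
    counts = 2 + rng.poisson(max(config.records_per_species - 2, 0.0),
                             size=n_sp)
    n_thin = round(config.thin_fraction * n_sp)
    thin = rng.choice(n_sp, size=n_thin, replace=False)
    counts[thin[: n_thin // 2]] = 0
    counts[thin[n_thin // 2:]] = 1

    rows = []
    for (sp, order, group), f_sp, k in zip(
            taxonomy.itertuples(index=False, name=None), sp_factor, counts):
        sp_mean = config.group_mean_conc[group] * order_factor[order] * f_sp
        vals = sp_mean * _mean_one_factors(rng, config.species_cv, int(k))
        for v in vals:
            rows.append((sp, order, group, float(v)))
    df = pd.DataFrame(rows, columns=["species", "order", "group", "value"])
    df["basis"] = "wet"
    df["moisture"] = np.nan

    n_rec = len(df)
    n_dry = round(config.dry_fraction * n_rec)
    if n_dry:
        dry_idx = rng.choice(n_rec, size=n_dry, replace=False)
        moisture = rng.uniform(0.60, 0.85, size=n_dry)
        df.loc[dry_idx, "value"] = df.loc[dry_idx, "value"].to_numpy() / (
            1.0 - moisture)
        df.loc[dry_idx, "basis"] = "dry"
        df.loc[dry_idx, "moisture"] = moisture
        n_missing = round(config.missing_moisture_fraction * n_dry)
        if n_missing:
            df.loc[dry_idx[:n_missing], "moisture"] = np.nan
    df["origin"] = rng.choice(["wild", "raised"], size=n_rec, p=[0.25, 0.75])
    return df


def _wild_ramp(years: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Linear rise from wild_start_frac to 1.0 at the plateau year, flat after."""
    y0 = config.year_range[0]
    plateau = config.wild_plateau_year
    if plateau <= y0:
        return np.ones_like(years, dtype=float)
    t = np.clip((years - y0) / (plateau - y0), 0.0, 1.0)
    return config.wild_start_frac + (1.0 - config.wild_start_frac) * t


def _aqua_ramp(years: np.ndarray, config: SynthConfig) -> np.ndarray:
    """Near-zero before takeoff, then geometric growth."""
    dt = np.maximum(years - config.aquaculture_takeoff_year, 0)
    return config.aqua_start_frac * np.exp(config.aqua_growth_rate * dt)


def generate_production(taxonomy: pd.DataFrame,
                        config: SynthConfig) -> pd.DataFrame:
    """Per species x country x year production, capture and aquaculture."""
    rng = np.random.default_rng(config.seed + 2)
    countries = _country_names(config.n_countries)
    years = np.arange(config.year_range[0], config.year_range[1] + 1)
    wild_ramp = _wild_ramp(years, config)
    aqua_ramp = _aqua_ramp(years, config)

    order_index = {o: i for i, o in enumerate(taxonomy["order"].unique())}
    group_scale = {"finfish": 1.0, "crustacean": 0.25, "mollusk": 0.25}

    rows = []
    for sp, order, group in taxonomy.itertuples(index=False, name=None):
        base = (config.production_scale * group_scale[group]
                * rng.lognormal(0.0, 0.8))
        env = "freshwater" if order_index[order] % 2 == 0 else "marine"
        n_home = int(rng.integers(1, min(3, config.n_countries) + 1))
        home = rng.choice(countries, size=n_home, replace=False)
        split = rng.dirichlet(np.ones(n_home))
        cultured = rng.random() < config.cultured_fraction
        for country, w in zip(home, split):
            for year, wr, ar in zip(years, wild_ramp, aqua_ramp):
                rows.append((int(year), country, sp, order, group, env,
                             "capture", base * w * wr))
                if cultured:
                    rows.append((int(year), country, sp, order, group, env,
                                 "aquaculture", base * w * ar))
    df = pd.DataFrame(rows, columns=["year", "country", "species", "order",
                                     "group", "environment", "source",
                                     "weight"])
    if config.other_invert_share > 0:
        yearly_wild = df[df["source"] == "capture"].groupby("year")[
            "weight"].sum()
        extra = pd.DataFrame({
            "year": yearly_wild.index.to_numpy(),
            "country": countries[0],
            "species": "other_invertebrates",
            "order": np.nan,
            "group": "other-invertebrate",
            "environment": "marine",
            "source": "capture",
            "weight": yearly_wild.to_numpy() * config.other_invert_share,
        })
        df = pd.concat([df, extra], ignore_index=True)
    df["unit"] = "Tg"
    return df


def _truncated_lognormal(rng, median: float, sigma: float, n: int,
                         lo: float, hi: float) -> np.ndarray:
    """Median-preserving lognormal draws, resampled into [lo, hi]."""
    if not lo <= median <= hi:
        raise ConfigError(f"median {median} outside truncation [{lo}, {hi}]")
    if sigma == 0:
        return np.full(n, median)
    v = median * np.exp(rng.normal(0.0, sigma, size=n))
    bad = (v < lo) | (v > hi)
    while bad.any():
        v[bad] = median * np.exp(rng.normal(0.0, sigma, size=int(bad.sum())))
        bad = (v < lo) | (v > hi)
    return v


def generate_pue_db(config: SynthConfig) -> pd.DataFrame:
    """Culture-system PUE entries per six-group, right-skewed, truncated to
    the observed [0.01, 1.67] span; freshwater mollusk is empty by default to
    exercise the marine-mollusk substitution rule."""
    rng = np.random.default_rng(config.seed + 3)
    systems = np.array(["pond", "tank", "cage", "recirculating",
                        "flow-through"])
    rows = []
    for key in GROUP6:
        env, taxon = key.split("_", 1)
        n = (config.freshwater_mollusk_n if key == "freshwater_mollusk"
             else config.pue_per_group)
        if n == 0:
            continue
        vals = _truncated_lognormal(rng, config.pue_median[taxon],
                                    config.pue_sigma, n, PUE_MIN, PUE_MAX)
        sys_labels = rng.choice(systems, size=n)
        for v, s in zip(vals, sys_labels):
            rows.append((key, float(v), s, np.nan))
    return pd.DataFrame(rows, columns=["group6", "value", "system", "country"])


def generate_pre_db(config: SynthConfig) -> pd.DataFrame:
    """Feeding-experiment P-retention entries, truncated to (0, 1]."""
    rng = np.random.default_rng(config.seed + 4)
    rows = []
    for taxon in MAJOR_GROUPS:
        median = config.pre_median.get(taxon)
        if median is None or config.pre_per_group == 0:
            continue
        vals = _truncated_lognormal(rng, median, config.pre_sigma,
                                    config.pre_per_group, 1e-6, 1.0)
        rows.extend((taxon, float(v)) for v in vals)
    return pd.DataFrame(rows, columns=["group", "value"])


def generate_scaling_factors(countries, years,
                             config: SynthConfig) -> pd.DataFrame:
    """Country x year reconstruction factors >= 1, declining toward 1 and
    defined only through ``scaling_last_year``."""
    rng = np.random.default_rng(config.seed + 5)
    anchors = sorted(config.scaling_anchors)
    ax = np.array([a[0] for a in anchors], float)
    ay = np.array([a[1] for a in anchors], float)
    years = np.array([y for y in years if y <= config.scaling_last_year], int)
    mean_path = np.interp(years, ax, ay)
    rows = []
    for country in countries:
        offset = rng.uniform(0.97, 1.03)  # constant per country: yearly means
        # stay monotone between the anchor endpoints
        factors = np.maximum(mean_path * offset, 1.0)
        rows.extend((country, int(y), float(f))
                    for y, f in zip(years, factors))
    return pd.DataFrame(rows, columns=["country", "year", "factor"])


def generate_region_map(countries) -> pd.DataFrame:
    """Round-robin continent assignment for synthetic country labels."""
    return pd.DataFrame({
        "country": list(countries),
        "region": [CONTINENTS[i % len(CONTINENTS)]
                   for i in range(len(countries))],
        "year_start": np.nan,
        "year_end": np.nan,
    })


def generate_all(config: SynthConfig,
                 out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Generate the five input tables plus the region map; optionally write
    them as CSV with a manifest recording the seed and config."""
    taxonomy = generate_taxonomy(config)
    tables = {
        "taxonomy": taxonomy,
        "concentration": generate_concentration_db(taxonomy, config),
        "production": generate_production(taxonomy, config),
        "pue": generate_pue_db(config),
        "pre": generate_pre_db(config),
        "scaling": generate_scaling_factors(
            _country_names(config.n_countries),
            range(config.year_range[0], config.year_range[1] + 1), config),
        "region": generate_region_map(_country_names(config.n_countries)),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in tables.items():
            schema = data_io.SCHEMAS.get(name)
            paths[name] = data_io.write_table(df, out_dir / f"{name}.csv",
                                              schema)
        counts = {name: len(df) for name, df in tables.items()}
        cfg = asdict(config)
        cfg["year_range"] = list(config.year_range)
        cfg["scaling_anchors"] = [list(a) for a in config.scaling_anchors]
        data_io.write_manifest(out_dir / "manifest.json", inputs=paths,
                               config=cfg, seed=config.seed, counts=counts)
    return tables
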