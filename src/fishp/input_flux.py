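"""Stage 2: aquaculture P-input via six-group phosphorus-use efficiency.

P-input is ``sum_j P_harvest,j / PUE_j`` over the six environment x taxon
groups. Only aquaculture harvest enters; wild capture requires no feed or
fertilizer in this accounting. Group PUE is time-invariant and pooled
globally; the central value is the pool median.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import ENVIRONMENTS, GROUP6, MAJOR_GROUPS, SchemaError


def group_of(environment: str, group: str, *,
             other_invertebrate_as: str = "finfish") -> str:
    """Map an aquaculture record to its six-group key.

    Brackish must already be folded into marine. Other aquatic invertebrates
    are assigned to a configurable taxon pool (default finfish).
    """
    if environment not in ENVIRONMENTS:
        raise SchemaError(f"environment {environment!r} not in {ENVIRONMENTS}")
    taxon = group
    if group == "other-invertebrate":
        taxon = other_invertebrate_as
    if taxon not in MAJOR_GROUPS:
        raise SchemaError(f"group {group!r} has no PUE pool")
    return f"{environment}_{taxon}"


def assign_group6(production: pd.DataFrame, *,
                  other_invertebrate_as: str = "finfish") -> pd.Series:
    """Six-group key per row; NA for wild-capture rows."""
    keys = pd.Series(pd.NA, index=production.index, dtype=object)
    aqua = production["source"] == "aquaculture"
    keys.loc[aqua] = [
        group_of(env, grp, other_invertebrate_as=other_invertebrate_as)
        for env, grp in zip(production.loc[aqua, "environment"],
                            production.loc[aqua, "group"])
    ]
    return keys


def pue_pool(pue_db: pd.DataFrame, key: str) -> np.ndarray:
    """Empirical PUE values for one group key.

    Freshwater mollusk has no experimental coverage and borrows the marine
    mollusk pool.
    """
    if key not in GROUP6:
        raise SchemaError(f"unknown group key {key!r}")
    vals = pue_db.loc[pue_db["group6"] == key, "value"].to_numpy(float)
    if vals.size == 0 and key == "freshwater_mollusk":
        vals = pue_db.loc[pue_db["group6"] == "marine_mollusk",
                          "value"].to_numpy(float)
    if vals.size == 0:
        raise SchemaError(f"no PUE entries for group {key!r} (after substitution)")
    return vals


def group_pue(pue_db: pd.DataFrame, key: str,
              statistic: str = "median") -> float:
    """Central PUE for a group (median of its pool)."""
    pool = pue_pool(pue_db, key)
    if statistic == "median":
        return float(np.median(pool))
    if statistic == "mean":
        return float(pool.mean())
    raise SchemaError(f"unknown statistic {statistic!r}")


def compute_p_input(harvest_by_group: Mapping[str, float],
                    pue_by_group: Mapping[str, float]
                    ) -> tuple[float, dict[str, float]]:
    """P-input total and per group: ``P_harvest,j / PUE_j`` (Tg P)."""
    per_group: dict[str, float] = {}
    for key, p_hat in harvest_by_group.items():
        pue = pue_by_group[key]
        if not pue > 0:
            raise SchemaError(f"PUE for {key!r} must be > 0, got {pue!r}")
        per_group[key] = float(p_hat) / float(pue)
    return sum(per_group.values()), per_group
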