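"""Ace-points (AP) scoring of pigeon race records.

Each race awards points to the prize list — the fastest ~20% of starters.  With
``a`` birds on the prize list and a bird finishing in position ``b``, the score
is

    AP = (a - b + 1) / a * 100        for b <= a,
    AP = 0                            otherwise (including did-not-finish),

so the winner always receives 100 AP and the last prize position receives
100/a.  Races are classed as short (<= 400 km) or long (>= 500 km); the
400-500 km interval is undefined in this scheme and rejected by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import InputError

WEATHER_START_LEVELS = ("sunny", "changeable")
WEATHER_END_LEVELS = ("sunny", "changeable", "rainy", "windy", "cloudy")
SEX_LEVELS = ("male", "female")
BREEDER_LEVELS = ("A", "B")
CATEGORY_LEVELS = ("short", "long")

#: prize-list fraction of starters
PRIZE_FRACTION = 0.20


@dataclass(frozen=True)
class RaceRecord:
    """One pigeon's result in one race, with the covariates the model uses.

    ``position`` is ``None`` for a bird that did not finish; such records keep
    AP = 0 and stay in the dataset.
    """

    pigeon_id: str
    race_id: str
    distance_km: float
    n_starters: int
    position: Optional[int]
    weather_start: str
    weather_end: str
    breeder: str
    sex: str
    ap: Optional[float] = None


def prize_list_size(n_starters: int, rounding: str = "floor") -> int:
    """Number of prize positions: 20% of starters, minimum 1.

    Federations differ in how they round the 20%; ``rounding`` selects
    ``floor`` (default), ``round`` or ``ceil``.
    """
    if n_starters < 1:
        raise InputError(f"n_starters must be >= 1, got {n_starters}")
    x = PRIZE_FRACTION * n_starters
    if rounding == "floor":
        a = math.floor(x)
    elif rounding == "ceil":
        a = math.ceil(x)
    elif rounding == "round":
        a = round(x)
    else:
        raise InputError(f"unknown rounding mode {rounding!r}")
    return max(a, 1)


def ace_points(a: int, b: Optional[int]) -> float:
    """Eq.-style AP for prize-list size ``a`` and finishing position ``b``."""
    if a < 1:
        raise InputError(f"prize-list size must be >= 1, got {a}")
    if b is None:
        return 0.0
    if b < 1:
        raise InputError(f"position must be >= 1, got {b}")
    if b > a:
        return 0.0
    return (a - b + 1) / a * 100.0


def categorize_race(distance_km: float, strict: bool = True) -> str:
    """Classify a race distance as 'short' (<=400 km) or 'long' (>=500 km).

    Distances strictly between 400 and 500 km fall outside both definitions:
    an error in strict mode, nearest-boundary assignment otherwise.
    """
    if distance_km <= 0:
        raise InputError(f"distance must be positive, got {distance_km}")
    if distance_km <= 400:
        return "short"
    if distance_km >= 500:
        return "long"
    if strict:
        raise InputError(
            f"distance {distance_km} km is in the undefined 400-500 km gap"
        )
    return "short" if distance_km - 400 <= 500 - distance_km else "long"


def score_races(
    records: pd.DataFrame,
    rounding: str = "floor",
    strict_categories: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill in AP and race category for a race-record table.

    ``records`` needs columns ``race_id``, ``pigeon_id``, ``distance_km``,
    ``n_starters`` and ``position`` (NaN = did not finish).  Returns a copy
    with ``ap`` and ``category`` columns plus the per-race prize-list sizes.
    The operation is idempotent and independent of row order.
    """
    required = {"race_id", "pigeon_id", "distance_km", "n_starters", "position"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"race table is missing columns: {sorted(missing)}")

    out = records.copy()
    prize_sizes: dict[str, int] = {}
    ap = pd.Series(0.0, index=out.index)
    category = pd.Series("", index=out.index, dtype=object)

    for race_id, grp in out.groupby("race_id", sort=False):
        n_starters = grp["n_starters"].unique()
        if len(n_starters) != 1:
            raise InputError(f"race {race_id!r} has inconsistent n_starters values")
        distances = grp["distance_km"].unique()
        if len(distances) != 1:
            raise InputError(f"race {race_id!r} has inconsistent distances")
        finishers = grp["position"].dropna()
        if finishers.duplicated().any():
            raise InputError(f"race {race_id!r} has duplicate finishing positions")
        if (finishers > int(n_starters[0])).any():
            raise InputError(f"race {race_id!r} has a position exceeding n_starters")

        a = prize_list_size(int(n_starters[0]), rounding=rounding)
        prize_sizes[race_id] = a
        cat = categorize_race(float(distances[0]), strict=strict_categories)
        category.loc[grp.index] = cat
        for idx, pos in grp["position"].items():
            b = None if pd.isna(pos) else int(pos)
            ap.loc[idx] = ace_points(a, b)

    out["ap"] = ap
    out["category"] = category
    return out, prize_sizes


def record_to_dict(rec: RaceRecord) -> dict:
    """Flatten a RaceRecord for tabular output."""
    return {
        "pigeon_id": rec.pigeon_id,
        "race_id": rec.race_id,
        "distance_km": rec.distance_km,
        "n_starters": rec.n_starters,
        "position": rec.position,
        "weather_start": rec.weather_start,
        "weather_end": rec.weather_end,
        "breeder": rec.breeder,
        "sex": rec.sex,
        "ap": rec.ap,
    }
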