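"""Build six-part time-use compositions and the active-travel exposure flag.

The composition is defined from the primary-activity ('what') codes: part
minutes are 10 x the number of slots mapping to each component, so every
built composition sums to exactly 1440 minutes.  Active travel is a
separate, mode-based variable: a participant is exposed when at least one
slot's 'where' code is an active travel mode (on foot or bicycle).  A slot
can therefore contribute to the travel *component* via its what-code while
its where-code determines *exposure* — and recreational walking or cycling
(a leisure what-code at a non-travel location) never triggers exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import N_SLOTS
from .taxonomy import COMPONENTS, DEFAULT_MAPPING, ComponentMapping

__all__ = [
    "build_composition",
    "build_compositions",
    "derive_active_travel",
    "active_travel_minutes",
    "summarise_exposure",
    "ExposureSummary",
]

SLOT_MIN = 10
MINUTES_PER_DAY = 1440


def _map_components(what: np.ndarray, mapping: ComponentMapping) -> pd.Series:
    comp = pd.Series(np.asarray(what)).map(mapping.what_to_component)
    if comp.isna().any():
        bad = sorted(pd.Series(np.asarray(what))[comp.isna()].unique())
        raise KeyError(f"unmapped what-codes encountered: {bad}")
    return comp


def build_composition(
    what: np.ndarray, mapping: ComponentMapping = DEFAULT_MAPPING
) -> pd.Series:
    """Six-part composition (minutes/day) of a single QC-passed diary."""
    what = np.asarray(what)
    if what.shape != (N_SLOTS,):
        raise ValueError(f"a diary must have exactly {N_SLOTS} slots")
    comp = _map_components(what, mapping)
    counts = comp.value_counts().reindex(COMPONENTS, fill_value=0)
    return (counts * SLOT_MIN).astype(float).rename("minutes")


def derive_active_travel(
    where: np.ndarray, mapping: ComponentMapping = DEFAULT_MAPPING
) -> bool:
    """True iff any slot's where-code is an active travel mode."""
    return bool(np.isin(np.asarray(where), list(mapping.active_where_codes)).any())


def build_compositions(
    diaries: pd.DataFrame,
    participants: pd.DataFrame,
    mapping: ComponentMapping = DEFAULT_MAPPING,
) -> pd.DataFrame:
    """Compositions + exposure + covariates for every diary in the table.

    Returns one row per diary: participant id, the six part columns in
    minutes/day (summing to exactly 1440), the ``active_travel`` flag, age,
    sex, work status and day type.  Raises on any unmapped what-code.
    """
    comp = _map_components(diaries["what_code"].to_numpy(), mapping)
    tab = (
        pd.DataFrame(
            {
                "diary_id": diaries["diary_id"].to_numpy(),
                "participant_id": diaries["participant_id"].to_numpy(),
                "day_type": diaries["day_type"].to_numpy(),
                "component": comp.to_numpy(),
            }
        )
        .pivot_table(
            index=["participant_id", "diary_id", "day_type"],
            columns="component",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=list(COMPONENTS), fill_value=0)
        * SLOT_MIN
    )
    tab = tab.astype(float).reset_index()
    tab.columns.name = None

    active = (
        pd.Series(
            np.isin(diaries["where_code"].to_numpy(), list(mapping.active_where_codes)),
            index=diaries["diary_id"].to_numpy(),
        )
        .groupby(level=0)
        .any()
    )
    tab["active_travel"] = tab["diary_id"].map(active)
    covs = participants.set_index("participant_id")[["age", "sex", "work_status"]]
    tab = tab.join(covs, on="participant_id")
    return tab


def active_travel_minutes(
    diaries: pd.DataFrame, mapping: ComponentMapping = DEFAULT_MAPPING
) -> pd.Series:
    """Minutes/day in active travel modes per diary (10 x active-mode slots)."""
    is_active = np.isin(diaries["where_code"].to_numpy(), list(mapping.active_where_codes))
    return (
        pd.Series(is_active, index=diaries["diary_id"].to_numpy())
        .groupby(level=0)
        .sum()
        .astype(float)
        * SLOT_MIN
    ).rename("active_travel_min")


@dataclass(frozen=True)
class ExposureSummary:
    """Prevalence and dose of active travel, with the mode breakdown."""

    n: int
    n_exposed: int
    prevalence: float
    median_active_min: float | None  # None when nobody is exposed
    iqr_active_min: float | None
    pct_walking: float
    pct_cycling: float
    pct_both: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarise_exposure(
    diaries: pd.DataFrame, mapping: ComponentMapping = DEFAULT_MAPPING
) -> ExposureSummary:
    """Prevalence, median and IQR of active-travel minutes among the
    exposed, and the walking/cycling/both percentages (of all participants)."""
    where = diaries["where_code"].to_numpy()
    ids = diaries["diary_id"].to_numpy()
    walk = pd.Series(np.isin(where, list(mapping.on_foot_codes)), index=ids).groupby(level=0).any()
    cycle = pd.Series(np.isin(where, list(mapping.bicycle_codes)), index=ids).groupby(level=0).any()
    exposed = walk | cycle
    n = len(exposed)
    n_exp = int(exposed.sum())
    minutes = active_travel_minutes(diaries, mapping)[exposed[exposed].index]
    if n_exp:
        # quartiles as observed order statistics: diary durations are
        # multiples of 10 min and survey summaries quote observed values
        q25, q50, q75 = np.percentile(minutes, [25, 50, 75], method="nearest")
        med, iqr = float(q50), float(q75 - q25)
    else:
        med = iqr = None
    return ExposureSummary(
        n=n,
        n_exposed=n_exp,
        prevalence=n_exp / n if n else 0.0,
        median_active_min=med,
        iqr_active_min=iqr,
        pct_walking=100.0 * float((walk & ~cycle).sum()) / n if n else 0.0,
        pct_cycling=100.0 * float((cycle & ~walk).sum()) / n if n else 0.0,
        pct_both=100.0 * float((walk & cycle).sum()) / n if n else 0.0,
    )
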