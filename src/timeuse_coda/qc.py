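"""Diary quality control and one-diary-per-participant selection.

Filters applied, in the sequential order used for survey-style accounting:

1. General quality control (any failure removes the diary):
   more than 90 minutes of missing time; fewer than seven episodes of
   activity (an episode is a maximal run of consecutive slots sharing a
   primary-activity code); or two or more of the four basic activity
   categories (sleeping/resting, eating/drinking, personal care,
   exercise/travel) absent.
2. Analysis-specific checks on the survivors: a full 24 h of eligible
   activity codes (no missing slots, none of the 9960-9999 placeholder
   codes), and at least some sleep reported.
3. Diaries from participants under a minimum age (default 16 years).
4. Finally, one diary per remaining participant is selected uniformly at
   random so participants are not represented twice.

Each stage's removals are tallied on the diaries surviving the previous
stages, mirroring how survey analyses report their attrition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import N_SLOTS
from .taxonomy import BASIC_CATEGORIES, DEFAULT_MAPPING, ComponentMapping

__all__ = [
    "QcReport",
    "episode_count",
    "check_general_quality",
    "check_eligible_24h",
    "check_sleep_reported",
    "apply_qc",
    "select_one_diary_per_participant",
]

MAX_MISSING_MIN = 90
MIN_EPISODES = 7
SLOT_MIN = 10


def _check_slots(what: np.ndarray) -> np.ndarray:
    what = np.asarray(what)
    if what.shape != (N_SLOTS,):
        raise ValueError(f"a diary must have exactly {N_SLOTS} slots, got {what.shape}")
    return what


def episode_count(what: np.ndarray, missing: np.ndarray | None = None) -> int:
    """Number of activity episodes: maximal runs of a shared what-code.

    Missing slots do not form episodes and break a run in two, the standard
    time-use convention.
    """
    what = _check_slots(what)
    valid = np.ones(N_SLOTS, bool) if missing is None else ~np.asarray(missing, bool)
    n = 0
    prev = None
    for code, ok in zip(what, valid):
        if not ok:
            prev = None
            continue
        if code != prev:
            n += 1
            prev = code
    return n


def check_general_quality(
    what: np.ndarray,
    missing: np.ndarray | None = None,
    mapping: ComponentMapping = DEFAULT_MAPPING,
    conjunctive: bool = False,
) -> tuple[bool, list[str]]:
    """General diary quality control; returns (passed, failed-rule reasons).

    All three conditions are always evaluated so every reason is reported:
    ``missing_time`` (> 90 min missing, strict), ``few_episodes`` (< 7,
    strict) and ``missing_basic`` (>= 2 of the 4 basic activity categories
    absent).  With ``conjunctive=True`` a diary is only removed when all
    three conditions hold at once (the alternative reading of a removal
    narrative phrased as a conjunction); the default removes on any single
    failure.
    """
    what = _check_slots(what)
    miss = np.zeros(N_SLOTS, bool) if missing is None else np.asarray(missing, bool)
    reasons = []
    if int(miss.sum()) * SLOT_MIN > MAX_MISSING_MIN:
        reasons.append("missing_time")
    if episode_count(what, miss) < MIN_EPISODES:
        reasons.append("few_episodes")
    cats = {mapping.basic_category.get(int(c)) for c in what[~miss]}
    if len(BASIC_CATEGORIES) - len(cats & set(BASIC_CATEGORIES)) >= 2:
        reasons.append("missing_basic")
    passed = len(reasons) < 3 if conjunctive else not reasons
    return passed, reasons


def check_eligible_24h(
    what: np.ndarray,
    missing: np.ndarray | None = None,
    mapping: ComponentMapping = DEFAULT_MAPPING,
) -> bool:
    """True iff every slot carries an eligible activity code.

    Fails when any slot is missing or coded to one of the ineligible
    placeholder codes (9960, 9970, 9980, 9990, 9991, 9999).
    """
    what = _check_slots(what)
    if missing is not None and np.asarray(missing, bool).any():
        return False
    return not np.isin(what, list(mapping.ineligible_codes)).any()


def check_sleep_reported(
    what: np.ndarray, mapping: ComponentMapping = DEFAULT_MAPPING
) -> bool:
    """True iff at least one slot maps to the sleep component.

    Presence, not duration: a single 10-minute sleep slot passes.  Raises on
    what-codes absent from the mapping (ineligible codes should have been
    screened first).
    """
    what = _check_slots(what)
    components = [mapping.component_of(int(c)) for c in np.unique(what)]
    return "sleep" in components


@dataclass
class QcReport:
    """Sequential QC accounting: per-stage removal counts plus a per-diary
    failure table listing every failed rule."""

    n_input: int
    removed_general: int
    removed_ineligible: int
    removed_no_sleep: int
    removed_underage: int
    n_retained: int
    failures: pd.DataFrame = field(repr=False)  # diary_id, stage, reasons

    @property
    def n_removed(self) -> int:
        return (
            self.removed_general
            + self.removed_ineligible
            + self.removed_no_sleep
            + self.removed_underage
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_general": self.removed_general,
            "removed_ineligible": self.removed_ineligible,
            "removed_no_sleep": self.removed_no_sleep,
            "removed_underage": self.removed_underage,
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def log_lines(self) -> list[str]:
        d = self.to_dict()
        return [
            f"QC input diaries: {d['n_input']}",
            f"removed at general quality control: {d['removed_general']}",
            f"removed reporting <24h of eligible codes: {d['removed_ineligible']}",
            f"removed reporting no sleep: {d['removed_no_sleep']}",
            f"removed under minimum age: {d['removed_underage']}",
            f"retained: {d['n_retained']}",
        ]


def _per_diary_table(diaries: pd.DataFrame, mapping: ComponentMapping) -> pd.DataFrame:
    """Vectorised per-diary QC statistics from the long slot table."""
    d = diaries.sort_values(["diary_id", "slot_index"], kind="stable")
    if (d.groupby("diary_id").size() != N_SLOTS).any():
        raise ValueError(f"every diary must have exactly {N_SLOTS} slots")
    what = d["what_code"].to_numpy()
    miss = d["missing"].to_numpy(dtype=bool)
    gid = d["diary_id"].to_numpy()
    new_diary = np.r_[True, gid[1:] != gid[:-1]]

    # episode starts: valid slot whose code differs from the previous valid
    # slot in the same diary, or that follows a missing slot / diary break
    prev_invalid = np.r_[True, miss[:-1]]
    prev_what = np.r_[0, what[:-1]]
    starts = ~miss & (new_diary | prev_invalid | (what != prev_what))

    cat = pd.Series(what).map(mapping.basic_category).to_numpy(dtype=object)
    cat[miss] = None
    ineligible = np.isin(what, list(mapping.ineligible_codes))
    comp = pd.Series(what).map(mapping.what_to_component)
    is_sleep = (comp == "sleep").to_numpy()

    g = pd.DataFrame(
        {
            "diary_id": gid,
            "participant_id": d["participant_id"].to_numpy(),
            "missing": miss,
            "episode_start": starts,
            "basic_cat": cat,
            "ineligible": ineligible,
            "sleep": is_sleep,
        }
    ).groupby("diary_id", sort=False)
    out = pd.DataFrame(
        {
            "participant_id": g["participant_id"].first(),
            "missing_slots": g["missing"].sum(),
            "episodes": g["episode_start"].sum(),
            "basic_present": g["basic_cat"].nunique(),
            "has_ineligible": g["ineligible"].any(),
            "has_sleep": g["sleep"].any(),
        }
    )
    return out


def apply_qc(
    diaries: pd.DataFrame,
    participants: pd.DataFrame,
    mapping: ComponentMapping = DEFAULT_MAPPING,
    min_age: float = 16,
    conjunctive_general: bool = False,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply all QC stages sequentially; returns (retained diaries, report).

    Stage order: general QC, then eligible-24h / no-sleep, then age below
    ``min_age``; each stage is tallied on the survivors of the previous
    stages.  Diaries whose participant has no covariate record raise.
    """
    stats = _per_diary_table(diaries, mapping)
    ages = participants.set_index("participant_id")["age"]
    orphan = ~stats["participant_id"].isin(ages.index)
    if orphan.any():
        bad = stats.loc[orphan, "participant_id"].unique()[:5]
        raise ValueError(f"diaries with no participant record, e.g. participant ids {list(bad)}")
    stats["age"] = stats["participant_id"].map(ages)

    fail_missing = stats["missing_slots"] * SLOT_MIN > MAX_MISSING_MIN
    fail_episodes = stats["episodes"] < MIN_EPISODES
    fail_basic = len(BASIC_CATEGORIES) - stats["basic_present"] >= 2
    n_general_rules = (
        fail_missing.astype(int) + fail_episodes.astype(int) + fail_basic.astype(int)
    )
    fail_general = n_general_rules == 3 if conjunctive_general else n_general_rules > 0

    survivors = ~fail_general
    fail_inelig = survivors & stats["has_ineligible"]
    survivors = survivors & ~fail_inelig
    fail_sleep = survivors & ~stats["has_sleep"]
    survivors = survivors & ~fail_sleep
    fail_age = survivors & (stats["age"] < min_age)
    survivors = survivors & ~fail_age

    rows = []
    for did in stats.index[fail_general]:
        reasons = [
            r
            for r, f in (
                ("missing_time", fail_missing),
                ("few_episodes", fail_episodes),
                ("missing_basic", fail_basic),
            )
            if f[did]
        ]
        rows.append((did, "general", reasons))
    rows += [(d, "ineligible", ["ineligible"]) for d in stats.index[fail_inelig]]
    rows += [(d, "no_sleep", ["no_sleep"]) for d in stats.index[fail_sleep]]
    rows += [(d, "underage", ["underage"]) for d in stats.index[fail_age]]
    failures = pd.DataFrame(rows, columns=["diary_id", "stage", "reasons"])

    report = QcReport(
        n_input=len(stats),
        removed_general=int(fail_general.sum()),
        removed_ineligible=int(fail_inelig.sum()),
        removed_no_sleep=int(fail_sleep.sum()),
        removed_underage=int(fail_age.sum()),
        n_retained=int(survivors.sum()),
        failures=failures,
    )
    retained_ids = stats.index[survivors]
    retained = diaries[diaries["diary_id"].isin(retained_ids)].reset_index(drop=True)
    return retained, report


def select_one_diary_per_participant(diaries: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep exactly one diary per participant, chosen uniformly at random.

    Deterministic for a fixed seed: diaries are ordered by (participant,
    diary id) before drawing, so the selection does not depend on input row
    order.
    """
    meta = (
        diaries[["participant_id", "diary_id"]]
        .drop_duplicates()
        .sort_values(["participant_id", "diary_id"], kind="stable")
        .reset_index(drop=True)
    )
    rng = np.random.default_rng(seed)
    meta["u"] = rng.random(len(meta))
    keep = meta.loc[meta.groupby("participant_id")["u"].idxmin(), "diary_id"]
    return diaries[diaries["diary_id"].isin(keep)].reset_index(drop=True)
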