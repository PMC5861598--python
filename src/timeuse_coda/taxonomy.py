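"""Activity-code taxonomy and the six-component mapping.

Harmonised time-use diaries code each 10-minute slot with a numeric primary
activity ('what') code and a location/mode ('where') code.  This module maps
what-codes onto the six mutually exclusive analysis components

    sleep, leisure_mvpa, screen, non_discretionary, travel, other

and classifies where-codes into active travel modes (on foot, bicycle)
versus motorised modes.  The full national-survey taxonomy runs to several
hundred codes; the compact default shipped here covers the same structure
(at least two codes per component, the six ineligible placeholder codes and
the four basic-activity markers used by quality control) and can be replaced
by loading a full mapping from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

COMPONENTS = (
    "sleep",
    "leisure_mvpa",
    "screen",
    "non_discretionary",
    "travel",
    "other",
)

#: The four basic activity categories used by general diary quality control.
BASIC_CATEGORIES = (
    "sleeping_resting",
    "eating_drinking",
    "personal_care",
    "exercise_travel",
)

#: Placeholder codes marking time that is not an eligible activity report.
INELIGIBLE_CODES = frozenset({9960, 9970, 9980, 9990, 9991, 9999})


@dataclass(frozen=True)
class ComponentMapping:
    """Mapping from diary codes to analysis components and travel modes.

    ``what_to_component`` must be mutually exclusive and exhaustive over the
    eligible codes a diary may contain; unmapped codes raise at use time so
    taxonomy gaps surface loudly rather than silently dropping minutes.
    """

    what_to_component: dict[int, str]
    basic_category: dict[int, str] = field(default_factory=dict)
    ineligible_codes: frozenset[int] = INELIGIBLE_CODES
    on_foot_codes: frozenset[int] = frozenset({11})
    bicycle_codes: frozenset[int] = frozenset({12})
    motorised_codes: frozenset[int] = frozenset({13, 14})

    def __post_init__(self) -> None:
        bad = set(self.what_to_component.values()) - set(COMPONENTS)
        if bad:
            raise ValueError(f"unknown components in mapping: {sorted(bad)}")
        bad = set(self.basic_category.values()) - set(BASIC_CATEGORIES)
        if bad:
            raise ValueError(f"unknown basic categories: {sorted(bad)}")
        overlap = set(self.what_to_component) & self.ineligible_codes
        if overlap:
            raise ValueError(f"ineligible codes mapped to components: {sorted(overlap)}")

    @property
    def active_where_codes(self) -> frozenset[int]:
        return self.on_foot_codes | self.bicycle_codes

    def component_of(self, code: int) -> str:
        try:
            return self.what_to_component[int(code)]
        except KeyError:
            raise KeyError(
                f"what-code {code} has no component mapping; extend the "
                "ComponentMapping before building compositions"
            ) from None

    def codes_for(self, component: str) -> list[int]:
        return sorted(c for c, comp in self.what_to_component.items() if comp == component)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "what_code": code,
                "component": comp,
                "basic_category": self.basic_category.get(code),
            }
            for code, comp in sorted(self.what_to_component.items())
        ]
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        doc = {
            "what_to_component": {int(k): v for k, v in self.what_to_component.items()},
            "basic_category": {int(k): v for k, v in self.basic_category.items()},
            "ineligible_codes": sorted(self.ineligible_codes),
            "on_foot_codes": sorted(self.on_foot_codes),
            "bicycle_codes": sorted(self.bicycle_codes),
            "motorised_codes": sorted(self.motorised_codes),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ComponentMapping":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            what_to_component={int(k): v for k, v in doc["what_to_component"].items()},
            basic_category={int(k): v for k, v in doc.get("basic_category", {}).items()},
            ineligible_codes=frozenset(doc.get("ineligible_codes", INELIGIBLE_CODES)),
            on_foot_codes=frozenset(doc.get("on_foot_codes", {11})),
            bicycle_codes=frozenset(doc.get("bicycle_codes", {12})),
            motorised_codes=frozenset(doc.get("motorised_codes", {13, 14})),
        )


# Compact default taxonomy: >= 2 what-codes per component.  Code families
# loosely follow harmonised-survey conventions (1xx sleep/personal, 2xx
# eating/care, 3xx work & chores, 5xx social/hobbies, 6xx exercise, 8xx
# media, 9xx travel).
_WHAT = {
    110: "sleep",  # night sleep
    120: "sleep",  # nap / resting
    210: "other",  # eating & drinking
    231: "other",  # washing, dressing, personal care
    310: "non_discretionary",  # paid work
    321: "non_discretionary",  # study
    331: "non_discretionary",  # housework, cooking
    341: "non_discretionary",  # caring duties
    361: "non_discretionary",  # shopping & services
    510: "other",  # socialising
    525: "other",  # hobbies
    531: "other",  # reading
    611: "leisure_mvpa",  # walking & hiking (recreational)
    621: "leisure_mvpa",  # sport & exercise
    821: "screen",  # television & video
    831: "screen",  # computer, internet, games
    901: "travel",  # travel to/from work or study
    911: "travel",  # travel for shopping & services
    921: "travel",  # other travel
}

_BASIC = {
    110: "sleeping_resting",
    120: "sleeping_resting",
    210: "eating_drinking",
    231: "personal_care",
    611: "exercise_travel",
    621: "exercise_travel",
    901: "exercise_travel",
    911: "exercise_travel",
    921: "exercise_travel",
}

DEFAULT_MAPPING = ComponentMapping(what_to_component=_WHAT, basic_category=_BASIC)

#: Location ('where') codes used by the compact taxonomy.
WHERE_HOME = 1
WHERE_WORK = 2
WHERE_OTHER = 3
WHERE_ON_FOOT = 11
WHERE_BICYCLE = 12
WHERE_CAR = 13
WHERE_PUBLIC_TRANSPORT = 14
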