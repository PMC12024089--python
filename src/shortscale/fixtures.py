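"""Packaged reference data.

* the full 90-item SCL-90 bank with the standard published subscale map,
* ``cscl11`` — the published 11-item short form of the Chinese SCL-90
  (items 8, 9, 16, 30, 33, 45, 52, 63, 66, 70, 85) with its subscale map,
* the reported unidimensional EFA loadings for those 11 items, packaged purely
  as a comparison fixture (they are sample statistics of the original survey,
  never an expected value in tests).

Only the 11 short-form stems are stored verbatim; stems for the remaining
items are left empty rather than redistributing the full instrument text.
"""

from __future__ import annotations

import pandas as pd

from .core import ItemBank, ShortscaleError

#: Standard SCL-90 subscale composition (item numbers per subscale).
SCL90_SUBSCALE_ITEMS: dict[str, tuple[int, ...]] = {
    "SOM": (1, 4, 12, 27, 40, 42, 48, 49, 52, 53, 56, 58),
    "OC": (3, 9, 10, 28, 38, 45, 46, 51, 55, 65),
    "IS": (6, 21, 34, 36, 37, 41, 61, 69, 73),
    "DEP": (5, 14, 15, 20, 22, 26, 29, 30, 31, 32, 54, 71, 79),
    "ANX": (2, 17, 23, 33, 39, 57, 72, 78, 80, 86),
    "HOS": (11, 24, 63, 67, 74, 81),
    "PHOB": (13, 25, 47, 50, 70, 75, 82),
    "PAR": (8, 18, 43, 68, 76, 83),
    "PSY": (7, 16, 35, 62, 77, 84, 85, 87, 88, 90),
    "ADD": (19, 44, 59, 60, 64, 66, 89),
}

#: The published 11-item short form: item number -> (stem, subscale).
CSCL11_ITEMS: dict[int, tuple[str, str]] = {
    8: ("Feeling others are to blame for most of your troubles", "PAR"),
    9: ("Trouble remembering things", "OC"),
    16: ("Hearing voices that other people do not hear", "PSY"),
    30: ("Feeling blue", "DEP"),
    33: ("Feeling fearful", "ANX"),
    45: ("Having to check and double-check what you do", "OC"),
    52: ("Numbness or tingling in parts of your body", "SOM"),
    63: ("Having urges to beat, injure, or harm someone", "HOS"),
    66: ("Sleep that is restless or disturbed", "ADD"),
    70: ("Feeling uneasy in crowds, such as shopping or at a movie", "PHOB"),
    85: ("The idea that you should be punished for your sins", "PSY"),
}

#: Reported unidimensional EFA loadings of the 11-item short form
#: (sample statistics of the original survey; comparison fixture only).
CSCL11_REFERENCE_LOADINGS: dict[int, float] = {
    8: 0.584, 9: 0.575, 16: 0.425, 30: 0.748, 33: 0.690, 45: 0.574,
    52: 0.541, 63: 0.606, 66: 0.491, 70: 0.555, 85: 0.547,
}


class ReferenceScale:
    """Immutable named item subset with subscale labels."""

    def __init__(self, name: str, item_ids, subscales, source: str = ""):
        self.name = name
        self.item_ids = tuple(item_ids)
        self.subscales = tuple(subscales)
        self.source = source

    def __len__(self):
        return len(self.item_ids)

    def __repr__(self):
        return f"ReferenceScale({self.name!r}, {len(self)} items)"


def scl90_bank() -> ItemBank:
    """The full 90-item bank with the standard subscale map, in item order."""
    rows = []
    sub_of = {
        item: sub for sub, items in SCL90_SUBSCALE_ITEMS.items() for item in items
    }
    for item in range(1, 91):
        stem = CSCL11_ITEMS.get(item, ("",))[0]
        rows.append({"item_id": item, "stem": stem, "subscale": sub_of[item]})
    return ItemBank(pd.DataFrame(rows))


_REGISTRY = {}


def _register():
    items = sorted(CSCL11_ITEMS)
    _REGISTRY["cscl11"] = ReferenceScale(
        "cscl11",
        items,
        [CSCL11_ITEMS[i][1] for i in items],
        source="published 11-item short form of the Chinese SCL-90",
    )


_register()


def load_reference(name: str) -> ReferenceScale:
    """Look up a packaged reference scale by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ShortscaleError(
            f"unknown reference scale {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_references() -> list[str]:
    return sorted(_REGISTRY)
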