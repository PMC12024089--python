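"""Core data model: item banks, Likert response matrices, scoring, risk labeling.

The SCL-90 family of symptom checklists is scored on a 5-point Likert scale
(1 = "no problem" .. 5 = "very serious").  The Global Severity Index (GSI) is
the mean of all item scores; respondents whose GSI T-score (mean 50, SD 10)
is at or above 63 form the high-risk group for clinically significant
psychological distress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical SCL-90 subscale labels, in conventional order.
SUBSCALES: tuple[str, ...] = (
    "SOM", "OC", "IS", "DEP", "ANX", "HOS", "PHOB", "PAR", "PSY", "ADD",
)

LIKERT_MIN = 1
LIKERT_MAX = 5


class ShortscaleError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(ShortscaleError):
    """An input violated a documented invariant."""


class ParseError(ShortscaleError):
    """A file could not be parsed; the message carries coordinates."""


def _item_column(item_id) -> str:
    """CSV header for an item: integers become ``item_<k>``, strings pass through."""
    if isinstance(item_id, (int, np.integer)):
        return f"item_{int(item_id)}"
    return str(item_id)


def _parse_item_header(name: str):
    """Inverse of :func:`_item_column`: ``item_8`` -> 8, otherwise the string."""
    name = str(name).strip()
    if name.startswith("item_"):
        suffix = name[5:]
        if suffix.isdigit():
            return int(suffix)
    if name.isdigit():
        return int(name)
    return name


@dataclass(frozen=True)
class ItemBank:
    """Ordered table of items: id, stem text, and subscale membership.

    Item ids must be unique; each item belongs to exactly one subscale.
    """

    table: pd.DataFrame  # columns: item_id, stem, subscale

    def __post_init__(self):
        required = {"item_id", "stem", "subscale"}
        if not required.issubset(self.table.columns):
            raise ValidationError(
                f"item bank needs columns {sorted(required)}, got {list(self.table.columns)}"
            )
        ids = self.table["item_id"].tolist()
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate item_ids in bank: {dupes}")
        bad = set(self.table["subscale"]) - set(SUBSCALES)
        if bad:
            raise ValidationError(f"unknown subscale labels: {sorted(bad)}")

    @property
    def item_ids(self) -> list:
        return self.table["item_id"].tolist()

    def subscale_of(self, item_id) -> str:
        row = self.table.loc[self.table["item_id"] == item_id, "subscale"]
        if row.empty:
            raise ValidationError(f"item {item_id!r} not in bank")
        return row.iloc[0]

    def items_in(self, subscale: str) -> list:
        return self.table.loc[self.table["subscale"] == subscale, "item_id"].tolist()

    @property
    def subscales(self) -> list[str]:
        """Subscales present in the bank, in canonical order."""
        present = set(self.table["subscale"])
        return [s for s in SUBSCALES if s in present]

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        df = pd.read_csv(path, dtype={"stem": str, "subscale": str}, keep_default_na=False)
        df["item_id"] = [_parse_item_header(v) for v in df["item_id"]]
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ResponseMatrix:
    """n respondents x p items of integer Likert responses in {1..5}."""

    values: np.ndarray
    item_ids: list
    respondent_ids: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("responses must be a 2-D matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.round(self.values)):
                raise ValidationError("responses must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.size and (
            self.values.min() < LIKERT_MIN or self.values.max() > LIKERT_MAX
        ):
            bad = np.argwhere((self.values < LIKERT_MIN) | (self.values > LIKERT_MAX))[0]
            raise ValidationError(
                f"response out of range 1..5 at row {bad[0]}, column {bad[1]}"
            )
        self.item_ids = list(self.item_ids)
        if len(self.item_ids) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.item_ids)} item_ids for {self.values.shape[1]} columns"
            )
        if len(set(map(str, self.item_ids))) != len(self.item_ids):
            raise ValidationError("duplicate item_ids")
        if self.respondent_ids is None:
            self.respondent_ids = list(range(self.values.shape[0]))
        else:
            self.respondent_ids = list(self.respondent_ids)
            if len(self.respondent_ids) != self.values.shape[0]:
                raise ValidationError("respondent_ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column_index(self, item_ids: Iterable) -> np.ndarray:
        lookup = {item: j for j, item in enumerate(self.item_ids)}
        try:
            return np.array([lookup[i] for i in item_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"item {exc.args[0]!r} not present in responses") from None

    def subset(self, item_ids: Sequence) -> "ResponseMatrix":
        idx = self.column_index(item_ids)
        return ResponseMatrix(self.values[:, idx], list(item_ids), self.respondent_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[_item_column(i) for i in self.item_ids]
        )
        df.insert(0, "respondent_id", self.respondent_ids)
        return df


def read_responses(path) -> ResponseMatrix:
    """Read a response CSV (header of item ids, one respondent per row).

    An optional leading ``respondent_id`` column is honored.  Any cell that is
    not an integer in 1..5 raises :class:`ParseError` naming its coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with open(path) as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
    if len(header) != len(set(header)):
        raise ParseError(f"duplicate header ids in {path}")
    df = pd.read_csv(path)
    respondent_ids = None
    if df.columns[0] == "respondent_id":
        respondent_ids = df["respondent_id"].tolist()
        df = df.drop(columns=["respondent_id"])
    item_ids = [_parse_item_header(c) for c in df.columns]
    if len(set(map(str, item_ids))) != len(item_ids):
        raise ParseError(f"duplicate item ids after header parsing in {path}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=np.int64)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(df.iloc[:, j], errors="coerce")
        bad = col.isna() | (col != np.floor(col)) | (col < LIKERT_MIN) | (col > LIKERT_MAX)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"invalid response {raw[i, j]!r} at row {i + 2}, column "
                f"{df.columns[j]!r} of {path} (expected integer 1..5)"
            )
        values[:, j] = col.astype(np.int64)
    return ResponseMatrix(values, item_ids, respondent_ids)


def write_responses(r: ResponseMatrix, path) -> None:
    r.to_frame().to_csv(path, index=False)


@dataclass
class ScoreReport:
    """GSI and per-subscale mean scores, one row per respondent."""

    gsi: np.ndarray
    subscale_scores: pd.DataFrame  # columns = subscale labels


def compute_scores(r: ResponseMatrix, bank: ItemBank) -> ScoreReport:
    """GSI = row mean over all present items; subscale scores = row means per subscale.

    Every item in ``r`` must be registered in ``bank``.
    """
    missing = [i for i in r.item_ids if i not in set(bank.item_ids)]
    if missing:
        raise ValidationError(f"items not in bank: {missing[:5]}")
    gsi = r.values.mean(axis=1)
    cols = {}
    present = set(r.item_ids)
    for sub in bank.subscales:
        items = [i for i in bank.items_in(sub) if i in present]
        if items:
            idx = r.column_index(items)
            cols[sub] = r.values[:, idx].mean(axis=1)
    return ScoreReport(gsi=gsi, subscale_scores=pd.DataFrame(cols, index=r.respondent_ids))


def gsi_scores(r: ResponseMatrix) -> np.ndarray:
    """Global Severity Index: the plain row mean over all items present."""
    return r.values.mean(axis=1)


T_SCORE_CUTOFF = 63.0


@dataclass
class RiskLabeling:
    """T-standardized GSI and the boolean high-risk flags (T >= 63, inclusive)."""

    t_scores: np.ndarray
    labels: np.ndarray
    norm_mean: float
    norm_sd: float


def label_high_risk(gsi, norm_mean: float, norm_sd: float) -> RiskLabeling:
    """T = 50 + 10*(GSI - norm_mean)/norm_sd; high risk iff T >= 63 (inclusive)."""
    if norm_sd <= 0:
        raise ValidationError(f"norm_sd must be positive, got {norm_sd}")
    gsi = np.asarray(gsi, dtype=float)
    t = 50.0 + 10.0 * (gsi - norm_mean) / norm_sd
    return RiskLabeling(t_scores=t, labels=t >= T_SCORE_CUTOFF,
                        norm_mean=float(norm_mean), norm_sd=float(norm_sd))


def split_train_test(
    r: ResponseMatrix, test_fraction: float = 0.2, seed: int = 0, stratify_labels=None
) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Random disjoint row partition into (train, test).

    Train size is ``round(n * (1 - test_fraction))``.  With
    ``stratify_labels`` the split preserves label proportions per stratum.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = r.n
    n_train = int(round(n * (1.0 - test_fraction)))
    if n - n_train < 1:
        raise ValidationError("test split would be empty")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape[0] != n:
            raise ValidationError("stratify_labels length mismatch")
        train_parts, test_parts = [], []
        for val in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == val))
            k = int(round(len(idx) * (1.0 - test_fraction)))
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
        if len(test_idx) < 1:
            raise ValidationError("test split would be empty")

    def take(idx):
        return ResponseMatrix(
            r.values[idx], r.item_ids, [r.respondent_ids[i] for i in idx]
        )

    return take(train_idx), take(test_idx)
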