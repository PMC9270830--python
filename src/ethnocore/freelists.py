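"""Data model and I/O for free-list interview data.

A free list is the ordered sequence of items (here: medicinal plant names)
an informant recalls for a cultural domain.  The canonical interchange
format is a long CSV with columns ``informant,group,rank,item`` where
``rank`` is 1-based recall order within one informant's list and ``group``
tags the collection an informant belongs to (e.g. interview period or life
stage).  One file may hold several groups.
"""

from __future__ import annotations

import io
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FreeListRecord",
    "FreeListDataset",
    "DatasetSummary",
    "FreeListValidationError",
    "read_freelists",
    "read_freelists_wide",
    "write_freelists",
    "read_synonym_map",
    "canonicalize_items",
    "summarize",
]

CANONICAL_COLUMNS = ("informant", "group", "rank", "item")


class FreeListValidationError(ValueError):
    """Raised when free-list data violates the structural invariants."""


@dataclass(frozen=True)
class FreeListRecord:
    """One cited item: informant, group tag, 1-based recall rank, item name."""

    informant_id: str
    group_label: str
    rank: int
    item_name: str


@dataclass(frozen=True)
class DatasetSummary:
    """Parameters of a dataset that the null model must match.

    ``n_informants`` (N), ``n_items`` (M, distinct names cited by anyone) and
    the list-length multiset (hence the mean citations per informant) fully
    specify the null scenario used by the salience threshold.
    """

    n_informants: int
    n_items: int
    list_lengths: tuple[int, ...]

    @property
    def mean_list_length(self) -> float:
        return sum(self.list_lengths) / self.n_informants

    def __post_init__(self) -> None:
        if self.n_informants < 1 or self.n_items < 1:
            raise FreeListValidationError("summary requires N >= 1 and M >= 1")
        if len(self.list_lengths) != self.n_informants:
            raise FreeListValidationError("one list length per informant required")


class FreeListDataset:
    """Validated collection of free-list records.

    Informants are identified by the pair ``(informant_id, group_label)`` so
    the same person interviewed in two periods contributes two lists.
    """

    def __init__(self, records: Iterable[FreeListRecord]):
        recs = list(records)
        if not recs:
            raise FreeListValidationError("dataset is empty")
        self._df = pd.DataFrame(
            {
                "informant": [r.informant_id for r in recs],
                "group": [r.group_label for r in recs],
                "rank": [r.rank for r in recs],
                "item": [r.item_name for r in recs],
            }
        )
        self._validate()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FreeListDataset":
        obj = cls.__new__(cls)
        obj._df = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        obj._validate()
        return obj

    def _validate(self) -> None:
        df = self._df
        if df.empty:
            raise FreeListValidationError("dataset is empty")
        if (df["rank"] < 1).any():
            raise FreeListValidationError("ranks must be >= 1")
        for (inf, grp), sub in df.groupby(["informant", "group"], sort=False):
            dup = sub["item"][sub["item"].duplicated()]
            if not dup.empty:
                raise FreeListValidationError(
                    f"duplicate item {dup.iloc[0]!r} for informant {inf!r} (group {grp!r})"
                )
            ranks = sorted(sub["rank"])
            expected = list(range(1, len(ranks) + 1))
            if ranks != expected:
                missing = sorted(set(expected) - set(ranks))
                raise FreeListValidationError(
                    f"rank gap for informant {inf!r} (group {grp!r}): "
                    f"missing ranks {missing}, got {sorted(sub['rank'])}"
                )

    # -- derived views ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format copy with columns informant, group, rank, item."""
        return self._df.copy()

    @property
    def records(self) -> list[FreeListRecord]:
        return [
            FreeListRecord(r.informant, r.group, int(r.rank), r.item)
            for r in self._df.itertuples(index=False)
        ]

    @property
    def informants(self) -> list[tuple[str, str]]:
        """Roster of (informant_id, group_label) pairs, in first-seen order."""
        seen = self._df[["informant", "group"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))

    @property
    def n_informants(self) -> int:
        return len(self.informants)

    @property
    def item_pool(self) -> list[str]:
        return sorted(self._df["item"].unique())

    @property
    def n_items(self) -> int:
        return self._df["item"].nunique()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self._df["group"]))

    def list_lengths(self) -> dict[tuple[str, str], int]:
        return {
            key: len(sub) for key, sub in self._df.groupby(["informant", "group"], sort=False)
        }

    def subset_group(self, group_label: str) -> "FreeListDataset":
        sub = self._df[self._df["group"] == group_label]
        if sub.empty:
            raise FreeListValidationError(f"no records for group {group_label!r}")
        return FreeListDataset.from_frame(sub)

    def ordered_list(self, informant_id: str, group_label: str) -> list[str]:
        sub = self._df[
            (self._df["informant"] == informant_id) & (self._df["group"] == group_label)
        ]
        return list(sub.sort_values("rank")["item"])

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FreeListDataset):
            return NotImplemented
        key = ["informant", "group", "rank", "item"]
        a = self._df.sort_values(key).reset_index(drop=True)
        b = other._df.sort_values(key).reset_index(drop=True)
        return a.equals(b)


# -- readers / writers ----------------------------------------------------

def read_freelists(
    source, column_map: Mapping[str, str] | None = None
) -> FreeListDataset:
    """Read a long-format free-list CSV (``informant,group,rank,item``).

    ``column_map`` maps canonical names to the file's actual headers, e.g.
    ``{"informant": "ID", "item": "plant"}``.  Row order is irrelevant;
    ranks alone define recall order.
    """
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if df.empty:
        raise FreeListValidationError("empty free-list file")
    rename = {}
    column_map = column_map or {}
    for canon in CANONICAL_COLUMNS:
        actual = column_map.get(canon, canon)
        if actual not in df.columns:
            raise FreeListValidationError(
                f"missing column {actual!r} (for {canon!r}); found {list(df.columns)}"
            )
        rename[actual] = canon
    df = df.rename(columns=rename)[list(CANONICAL_COLUMNS)]
    try:
        df["rank"] = df["rank"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FreeListValidationError(f"non-integer rank: {exc}") from exc
    return FreeListDataset.from_frame(df)


def read_freelists_wide(source, group_label: str = "all") -> FreeListDataset:
    """Read a wide layout: one row per informant, items in recall order.

    The first column is the informant id (an optional second column named
    ``group`` overrides ``group_label``); the remaining cells are the cited
    items, left to right, blanks ignored.
    """
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if df.empty:
        raise FreeListValidationError("empty free-list file")
    cols = list(df.columns)
    has_group = len(cols) > 1 and cols[1].lower() == "group"
    item_cols = cols[(2 if has_group else 1):]
    records = []
    for row in df.itertuples(index=False):
        informant = row[0]
        group = row[1] if has_group else group_label
        rank = 0
        for col_idx in range(2 if has_group else 1, len(cols)):
            val = row[col_idx]
            if pd.isna(val) or str(val).strip() == "":
                continue
            rank += 1
            records.append(FreeListRecord(str(informant), str(group), rank, str(val)))
    return FreeListDataset(records)


def write_freelists(dataset: FreeListDataset, target) -> None:
    """Write the canonical long CSV (UTF-8, header ``informant,group,rank,item``)."""
    df = dataset.to_frame().sort_values(["group", "informant", "rank"])
    df.to_csv(target, index=False)


def read_synonym_map(source) -> dict[str, str]:
    """Read a two-column CSV ``variant,canonical`` into a mapping."""
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if list(df.columns[:2]) != ["variant", "canonical"]:
        raise FreeListValidationError(
            f"synonym map must have columns variant,canonical; found {list(df.columns)}"
        )
    return dict(zip(df["variant"], df["canonical"]))


# -- canonicalization -----------------------------------------------------

_WS = re.compile(r"\s+")


def _normalize_name(name: str) -> str:
    # NFC so composed/decomposed diacritics compare equal; diacritics kept
    name = unicodedata.normalize("NFC", str(name))
    return _WS.sub(" ", name.strip()).lower()


def _resolve_synonyms(synonym_map: Mapping[str, str]) -> dict[str, str]:
    """Follow variant -> canonical chains to a fixed point; reject cycles."""
    norm = {_normalize_name(k): _normalize_name(v) for k, v in synonym_map.items()}
    resolved: dict[str, str] = {}
    for start in norm:
        seen = [start]
        cur = start
        while cur in norm:
            cur = norm[cur]
            if cur in seen:
                raise FreeListValidationError(f"synonym cycle involving {cur!r}")
            seen.append(cur)
        resolved[start] = cur
    return resolved


def canonicalize_items(
    dataset: FreeListDataset, synonym_map: Mapping[str, str] | None = None
) -> FreeListDataset:
    """Normalize item names and merge synonyms.

    Names are lower-cased, trimmed, internal whitespace collapsed, diacritics
    preserved.  If merging synonyms makes an item appear twice in one list,
    the earliest rank wins and later ranks close up.  Idempotent.
    """
    resolved = _resolve_synonyms(synonym_map or {})
    out: list[FreeListRecord] = []
    df = dataset.to_frame()
    for (inf, grp), sub in df.groupby(["informant", "group"], sort=False):
        seen: set[str] = set()
        rank = 0
        for item in sub.sort_values("rank")["item"]:
            name = _normalize_name(item)
            name = resolved.get(name, name)
            if name in seen:
                continue
            seen.add(name)
            rank += 1
            out.append(FreeListRecord(inf, grp, rank, name))
    return FreeListDataset(out)


def summarize(dataset: FreeListDataset) -> DatasetSummary:
    """N, M and the list-length multiset — the null model's matching targets.

    Lengths are reported sorted, making the summary a canonical multiset
    representation that is invariant to record order.
    """
    lengths = tuple(sorted(dataset.list_lengths().values()))
    return DatasetSummary(
        n_informants=dataset.n_informants,
        n_items=dataset.n_items,
        list_lengths=lengths,
    )
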