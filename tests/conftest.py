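"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import io

import numpy as np
import pytest

from ethnocore.freelists import FreeListDataset, FreeListRecord


def make_dataset(lists: dict, group: str = "g") -> FreeListDataset:
    """Build a dataset from {informant: [items in recall order]}."""
    records = []
    for informant, items in lists.items():
        for r, item in enumerate(items, start=1):
            records.append(FreeListRecord(str(informant), group, r, str(item)))
    return FreeListDataset(records)


def random_dataset(rng: np.random.Generator, n: int, m: int) -> FreeListDataset:
    """Random free lists: each informant cites a nonempty random distinct
    subset of m abstract items in random order."""
    lists = {}
    for j in range(n):
        length = int(rng.integers(1, m + 1))
        items = rng.permutation(m)[:length]
        lists[f"i{j}"] = [f"x{v}" for v in items]
    return make_dataset(lists)


def naive_salience(dataset: FreeListDataset) -> dict[str, float]:
    """Double-loop Smith's salience oracle, independent of the library path."""
    informants = dataset.informants
    n = len(informants)
    totals: dict[str, float] = {}
    for informant, group in informants:
        items = dataset.ordered_list(informant, group)
        length = len(items)
        for r, item in enumerate(items, start=1):
            totals[item] = totals.get(item, 0.0) + (length - r + 1) / length
    return {item: s / n for item, s in totals.items()}


@pytest.fixture
def two_informant_dataset() -> FreeListDataset:
    # forced by the formula: S(a) = (1.0 + 0)/2, S(b) = (0.5 + 1.0)/2
    return make_dataset({"i1": ["a", "b"], "i2": ["b"]})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def long_csv(text: str) -> io.StringIO:
    return io.StringIO(text)
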