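"""Smith's cultural salience and the null-model salience threshold.

Smith's salience of item *i* is the mean, over **all** N informants, of the
positional score (L - r + 1)/L, where r is the item's 1-based recall rank in
an informant's list of length L (informants not citing the item score 0).
Frequent and early-recalled items therefore score high.

The salience threshold separates a "structural core" of items whose
salience is higher than expected by chance from the remaining "satellite"
items.  The null model simulates B free-list datasets matched to the
observed one on the number of informants N, the item-pool size M and the
citation effort per informant (list lengths resampled from the observed
multiset by default); each simulated informant cites a uniform random
subset of distinct items in uniform random order.  Observed salience at
salience rank k is compared with the B simulated values at the same rank;
the per-item p-value is the smaller empirical tail.  The structural core is
the maximal salience-ranked prefix whose items are prominent (above the
null mean) with p below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freelists import (
    DatasetSummary,
    FreeListDataset,
    FreeListRecord,
    summarize,
)

__all__ = [
    "SalienceTable",
    "NullModelConfig",
    "NullSalienceDistribution",
    "informant_item_score",
    "compute_salience",
    "simulate_null_dataset",
    "null_salience_distribution",
    "salience_pvalues",
    "classify_core",
]

LENGTH_MODELS = ("resample_observed", "fixed_mean", "poisson_mean")

CORE = "core"
SATELLITE = "satellite"
PROMINENT = "prominent"
NON_PROMINENT = "non-prominent"


@dataclass(frozen=True)
class NullModelConfig:
    """Settings of the Monte-Carlo salience threshold.

    n_runs
        Number of simulated null datasets B (default 1000).
    alpha
        Decision level for the core/satellite split (default 0.05).
    seed
        Master seed; each run draws from a deterministically spawned
        substream, so runs could be parallelized without changing results.
    length_model
        How simulated list lengths are drawn: ``resample_observed`` samples
        with replacement from the observed length multiset (preserves mean
        and spread), ``fixed_mean`` uses round(mean) for everyone,
        ``poisson_mean`` draws Poisson(mean) truncated to [1, M].
    corrected_pvalues
        If True, report (b + 1)/(B + 1) add-one tail estimates instead of
        raw proportions b/B (raw matches the zero p-values the method is
        usually reported with).
    """

    n_runs: int = 1000
    alpha: float = 0.05
    seed: int = 0
    length_model: str = "resample_observed"
    corrected_pvalues: bool = False

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.length_model not in LENGTH_MODELS:
            raise ValueError(f"length_model must be one of {LENGTH_MODELS}")


@dataclass
class SalienceTable:
    """Per-item salience, ranked; optionally annotated with p and label.

    ``table`` columns: rank, item, frequency, salience and, once a null
    comparison has been made, null_mean, p_value, side, label.
    """

    table: pd.DataFrame
    summary: DatasetSummary | None = None

    @property
    def items(self) -> list[str]:
        return list(self.table["item"])

    @property
    def saliences(self) -> np.ndarray:
        return self.table["salience"].to_numpy()

    @property
    def core_items(self) -> list[str]:
        if "label" not in self.table.columns:
            raise ValueError("table has no core/satellite labels yet")
        return list(self.table.loc[self.table["label"] == CORE, "item"])

    @property
    def core_size(self) -> int:
        return len(self.core_items)

    def to_tsv(self, target) -> None:
        df = self.table.copy()
        for col in ("salience", "p_value", "null_mean"):
            if col in df.columns:
                df[col] = df[col].map(lambda v: f"{v:.6f}")
        cols = [c for c in ("rank", "item", "frequency", "salience", "p_value", "label") if c in df.columns]
        df[cols].to_csv(target, sep="\t", index=False)


@dataclass
class NullSalienceDistribution:
    """B simulated salience values at each salience rank k = 1..M.

    ``values`` has shape (B, M): row b holds run b's salience values sorted
    descending, padded with zeros past the run's realized item count.
    """

    values: np.ndarray
    config: NullModelConfig
    summary: DatasetSummary

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_ranks(self) -> int:
        return self.values.shape[1]

    @property
    def rank_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def informant_item_score(rank: int, list_length: int) -> float:
    """Positional score (L - r + 1)/L of the item recalled at ``rank``."""
    if not 1 <= rank <= list_length:
        raise ValueError(f"rank {rank} outside 1..{list_length}")
    return (list_length - rank + 1) / list_length


def compute_salience(dataset: FreeListDataset) -> SalienceTable:
    """Smith's salience for every cited item, ranked descending.

    Ties in salience are broken by higher citation frequency, then by item
    name, so ranks are a reproducible permutation of 1..M.
    """
    df = dataset.to_frame()
    n = dataset.n_informants
    lengths = df.groupby(["informant", "group"], sort=False)["rank"].transform("max")
    df = df.assign(score=(lengths - df["rank"] + 1) / lengths)
    agg = (
        df.groupby("item")
        .agg(frequency=("score", "size"), total=("score", "sum"))
        .reset_index()
    )
    agg["salience"] = agg["total"] / n
    agg = agg.sort_values(
        ["salience", "frequency", "item"], ascending=[False, False, True]
    ).reset_index(drop=True)
    agg.insert(0, "rank", np.arange(1, len(agg) + 1))
    return SalienceTable(
        table=agg[["rank", "item", "frequency", "salience"]],
        summary=summarize(dataset),
    )


# -- null model -----------------------------------------------------------

def _draw_lengths(
    summary: DatasetSummary, rng: np.random.Generator, length_model: str
) -> np.ndarray:
    n, m = summary.n_informants, summary.n_items
    if length_model == "resample_observed":
        pool = np.minimum(np.asarray(summary.list_lengths), m)
        return rng.choice(pool, size=n, replace=True)
    if length_model == "fixed_mean":
        fixed = int(round(summary.mean_list_length))
        if fixed > m:
            raise ValueError(f"fixed length {fixed} exceeds item pool M={m}")
        return np.full(n, max(fixed, 1))
    if length_model == "poisson_mean":
        return np.clip(rng.poisson(summary.mean_list_length, size=n), 1, m)
    raise ValueError(length_model)


def _draw_lists(
    lengths: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Random distinct-item lists in random order, as an (N, max L) index
    matrix; positions past each list's length hold -1."""
    n = len(lengths)
    # argsort of iid uniforms = uniform random permutation per informant
    order = np.argsort(rng.random((n, m)), axis=1)
    out = order[:, : lengths.max()].copy()
    for j, L in enumerate(lengths):
        out[j, L:] = -1
    return out


def _null_run_salience(
    summary: DatasetSummary, rng: np.random.Generator, length_model: str
) -> np.ndarray:
    """Sorted (descending) salience vector of one simulated null dataset,
    length M with zeros for uncited items."""
    n, m = summary.n_informants, summary.n_items
    lengths = _draw_lengths(summary, rng, length_model)
    lists = _draw_lists(lengths, m, rng)
    sal = np.zeros(m)
    for j, L in enumerate(lengths):
        idx = lists[j, :L]
        sal[idx] += (L - np.arange(1, L + 1) + 1) / L
    sal /= n
    sal.sort()
    return sal[::-1]


def simulate_null_dataset(
    summary: DatasetSummary,
    rng: np.random.Generator,
    length_model: str = "resample_observed",
) -> FreeListDataset:
    """One simulated dataset matched to ``summary`` (N, M, citation effort).

    Items are abstract labels ``item_0001`` .. ``item_M``; each informant
    cites a uniform random distinct subset in uniform random order.
    """
    n, m = summary.n_informants, summary.n_items
    lengths = _draw_lengths(summary, rng, length_model)
    lists = _draw_lists(lengths, m, rng)
    width = max(4, len(str(m)))
    records = [
        FreeListRecord(f"sim_{j + 1}", "null", r + 1, f"item_{lists[j, r] + 1:0{width}d}")
        for j in range(n)
        for r in range(lengths[j])
    ]
    return FreeListDataset(records)


def null_salience_distribution(
    summary: DatasetSummary, config: NullModelConfig
) -> NullSalienceDistribution:
    """Rank-wise salience distribution across B simulated null datasets.

    Each run gets its own spawned RNG substream from ``config.seed``; the
    result is reproducible and independent of evaluation order.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    values = np.empty((config.n_runs, summary.n_items))
    for b, child in enumerate(children):
        values[b] = _null_run_salience(
            summary, np.random.default_rng(child), config.length_model
        )
    return NullSalienceDistribution(values=values, config=config, summary=summary)


def salience_pvalues(
    observed: SalienceTable, null: NullSalienceDistribution
) -> SalienceTable:
    """Annotate each observed rank-k salience with its rank-matched p-value.

    p_k is the smaller of the two empirical tails at rank k (ties counted in
    both, tails inclusive); ``side`` records whether the observed value sits
    above (prominent) or at/below (non-prominent) the null mean at that rank.
    """
    m = len(observed.table)
    if m != null.n_ranks:
        raise ValueError(
            f"observed item count {m} does not match null rank count {null.n_ranks}"
        )
    s = observed.saliences
    vals = null.values  # (B, M)
    b = null.n_runs
    upper = (vals >= s).sum(axis=0)
    lower = (vals <= s).sum(axis=0)
    if null.config.corrected_pvalues:
        p = np.minimum(upper + 1, lower + 1) / (b + 1)
    else:
        p = np.minimum(upper, lower) / b
    means = null.rank_means
    out = observed.table.copy()
    out["null_mean"] = means
    out["p_value"] = p
    out["side"] = np.where(s > means, PROMINENT, NON_PROMINENT)
    return SalienceTable(table=out, summary=observed.summary)


def classify_core(table: SalienceTable, alpha: float = 0.05) -> SalienceTable:
    """Split the ranked list into a structural core and satellites.

    The core is the maximal prefix of the salience-ranked list whose entries
    are all prominent with p < alpha; everything after the first failure is
    a satellite.  Tables lacking a ``side`` column (e.g. transcribed from a
    published ranking that prints only p) treat every entry as prominent;
    the prefix rule stops at the first p >= alpha regardless.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = table.table
    if "p_value" not in df.columns:
        raise ValueError("run salience_pvalues before classify_core")
    df = df.sort_values("rank").reset_index(drop=True)
    p = df["p_value"].to_numpy()
    if "side" in df.columns:
        prominent = df["side"].to_numpy() == PROMINENT
    else:
        prominent = np.ones(len(df), bool)
    ok = (p < alpha) & prominent
    core_size = int(np.argmin(ok)) if not ok.all() else len(df)
    labels = np.where(np.arange(len(df)) < core_size, CORE, SATELLITE)
    out = df.copy()
    out["label"] = labels
    return SalienceTable(table=out, summary=table.summary)
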