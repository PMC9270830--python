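"""Compositional comparison of structural cores between two groups.

Participants are encoded as binary presence/absence vectors over the union
of the compared structural cores, dissimilarity is binary Jaccard, and
group differences are tested with one-factor PERMANOVA (pseudo-F on the
distance decomposition, permutation p), multivariate-dispersion homogeneity
(PERMDISP with group centroids), and visualised by principal coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "CompositionMatrix",
    "PermanovaResult",
    "DispersionResult",
    "PcoaResult",
    "build_core_matrix",
    "read_matrix_csv",
    "jaccard_distances",
    "permanova",
    "betadisper",
    "pcoa",
    "plot_ordination",
]


@dataclass
class CompositionMatrix:
    """Binary participants x core-plants matrix with group labels.

    ``data`` is 0/1 with index ``informant:group`` row ids and core-plant
    columns; ``groups`` aligns to rows; ``dropped_rows`` lists participants
    removed for citing none of the core plants (Jaccard is undefined
    between two empty sets).
    """

    data: pd.DataFrame
    groups: pd.Series
    dropped_rows: list[str]

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    def to_csv(self, target) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.groups.values)
        out.index.name = "row_id"
        out.to_csv(target)


@dataclass(frozen=True)
class PermanovaResult:
    """One-factor PERMANOVA decomposition of a distance matrix."""

    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    pseudo_f: float
    r_squared: float
    p_perm: float
    n_permutations: int
    exhaustive: bool
    seed: int | None

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    def as_dict(self) -> dict:
        return {
            "df_between": self.df_between,
            "df_within": self.df_within,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
            "ss_total": self.ss_total,
            "ms_between": self.ms_between,
            "ms_within": self.ms_within,
            "pseudo_f": self.pseudo_f,
            "r_squared": self.r_squared,
            "p_perm": self.p_perm,
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
        }

    def anova_table(self) -> pd.DataFrame:
        """Human-readable decomposition (factor / residuals / total rows)."""
        return pd.DataFrame(
            {
                "df": [self.df_between, self.df_within, self.df_between + self.df_within],
                "sum_sq": [self.ss_between, self.ss_within, self.ss_total],
                "mean_sq": [self.ms_between, self.ms_within, np.nan],
                "pseudo_F": [self.pseudo_f, np.nan, np.nan],
                "R2": [self.r_squared, 1 - self.r_squared, 1.0],
                "p_perm": [self.p_perm, np.nan, np.nan],
            },
            index=["between", "residuals", "total"],
        )


@dataclass
class DispersionResult:
    """Homogeneity of multivariate dispersions (group distances to centroid)."""

    distances: pd.Series  # per-row distance to own group centroid
    group_means: pd.Series
    f_statistic: float
    p_perm: float
    n_permutations: int
    seed: int | None


@dataclass
class PcoaResult:
    """Classical scaling of a distance matrix.

    ``coordinates`` spans only the positive-eigenvalue axes; negative
    eigenvalues (possible for non-Euclidean dissimilarities such as
    Jaccard) are reported in ``eigenvalues`` but excluded from the
    embedding and from ``proportion_explained``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


# -- composition matrix ---------------------------------------------------

def build_core_matrix(datasets, core_union) -> CompositionMatrix:
    """Binary matrix over ``core_union`` columns from one or more datasets.

    One row per (informant, group); cell 1 iff that informant's free list
    contains the column plant.  All-zero rows are dropped and reported.
    """
    core_union = list(core_union)
    if not core_union:
        raise ValueError("core_union is empty")
    if hasattr(datasets, "to_frame"):
        datasets = [datasets]
    frames = [d.to_frame() for d in datasets]
    df = pd.concat(frames, ignore_index=True)
    rows, groups, row_ids = [], [], []
    for (inf, grp), sub in df.groupby(["informant", "group"], sort=False):
        cited = set(sub["item"])
        rows.append([int(p in cited) for p in core_union])
        groups.append(grp)
        row_ids.append(f"{inf}:{grp}")
    mat = pd.DataFrame(rows, index=row_ids, columns=core_union)
    grp = pd.Series(groups, index=row_ids, name="group")
    keep = mat.sum(axis=1) > 0
    dropped = list(mat.index[~keep])
    mat, grp = mat[keep], grp[keep]
    counts = grp.value_counts()
    if len(counts) and (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"fewer than 2 non-empty rows in group(s) {bad}")
    return CompositionMatrix(data=mat, groups=grp, dropped_rows=dropped)


def read_matrix_csv(source, group_column: str = "group") -> CompositionMatrix:
    """Read a pre-built binary matrix CSV (first column ``row_id``).

    The declared ``group_column`` carries the factor; remaining columns are
    plant names with 0/1 cells.  All-zero rows are dropped (idempotent if
    the file already excludes them).
    """
    df = pd.read_csv(source, index_col=0)
    if group_column not in df.columns:
        raise ValueError(f"missing group column {group_column!r}")
    groups = df[group_column].astype(str)
    mat = df.drop(columns=[group_column])
    vals = mat.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("matrix cells must be binary 0/1")
    mat = mat.astype(int)
    keep = mat.sum(axis=1) > 0
    dropped = list(mat.index[~keep].astype(str))
    return CompositionMatrix(
        data=mat[keep], groups=groups[keep].rename("group"), dropped_rows=dropped
    )


# -- distances ------------------------------------------------------------

def jaccard_distances(matrix: CompositionMatrix) -> DistanceMatrix:
    """Binary Jaccard dissimilarity (b + c)/(a + b + c) between all rows."""
    x = matrix.data.to_numpy(dtype=bool)
    if (~x.any(axis=1)).any():
        raise ValueError("all-zero row: drop empty participants before distances")
    condensed = pdist(x, metric="jaccard")
    return DistanceMatrix(squareform(condensed), ids=matrix.row_ids)


# -- PERMANOVA ------------------------------------------------------------

def _align_labels(dist: DistanceMatrix, labels) -> np.ndarray:
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if len(labels) != dist.shape[0]:
        raise ValueError(
            f"labels length {len(labels)} does not match distance matrix size {dist.shape[0]}"
        )
    return labels.to_numpy()


def _ss_terms(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    return ss_total, ss_within


def _f_for_masks(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray, ss_total: float,
                 df_b: int, df_w: int) -> np.ndarray:
    """Vectorized pseudo-F for many relabelings.

    ``masks`` is (n, P, G) boolean: permutation p assigns row i to group g.
    """
    n, p_count, g_count = masks.shape
    ss_within = np.zeros(p_count)
    for g in range(g_count):
        x = masks[:, :, g].astype(float)  # (n, P)
        ss_within += np.einsum("ip,ip->p", x, d2 @ x) / (2 * sizes[g])
    ss_between = ss_total - ss_within
    return (ss_between / df_b) / (ss_within / df_w)


def _count_relabelings(sizes: np.ndarray) -> float:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total /= math.factorial(int(s))
    return total


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums (1/n_g) sum_{i<j in g}
    d_ij^2 over groups; pseudo-F = MS_between / MS_within.  p is estimated
    by uniform random relabelings with the add-one rule, or computed exactly
    by enumerating all distinct relabelings when there are at most
    ``n_permutations`` of them.
    """
    arr = _align_labels(dist, labels)
    uniq, codes = np.unique(arr, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("each group needs at least 2 rows")
    n = dist.shape[0]
    d2 = np.asarray(dist.data) ** 2
    ss_total, ss_within = _ss_terms(d2, codes, a)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)

    n_distinct = _count_relabelings(sizes)
    if n_distinct <= n_permutations:
        f_all = _enumerate_f(d2, sizes, ss_total, df_b, df_w)
        # float comparison: count ties as >= with small tolerance
        p = float((f_all >= f_obs - 1e-12).sum() / len(f_all))
        n_used, exhaustive = len(f_all), True
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n, n_permutations), dtype=int)
        for p_i in range(n_permutations):
            perms[:, p_i] = rng.permutation(codes)
        masks = perms[:, :, None] == np.arange(a)[None, None, :]
        f_perm = _f_for_masks(d2, masks, sizes, ss_total, df_b, df_w)
        p = float((1 + (f_perm >= f_obs - 1e-12).sum()) / (1 + n_permutations))
        n_used, exhaustive = n_permutations, False

    return PermanovaResult(
        df_between=df_b,
        df_within=df_w,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        pseudo_f=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_perm=p,
        n_permutations=n_used,
        exhaustive=exhaustive,
        seed=seed,
    )


def _enumerate_f(d2, sizes, ss_total, df_b, df_w) -> np.ndarray:
    """Pseudo-F over every distinct assignment of the label multiset."""
    n = d2.shape[0]
    a = len(sizes)
    fs = []
    slots = list(range(n))

    def assign(remaining: list[int], group: int, codes: np.ndarray):
        if group == a - 1:
            codes[remaining] = group
            st, sw = _ss_terms(d2, codes, a)
            fs.append(((ss_total - sw) / df_b) / (sw / df_w))
            return
        # fix the smallest remaining index into this group iff possible to
        # avoid double counting? groups are labeled, so all combinations count
        for combo in itertools.combinations(remaining, int(sizes[group])):
            codes2 = codes.copy()
            codes2[list(combo)] = group
            rest = [i for i in remaining if i not in combo]
            assign(rest, group + 1, codes2)

    assign(slots, 0, np.full(n, -1))
    return np.asarray(fs)


# -- PCoA and dispersion --------------------------------------------------

def _gower_decomposition(dist: DistanceMatrix):
    """Eigen-decomposition of the Gower-centered matrix -1/2 J D^2 J.

    Returns (eigenvalues desc, eigenvectors column-aligned).
    """
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis (classical metric scaling).

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; negative eigenvalues are reported but give no axis.
    """
    w, v = _gower_decomposition(dist)
    tol = max(abs(w[0]), 1.0) * 1e-9
    pos = w > tol
    coords = v[:, pos] * np.sqrt(w[pos])
    prop = w[pos] / w[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(pos.sum())]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=cols),
        eigenvalues=w,
        proportion_explained=prop,
    )


def _centroid_distances(dist: DistanceMatrix, codes: np.ndarray, a: int) -> np.ndarray:
    """Per-row distance to own group centroid in the full PCoA embedding.

    Axes with negative eigenvalues contribute imaginary coordinates; their
    squared distances subtract (Anderson's correction), clamped at zero.
    """
    w, v = _gower_decomposition(dist)
    tol = max(abs(w).max(), 1.0) * 1e-9
    pos, neg = w > tol, w < -tol
    c_pos = v[:, pos] * np.sqrt(w[pos])
    c_neg = v[:, neg] * np.sqrt(-w[neg])
    z = np.empty(len(codes))
    for g in range(a):
        mask = codes == g
        dp = c_pos[mask] - c_pos[mask].mean(axis=0)
        dn = c_neg[mask] - c_neg[mask].mean(axis=0) if c_neg.size else np.zeros((mask.sum(), 0))
        z[mask] = np.sqrt(np.maximum((dp ** 2).sum(1) - (dn ** 2).sum(1), 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_b = ss_w = 0.0
    for g in range(a):
        zg = z[codes == g]
        ss_b += len(zg) * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    tol = 1e-12 * max((z**2).sum(), 1e-300)
    if ss_w <= tol:
        return math.inf if ss_b > tol else 0.0
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def betadisper(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions (PERMDISP, group centroids).

    Rows are embedded by PCoA on all axes; each row's dispersion is its
    distance to its group centroid (negative-eigenvalue axes subtract);
    the F statistic is a one-way ANOVA on those dispersions and p comes
    from permuting the dispersions across groups.
    """
    arr = _align_labels(dist, labels)
    uniq, codes = np.unique(arr, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("betadisper requires at least two groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("each group needs at least 2 rows")
    z = _centroid_distances(dist, codes, a)
    f_obs = _anova_f(z, codes, a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _anova_f(z, rng.permutation(codes), a) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    dists = pd.Series(z, index=list(dist.ids), name="centroid_distance")
    means = pd.Series(
        [z[codes == g].mean() for g in range(a)], index=list(uniq), name="mean_dispersion"
    )
    return DispersionResult(
        distances=dists,
        group_means=means,
        f_statistic=float(f_obs),
        p_perm=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


# -- plotting -------------------------------------------------------------

def plot_ordination(result: PcoaResult, labels, path) -> None:
    """Scatter of the first two principal coordinates, colored by group.

    Falls back to a 1-D strip plot (with a warning) when only one positive
    axis exists.  Output is deterministic for identical inputs.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matplotlib.rcParams["svg.hashsalt"] = "ethnocore"
    labels = pd.Series(list(labels), index=result.coordinates.index)
    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    one_d = coords.shape[1] < 2
    if one_d:
        warnings.warn("fewer than 2 positive axes; drawing 1-D strip plot")
    for i, (grp, sub) in enumerate(coords.groupby(labels, sort=True)):
        x = sub.iloc[:, 0]
        y = sub.iloc[:, 1] if not one_d else np.zeros(len(sub))
        ax.scatter(x, y, label=str(grp), s=22, alpha=0.8)
    pe = result.proportion_explained
    ax.set_xlabel(f"PCo1 ({pe[0] * 100:.1f}%)")
    ax.set_ylabel(f"PCo2 ({pe[1] * 100:.1f}%)" if not one_d else "")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, metadata=_deterministic_metadata(str(path)))
    plt.close(fig)


def _deterministic_metadata(path: str) -> dict:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return {}
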