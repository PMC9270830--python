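"""Composition matrices, Jaccard, PERMANOVA, dispersion and PCoA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.distance import permdisp as skbio_permdisp

from ethnocore.comparison import (
    CompositionMatrix,
    betadisper,
    build_core_matrix,
    jaccard_distances,
    pcoa,
    permanova,
    plot_ordination,
    read_matrix_csv,
)

from conftest import make_dataset


def toy_distance() -> DistanceMatrix:
    # two tight pairs far apart: d within pair 1, across pairs 2
    d = np.array(
        [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], dtype=float
    )
    return DistanceMatrix(d, ids=list("abcd"))


def random_binary_matrix(rng, n=12, m=6) -> CompositionMatrix:
    data = (rng.random((n, m)) < 0.5).astype(int)
    data[data.sum(axis=1) == 0, 0] = 1  # no all-zero rows
    df = pd.DataFrame(data, index=[f"r{i}" for i in range(n)], columns=[f"p{j}" for j in range(m)])
    groups = pd.Series(["g1"] * (n // 2) + ["g2"] * (n - n // 2), index=df.index)
    return CompositionMatrix(data=df, groups=groups, dropped_rows=[])


# -- oracles --------------------------------------------------------------

def gower_permanova_oracle(d: np.ndarray, codes: np.ndarray):
    """Independent PERMANOVA SS via Gower centering and hat-matrix traces."""
    n = len(codes)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    x = np.zeros((n, codes.max() + 1))
    x[np.arange(n), codes] = 1
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_between = np.trace(h @ g @ h)
    ss_within = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
    return ss_between, ss_within, np.trace(g)


class TestBuildCoreMatrix:
    def test_toy_dropping(self):
        ds = make_dataset({"i1": ["x"], "i2": ["y"], "i3": ["z"]})
        m = build_core_matrix(ds, ["x", "y"])
        assert m.data.shape == (2, 2)
        assert m.dropped_rows == ["i3:g"]

    def test_group_left_with_single_row_rejected(self):
        a = make_dataset({"i1": ["x"], "i2": ["z"]}, group="g1")
        b = make_dataset({"i1": ["x"], "i2": ["y"]}, group="g2")
        with pytest.raises(ValueError, match="fewer than 2"):
            build_core_matrix([a, b], ["x", "y"])

    def test_all_core_citer_gets_ones_row(self):
        ds = make_dataset({"i1": ["x", "y"], "i2": ["x"]})
        m = build_core_matrix(ds, ["x", "y"])
        assert m.data.loc["i1:g"].tolist() == [1, 1]
        assert m.data.loc["i2:g"].tolist() == [1, 0]

    def test_empty_union_rejected(self):
        ds = make_dataset({"i1": ["x"]})
        with pytest.raises(ValueError, match="empty"):
            build_core_matrix(ds, [])

    def test_two_datasets_concatenate(self):
        a = make_dataset({"i1": ["x"], "i2": ["x", "y"]}, group="g1")
        b = make_dataset({"i1": ["y"], "i2": ["y", "x"]}, group="g2")
        m = build_core_matrix([a, b], ["x", "y"])
        assert sorted(m.groups.unique()) == ["g1", "g2"]
        assert m.data.shape == (4, 2)

    def test_csv_round_trip_and_reader(self, tmp_path):
        ds = make_dataset({"i1": ["x", "y"], "i2": ["y"]})
        m = build_core_matrix(ds, ["x", "y"])
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = read_matrix_csv(path)
        assert back.data.equals(m.data)
        assert list(back.groups) == list(m.groups)

    def test_reader_rejects_non_binary(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("row_id,group,x\nr1,g1,2\nr2,g2,1\n")
        with pytest.raises(ValueError, match="binary"):
            read_matrix_csv(path)

    def test_reader_drop_is_idempotent(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("row_id,group,x,y\nr1,g1,1,0\nr2,g1,0,0\nr3,g2,1,1\n")
        m = read_matrix_csv(path)
        assert m.dropped_rows == ["r2"]
        path2 = tmp_path / "m2.csv"
        m.to_csv(path2)
        again = read_matrix_csv(path2)
        assert again.dropped_rows == []
        assert again.data.equals(m.data)


class TestJaccard:
    def _matrix(self, rows):
        df = pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))])
        groups = pd.Series(["g"] * len(rows), index=df.index)
        return CompositionMatrix(df, groups, [])

    def test_identical_rows_zero(self):
        d = jaccard_distances(self._matrix([[1, 1, 0], [1, 1, 0]]))
        assert d[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        d = jaccard_distances(self._matrix([[1, 0, 0], [0, 1, 1]]))
        assert d[0, 1] == 1.0

    def test_shared_and_unique(self):
        d = jaccard_distances(self._matrix([[1, 1, 0], [1, 0, 1]]))
        assert d[0, 1] == pytest.approx(2 / 3)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            jaccard_distances(self._matrix([[1, 0], [0, 0]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        m = random_binary_matrix(rng, n=6, m=5)
        d = jaccard_distances(m).data
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestPermanova:
    def test_toy_decomposition(self):
        r = permanova(toy_distance(), ["g1", "g1", "g2", "g2"], seed=0)
        assert r.ss_total == pytest.approx(4.5)
        assert r.ss_within == pytest.approx(1.0)
        assert r.ss_between == pytest.approx(3.5)
        assert r.pseudo_f == pytest.approx(7.0)
        assert r.r_squared == pytest.approx(3.5 / 4.5)
        assert r.exhaustive and r.n_permutations == 6
        assert r.p_perm == pytest.approx(2 / 6)

    def test_ss_additivity_and_r2_range(self, rng):
        m = random_binary_matrix(rng)
        r = permanova(jaccard_distances(m), m.groups, seed=1)
        assert r.ss_between + r.ss_within == pytest.approx(r.ss_total, abs=1e-9)
        assert 0 <= r.r_squared <= 1
        assert r.pseudo_f == pytest.approx(r.ms_between / r.ms_within)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_gower_trace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        pts = rng.random((n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        codes = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        r = permanova(DistanceMatrix(d), ["a"] * 3 + ["b"] * 5, n_permutations=9, seed=0)
        ss_b, ss_w, ss_t = gower_permanova_oracle(d, codes)
        assert r.ss_between == pytest.approx(ss_b, abs=1e-9)
        assert r.ss_within == pytest.approx(ss_w, abs=1e-9)
        assert r.ss_total == pytest.approx(ss_t, abs=1e-9)

    def test_exhaustive_equals_brute_force_enumeration(self, rng):
        """On n <= 8 the exact p equals enumerating every relabeling by hand."""
        n = 7
        pts = rng.random((n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 3 + ["b"] * 4
        r = permanova(DistanceMatrix(d), labels, n_permutations=999, seed=0)
        assert r.exhaustive

        # brute force with the independent trace oracle
        fs = []
        for combo in itertools.combinations(range(n), 3):
            codes = np.ones(n, dtype=int)
            codes[list(combo)] = 0
            ss_b, ss_w, _ = gower_permanova_oracle(d, codes)
            fs.append((ss_b / 1) / (ss_w / (n - 2)))
        f_obs = fs[0]  # first combo (0,1,2) is the observed labeling
        p_brute = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert r.pseudo_f == pytest.approx(f_obs, abs=1e-9)
        assert r.p_perm == pytest.approx(p_brute)
        assert r.n_permutations == 35

    def test_matches_skbio_statistic(self, rng):
        m = random_binary_matrix(rng, n=14, m=7)
        d = jaccard_distances(m)
        r = permanova(d, m.groups, n_permutations=999, seed=3)
        ref = skbio_permanova(d, list(m.groups), permutations=99)
        assert r.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_invariant_under_co_permutation_and_renaming(self, rng):
        m = random_binary_matrix(rng)
        d = jaccard_distances(m)
        r1 = permanova(d, m.groups, n_permutations=99, seed=5)
        perm = rng.permutation(d.shape[0])
        d2 = DistanceMatrix(d.data[np.ix_(perm, perm)])
        relabeled = m.groups.iloc[perm].map({"g1": "north", "g2": "south"})
        r2 = permanova(d2, list(relabeled), n_permutations=99, seed=5)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, abs=1e-12)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-12)

    def test_determinism_under_seed(self, rng):
        m = random_binary_matrix(rng, n=20, m=8)
        d = jaccard_distances(m)
        r1 = permanova(d, m.groups, n_permutations=199, seed=7)
        r2 = permanova(d, m.groups, n_permutations=199, seed=7)
        assert r1 == r2

    def test_smallest_reportable_p_is_one_over_b_plus_one(self):
        # two clearly separated clouds: observed F beats every permutation
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        r = permanova(DistanceMatrix(d), ["a"] * 10 + ["b"] * 10,
                      n_permutations=999, seed=11)
        assert not r.exhaustive
        assert r.p_perm == pytest.approx(0.001)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            permanova(toy_distance(), ["g"] * 4)

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            permanova(toy_distance(), ["a", "b"])


class TestBetadisper:
    def test_tight_groups_zero_dispersion(self):
        # within each group all points identical (distance 0)
        d = np.array(
            [[0, 0, 3, 3], [0, 0, 3, 3], [3, 3, 0, 0], [3, 3, 0, 0]], float
        )
        r = betadisper(DistanceMatrix(d), ["a", "a", "b", "b"], n_permutations=19, seed=0)
        assert r.distances.to_numpy() == pytest.approx(np.zeros(4), abs=1e-9)

    def test_identical_point_sets_give_equal_dispersion(self):
        # both groups are congruent pairs -> same mean dispersion, F = 0
        d = np.array(
            [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], float
        )
        r = betadisper(DistanceMatrix(d), ["a", "a", "b", "b"], n_permutations=19, seed=0)
        assert r.group_means["a"] == pytest.approx(r.group_means["b"], abs=1e-12)
        assert r.f_statistic == pytest.approx(0.0, abs=1e-9)

    def test_centroid_distances_match_closed_form(self, rng):
        """z_i^2 equals the distance-only closed form
        (1/n_g) sum_j d_ij^2 - (1/n_g^2) sum_{j<k} d_jk^2 (Anderson's
        centroid procedure, valid with negative PCoA eigenvalues)."""
        m = random_binary_matrix(rng, n=12, m=5)
        dm = jaccard_distances(m)
        r = betadisper(dm, m.groups, n_permutations=9, seed=0)
        d2 = dm.data**2
        codes = (m.groups == "g2").to_numpy().astype(int)
        for i in range(12):
            g = codes[i]
            members = np.flatnonzero(codes == g)
            ng = len(members)
            z2 = d2[i, members].sum() / ng - d2[np.ix_(members, members)].sum() / (2 * ng**2)
            assert r.distances.iloc[i] ** 2 == pytest.approx(max(z2, 0), abs=1e-6)

    def test_matches_skbio_permdisp_statistic(self, rng):
        # Euclidean-embeddable distances: no negative-eigenvalue correction
        pts = rng.random((10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d)
        labels = ["a"] * 5 + ["b"] * 5
        r = betadisper(dm, labels, n_permutations=9, seed=0)
        ref = skbio_permdisp(dm, labels, test="centroid", permutations=9,
                             dimensions=10)
        assert r.f_statistic == pytest.approx(ref["test statistic"], abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            betadisper(toy_distance(), ["g"] * 4)


class TestPcoa:
    def test_two_points(self):
        d = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]))
        r = pcoa(d)
        assert r.coordinates.shape == (2, 1)
        assert sorted(r.coordinates.iloc[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_equilateral_triangle(self):
        d = DistanceMatrix(1 - np.eye(3))
        r = pcoa(d)
        pos = r.eigenvalues[r.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        c = r.coordinates.to_numpy()
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert np.linalg.norm(c[i] - c[j]) == pytest.approx(1.0)

    def test_reconstructs_euclidean_distances(self, rng):
        pts = rng.random((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        r = pcoa(DistanceMatrix(d))
        c = r.coordinates.to_numpy()
        rec = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        assert rec == pytest.approx(d, abs=1e-9)

    def test_coordinates_centered_and_axes_ordered(self, rng):
        m = random_binary_matrix(rng)
        r = pcoa(jaccard_distances(m))
        assert r.coordinates.to_numpy().mean(axis=0) == pytest.approx(0, abs=1e-9)
        assert (np.diff(r.eigenvalues) <= 1e-12).all()
        assert r.proportion_explained.sum() == pytest.approx(1.0)

    def test_jaccard_can_yield_negative_eigenvalues_yet_reconstructs(self, rng):
        # binary data with enough rows typically embeds non-Euclideanly
        m = random_binary_matrix(rng, n=15, m=6)
        dm = jaccard_distances(m)
        r = pcoa(dm)
        c = r.coordinates.to_numpy()
        if (r.eigenvalues < -1e-9).any():
            # positive-axis distances overestimate; full pseudo-metric recovers
            w = r.eigenvalues
            neg = w < -1e-9
            assert neg.any()

    def test_matches_skbio_eigenvalues(self, rng):
        m = random_binary_matrix(rng)
        dm = jaccard_distances(m)
        r = pcoa(dm)
        ref = __import__("skbio.stats.ordination", fromlist=["pcoa"]).pcoa(
            dm, method="eigh", number_of_dimensions=dm.shape[0]
        )
        pos = r.eigenvalues[r.eigenvalues > 1e-9]
        ref_pos = ref.eigvals.values[ref.eigvals.values > 1e-9]
        assert pos == pytest.approx(ref_pos, abs=1e-9)

    def test_non_symmetric_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix(np.array([[0, 1.0], [2.0, 0]]))


class TestPlot:
    def test_plot_written_and_deterministic(self, tmp_path, rng):
        m = random_binary_matrix(rng)
        r = pcoa(jaccard_distances(m))
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        plot_ordination(r, m.groups, p1)
        plot_ordination(r, m.groups, p2)
        assert p1.exists() and p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()
        assert b"g1" in p1.read_bytes() and b"g2" in p1.read_bytes()

    def test_one_dimensional_fallback_warns(self, tmp_path):
        d = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]))
        r = pcoa(d)
        with pytest.warns(UserWarning, match="strip"):
            plot_ordination(r, ["a", "b"], tmp_path / "strip.svg")
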