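import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from zfscreen.clustering import (
    cluster_fingerprints,
    cluster_quality,
    distance_to_reference,
    normalize_matrix,
    select_polytherapy,
)


def _planted_matrix(rng, n_feat=20, centers=None, noise=0.1):
    """Reference rows near the origin plus labeled compound clusters."""
    if centers is None:
        centers = {"C1": 2.0, "C2": 3.5, "C3": 5.0}
    rows, labels, truth = [], [], {}
    for r in range(3):
        rows.append(rng.normal(0.0, noise, n_feat))
        labels.append(f"WT-0h-{r}")
    dirs = np.linalg.qr(rng.normal(size=(n_feat, len(centers))))[0].T
    for ci, (cname, dist) in enumerate(centers.items()):
        center = dirs[ci] * dist
        members = []
        for m in range(3):
            offset = (m - 1) * 0.35  # member 0 is closest to the reference
            vec = center * (1 + offset / dist) + rng.normal(0.0, noise, n_feat)
            name = f"{cname}-m{m}"
            rows.append(vec)
            labels.append(name)
            members.append(name)
        truth[cname] = members
    return pd.DataFrame(rows, index=labels), truth


class TestNormalize:
    def test_hand_column(self):
        M = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        Z = normalize_matrix(M)
        assert np.allclose(Z["a"], [-1.0, 0.0, 1.0])
        assert np.allclose(Z["b"], 0.0)

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        Z = normalize_matrix(pd.DataFrame(rng.random((8, 5))))
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_missing_values_imputed(self):
        M = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        Z = normalize_matrix(M)
        assert not Z.isna().any().any()

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            normalize_matrix(pd.DataFrame({"a": [1.0]}))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 1000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        M = pd.DataFrame(rng.random((6, 4)))
        Z1 = normalize_matrix(M)
        Z2 = normalize_matrix(Z1)
        assert np.max(np.abs(Z1.values - Z2.values)) < 1e-12


class TestClusterTree:
    def test_two_planted_groups_perfectly_cut(self):
        rng = np.random.default_rng(1)
        A = rng.normal(0.0, 0.1, (5, 10))
        B = rng.normal(0.0, 0.1, (5, 10)) + 5.0 / np.sqrt(10)
        M = pd.DataFrame(np.vstack([A, B]),
                         index=[f"wt{i}" for i in range(5)] + [f"mut{i}" for i in range(5)])
        tree = cluster_fingerprints(M, reference_rows=["wt0"])
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, tree.assignment) == 1.0
        assert len(tree.cluster_ids) == 2

    def test_duplicate_rows_merge_at_zero(self):
        M = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [4.0, 0.0]], index=["a", "b", "c"])
        tree = cluster_fingerprints(M, reference_rows=["a"], n_clusters=2)
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_single_row(self):
        M = pd.DataFrame([[1.0, 2.0]], index=["only"])
        tree = cluster_fingerprints(M, reference_rows=["only"])
        assert tree.linkage.shape[0] == 0
        assert tree.assignment.tolist() == [1]

    def test_distance_to_reference_examples(self):
        rng = np.random.default_rng(2)
        M, _ = _planted_matrix(rng, noise=0.0)
        tree = cluster_fingerprints(M, reference_rows=["WT-0h-0", "WT-0h-1", "WT-0h-2"])
        centroid = tree.centroid(tree.reference_cluster)
        assert distance_to_reference(centroid, tree) == pytest.approx(0.0)
        off = centroid.copy()
        off[0] += 3.0
        off[1] += 4.0
        assert distance_to_reference(off, tree) == pytest.approx(5.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        M, _ = _planted_matrix(rng)
        refs = [r for r in M.index if r.startswith("WT")]
        t1 = cluster_fingerprints(M, reference_rows=refs)
        shifted = M + 7.0
        t2 = cluster_fingerprints(shifted, reference_rows=refs)
        for row in M.index:
            assert distance_to_reference(row, t1) == pytest.approx(
                distance_to_reference(row, t2), abs=1e-8
            )


class TestClusterQuality:
    def test_trivial_anchors(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((4, 6)), index=["w1", "w2", "m1", "m2"])
        same = X.copy()
        same.loc[["m1", "m2"]] = X.loc[["w1", "w2"]].values
        bcd, _ = cluster_quality(same, ["w1", "w2"], ["m1", "m2"])
        assert bcd == pytest.approx(0.0)
        X2 = X.copy()
        X2.loc["w2"] = X2.loc["w1"]
        _, wcd = cluster_quality(X2, ["w1", "w2"], ["m1", "m2"])
        assert wcd == pytest.approx(0.0)

    def test_planted_geometry(self):
        """BCD ~ planted centroid distance; WCD ~ s*sqrt(d) in high dim."""
        rng = np.random.default_rng(5)
        d, s, dist = 400, 0.3, 4.0
        wt = rng.normal(0.0, s, (20, d))
        mut = rng.normal(0.0, s, (20, d))
        mut[:, 0] += dist
        X = pd.DataFrame(np.vstack([wt, mut]),
                         index=[f"w{i}" for i in range(20)] + [f"m{i}" for i in range(20)])
        bcd, wcd = cluster_quality(X, [f"w{i}" for i in range(20)], [f"m{i}" for i in range(20)])
        assert bcd == pytest.approx(dist, rel=0.15)
        assert wcd == pytest.approx(s * np.sqrt(d), rel=0.1)

    def test_ratio_improves_with_less_noise(self):
        rng = np.random.default_rng(6)
        ratios = []
        for s in (0.8, 0.4, 0.2, 0.1):
            wt = rng.normal(0.0, s, (10, 50))
            mut = rng.normal(0.0, s, (10, 50))
            mut[:, 0] += 3.0
            X = pd.DataFrame(np.vstack([wt, mut]),
                             index=[f"w{i}" for i in range(10)] + [f"m{i}" for i in range(10)])
            bcd, wcd = cluster_quality(X, [f"w{i}" for i in range(10)], [f"m{i}" for i in range(10)])
            ratios.append(bcd / wcd)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_few_wt_rows_raise(self):
        X = pd.DataFrame(np.zeros((3, 4)), index=["w1", "m1", "m2"])
        with pytest.raises(ValueError):
            cluster_quality(X, ["w1"], ["m1", "m2"])


def brute_force_selection(M, ref_rows, clusters, n_rounds):
    """Independent oracle: iterate the selection definition directly on the
    planted cluster labels, without any hierarchical clustering."""
    ref_centroid = M.loc[ref_rows].values.mean(axis=0)
    remaining = [list(c) for c in clusters]
    picks = []
    for _ in range(min(n_rounds, len(remaining))):
        dists = [np.linalg.norm(M.loc[c].values.mean(axis=0) - ref_centroid) for c in remaining]
        i = int(np.argmin(dists))
        best = min(
            remaining[i],
            key=lambda m: (np.linalg.norm(M.loc[m].values - ref_centroid), m),
        )
        picks.append(best)
        remaining.pop(i)
    return picks


class TestSelection:
    REFS = ["WT-0h-0", "WT-0h-1", "WT-0h-2"]

    def test_planted_three_cluster_selection(self):
        rng = np.random.default_rng(7)
        M, truth = _planted_matrix(rng)
        compounds = [m for ms in truth.values() for m in ms]
        sel = select_polytherapy(M, self.REFS, compounds, n_rounds=3)
        assert sel.selected == ["C1-m0", "C2-m0", "C3-m0"]

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            M, truth = _planted_matrix(rng, noise=0.15)
            compounds = [m for ms in truth.values() for m in ms]
            sel = select_polytherapy(M, self.REFS, compounds, n_rounds=3)
            oracle = brute_force_selection(M, self.REFS, truth.values(), 3)
            assert sel.selected == oracle

    def test_single_round_single_cluster(self):
        rng = np.random.default_rng(8)
        M, truth = _planted_matrix(rng, centers={"C1": 2.0})
        sel = select_polytherapy(M, self.REFS, truth["C1"], n_rounds=1)
        assert sel.selected == ["C1-m0"]

    def test_reference_rows_never_selected(self):
        rng = np.random.default_rng(9)
        M, truth = _planted_matrix(rng)
        compounds = [m for ms in truth.values() for m in ms]
        sel = select_polytherapy(M, self.REFS, compounds, n_rounds=3)
        assert not set(sel.selected) & set(self.REFS)
        assert not set(sel.eliminated) & set(self.REFS)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(10)
        M, truth = _planted_matrix(rng)
        compounds = [m for ms in truth.values() for m in ms]
        sel1 = select_polytherapy(M, self.REFS, compounds, n_rounds=3)
        perm = M.sample(frac=1.0, random_state=3)
        sel2 = select_polytherapy(perm, self.REFS, list(reversed(compounds)), n_rounds=3)
        assert sel1.selected == sel2.selected

    def test_exhausted_clusters_partial_result(self):
        rng = np.random.default_rng(11)
        M, truth = _planted_matrix(rng, centers={"C1": 2.0})
        sel = select_polytherapy(M, self.REFS, truth["C1"], n_rounds=3)
        assert len(sel.rounds) == 1
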