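"""Distance features, PCA oracles, Ward clustering, stratification."""

from itertools import combinations

import numpy as np
import pytest

from phytotraj import pocket, synth
from phytotraj.io import HopRecord
from phytotraj.synth import build_bridge_frame
from phytotraj.io import Trajectory


def _probe_traj():
    probes = {"His278_NE2": 3.0, "Gln190_NE2": 4.0}
    frames = [
        build_bridge_frame(0.0, "S0", 5.0, 160.0, 180.0, probe_distances=probes),
        build_bridge_frame(1.0, "S0", 5.0, 162.0, 178.0, probe_distances=probes),
    ]
    return Trajectory("p", frames, 1.0)


class TestDistanceFeatures:
    def test_three_four_five(self):
        import phytotraj.io as tio

        f = tio.Frame(0.0, "S0", ["A", "B"], np.array([[0, 0, 0], [3, 4, 0]]))
        f2 = tio.Frame(1.0, "S0", ["A", "B"], np.array([[0, 0, 0], [3, 4, 0]]))
        traj = tio.Trajectory("t", [f, f2], 1.0)
        feats = pocket.distance_features(traj, [("A", "B")])
        assert feats.iloc[0, 0] == pytest.approx(5.0)

    def test_same_atom_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pocket.distance_features(_probe_traj(), [("D_ring_O", "D_ring_O")])

    def test_unknown_label_named(self):
        with pytest.raises(KeyError, match="Xyz999"):
            pocket.distance_features(_probe_traj(), [("D_ring_O", "Xyz999_CA")])

    def test_probe_distances_match_generator(self):
        """Recomputed features equal the generator's placement distances."""
        feats = pocket.distance_features(
            _probe_traj(), [("D_ring_O", "His278_NE2"), ("D_ring_O", "Gln190_NE2")]
        )
        np.testing.assert_allclose(feats.iloc[0], [3.0, 4.0], atol=1e-9)


def _power_iteration_eig(cov, n_comp, n_iter=8000):
    """Independent eigen-decomposition: power iteration with deflation."""
    rng = np.random.default_rng(0)
    vals, vecs = [], []
    A = cov.copy()
    for _ in range(n_comp):
        v = rng.normal(size=A.shape[0])
        for _ in range(n_iter):
            v = A @ v
            v /= np.linalg.norm(v)
        lam = float(v @ A @ v)
        vals.append(lam)
        vecs.append(v.copy())
        A = A - lam * np.outer(v, v)
    return np.array(vals), np.array(vecs)


class TestPCA:
    def test_single_axis_variation(self):
        rng = np.random.default_rng(1)
        X = np.zeros((40, 3))
        X[:, 0] = rng.normal(0, 2, 40)
        _, _, evr = pocket.pca(X, standardize=False)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 5)) @ rng.normal(0, 1, (5, 5))
        _, scores, _ = pocket.pca(X)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9

    def test_power_iteration_oracle(self):
        """Loadings/eigenvalues agree with an independent decomposition of
        the covariance computed by power iteration with deflation."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (50, 8))
        loadings, scores, evr = pocket.pca(X, standardize=True)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        cov = (Z.T @ Z) / (len(Z) - 1)
        vals, vecs = _power_iteration_eig(cov, 3)
        ev = evr * cov.trace()
        np.testing.assert_allclose(ev[:3], vals, rtol=1e-6)
        for i in range(3):
            dot = abs(float(loadings[i] @ vecs[i]))
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_full_reconstruction(self):
        """All components reproduce the standardized matrix to 1e-9."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 6))
        loadings, scores, _ = pocket.pca(X)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        np.testing.assert_allclose(scores @ loadings, Z, atol=1e-9)


class TestWardCluster:
    def test_k1_single_label(self):
        rng = np.random.default_rng(5)
        res = pocket.ward_cluster(rng.normal(0, 1, (10, 2)), 1)
        assert set(res.labels) == {0}

    def test_k_exceeds_rows(self):
        with pytest.raises(ValueError):
            pocket.ward_cluster(np.zeros((3, 2)), 5)

    def test_heights_monotone(self):
        rng = np.random.default_rng(6)
        res = pocket.ward_cluster(rng.normal(0, 1, (40, 3)), 4)
        assert np.all(np.diff(res.linkage_heights) >= -1e-9)

    @staticmethod
    def _wcss(X, labels):
        tot = 0.0
        for lab in set(labels):
            pts = X[np.asarray(labels) == lab]
            tot += ((pts - pts.mean(axis=0)) ** 2).sum()
        return tot

    @classmethod
    def _brute_best(cls, X):
        return min(
            cls._wcss(X, [0 if i in grp else 1 for i in range(6)])
            for r in range(1, 6)
            for grp in combinations(range(6), r)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exhaustive_bipartition_oracle(self, seed):
        """n=6, k=2 on two separated 3-point groups: Ward's within-cluster
        variance equals the minimum over all 31 bipartitions found by
        brute force."""
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 0.5, (6, 2))
        X[3:] += [4.0, 0.0]
        res = pocket.ward_cluster(X, 2)
        assert self._wcss(X, res.labels) == pytest.approx(
            self._brute_best(X), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_never_beats_brute_force(self, seed):
        """On arbitrary points the agglomerative cut is bounded below by
        the exhaustive optimum (and may exceed it: Ward is greedy)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (6, 2))
        res = pocket.ward_cluster(X, 2)
        assert self._wcss(X, res.labels) >= self._brute_best(X) - 1e-9

    def test_blob_recovery_and_row_permutation_invariance(self):
        X, y = synth.generate_pocket_frames(synth.get_preset("pocket-3", seed=8))
        from sklearn.metrics import adjusted_rand_score

        labels = pocket.ward_cluster(X.to_numpy(), 3).labels
        assert adjusted_rand_score(y, labels) == pytest.approx(1.0)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(y))
        labels_p = pocket.ward_cluster(X.to_numpy()[perm], 3).labels
        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)


class TestPocketClusterer:
    def test_blob_preset_silhouette_peaks_at_three(self):
        X, _ = synth.generate_pocket_frames(synth.get_preset("pocket-3", seed=10))
        sil = {
            k: pocket.PocketClusterer(n_clusters=k).fit(X.to_numpy()).silhouette_
            for k in (2, 3, 4)
        }
        assert sil[3] > sil[2] and sil[3] > sil[4]

    def test_sklearn_api(self):
        from sklearn.base import clone

        est = pocket.PocketClusterer(n_clusters=2, var_threshold=0.8)
        assert clone(est).get_params()["n_clusters"] == 2
        X, _ = synth.generate_pocket_frames(
            synth.PocketEnsembleConfig(n_frames=30, seed=11)
        )
        labels = est.fit_predict(X.to_numpy())
        assert set(labels) == {0, 1}
        assert est.result().k == 2


class TestStratifyLifetimes:
    def test_single_group_reproduces_overall(self, sh_records_preset):
        _, ens = sh_records_preset
        recs = ens.hop_records[:200]
        df = pocket.stratify_lifetimes(recs, ["all"] * 200)
        assert df.loc[0, "n"] == 200
        assert df.loc[0, "n_censored"] == sum(r.censored for r in recs)

    def test_stochastic_dominance_construction(self):
        """Pattern A drawn at 4x the lifetime of B: median(A) > median(B)
        in at least 19 of 20 seeded replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            ta = rng.exponential(4.0, 60)
            tb = rng.exponential(1.0, 60)
            recs = [
                HopRecord(f"a{i}", float(t), 50.0, False) for i, t in enumerate(ta)
            ] + [HopRecord(f"b{i}", float(t), 50.0, False) for i, t in enumerate(tb)]
            df = pocket.stratify_lifetimes(recs, ["A"] * 60 + ["B"] * 60)
            med = dict(zip(df["pattern"], df["median_hop_time"]))
            wins += med["A"] > med["B"]
        assert wins >= 19

    def test_empty_group_reported_without_statistics(self):
        recs = [HopRecord("x", 1.0, 20.0, False)]
        df = pocket.stratify_lifetimes(recs, {"x": "present"})
        assert "present" in set(df["pattern"])

    def test_generator_pattern_coupling(self, sh_records_preset):
        """The Asp196+water pocket population outlives the Gln190 one."""
        _, ens = sh_records_preset
        patterns = dict(
            zip(ens.manifest["trajectory_id"], ens.manifest["pattern"])
        )
        df = pocket.stratify_lifetimes(ens.hop_records, patterns)
        med = dict(zip(df["pattern"], df["median_hop_time"]))
        cens = dict(zip(df["pattern"], df["censored_fraction"]))
        assert med["asp_water"] > med["gln"]
        assert cens["asp_water"] > cens["gln"]
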