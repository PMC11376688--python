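"""H-bond detection, water bridges, state classification, Meta-F
signature, spine tilt."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytotraj import mechanism as mech
from phytotraj import synth
from phytotraj.geometry import dihedral_series
from phytotraj.io import Frame
from phytotraj.synth import generate_helix_pair


def _random_frame(rng, n=12):
    labels = [f"P{i}_O" if i % 2 else f"P{i}_N" for i in range(n)]
    return Frame(0.0, "S0", labels, rng.uniform(-4.0, 4.0, (n, 3)))


class TestHBonds:
    def test_well_inside_criteria(self):
        f = Frame(0.0, "S0", ["don_N", "acc_O"], np.array([[0, 0, 0], [2.8, 0, 0]]))
        hbs = mech.detect_hbonds(f)
        assert any(hb.distance == pytest.approx(2.8) for hb in hbs)

    def test_outside_cutoff(self):
        f = Frame(0.0, "S0", ["don_N", "acc_O"], np.array([[0, 0, 0], [4.0, 0, 0]]))
        assert mech.detect_hbonds(f, donors=["don_N"], acceptors=["acc_O"]) == []

    def test_angle_criterion_with_hydrogen(self):
        # linear D-H...A passes; bent (60 deg) fails
        f = Frame(
            0.0, "S0", ["don_N", "don_H", "acc_O"],
            np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]]),
        )
        hbs = mech.detect_hbonds(
            f, donors=["don_N"], acceptors=["acc_O"], hydrogens={"don_N": "don_H"}
        )
        assert len(hbs) == 1 and hbs[0].angle == pytest.approx(180.0)
        f2 = Frame(
            0.0, "S0", ["don_N", "don_H", "acc_O"],
            np.array([[0, 0, 0], [1.0, 0, 0], [1.5, 2.0, 0]]),
        )
        assert (
            mech.detect_hbonds(
                f2, donors=["don_N"], acceptors=["acc_O"], hydrogens={"don_N": "don_H"}
            )
            == []
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_exhaustive_pair_oracle(self, seed):
        """KD-tree detection equals a brute-force double loop."""
        rng = np.random.default_rng(seed)
        frame = _random_frame(rng)
        donors = [lab for lab in frame.labels if lab.endswith("_N")]
        acceptors = [lab for lab in frame.labels if lab.endswith("_O")]
        ours = {
            (hb.donor_label, hb.acceptor_label)
            for hb in mech.detect_hbonds(frame, donors, acceptors)
        }
        brute = {
            (d, a)
            for d in donors
            for a in acceptors
            if d != a
            and np.linalg.norm(frame.position(d) - frame.position(a)) <= 3.5
        }
        assert ours == brute

    def test_sorted_by_distance(self):
        rng = np.random.default_rng(123)
        frame = _random_frame(rng, n=16)
        hbs = mech.detect_hbonds(frame)
        dists = [hb.distance for hb in hbs]
        assert dists == sorted(dists)


class TestWaterBridges:
    def test_midpoint_bridge_found(self):
        f = Frame(
            0.0, "S0", ["D_ring_O", "His278_NE2", "WAT0_O"],
            np.array([[0, 0, 0], [5, 0, 0], [2.5, 0, 0]]),
        )
        out = mech.water_bridges(f, "D_ring_O", "His278_NE2")
        assert len(out) == 1 and out[0].bridging_water == "WAT0_O"
        assert out[0].water_mediated

    def test_no_waters_empty(self):
        f = Frame(0.0, "S0", ["D_ring_O", "His278_NE2"], np.array([[0, 0, 0], [5, 0, 0]]))
        assert mech.water_bridges(f, "D_ring_O", "His278_NE2") == []

    def test_generator_placed_bridges_recalled(self):
        """Waters placed within the cutoff of both partners are always found."""
        found = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 3)
            b = a + rng.normal(0, 1, 3)
            b = a + 5.0 * (b - a) / np.linalg.norm(b - a)
            w = 0.5 * (a + b) + rng.normal(0, 0.2, 3)
            if max(np.linalg.norm(w - a), np.linalg.norm(w - b)) > 3.5:
                continue
            f = Frame(0.0, "S0", ["A_O", "B_N", "WAT0_O"], np.vstack([a, b, w]))
            out = mech.water_bridges(f, "A_O", "B_N")
            assert len(out) == 1
            found += 1
        assert found > 10


class TestClassifyPhotoproduct:
    def test_idealized_pfr(self):
        label = mech.classify_photoproduct(
            {"D1": 10, "D2": 5, "D3": -8, "D4": 5, "D5": 160, "D6": 180}, []
        )
        assert label.value is mech.StateValue.PFR

    def test_missing_dihedral_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mech.classify_photoproduct({"D5": 100.0}, [])

    def test_bv_pr_requires_hbond(self):
        d = {"D4": 5, "D5": -100, "D6": 0}
        hb = [mech.HBond("His278_NE2", "D_ring_O", 2.8)]
        assert mech.classify_photoproduct(d, hb).value is mech.StateValue.BV_PR
        # same dihedrals without the stabilizing H-bond are not BV-Pr
        assert mech.classify_photoproduct(d, []).value is not mech.StateValue.BV_PR

    def test_lumi_ensemble_matches_generator(self, lumi_ensemble):
        """Labels equal the generator's intended population for every
        member of all three populations (20 / 41 / 2)."""
        counts = {}
        for traj, (_, row) in zip(
            lumi_ensemble.trajectories, lumi_ensemble.manifest.iterrows()
        ):
            series = dihedral_series(traj)
            dmap = {k: float(s.values[-1]) for k, s in series.items()}
            hbs = mech.detect_hbonds(traj.frames[-1])
            label = mech.classify_photoproduct(dmap, hbs)
            assert label.value.value == row["population"]
            counts[label.value.value] = counts.get(label.value.value, 0) + 1
            if label.value is mech.StateValue.BV_PR:
                assert any("His278" in e or "Tyr165" in e for e in label.evidence)
        assert counts == {"BV_PR": 20, "BV_PR_PRIME": 41, "BV_PR_DPRIME": 2}

    def test_partition_sums_to_ensemble(self, lumi_ensemble):
        n = sum(1 for _ in lumi_ensemble)
        assert n == 63


class TestMetaFSignature:
    LABELS = ("D_ring_O", "His278_NE2", "Gln190_NE2", "Trp440_CZ2")

    def _frame(self, his, gln, trp):
        coords = np.array([[0.0, 0.0, 0.0], his, gln, trp])
        return Frame(0.0, "S0", self.LABELS, coords)

    def _ref(self):
        # Pfr-like pocket: His far, Gln proximal, Trp near Gln
        return self._frame([5.6, 0, 0], [0, 3.0, 0], [0, 3.5, 1.0])

    def test_all_three_criteria(self):
        frame = self._frame([2.8, 0, 0], [0, 9.0, 0], [3.0, 1.0, 0])
        sig = mech.metaF_signature(frame, self._ref())
        assert sig.is_metaf_like and sig.score == pytest.approx(1.0)

    def test_pfr_like_pocket_scores_low(self):
        ref = self._ref()
        sig = mech.metaF_signature(ref, ref)
        assert not sig.is_metaf_like and sig.score <= 1 / 3 + 1e-9

    def test_trp_gate_blocks(self):
        """Trp440 adjacent to Gln190 gates the signature at 2/3 even when
        the other criteria hold."""
        frame = self._frame([2.8, 0, 0], [0, 9.0, 0], [0, 10.0, 0])
        sig = mech.metaF_signature(frame, self._ref())
        assert not sig.is_metaf_like and sig.score == pytest.approx(2 / 3)

    def test_monotone_in_criteria(self):
        ref = self._ref()
        partial = self._frame([2.8, 0, 0], [0, 3.0, 0], [0, 3.5, 1.0])
        full = self._frame([2.8, 0, 0], [0, 9.0, 0], [3.0, 1.0, 0])
        assert (
            mech.metaF_signature(partial, ref).score
            <= mech.metaF_signature(full, ref).score
        )


class TestSpineTilt:
    @pytest.mark.parametrize("tilt", [0.0, 10.0, 30.0, 60.0])
    def test_construction_round_trip(self, tilt):
        hp = generate_helix_pair(tilt, seed=1)
        assert mech.spine_tilt(hp.ca_a, hp.ca_b) == pytest.approx(tilt, abs=0.5)

    def test_rigid_motion_invariance(self):
        from scipy.stats import special_ortho_group

        hp = generate_helix_pair(30.0, seed=2)
        base = mech.spine_tilt(hp.ca_a, hp.ca_b)
        rot = special_ortho_group.rvs(3, random_state=7)
        shift = np.array([12.0, -4.0, 33.0])
        moved = mech.spine_tilt(hp.ca_a @ rot.T + shift, hp.ca_b @ rot.T + shift)
        assert moved == pytest.approx(base, abs=1e-6)

    def test_symmetry_and_folding(self):
        hp = generate_helix_pair(120.0, seed=3)   # obtuse construction folds
        t_ab = mech.spine_tilt(hp.ca_a, hp.ca_b)
        t_ba = mech.spine_tilt(hp.ca_b, hp.ca_a)
        assert t_ab == pytest.approx(t_ba, abs=1e-9)
        assert 0.0 <= t_ab <= 90.0

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            mech.spine_tilt(np.zeros((3, 3)), np.zeros((5, 3)))
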