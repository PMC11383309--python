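"""Interface metrics vs brute-force oracles, rigid-motion invariance, PDB IO."""

import math

import numpy as np
import pandas as pd
import pytest

import receptorkit as rk
from receptorkit.md_metrics import MetricSpec, select_atoms
from receptorkit.trajectory import Trajectory


def _top(rows):
    return pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name", "atom_name", "element"]
    )


def _simple_system():
    top = _top(
        [
            ("A", 1, "GLY", "N", "N"),
            ("A", 1, "GLY", "CA", "C"),
            ("A", 1, "GLY", "HA", "H"),
            ("B", 2, "GLY", "CA", "C"),
            ("B", 2, "GLY", "CB", "C"),
        ]
    )
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [3, 4, 0], [10, 0, 0]], dtype=float
    )
    traj = Trajectory(topology=top, frames=coords[None], frame_times=[0.0])
    return traj


# ---------------------------------------------------------------------------
# Brute-force oracles (pure double loops, independent of the implementation)
# ---------------------------------------------------------------------------

def _min_dist_oracle(coords, ia, ib):
    best = math.inf
    for i in ia:
        for j in ib:
            if i == j:
                continue
            d = math.dist(coords[i], coords[j])
            best = min(best, d)
    return best


def _hbond_oracle(coords, top, range_a, range_b, d_cut=3.5, theta_cut=150.0):
    def atoms_of(chain, lo, hi, name):
        return [
            i for i in range(len(top))
            if top.chain[i] == chain and lo <= top.residue_number[i] <= hi
            and top.atom_name[i] == name
        ]

    def find_h(i):
        for j in range(len(top)):
            if (
                top.chain[j] == top.chain[i]
                and top.residue_number[j] == top.residue_number[i]
                and top.atom_name[j] in ("H", "HN")
            ):
                return j
        return None

    count = 0
    for (ca, la, ha_), (cb, lb, hb_) in ((range_a, range_b), (range_b, range_a)):
        for n in atoms_of(ca, la, ha_, "N"):
            for o in atoms_of(cb, lb, hb_, "O"):
                if math.dist(coords[n], coords[o]) > d_cut:
                    continue
                h = find_h(n)
                if h is not None:
                    v1 = coords[n] - coords[h]
                    v2 = coords[o] - coords[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    if math.degrees(math.acos(max(-1, min(1, cosang)))) < theta_cut:
                        continue
                count += 1
    return count


def _random_protein_frame(rng, n_res_a=20, n_res_b=15):
    """Random two-chain system with backbone + occasional sidechain/H atoms."""
    rows, coords = [], []
    for chain, n_res, start in (("A", n_res_a, 1), ("B", n_res_b, 101)):
        for r in range(start, start + n_res):
            center = rng.uniform(0, 25, 3)
            for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                rows.append((chain, r, "ALA", name, elem))
                coords.append(center + rng.normal(0, 1.2, 3))
            if rng.random() < 0.7:
                rows.append((chain, r, "ALA", "H", "H"))
                coords.append(coords[-4] + rng.normal(0, 0.8, 3))
            for k in range(rng.integers(0, 4)):
                rows.append((chain, r, "ALA", f"CB{k}" if k else "CB", "C"))
                coords.append(center + rng.normal(0, 1.5, 3))
    return _top(rows), np.asarray(coords)


class TestMinDistance:
    def test_three_four_five_triangle(self):
        traj = _simple_system()
        a = select_atoms(traj.topology, chain="A", atom_names={"N"})
        b = select_atoms(traj.topology, chain="B", atom_names={"CA"})
        assert rk.min_distance(traj.frames[0], a, b) == pytest.approx(5.0)

    def test_symmetric_in_arguments(self):
        traj = _simple_system()
        a = select_atoms(traj.topology, chain="A")
        b = select_atoms(traj.topology, chain="B")
        c = traj.frames[0]
        assert rk.min_distance(c, a, b) == rk.min_distance(c, b, a)

    def test_identical_selection_excludes_self_pairs(self):
        coords = np.array([[0, 0, 0], [0, 0, 2], [0, 0, 5.0]])
        sel = np.array([0, 1, 2])
        assert rk.min_distance(coords, sel, sel) == pytest.approx(2.0)

    def test_empty_selection_is_error(self):
        coords = np.zeros((3, 3))
        with pytest.raises(ValueError, match="selection_a"):
            rk.min_distance(coords, np.array([], dtype=int), np.array([0]))

    def test_matches_brute_force_on_random_selections(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 30, (350, 3))
        ia = rng.choice(350, 200, replace=False)
        ib = rng.choice(350, 150, replace=False)
        assert rk.min_distance(coords, ia, ib) == pytest.approx(
            _min_dist_oracle(coords, ia, ib), abs=1e-9
        )


class TestInsertionDepth:
    def test_single_heavy_atom_probe(self):
        top = _top([("A", 36, "TRP", "CB", "C"), ("B", 119, "LEU", "CA", "C")])
        coords = np.array([[0, 0, 0], [0, 0, 2.0]])
        assert rk.insertion_depth(coords, top) == pytest.approx(2.0)

    def test_hydrogens_do_not_contribute(self):
        top = _top(
            [
                ("A", 36, "TRP", "CB", "C"),
                ("A", 36, "TRP", "HB", "H"),
                ("B", 119, "LEU", "CA", "C"),
            ]
        )
        coords = np.array([[0, 0, 0], [0, 0, 1.5], [0, 0, 2.0]])
        assert rk.insertion_depth(coords, top) == pytest.approx(2.0)

    def test_multi_atom_probe_matches_brute_force(self, toy_traj):
        traj, _ = toy_traj
        coords = traj.frames[0]
        probe = select_atoms(traj.topology, chain="A", residue_number=36, heavy_only=True)
        anchor = select_atoms(
            traj.topology, chain="B", residue_number=119, atom_names={"CA"}
        )
        assert len(probe) >= 10
        assert rk.insertion_depth(coords, traj.topology) == pytest.approx(
            _min_dist_oracle(coords, probe, anchor), abs=1e-9
        )

    def test_ambiguous_anchor_is_error(self):
        top = _top([("A", 36, "TRP", "CB", "C"), ("B", 119, "LEU", "CB", "C")])
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="anchor"):
            rk.insertion_depth(coords, top, anchor=("B", 119, "CA"))


class TestPocketDistance:
    def test_two_single_cb_residues(self):
        top = _top(
            [
                ("B", 133, "ILE", "CB", "C"),
                ("B", 133, "ILE", "CA", "C"),
                ("B", 169, "PHE", "CB", "C"),
                ("B", 169, "PHE", "CA", "C"),
            ]
        )
        coords = np.array([[0, 0, 0], [1, 0, 0], [7.2, 0, 0], [6.0, 0, 0]])
        assert rk.pocket_distance(coords, top) == pytest.approx(7.2)

    def test_backbone_atoms_excluded(self):
        # CA atoms placed arbitrarily close must not change the result
        top = _top(
            [
                ("B", 133, "ILE", "CB", "C"),
                ("B", 133, "ILE", "CA", "C"),
                ("B", 169, "PHE", "CB", "C"),
                ("B", 169, "PHE", "CA", "C"),
            ]
        )
        coords = np.array([[0, 0, 0], [3.0, 0, 0], [7.2, 0, 0], [3.1, 0, 0]])
        assert rk.pocket_distance(coords, top) == pytest.approx(7.2)

    def test_glycine_like_residue_is_error(self):
        top = _top(
            [("B", 133, "GLY", "CA", "C"), ("B", 169, "PHE", "CB", "C")]
        )
        with pytest.raises(ValueError, match="sidechain"):
            rk.pocket_distance(np.zeros((2, 3)), top)

    def test_constructed_sidechains_match_brute_force(self, toy_traj):
        traj, _ = toy_traj
        coords = traj.frames[0]
        a = select_atoms(traj.topology, chain="B", residue_number=133, sidechain_only=True)
        b = select_atoms(traj.topology, chain="B", residue_number=169, sidechain_only=True)
        assert rk.pocket_distance(coords, traj.topology) == pytest.approx(
            _min_dist_oracle(coords, a, b), abs=1e-9
        )


class TestBackboneHbonds:
    def _pair(self, n_xyz, h_xyz, o_xyz, with_h=True):
        rows = [("A", 36, "ALA", "N", "N")]
        coords = [n_xyz]
        if with_h:
            rows.append(("A", 36, "ALA", "H", "H"))
            coords.append(h_xyz)
        rows.append(("B", 130, "GLY", "O", "O"))
        coords.append(o_xyz)
        return _top(rows), np.asarray(coords, dtype=float)

    def test_ideal_geometry_counts_one(self):
        top, coords = self._pair([0, 0, 2.9], [0, 0, 1.9], [0, 0, 0])
        assert rk.count_backbone_hbonds(coords, top) == 1

    def test_bent_geometry_rejected_with_h_accepted_without(self):
        # N-H...O angle of 90 degrees fails the angular criterion
        top, coords = self._pair([0, 1.0, 1.9], [0, 0, 1.9], [0, 0, 0])
        assert rk.count_backbone_hbonds(coords, top) == 0
        top2, coords2 = self._pair([0, 1.0, 1.9], None, [0, 0, 0], with_h=False)
        assert rk.count_backbone_hbonds(coords2, top2) == 1

    def test_distant_ranges_count_zero(self):
        top, coords = self._pair([0, 0, 20.0], [0, 0, 19.0], [0, 0, 0])
        assert rk.count_backbone_hbonds(coords, top) == 0

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(13)
        top, coords = _random_protein_frame(rng, 8, 8)
        range_a, range_b = ("A", 1, 8), ("B", 101, 108)
        counts_d = [
            rk.count_backbone_hbonds(coords, top, range_a, range_b, d_cut=d)
            for d in (5.0, 4.0, 3.5, 3.0, 2.0)
        ]
        assert counts_d == sorted(counts_d, reverse=True)
        counts_t = [
            rk.count_backbone_hbonds(coords, top, range_a, range_b, d_cut=5.0,
                                     theta_cut=t)
            for t in (0.0, 90.0, 150.0, 179.0)
        ]
        assert counts_t == sorted(counts_t, reverse=True)

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            top, coords = _random_protein_frame(rng, 10, 10)
            got = rk.count_backbone_hbonds(
                coords, top, ("A", 1, 10), ("B", 101, 110), d_cut=6.0, theta_cut=120.0
            )
            want = _hbond_oracle(
                coords, top, ("A", 1, 10), ("B", 101, 110), d_cut=6.0, theta_cut=120.0
            )
            assert got == want


class TestRigidMotionInvariance:
    @staticmethod
    def _random_rotation(rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def test_all_metrics_invariant_under_rigid_transforms(self, toy_traj):
        traj, _ = toy_traj
        rng = np.random.default_rng(15)
        coords = traj.frames[0]
        before = [spec.evaluate(coords, traj.topology)
                  for spec in rk.default_metric_specs()]
        for _ in range(5):
            moved = coords @ self._random_rotation(rng).T + rng.uniform(-50, 50, 3)
            after = [spec.evaluate(moved, traj.topology)
                     for spec in rk.default_metric_specs()]
            assert np.allclose(after, before, atol=1e-9)


class TestMetricSeries:
    def test_stride_one_uses_every_frame(self, toy_traj):
        traj, _ = toy_traj
        s = rk.metric_series(traj, MetricSpec.hbond(), stride_ns=1.0)
        assert len(s.values) == traj.n_frames

    def test_stride_two_subsamples_consistently(self, toy_traj):
        traj, _ = toy_traj
        s1 = rk.metric_series(traj, MetricSpec.pocket(), stride_ns=1.0)
        s2 = rk.metric_series(traj, MetricSpec.pocket(), stride_ns=2.0)
        assert np.allclose(s2.values, s1.values[::2])

    def test_fine_stride_warns_and_uses_every_frame(self, toy_traj):
        traj, _ = toy_traj
        with pytest.warns(UserWarning, match="finer"):
            s = rk.metric_series(traj, MetricSpec.pocket(), stride_ns=0.25)
        assert len(s.values) == traj.n_frames

    def test_tsv_roundtrip(self, toy_traj, tmp_path):
        traj, _ = toy_traj
        s = rk.metric_series(traj, MetricSpec.hbond())
        path = tmp_path / "series.tsv"
        s.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["time_ns", "value"]
        assert np.allclose(back["value"], s.values)


class TestMultimodelPdbIO:
    def test_two_model_file(self, tmp_path):
        top = _top([("A", 1, "GLY", "N", "N"), ("A", 1, "GLY", "CA", "C")])
        frames = np.array([[[0, 0, 0], [1, 0, 0]], [[0, 0, 1], [1, 0, 1.0]]])
        traj = Trajectory(topology=top, frames=frames, frame_times=[0.0, 1.0])
        path = tmp_path / "two.pdb"
        rk.write_multimodel_pdb(traj, path)
        back = rk.read_multimodel_pdb(path)
        assert back.n_frames == 2 and back.n_atoms == 2

    def test_roundtrip_at_pdb_precision(self, toy_traj, tmp_path):
        traj, _ = toy_traj
        path = tmp_path / "traj.pdb"
        rk.write_multimodel_pdb(traj, path)
        back = rk.read_multimodel_pdb(path)
        assert np.max(np.abs(back.frames - traj.frames)) <= 1e-3 + 1e-9
        pd.testing.assert_frame_equal(
            back.topology[["chain", "residue_number", "residue_name", "atom_name"]],
            traj.topology[["chain", "residue_number", "residue_name", "atom_name"]],
        )

    def test_element_inference_when_columns_absent(self, tmp_path):
        traj, _ = rk.generate_toy_trajectory(
            rk.TrajSimConfig(n_frames=1, switch_frame=1)
        )
        path = tmp_path / "noelem.pdb"
        rk.write_multimodel_pdb(traj, path)
        stripped = "\n".join(
            line[:76].rstrip() if line.startswith("ATOM") else line
            for line in path.read_text().splitlines()
        )
        path.write_text(stripped + "\n")
        back = rk.read_multimodel_pdb(path)
        # " CA " is a backbone carbon, not calcium; NE1 is nitrogen
        assert set(back.topology.loc[back.topology.atom_name == "CA", "element"]) == {"C"}
        assert set(back.topology.loc[back.topology.atom_name == "NE1", "element"]) == {"N"}
        assert set(back.topology.loc[back.topology.atom_name == "H", "element"]) == {"H"}

    def test_mismatched_model_atom_count_is_error(self, tmp_path):
        top = _top([("A", 1, "GLY", "N", "N"), ("A", 1, "GLY", "CA", "C")])
        frames = np.zeros((1, 2, 3))
        traj = Trajectory(topology=top, frames=frames, frame_times=[0.0])
        path = tmp_path / "bad.pdb"
        rk.write_multimodel_pdb(traj, path)
        text = path.read_text().replace(
            "END\n", "MODEL        2\n"
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00"
            "           N\nENDMDL\nEND\n"
        )
        path.write_text(text)
        with pytest.raises(ValueError, match="MODEL 2"):
            rk.read_multimodel_pdb(path)

    def test_min_distance_agrees_with_mdanalysis(self, toy_traj, tmp_path):
        MDAnalysis = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.distances import distance_array

        traj, _ = toy_traj
        path = tmp_path / "traj.pdb"
        rk.write_multimodel_pdb(traj, path)
        u = MDAnalysis.Universe(str(path))
        ours = rk.read_multimodel_pdb(path)
        a = select_atoms(ours.topology, chain="A", heavy_only=True)
        b = select_atoms(ours.topology, chain="B", heavy_only=True)
        sel_a = u.select_atoms("segid A and not element H")
        sel_b = u.select_atoms("segid B and not element H")
        if len(sel_a) == 0:  # chain recorded as chainID in some readers
            sel_a = u.select_atoms("chainID A and not element H")
            sel_b = u.select_atoms("chainID B and not element H")
        ref = float(distance_array(sel_a.positions, sel_b.positions).min())
        assert rk.min_distance(ours.frames[0], a, b) == pytest.approx(ref, abs=1e-3)
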