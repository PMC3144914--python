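import numpy as np
import pytest

from dfgflip.docking_selection import (
    DockedPose,
    build_hitlist,
    filter_in_cleft,
    ligand_rmsd,
    parse_poses,
    representative_pose,
    roc_auc,
    top_fraction_rank,
    write_poses_tsv,
)
from dfgflip.pocket_analysis import BindingSites
from oracles import pairwise_auc


def _pose(lig="lig", model="m01", run=1, energy=-8.0, coords=((0.0, 0.0, 0.0),),
          names=None):
    coords = np.asarray(coords, dtype=float)
    if names is None:
        names = tuple(f"C{i+1}" for i in range(len(coords)))
    return DockedPose(ligand_id=lig, model_id=model, run_index=run,
                      energy=energy, atom_names=tuple(names), coords=coords)


def _sites(b2=(0.0, 0.0, 0.0), b3=(10.0, 0.0, 0.0)):
    return BindingSites(centers=np.array([b2, b3]),
                        weights=np.array([2.0, 1.0]),
                        labels={"B2": 0, "B3": 1})


DLG_TEXT = """\
DOCKED: MODEL        1
DOCKED: USER    Estimated Free Energy of Binding    =   -7.10 kcal/mol
DOCKED: ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00     0.000 C
DOCKED: ATOM      2  HD1 LIG A   1       0.500   0.000   0.000  1.00  0.00     0.000 HD
DOCKED: ENDMDL
DOCKED: MODEL        2
DOCKED: USER    Estimated Free Energy of Binding    =   -8.30 kcal/mol
DOCKED: ATOM      1  C1  LIG A   1       1.000   0.000   0.000  1.00  0.00     0.000 C
DOCKED: ENDMDL
"""


class TestParsePoses:
    def test_dlg_two_models_with_energies(self, tmp_path):
        p = tmp_path / "lig.dlg"
        p.write_text(DLG_TEXT)
        poses = parse_poses(p, "dlg")
        assert [(x.run_index, x.energy) for x in poses] == [(1, -7.1), (2, -8.3)]
        assert poses[0].atom_names == ("C1",)  # hydrogens dropped

    def test_missing_energy_is_an_error(self, tmp_path):
        broken = DLG_TEXT.replace(
            "DOCKED: USER    Estimated Free Energy of Binding    =   -7.10 kcal/mol\n",
            "", 1)
        p = tmp_path / "broken.dlg"
        p.write_text(broken)
        with pytest.raises(ValueError, match="energy"):
            parse_poses(p, "dlg")

    def test_tsv_pdb_round_trip(self, tmp_path):
        poses = [_pose(lig="a", energy=-9.25, coords=[(0, 0, 0), (1.5, 0, 0)]),
                 _pose(lig="a", run=2, energy=-7.0, coords=[(3, 3, 3)])]
        p = write_poses_tsv(poses, tmp_path / "poses.tsv")
        back = parse_poses(p, "tsv_pdb")
        assert len(back) == 2
        assert back[0].energy == -9.25
        np.testing.assert_allclose(back[0].coords, poses[0].coords, atol=1e-3)

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            parse_poses(p, "sdf")


class TestFilterInCleft:
    def test_strictly_within_three_angstrom(self):
        sites = _sites()
        near = _pose(coords=[(2.9, 0, 0)])
        boundary = _pose(run=2, coords=[(3.0, 0, 0), (7.0, 0, 0)])  # both at 3.0
        far = _pose(run=3, coords=[(50.0, 0, 0)])
        kept = filter_in_cleft([near, boundary, far], sites)
        assert [p.run_index for p in kept] == [1]

    def test_b3_proximity_also_suffices(self):
        sites = _sites(b2=(0, 0, 0), b3=(10, 0, 0))
        pose = _pose(coords=[(11.0, 0, 0)])  # 11 from B2, 1 from B3
        assert filter_in_cleft([pose], sites) == [pose]

    def test_missing_model_sites_is_an_error(self):
        pose = _pose(model="m99")
        with pytest.raises(KeyError, match="m99"):
            filter_in_cleft([pose], {"m01": _sites()})


class TestRepresentativePose:
    def test_lowest_energy_wins(self):
        poses = [_pose(run=1, energy=-8.2), _pose(run=2, energy=-9.1),
                 _pose(run=3, energy=-7.5)]
        assert representative_pose(poses).energy == -9.1

    def test_no_in_cleft_pose_is_none(self):
        assert representative_pose([]) is None

    def test_tie_breaks_to_smallest_model_then_run(self):
        poses = [_pose(model="m02", run=1, energy=-9.1),
                 _pose(model="m01", run=5, energy=-9.1),
                 _pose(model="m01", run=2, energy=-9.1)]
        rep = representative_pose(poses)
        assert (rep.model_id, rep.run_index) == ("m01", 2)

    def test_order_invariance_of_pipeline(self):
        rng = np.random.default_rng(3)
        poses = [_pose(model=f"m{i%4:02d}", run=i, energy=float(e),
                       coords=[(0.5, 0, 0)])
                 for i, e in enumerate(rng.normal(-8, 1, 30), start=1)]
        sites = _sites()
        rep1 = representative_pose(filter_in_cleft(poses, sites))
        shuffled = list(poses)
        rng.shuffle(shuffled)
        rep2 = representative_pose(filter_in_cleft(shuffled, sites))
        assert rep1 == rep2

    def test_representative_never_beaten_by_a_retained_pose(self):
        rng = np.random.default_rng(4)
        poses = [_pose(run=i, energy=float(e))
                 for i, e in enumerate(rng.normal(-8, 2, 50), start=1)]
        rep = representative_pose(poses)
        assert all(rep.energy <= p.energy for p in poses)


class TestLigandRmsd:
    def test_self_is_zero(self):
        p = _pose(coords=[(0, 0, 0), (1, 1, 1)])
        assert ligand_rmsd(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_translation(self):
        a = _pose(coords=[(0, 0, 0), (2, 0, 0)])
        b = _pose(coords=[(1, 0, 0), (3, 0, 0)])
        assert ligand_rmsd(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_name_matching_ignores_input_order(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(5, 3))
        names = ("C1", "N1", "O1", "C2", "C3")
        a = _pose(coords=coords, names=names)
        perm = [3, 0, 4, 1, 2]
        b = _pose(coords=coords[perm] + 0.5, names=tuple(names[i] for i in perm))
        # oracle: every atom displaced by exactly (0.5, 0.5, 0.5)
        assert ligand_rmsd(a, b) == pytest.approx(np.sqrt(0.75), abs=1e-9)

    def test_atom_set_mismatch_lists_names(self):
        a = _pose(coords=[(0, 0, 0)], names=("C1",))
        b = _pose(coords=[(0, 0, 0)], names=("N9",))
        with pytest.raises(ValueError, match="C1.*N9|N9.*C1"):
            ligand_rmsd(a, b)

    def test_receptor_frame_transform_applied(self):
        from dfgflip.cleft_geometry import rodrigues_matrix
        R = rodrigues_matrix((0, 0, 1), 90.0)
        a = _pose(coords=[(1, 0, 0), (2, 0, 0)])
        rotated = _pose(coords=np.asarray([(0, 1, 0), (0, 2, 0)]))
        assert ligand_rmsd(a, rotated, rotation=R) == pytest.approx(0.0, abs=1e-9)


class TestHitList:
    def test_ascending_energy_order(self):
        reps = {"a": _pose(lig="a", energy=-9.0),
                "b": _pose(lig="b", energy=-7.0),
                "c": _pose(lig="c", energy=-8.0)}
        h = build_hitlist(reps, {k: "active" for k in reps})
        assert [e[0] for e in h.entries] == ["a", "c", "b"]

    def test_no_pose_ligand_ranks_last(self):
        reps = {"a": _pose(lig="a", energy=-9.0), "b": None,
                "c": _pose(lig="c", energy=-2.0)}
        h = build_hitlist(reps, {k: "decoy" for k in reps})
        assert h.entries[-1][0] == "b"

    def test_rank_and_top_fraction(self):
        reps = {f"l{i:03d}": _pose(lig=f"l{i:03d}", energy=-float(100 - i))
                for i in range(100)}
        h = build_hitlist(reps, {k: "decoy" for k in reps})
        assert top_fraction_rank(h, "l000") == pytest.approx(0.01)
        assert top_fraction_rank(h, "l049") == pytest.approx(0.50)
        with pytest.raises(KeyError):
            top_fraction_rank(h, "absent")


class TestRocAuc:
    def test_perfect_separation(self):
        reps = {}
        labels = {}
        for i in range(5):
            reps[f"a{i}"] = _pose(lig=f"a{i}", energy=-10.0 - i)
            labels[f"a{i}"] = "active"
        for i in range(5):
            reps[f"d{i}"] = _pose(lig=f"d{i}", energy=-5.0 - 0.1 * i)
            labels[f"d{i}"] = "decoy"
        assert roc_auc(build_hitlist(reps, labels)).auc == pytest.approx(1.0)

    def test_interleaved_ranks(self):
        # actives at ranks 1 and 3, decoys at 2 and 4 -> AUC 3/4
        reps = {"a1": _pose(lig="a1", energy=-10.0),
                "d1": _pose(lig="d1", energy=-9.0),
                "a2": _pose(lig="a2", energy=-8.0),
                "d2": _pose(lig="d2", energy=-7.0)}
        labels = {"a1": "active", "a2": "active", "d1": "decoy", "d2": "decoy"}
        assert roc_auc(build_hitlist(reps, labels)).auc == pytest.approx(0.75)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            n = int(rng.integers(4, 21))
            energies = np.round(rng.normal(-8, 1, n), 1)  # rounding makes ties
            labels_bool = rng.random(n) < 0.4
            if labels_bool.all() or not labels_bool.any():
                continue
            reps, labels = {}, {}
            for i, (e, act) in enumerate(zip(energies, labels_bool)):
                lig = f"l{i}"
                reps[lig] = _pose(lig=lig, energy=float(e))
                labels[lig] = "active" if act else "decoy"
            r = roc_auc(build_hitlist(reps, labels))
            oracle = pairwise_auc(list(zip(energies, labels_bool)))
            assert abs(r.auc - oracle) < 1e-9

    def test_auc_equals_trapezoidal_curve_area(self):
        rng = np.random.default_rng(10)
        reps, labels = {}, {}
        for i in range(200):
            lig = f"l{i}"
            act = i % 5 == 0
            mu = -10.0 if act else -7.0
            reps[lig] = _pose(lig=lig, energy=float(rng.normal(mu, 1)))
            labels[lig] = "active" if act else "decoy"
        r = roc_auc(build_hitlist(reps, labels))
        assert abs(np.trapezoid(r.curve[:, 1], r.curve[:, 0]) - r.auc) < 1e-9

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(12)
        reps, labels = {}, {}
        for i in range(50):
            lig = f"l{i}"
            reps[lig] = _pose(lig=lig, energy=float(rng.normal(-8, 1)))
            labels[lig] = "active" if i % 3 == 0 else "decoy"
        swapped = {k: ("decoy" if v == "active" else "active")
                   for k, v in labels.items()}
        a1 = roc_auc(build_hitlist(reps, labels)).auc
        a2 = roc_auc(build_hitlist(reps, swapped)).auc
        assert abs(a1 - (1.0 - a2)) < 1e-9

    def test_single_class_rejected(self):
        reps = {"a": _pose(lig="a")}
        with pytest.raises(ValueError):
            roc_auc(build_hitlist(reps, {"a": "active"}))
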