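import numpy as np
import pytest

from dfgflip.fixtures import make_toy_cavity
from dfgflip.pocket_analysis import (
    BindingSites,
    CleftReport,
    build_grid,
    label_sites,
    occupied_waters,
    pass_sites,
    psp_scan,
)
from oracles import occupied_waters_enumeration, psp_counts_walking


class TestBuildGrid:
    def test_empty_structure_rejected(self):
        from dfgflip.structure_io import KinaseStructure
        with pytest.raises(ValueError):
            build_grid(KinaseStructure(atoms=[]))

    def test_single_carbon_protein_radius(self):
        from dfgflip.structure_io import AtomRecord, KinaseStructure
        s = KinaseStructure(atoms=[AtomRecord(
            serial=1, name="C", element="C", res_name="UNK", chain_id="A",
            res_seq=1, i_code=" ", coord=(0.2, 0.3, 0.4))])
        g = build_grid(s, spacing=1.0, margin=5.0, probe_radius=1.4)
        idx = np.argwhere(np.ones(g.protein.shape, dtype=bool))
        pts = g.origin + idx * g.spacing
        dist = np.linalg.norm(pts - np.array([0.2, 0.3, 0.4]), axis=1)
        inside = dist <= 1.70 + 1.4
        np.testing.assert_array_equal(g.protein.ravel(), inside)

    def test_hollow_cube_interior_is_solvent(self, cube_cavity):
        g = build_grid(cube_cavity.structure)
        center = cube_cavity.chamber_centers[0]
        idx = np.argwhere(~g.protein)
        pts = g.origin + idx * g.spacing
        # all points within the designed interior must be solvent
        interior = np.all(np.abs(pts - center) <= 4.5, axis=1)
        assert interior.sum() > 0
        all_idx = np.argwhere(np.ones(g.protein.shape, dtype=bool))
        all_pts = g.origin + all_idx * g.spacing
        inside_design = np.all(np.abs(all_pts - center) <= 4.5, axis=1)
        assert not g.protein.ravel()[inside_design].any()


class TestPspScan:
    def test_no_protein_means_no_pocket(self):
        g = _bare_grid(np.zeros((6, 6, 6), dtype=bool))
        psp_scan(g)
        assert g.psp_count.sum() == 0
        assert not g.pocket_mask.any()

    def test_single_axis_flanking_counts_one(self):
        protein = np.zeros((5, 3, 3), dtype=bool)
        protein[0, 1, 1] = protein[4, 1, 1] = True
        g = _bare_grid(protein)
        psp_scan(g, psp_threshold=1)
        assert g.psp_count[2, 1, 1] == 1  # enclosed along x only

    @pytest.mark.parametrize("kind,size", [
        ("cube", 10.0), ("sphere", 8.0), ("three_chamber", 8.0),
    ])
    def test_matches_walking_oracle_exactly(self, kind, size):
        cav = make_toy_cavity(kind, size, seed=0)
        g = build_grid(cav.structure, margin=3.0)
        psp_scan(g)
        np.testing.assert_array_equal(g.psp_count, psp_counts_walking(g.protein))

    def test_monotone_under_cavity_growth(self):
        sizes = (6.0, 8.0, 10.0, 12.0)
        masks, waters = [], []
        for L in sizes:
            cav = make_toy_cavity("cube", L, seed=0)
            g = psp_scan(build_grid(cav.structure))
            masks.append(int(g.pocket_mask.sum()))
            waters.append(occupied_waters(g))
        assert masks == sorted(masks)
        assert waters == sorted(waters)


class TestPassSites:
    def test_empty_mask_gives_no_sites(self):
        g = _bare_grid(np.zeros((4, 4, 4), dtype=bool))
        psp_scan(g)
        assert len(pass_sites(g)) == 0

    def test_single_cavity_center_recovered(self, cube_cavity):
        g = psp_scan(build_grid(cube_cavity.structure))
        sites = pass_sites(g)
        assert len(sites) == 1
        d = np.linalg.norm(sites.centers[0] - cube_cavity.chamber_centers[0])
        assert d <= g.spacing

    def test_three_chambers_give_three_ranked_sites(self, three_chamber_cavity):
        g = psp_scan(build_grid(three_chamber_cavity.structure))
        sites = pass_sites(g)
        assert len(sites) == 3
        assert list(sites.weights) == sorted(sites.weights, reverse=True)
        # each designed chamber center matched by exactly one site
        d = np.linalg.norm(
            sites.centers[:, None, :] - three_chamber_cavity.chamber_centers[None],
            axis=2)
        assert (d.min(axis=1) <= 1.5).all()
        assert sorted(np.argmin(d, axis=1).tolist()) == [0, 1, 2]


class TestLabelSites:
    def test_fewer_than_three_sites_is_an_error(self, toy_in):
        sites = BindingSites(centers=np.zeros((2, 3)), weights=np.ones(2))
        with pytest.raises(ValueError, match="underpopulated"):
            label_sites(sites, toy_in)

    def test_labels_follow_anchor_geometry(self, toy_in):
        ann = toy_in.annotation
        hinge = toy_in.atom_coord(ann.hinge_middle, "CA")
        dfg = toy_in.atom_coord(ann.dfg_asp, "CA")
        ke = 0.5 * (toy_in.atom_coord(ann.catalytic_lys, "CA")
                    + toy_in.atom_coord(ann.alphaC_glu, "CA"))
        centers = np.array([dfg + [0, -1, 0], ke + [0.5, 0, 0], hinge + [1, 0, 0]])
        sites = BindingSites(centers=centers, weights=np.array([9.0, 5.0, 3.0]))
        labeled = label_sites(sites, toy_in)
        assert labeled.labels["B3"] == 0
        assert labeled.labels["B2"] == 1
        assert labeled.labels["B1"] == 2
        assert len(set(labeled.labels.values())) == 3


class TestOccupiedWaters:
    def test_empty_mask_counts_zero(self):
        g = _bare_grid(np.zeros((4, 4, 4), dtype=bool))
        psp_scan(g)
        assert occupied_waters(g) == 0

    @pytest.mark.parametrize("kind,size", [
        ("cube", 6.0), ("cube", 10.0), ("sphere", 8.0),
    ])
    def test_matches_enumeration_oracle_exactly(self, kind, size):
        cav = make_toy_cavity(kind, size, seed=0)
        g = psp_scan(build_grid(cav.structure))
        assert occupied_waters(g) == occupied_waters_enumeration(g, g.pocket_mask)

    def test_count_invariant_under_corigid_translation(self):
        # moving the cavity (and hence its snapped grid) by whole grid steps
        # keeps mask and lattice co-registered
        base = make_toy_cavity("cube", 10.0, seed=0)
        moved = base.structure.transformed(np.eye(3), np.array([7.0, -3.0, 2.0]))
        g0 = psp_scan(build_grid(base.structure))
        g1 = psp_scan(build_grid(moved))
        assert occupied_waters(g0) == occupied_waters(g1)

    def test_volume_tracks_analytic_density(self, sphere_cavity):
        g = psp_scan(build_grid(sphere_cavity.structure))
        w = occupied_waters(g)
        # compare against direct enumeration of lattice points in the mask
        assert w == occupied_waters_enumeration(g, g.pocket_mask)
        assert w > 0


class TestSelectionRule:
    @pytest.mark.parametrize("n_sites,waters,expected", [
        (3, 25, True),
        (3, 21, True),
        (3, 20, False),   # strictly more than 20
        (2, 40, False),   # at least three sites
        (4, 100, True),
    ])
    def test_three_sites_and_twenty_waters(self, n_sites, waters, expected):
        r = CleftReport(model_id="m", n_sites_in_cleft=n_sites,
                        occupied_waters=waters)
        assert r.selected is expected


def _bare_grid(protein):
    from dfgflip.pocket_analysis import PocketGrid
    return PocketGrid(origin=np.zeros(3), spacing=1.0, protein=protein)
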