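"""SASA against analytic oracles, BSA properties, contacts and clashes."""

import numpy as np
import pytest

from bendkit.errors import ConfigurationError
from bendkit.interface import (
    buried_surface_area,
    contact_residues,
    golden_spiral_points,
    lattice_graft_clash,
    shrake_rupley_sasa,
)
from bendkit.model import AtomRecord, ResidueRecord, StructureModel
from bendkit.synthetic import make_bent_dimer, make_sphere_system, make_toy_lattice

PROBE = 1.4


def _two_sphere_reference(r1, r2, d, probe=PROBE):
    """Closed-form SASA of two intersecting spheres (spherical caps)."""
    e1, e2 = r1 + probe, r2 + probe
    if d >= e1 + e2:
        return 4 * np.pi * (e1**2 + e2**2)
    h1 = e1 - (d**2 + e1**2 - e2**2) / (2 * d)
    h2 = e2 - (d**2 + e2**2 - e1**2) / (2 * d)
    return 4 * np.pi * (e1**2 + e2**2) - 2 * np.pi * (e1 * h1 + e2 * h2)


def test_single_sphere_matches_analytic_area():
    m = make_sphere_system([[0.0, 0.0, 0.0]], [1.9])
    res = shrake_rupley_sasa(m)
    exact = 4 * np.pi * (1.9 + PROBE) ** 2
    assert abs(res.total - exact) / exact < 0.005
    assert res.total == pytest.approx(res.per_atom_area.sum())


def test_separated_spheres_are_additive():
    single = shrake_rupley_sasa(make_sphere_system([[0, 0, 0]], [1.9])).total
    double = shrake_rupley_sasa(
        make_sphere_system([[0, 0, 0], [20.0, 0, 0]], [1.9, 1.9])
    ).total
    assert double == pytest.approx(2 * single, rel=1e-9)


@pytest.mark.parametrize("d", [1.5, 2.5, 3.5, 5.0])
def test_overlapping_spheres_match_cap_formula(d):
    m = make_sphere_system([[0, 0, 0], [d, 0, 0]], [1.7, 1.52])
    res = shrake_rupley_sasa(m)
    exact = _two_sphere_reference(1.7, 1.52, d)
    assert abs(res.total - exact) / exact < 0.01


def test_quadrature_converges(dimer12):
    coarse = shrake_rupley_sasa(dimer12, n_sphere_points=960).total
    fine = shrake_rupley_sasa(dimer12, n_sphere_points=4000).total
    assert abs(coarse - fine) / fine < 0.005


def test_golden_spiral_points_unit_norm():
    pts = golden_spiral_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert abs(pts.mean(axis=0)).max() < 0.01  # near-uniform coverage


def test_sasa_cross_checked_against_independent_implementation(dimer12):
    """Totals agree with biotite's Shrake-Rupley on identical radii."""
    import biotite.structure as struc

    atoms = [
        (cid, res, atom)
        for cid, res, atom in dimer12.iter_atoms(heavy_only=True)
        if res.is_protein
    ]
    arr = struc.AtomArray(len(atoms))
    for i, (cid, res, atom) in enumerate(atoms):
        arr.coord[i] = atom.coord
        arr.chain_id[i] = cid
        arr.res_id[i] = res.seq_id
        arr.res_name[i] = res.comp_id
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
    radii = np.array([a.vdw_radius for _, _, a in atoms])
    ref = struc.sasa(arr, probe_radius=PROBE, vdw_radii=radii, point_number=960)
    ours = shrake_rupley_sasa(dimer12, n_sphere_points=960)
    assert ours.total == pytest.approx(float(np.nansum(ref)), rel=0.01)


def test_unknown_element_raises_configuration_error():
    res = ResidueRecord(
        seq_id=1,
        comp_id="ALA",
        atoms=[AtomRecord(name="Q1", element="Xx", coord=[0, 0, 0])],
    )
    model = StructureModel(id="x", chains={"A": [res]})
    with pytest.raises(ConfigurationError):
        shrake_rupley_sasa(model)


class TestBuriedSurfaceArea:
    def test_distant_partners_bury_nothing(self):
        m = make_sphere_system([[0, 0, 0], [100.0, 0, 0]], [1.9, 1.9])
        chains = dict(m.chains)
        model = StructureModel(
            id="x",
            chains={"A": [chains["A"][0]], "B": [chains["A"][1]]},
        )
        rep = buried_surface_area(model, ["A"], ["B"])
        assert rep.bsa_total == pytest.approx(0.0, abs=1e-6)

    def test_bsa_symmetric_in_partners(self, dimer12):
        ab = buried_surface_area(dimer12, ["A", "B"], ["X"])
        ba = buried_surface_area(dimer12, ["X"], ["A", "B"])
        assert ab.bsa_total == pytest.approx(ba.bsa_total, abs=1e-6)
        assert ab.bsa_total > 0

    def test_bsa_monotone_under_separation(self):
        # two overlapping probe spheres pulled apart along their axis
        prev = np.inf
        for d in [2.0, 3.0, 4.5, 6.0, 10.0]:
            m = make_sphere_system([[0, 0, 0], [d, 0, 0]], [1.9, 1.9])
            model = StructureModel(
                id="x",
                chains={"A": [m.chains["A"][0]], "B": [m.chains["A"][1]]},
            )
            bsa = buried_surface_area(model, ["A"], ["B"]).bsa_total
            assert bsa <= prev + 1e-9
            prev = bsa

    def test_overlapping_partner_sets_rejected(self, dimer12):
        with pytest.raises(ValueError):
            buried_surface_area(dimer12, ["A", "B"], ["B"])
        with pytest.raises(ValueError):
            buried_surface_area(dimer12, [], ["A"])


class TestContacts:
    def _pair_model(self, d):
        return StructureModel(
            id="x",
            chains={
                "A": [ResidueRecord(1, "ALA", [AtomRecord("CA", "C", [0, 0, 0])])],
                "B": [ResidueRecord(1, "GLY", [AtomRecord("CA", "C", [d, 0, 0])])],
            },
        )

    def test_cutoff_is_strict(self):
        assert len(contact_residues(self._pair_model(4.9), ["A"], ["B"])) == 1
        assert contact_residues(self._pair_model(5.1), ["A"], ["B"]) == []

    def test_contact_lists_min_distance(self, dimer12):
        contacts = contact_residues(dimer12, ["X"], ["A", "B"])
        assert contacts
        assert all(c.min_distance < 5.0 for c in contacts)
        assert {c.chain_b for c in contacts} == {"A"}  # binder touches α only

    def test_sse_attribution_uses_registry(self, registry):
        # place the binder against the longitudinal face and annotate
        model = make_bent_dimer(12.0, with_binder=True,
                                binder_site="longitudinal")
        from bendkit.conformation import analyze_model

        ann, _, _ = analyze_model(model, registry)
        contacts = contact_residues(model, ["X"], ["A", "B"], annotated=ann)
        named = {c.sse_b for c in contacts if c.sse_b}
        # every attribution must name a genuine registry element
        valid = {el.name for el in registry.elements if el.subunit == "alpha"}
        assert named <= valid


class TestLatticeGraft:
    def test_longitudinal_binder_clashes_on_interior_subunit(
        self, registry, lattice3_analyzed
    ):
        from bendkit.conformation import analyze_model

        complex_model = make_bent_dimer(18.2, with_binder=True,
                                        binder_site="longitudinal")
        ann, pairs, _ = analyze_model(complex_model, registry)
        lat_ann, _, _ = lattice3_analyzed
        rep = lattice_graft_clash(ann, "X", "A", lat_ann, "C")
        assert rep.clash_count > 0

    def test_outward_binder_clashes_nowhere(self, registry, lattice3_analyzed,
                                            dimer12_analyzed):
        ann, pairs, _ = dimer12_analyzed  # lateral binder points away
        lat_ann, _, _ = lattice3_analyzed
        rep = lattice_graft_clash(ann, "X", "A", lat_ann, "C")
        assert rep.clash_count == 0

    def test_constructed_single_clash(self, registry, lattice3_analyzed):
        from bendkit.conformation import analyze_model

        lat_ann, _, _ = lattice3_analyzed
        complex_model = make_bent_dimer(0.0, with_binder=False)
        # one-atom "binder" placed 1.0 Å from the most isolated lattice atom,
        # pointing away from that atom's nearest neighbour, so exactly one
        # heavy-atom pair falls under the 2.2 Å cutoff.  The complex α frame
        # coincides with lattice chain A for a 0° dimer, so the graft
        # transform is the identity and the construction survives it.
        from bendkit.model import select_atoms
        from scipy.spatial import cKDTree

        lattice_coords, _ = select_atoms(lat_ann.model, heavy_only=True)
        dists, idx = cKDTree(lattice_coords).query(lattice_coords, k=2)
        anchor_i = int(np.argmax(dists[:, 1]))
        anchor = lattice_coords[anchor_i]
        neighbour = lattice_coords[idx[anchor_i, 1]]
        away = (anchor - neighbour) / np.linalg.norm(anchor - neighbour)
        probe = anchor + 1.0 * away
        gaps = np.sort(np.linalg.norm(lattice_coords - probe, axis=1))
        assert gaps[0] == pytest.approx(1.0) and gaps[1] > 2.2  # one pair only
        complex_model.chains["X"] = [
            ResidueRecord(1, "ALA", [AtomRecord("CA", "C", probe)])
        ]
        ann, _, _ = analyze_model(complex_model, registry)
        rep = lattice_graft_clash(ann, "X", "A", lat_ann, "A",
                                  clash_cutoff=2.2)
        assert rep.clash_count == 1

    def test_missing_target_chain_rejected(self, dimer12_analyzed,
                                           lattice3_analyzed):
        ann, _, _ = dimer12_analyzed
        lat_ann, _, _ = lattice3_analyzed
        with pytest.raises(ValueError):
            lattice_graft_clash(ann, "X", "A", lat_ann, "Z")
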