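import math

import numpy as np
import pytest

from hbosprof.constants import ATOMIC_MASS
from hbosprof.features import (
    BlockTable,
    FeatureRecord,
    GeometryError,
    backbone_torsions,
    block_distance,
    chi1,
    compute_features,
    dihedral_angle,
    read_feature_tsv,
    sidechain_distance,
    write_feature_tsv,
)
from hbosprof.structure_io import Atom, Chain, Residue
from hbosprof.synthetic import PeptideSpec, build_peptide


def oracle_dihedral(p1, p2, p3, p4):
    """Independent torsion computation: project bond vectors off the axis."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b = b / np.linalg.norm(b)
    u = (p1 - p2) - np.dot(p1 - p2, b) * b
    w = (p4 - p3) - np.dot(p4 - p3, b) * b
    angle = math.degrees(math.atan2(np.dot(np.cross(b, u), w), np.dot(u, w)))
    return angle % 360.0


class TestDihedral:
    def test_trans_is_180(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_cis_is_0(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_matches_independent_oracle_on_random_quadruples(self, rng):
        for _ in range(2000):
            pts = rng.uniform(-5, 5, size=(4, 3))
            try:
                mine = dihedral_angle(*pts)
            except GeometryError:
                continue
            ref = oracle_dihedral(*pts)
            assert mine == pytest.approx(ref, abs=1e-6)
            assert 0.0 <= mine < 360.0

    def test_collinear_raises(self):
        with pytest.raises(GeometryError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBackboneTorsions:
    @pytest.mark.parametrize("phi,psi", [(303.0, 313.0), (240.0, 135.0), (65.0, 42.0)])
    def test_build_then_measure_roundtrip(self, phi, psi):
        model = build_peptide(PeptideSpec(["LEU"] * 8, phi=phi, psi=psi))
        torsions = backbone_torsions(model.chains[0])
        for i, (got_phi, got_psi) in enumerate(torsions):
            if i > 0:
                assert got_phi == pytest.approx(phi, abs=1e-6)
            if i < len(torsions) - 1:
                assert got_psi == pytest.approx(psi, abs=1e-6)

    def test_chain_termini_are_unavailable(self, tripeptide):
        torsions = backbone_torsions(tripeptide.chains[0])
        assert torsions[0][0] is None  # first residue: no phi
        assert torsions[-1][1] is None  # last residue: no psi

    def test_missing_successor_n_makes_psi_unavailable(self):
        model = build_peptide(PeptideSpec(["LEU"] * 4))
        chain = model.chains[0]
        del chain.residues[2].atoms["N"]
        torsions = backbone_torsions(chain)
        assert torsions[1][1] is None

    def test_chain_break_suppresses_crossing_torsions(self):
        model = build_peptide(PeptideSpec(["LEU"] * 6))
        chain = model.chains[0]
        # translate the second half far away: C(2)-N(3) >> 2.5 A
        for res in chain.residues[3:]:
            res.atoms = {
                name: Atom(a.x + 50.0, a.y, a.z, a.occupancy, a.element, a.altloc)
                for name, a in res.atoms.items()
            }
        torsions = backbone_torsions(chain)
        assert torsions[2][1] is None and torsions[3][0] is None
        assert torsions[1][1] is not None and torsions[4][0] is not None


class TestChi1:
    def test_gly_and_ala_are_a_caller_error(self):
        for res_type in ("GLY", "ALA"):
            with pytest.raises(ValueError):
                chi1(Residue(res_type=res_type, seq_id=1))

    @pytest.mark.parametrize(
        "res_type,target", [("LEU", 300.0), ("SER", 60.0), ("THR", 185.0), ("VAL", 175.0)]
    )
    def test_build_then_measure_roundtrip(self, res_type, target):
        model = build_peptide(PeptideSpec(["GLY", res_type, "GLY"], chi1=target))
        assert chi1(model.chains[0].residues[1]) == pytest.approx(target, abs=1e-6)

    def test_missing_fourth_atom_is_unavailable(self):
        model = build_peptide(PeptideSpec(["GLY", "LEU", "GLY"]))
        res = model.chains[0].residues[1]
        del res.atoms["CG"]
        assert chi1(res) is None


def _residue(res_type, atoms):
    res = Residue(res_type=res_type, seq_id=1)
    for name, (x, y, z) in atoms.items():
        res.atoms[name] = Atom(x, y, z, 1.0, name[0], "")
    return res


class TestCentroidDistances:
    def test_hand_computed_mass_weighted_centroid(self):
        """SER with CB at (1,0,0), OG at origin, CA at (2,0,0)."""
        res = _residue("SER", {"CA": (2, 0, 0), "CB": (1, 0, 0), "OG": (0, 0, 0)})
        m_c, m_o = ATOMIC_MASS["C"], ATOMIC_MASS["O"]
        expected = 2.0 - m_c / (m_c + m_o)  # centroid x = m_c*1/(m_c+m_o)
        assert sidechain_distance(res) == pytest.approx(expected, abs=1e-9)

    def test_single_sidechain_atom_equals_ca_atom_distance(self):
        res = _residue("SER", {"CA": (0, 0, 0), "OG": (1.0, 2.0, 2.0)})
        assert sidechain_distance(res) == pytest.approx(3.0)

    def test_no_sidechain_atoms_is_unavailable(self):
        res = _residue("SER", {"CA": (0, 0, 0), "N": (1, 0, 0)})
        assert sidechain_distance(res) is None

    def test_cys_block_is_ca_sg_distance(self):
        res = _residue("CYS", {"CA": (0, 0, 0), "CB": (1, 0, 0), "SG": (0, 3, 4)})
        assert block_distance(res) == pytest.approx(5.0)

    def test_leu_block_uses_cg_cd1_cd2_only(self):
        model = build_peptide(PeptideSpec(["GLY", "LEU", "GLY"]))
        res = model.chains[0].residues[1]
        names = BlockTable.default()["LEU"]
        assert names == frozenset({"CG", "CD1", "CD2"})
        ca = res.pos("CA")
        masses = np.array([ATOMIC_MASS[n[0]] for n in sorted(names)])
        pts = np.array([res.pos(n) for n in sorted(names)])
        centroid = (masses[:, None] * pts).sum(axis=0) / masses.sum()
        assert block_distance(res) == pytest.approx(float(np.linalg.norm(ca - centroid)))

    def test_all_block_atoms_missing_is_unavailable(self):
        res = _residue("LEU", {"CA": (0, 0, 0), "CB": (1, 0, 0)})
        assert block_distance(res) is None


def _rigid_transform(model, rotation, translation):
    import copy

    moved = copy.deepcopy(model)
    for chain in moved.chains:
        for res in chain.residues:
            res.atoms = {
                name: Atom(*(rotation @ a.pos + translation), a.occupancy, a.element, a.altloc)
                for name, a in res.atoms.items()
            }
    return moved


def test_features_are_rigid_body_invariant(tripeptide, rng):
    """Rotation + translation leaves all five features unchanged."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
    moved = _rigid_transform(tripeptide, rot, np.array([12.0, -7.0, 3.0]))
    before = compute_features(tripeptide.chains[0], "T")
    after = compute_features(moved.chains[0], "T")
    for b, a in zip(before, after):
        for vb, va in zip(b.values(), a.values()):
            if vb is None:
                assert va is None
            else:
                assert va == pytest.approx(vb, abs=1e-9)


class TestComputeFeatures:
    def test_tripeptide_excludes_gly(self, tripeptide):
        records = compute_features(tripeptide.chains[0], "TRIP")
        assert [r.res_type for r in records] == ["LEU", "SER"]
        leu = records[0]
        assert leu.complete  # interior LEU has all five features

    def test_all_gly_chain_yields_no_records(self):
        model = build_peptide(PeptideSpec(["GLY"] * 5))
        assert compute_features(model.chains[0], "G") == []

    def test_terminal_residue_has_unavailable_psi(self):
        model = build_peptide(PeptideSpec(["GLY", "GLY", "LEU"]))
        records = compute_features(model.chains[0], "T")
        assert records[0].psi is None and "psi" in records[0].missing

    def test_angle_ranges_and_positive_distances(self, helix):
        for rec in compute_features(helix.chains[0], "H"):
            for name, value in zip(("phi", "psi", "chi1"), rec.values()[:3]):
                if value is not None:
                    assert 0.0 <= value < 360.0
            for value in rec.values()[3:]:
                if value is not None:
                    assert value > 0.0


def test_feature_tsv_roundtrip(tmp_path, tripeptide):
    records = compute_features(tripeptide.chains[0], "TRIP")
    path = tmp_path / "features.tsv"
    write_feature_tsv(records, path)
    back = read_feature_tsv(path)
    assert back == records


def test_block_table_config_roundtrip(tmp_path):
    path = tmp_path / "blocks.txt"
    path.write_text("# comment\nLEU CG CD1 CD2\nSER OG\n")
    table = BlockTable.from_file(path)
    assert table == {"LEU": frozenset({"CG", "CD1", "CD2"}), "SER": frozenset({"OG"})}
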