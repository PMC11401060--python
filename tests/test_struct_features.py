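import numpy as np
import pytest
from scipy.stats import spearmanr

from mutstruct.core_io import Atom, ProteinRecord
from mutstruct.fixtures import build_ideal_helix
from mutstruct.struct_features import (
    PROBE_RADIUS,
    assign_secondary_structure,
    compute_depth_all,
    compute_rsa,
    compute_rsa_all,
    compute_torsions,
    max_asa_table,
    surface_point_cloud,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately separate implementations)
# ---------------------------------------------------------------------------

_ORACLE_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def _sphere_points(n):
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def oracle_sasa(record: ProteinRecord, n=960) -> dict[int, float]:
    """High-density sphere-sampling SASA, implemented from scratch."""
    coords = record.coords()
    radii = np.array([_ORACLE_VDW.get(a.element, 1.7) for a in record.atoms]) + PROBE_RADIUS
    unit = _sphere_points(n)
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        free = np.ones(n, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) > radii[i] + radii[j]:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * free.sum() / n
    out: dict[int, float] = {}
    for idx in record.residue_indices():
        mask = np.array([a.res_index == idx for a in record.atoms])
        out[idx] = float(per_atom[mask].sum())
    return out


def oracle_kabsch_sander(record: ProteinRecord) -> dict[int, str]:
    """Reference 3-state assignment from backbone hydrogen-bond energies."""
    idx = record.residue_indices()
    bb = {}
    for i in idx:
        atoms = {a.name: a.coord for a in record.residue_atoms(i)}
        bb[i] = atoms
    names = {i: record.residue_atoms(i)[0].res_name for i in idx}

    def energy(acc, don):
        if names[don] == "PRO" or don - 1 not in bb:
            return 0.0
        co = bb[don - 1]["C"] - bb[don - 1]["O"]
        h = bb[don]["N"] + co / np.linalg.norm(co)
        o, c, n = bb[acc]["O"], bb[acc]["C"], bb[don]["N"]
        q = 0.084 * 332.0
        return q * (
            1 / np.linalg.norm(o - n)
            + 1 / np.linalg.norm(c - h)
            - 1 / np.linalg.norm(o - h)
            - 1 / np.linalg.norm(c - n)
        )

    bonds = {
        (i, j)
        for i in idx
        for j in idx
        if abs(i - j) >= 2 and energy(i, j) < -0.5
    }
    ss = {i: "C" for i in idx}
    for n in (4, 3, 5):
        for i in idx:
            if (i - 1, i - 1 + n) in bonds and (i, i + n) in bonds:
                for k in range(i, i + n):
                    if k in ss:
                        ss[k] = "H"
    for i in idx:
        for j in idx:
            if j <= i + 2:
                continue
            para = ((i - 1, j) in bonds and (j, i + 1) in bonds) or (
                (j - 1, i) in bonds and (i, j + 1) in bonds
            )
            anti = ((i, j) in bonds and (j, i) in bonds) or (
                (i - 1, j + 1) in bonds and (j - 1, i + 1) in bonds
            )
            if para or anti:
                for k in (i, j):
                    if ss[k] == "C":
                        ss[k] = "E"
    return ss


def _single_residue(letter="A"):
    rec = build_ideal_helix(letter * 4, protein_id="ONE")
    atoms = [a for a in rec.atoms if a.res_index == 1]
    return ProteinRecord("ONE", letter, atoms, np.array([90.0]))


def _shelled_residue():
    """An ALA residue fully enclosed in a dense shell of occluding atoms."""
    core = _single_residue()
    center = core.coords().mean(axis=0)
    shell_pts = np.vstack(
        [center + 5.0 * _sphere_points(800), center + 7.0 * _sphere_points(1200)]
    )
    shell = [
        Atom(f"X{i}", "O", 2, "GLY", *p) for i, p in enumerate(shell_pts)
    ]
    return ProteinRecord("SHL", "AG", core.atoms + shell, np.array([90.0, 90.0]))


# ---------------------------------------------------------------------------
# RSA
# ---------------------------------------------------------------------------

class TestRSA:
    def test_fully_enclosed_is_zero(self):
        rec = _shelled_residue()
        assert compute_rsa(rec, 1, n_points=200) == pytest.approx(0.0, abs=1e-9)

    def test_isolated_residue_high(self):
        rec = _single_residue()
        rsa = compute_rsa(rec, 1, n_points=960)
        assert rsa >= 0.9
        # oracle agreement on the same record
        oracle = oracle_sasa(rec)[1] / max_asa_table()["A"]
        assert rsa == pytest.approx(oracle, rel=0.05)

    def test_buried_below_exposed_in_bundle(self, bundle):
        rsa = compute_rsa_all(bundle, n_points=200)
        oracle = oracle_sasa(bundle)
        max_asa = max_asa_table()
        oracle_rsa = {i: oracle[i] / max_asa[bundle.sequence[i - 1]] for i in oracle}
        interior = [i for i in range(3, 13)] + [i for i in range(17, 27)]
        buried = min(interior, key=lambda i: oracle_rsa[i])
        exposed = max(interior, key=lambda i: oracle_rsa[i])
        assert rsa[buried] < rsa[exposed]

    def test_monotone_under_occluder_removal(self, bundle):
        # stripping the partner helix never decreases RSA of the first
        n_a = 14
        atoms_a = [a for a in bundle.atoms if a.res_index <= n_a]
        alone = ProteinRecord(
            "HALF", bundle.sequence[:n_a], atoms_a, bundle.plddt[:n_a]
        )
        before = compute_rsa_all(bundle, n_points=200)
        after = compute_rsa_all(alone, n_points=200)
        for i in range(1, n_a + 1):
            assert after[i] >= before[i] - 1e-9


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

class TestDepth:
    def test_surface_atom_depth_near_zero(self):
        rec = _single_residue()
        depths = compute_depth_all(rec, n_points=200)
        assert depths[1] <= PROBE_RADIUS + 0.5

    def test_center_of_sphere_cluster(self):
        # dense ball of radius 6: the central atom's depth ~ cluster radius
        grid = np.arange(-6, 6.1, 1.5)
        pts = np.array(
            [[x, y, z] for x in grid for y in grid for z in grid if x * x + y * y + z * z <= 36]
        )
        order = np.argsort(np.linalg.norm(pts, axis=1))
        pts = pts[order]  # first atom is the center
        atoms = [Atom("CA", "C", 1, "ALA", *pts[0])] + [
            Atom("O", "O", 2, "GLY", *p) for p in pts[1:]
        ]
        rec = ProteinRecord("BALL", "AG", atoms, np.array([90.0, 90.0]))
        depths = compute_depth_all(rec, n_points=100)
        assert depths[1] == pytest.approx(6.0, abs=1.5)
        # brute-force oracle: distance from center to the exposed point cloud
        cloud = surface_point_cloud(rec, n_points=100)
        oracle = max(0.0, np.linalg.norm(cloud - pts[0], axis=1).min() - PROBE_RADIUS - 1.7)
        assert depths[1] == pytest.approx(oracle, abs=1e-9)

    def test_tiny_peptide_all_shallow(self, helix):
        atoms = [a for a in helix.atoms if a.res_index <= 2]
        rec = ProteinRecord("DI", helix.sequence[:2], atoms, helix.plddt[:2])
        depths = compute_depth_all(rec, n_points=200)
        assert all(d < 3.0 for d in depths.values())

    def test_degenerate_structure_error(self):
        atoms = [Atom("CA", "C", 1, "ALA", 0, 0, 0)]
        rec = ProteinRecord("X", "A", atoms, np.array([90.0]))
        with pytest.raises(ValueError, match="degenerate"):
            compute_depth_all(rec)

    def test_depth_rsa_anticorrelate(self, bundle):
        rsa = compute_rsa_all(bundle, n_points=200)
        depth = compute_depth_all(bundle, n_points=60)
        idx = sorted(rsa)
        rho = spearmanr([rsa[i] for i in idx], [depth[i] for i in idx]).statistic
        assert rho < 0


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

class TestSecondaryStructure:
    def test_helix_interior_is_H(self, helix):
        ss = assign_secondary_structure(helix)
        assert all(ss[i] == "H" for i in range(3, 28))

    def test_matches_reference_on_helix(self, helix):
        assert assign_secondary_structure(helix) == oracle_kabsch_sander(helix)

    def test_extended_has_no_H(self, extended):
        ss = assign_secondary_structure(extended)
        assert "H" not in ss.values()
        assert ss == oracle_kabsch_sander(extended)

    def test_three_residue_peptide_all_C(self, helix):
        atoms = [a for a in helix.atoms if a.res_index <= 3]
        rec = ProteinRecord("TRI", helix.sequence[:3], atoms, helix.plddt[:3])
        assert set(assign_secondary_structure(rec).values()) == {"C"}

    def test_missing_backbone_forced_C(self, helix):
        atoms = [a for a in helix.atoms if not (a.res_index == 10 and a.name == "O")]
        rec = ProteinRecord("DEL", helix.sequence, atoms, helix.plddt)
        with pytest.warns(UserWarning, match="missing backbone"):
            ss = assign_secondary_structure(rec)
        assert ss[10] == "C"


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

class TestTorsions:
    def test_helix_angles(self, helix):
        for i in (5, 10, 15):
            phi, psi = compute_torsions(helix, i)
            assert phi == pytest.approx(-57.0, abs=1.0)
            assert psi == pytest.approx(-47.0, abs=1.0)

    def test_first_residue_phi_undefined(self, helix):
        phi, psi = compute_torsions(helix, 1)
        assert phi is None and psi is not None

    def test_last_residue_psi_undefined(self, helix):
        phi, psi = compute_torsions(helix, helix.length)
        assert psi is None and phi is not None

    def test_extended_phi(self, extended):
        phi, _ = compute_torsions(extended, 10)
        assert abs(phi) == pytest.approx(180.0, abs=1.0)

    def test_chain_break_undefined(self, bundle):
        with pytest.warns(UserWarning, match="chain break"):
            _, psi = compute_torsions(bundle, 14)
        assert psi is None
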