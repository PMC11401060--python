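"""Structure-derived per-residue descriptors.

* relative solvent accessibility (Shrake-Rupley sampling, probe 1.4 A,
  normalized by a bundled theoretical max-ASA table);
* residue depth (mean distance of residue atoms to a solvent-exposed
  probe-position point cloud);
* three-state secondary structure from backbone hydrogen-bond energies
  (Kabsch-Sander criterion, helix/strand classes collapsed to H/E,
  everything else C);
* backbone phi/psi torsions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .core_io import ProteinRecord
from .geometry import dihedral

__all__ = [
    "StructuralDescriptors",
    "PROBE_RADIUS",
    "max_asa_table",
    "compute_sasa",
    "compute_rsa",
    "compute_rsa_all",
    "compute_depth",
    "compute_depth_all",
    "assign_secondary_structure",
    "compute_torsions",
    "compute_descriptors",
]

PROBE_RADIUS = 1.4
CHAIN_BREAK_CA_CA = 4.5

# van der Waals radii by element (A); fallback 1.7
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


@dataclass
class StructuralDescriptors:
    rsa: float
    depth: float
    ss: str  # one of H, E, C
    phi: float | None
    psi: float | None
    plddt: float


def max_asa_table() -> dict[str, float]:
    text = resources.files("mutstruct.data").joinpath("max_asa.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        aa, val = line.split("\t")
        table[aa] = float(val)
    return table


def _radii(protein: ProteinRecord) -> np.ndarray:
    return np.array([_VDW.get(a.element, 1.70) for a in protein.atoms])


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley via Biopython)
# ---------------------------------------------------------------------------

def _as_biopdb(protein: ProteinRecord):
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure(protein.protein_id)
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg(" ")
    current = None
    serial = 1
    for atom in protein.atoms:
        if atom.res_index != current:
            sb.init_residue(atom.res_name, " ", atom.res_index, " ")
            current = atom.res_index
        sb.init_atom(
            atom.name,
            np.array([atom.x, atom.y, atom.z]),
            0.0,
            1.0,
            " ",
            f" {atom.name:<3s}"[:4],
            serial,
            element=atom.element,
        )
        serial += 1
    return sb.get_structure()


def compute_sasa(protein: ProteinRecord, n_points: int = 200) -> dict[int, float]:
    """Per-residue solvent-accessible surface area (A^2)."""
    from Bio.PDB.SASA import ShrakeRupley

    structure = _as_biopdb(protein)
    ShrakeRupley(probe_radius=PROBE_RADIUS, n_points=n_points).compute(
        structure, level="R"
    )
    out: dict[int, float] = {}
    for res in structure.get_residues():
        out[res.id[1]] = float(res.sasa)
    return out


def compute_rsa_all(protein: ProteinRecord, n_points: int = 200) -> dict[int, float]:
    """Relative solvent accessibility for every modeled residue."""
    sasa = compute_sasa(protein, n_points=n_points)
    max_asa = max_asa_table()
    seq = protein.sequence
    return {i: sasa[i] / max_asa[seq[i - 1]] for i in sasa}


def compute_rsa(protein: ProteinRecord, position: int, n_points: int = 200) -> float:
    """RSA of one residue: residue ASA / residue-type theoretical max ASA."""
    res_atoms = protein.residue_atoms(position)
    if not res_atoms:
        raise ValueError(f"no atoms at position {position}")
    heavy_sidechain = [a for a in res_atoms if a.name not in ("N", "CA", "C", "O")]
    res3 = res_atoms[0].res_name
    if res3 != "GLY" and not heavy_sidechain:
        warnings.warn(
            f"{protein.protein_id} position {position}: backbone-only {res3}; "
            "RSA computed from backbone atoms"
        )
    return compute_rsa_all(protein, n_points=n_points)[position]


# ---------------------------------------------------------------------------
# Residue depth
# ---------------------------------------------------------------------------

def surface_point_cloud(protein: ProteinRecord, n_points: int = 80) -> np.ndarray:
    """Solvent-exposed probe positions approximating the accessible surface.

    Sphere points (golden-spiral) are placed at radius vdw + probe around
    every atom; points falling inside any other atom's expanded sphere are
    discarded.
    """
    coords = protein.coords()
    if len(coords) < 4:
        raise ValueError("degenerate structure: fewer than 4 atoms")
    radii = _radii(protein) + PROBE_RADIUS
    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    kept: list[np.ndarray] = []
    for i, (center, r) in enumerate(zip(coords, radii)):
        pts = center + r * sphere
        neighbors = tree.query_ball_point(center, r + max_r)
        others = [j for j in neighbors if j != i]
        if others:
            oc = coords[others]
            orad = radii[others]
            d2 = ((pts[:, None, :] - oc[None, :, :]) ** 2).sum(axis=2)
            exposed = (d2 >= (orad**2)[None, :] - 1e-9).all(axis=1)
            pts = pts[exposed]
        if len(pts):
            kept.append(pts)
    if not kept:
        raise ValueError("no solvent-exposed surface points found")
    return np.vstack(kept)


def _golden_spiral(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_depth_all(protein: ProteinRecord, n_points: int = 80) -> dict[int, float]:
    """Residue depth (A) for every modeled residue.

    Atom depth is the distance from the atom's van der Waals surface to
    the nearest exposed probe position (clamped at zero); residue depth is
    the mean over the residue's atoms. Surface atoms score ~0.
    """
    cloud = surface_point_cloud(protein, n_points=n_points)
    tree = cKDTree(cloud)
    coords = protein.coords()
    radii = _radii(protein)
    dist, _ = tree.query(coords)
    atom_depth = np.maximum(0.0, dist - PROBE_RADIUS - radii)
    out: dict[int, float] = {}
    for idx in protein.residue_indices():
        mask = np.array([a.res_index == idx for a in protein.atoms])
        out[idx] = float(atom_depth[mask].mean())
    return out


def compute_depth(protein: ProteinRecord, position: int, n_points: int = 80) -> float:
    return compute_depth_all(protein, n_points=n_points)[position]


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander hydrogen-bond criterion)
# ---------------------------------------------------------------------------

_HB_Q1Q2_F = 0.084 * 332.0  # electrostatic H-bond energy prefactor (kcal/mol * A)
_HB_CUTOFF = -0.5


def _backbone_maps(protein: ProteinRecord):
    indices = protein.residue_indices()
    bb: dict[int, dict[str, np.ndarray]] = {}
    incomplete: list[int] = []
    for i in indices:
        atoms = {a.name: a.coord for a in protein.residue_atoms(i)}
        if all(k in atoms for k in ("N", "CA", "C", "O")):
            bb[i] = atoms
        else:
            incomplete.append(i)
    return indices, bb, incomplete


def _hbond_energy(bb: dict[int, dict[str, np.ndarray]], donor: int, acceptor: int,
                  res_names: dict[int, str]) -> float:
    """Kabsch-Sander energy of the NH(donor) -> CO(acceptor) hydrogen bond."""
    if res_names.get(donor) == "PRO":
        return 0.0  # proline has no amide hydrogen
    if donor - 1 not in bb:  # H position needs the preceding carbonyl
        return 0.0
    n = bb[donor]["N"]
    prev = bb[donor - 1]
    co = prev["C"] - prev["O"]
    h = n + co / np.linalg.norm(co)
    c = bb[acceptor]["C"]
    o = bb[acceptor]["O"]
    d_on = np.linalg.norm(o - n)
    d_ch = np.linalg.norm(c - h)
    d_oh = np.linalg.norm(o - h)
    d_cn = np.linalg.norm(c - n)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:
        return -9.9  # atoms essentially on top of each other
    return _HB_Q1Q2_F * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)


def assign_secondary_structure(protein: ProteinRecord) -> dict[int, str]:
    """Three-state secondary structure per residue.

    Backbone i->i+3/4/5 hydrogen-bond turns give helices (8-state H/G/I
    collapse to H); hydrogen-bonded parallel/antiparallel bridges give
    strands (E/B collapse to E); everything else is C. Residues with an
    incomplete backbone are forced to C with a warning.
    """
    indices, bb, incomplete = _backbone_maps(protein)
    if incomplete:
        warnings.warn(
            f"{protein.protein_id}: residues {incomplete} missing backbone atoms; forced to C"
        )
    res_names = {
        i: protein.residue_atoms(i)[0].res_name for i in indices
    }
    present = sorted(bb)
    hbond: set[tuple[int, int]] = set()  # (acceptor CO, donor NH)
    ca = {i: bb[i]["CA"] for i in present}
    for i in present:  # acceptor
        for j in present:  # donor
            if abs(i - j) < 2:
                continue
            if np.linalg.norm(ca[i] - ca[j]) > 9.0:
                continue
            if _hbond_energy(bb, j, i, res_names) < _HB_CUTOFF:
                hbond.add((i, j))

    def turn(i: int, n: int) -> bool:
        return (i, i + n) in hbond

    ss = {i: "C" for i in indices}
    # helices: n-turn at i-1 and i starts an n-helix at residue i
    for n in (4, 3, 5):
        for i in present:
            if turn(i - 1, n) and turn(i, n):
                for k in range(i, i + n):
                    if k in ss and k in bb:
                        ss[k] = "H"
    # bridges
    for i in present:
        for j in present:
            if j <= i + 2:
                continue
            para = ((i - 1, j) in hbond and (j, i + 1) in hbond) or (
                (j - 1, i) in hbond and (i, j + 1) in hbond
            )
            anti = ((i, j) in hbond and (j, i) in hbond) or (
                (i - 1, j + 1) in hbond and (j - 1, i + 1) in hbond
            )
            if para or anti:
                for k in (i, j):
                    if ss.get(k) == "C":
                        ss[k] = "E"
    return ss


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def compute_torsions(
    protein: ProteinRecord, position: int
) -> tuple[float | None, float | None]:
    """(phi, psi) in degrees; ``None`` where undefined (termini, breaks)."""
    indices, bb, _ = _backbone_maps(protein)

    def _ca_link(i: int, j: int) -> bool:
        if i not in bb or j not in bb:
            return False
        d = np.linalg.norm(bb[i]["CA"] - bb[j]["CA"])
        if d > CHAIN_BREAK_CA_CA:
            warnings.warn(
                f"{protein.protein_id}: chain break between {i} and {j} (CA-CA {d:.1f} A)"
            )
            return False
        return True

    phi = psi = None
    if position in bb:
        if _ca_link(position - 1, position):
            prev = bb[position - 1]
            cur = bb[position]
            phi = dihedral(prev["C"], cur["N"], cur["CA"], cur["C"])
        if _ca_link(position, position + 1):
            cur = bb[position]
            nxt = bb[position + 1]
            psi = dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
    return phi, psi


def compute_descriptors(
    protein: ProteinRecord, position: int, sasa_points: int = 200, depth_points: int = 80
) -> StructuralDescriptors:
    """All structural descriptors for one residue."""
    rsa = compute_rsa_all(protein, n_points=sasa_points)[position]
    depth = compute_depth_all(protein, n_points=depth_points)[position]
    ss = assign_secondary_structure(protein)[position]
    phi, psi = compute_torsions(protein, position)
    indices = protein.residue_indices()
    plddt = float(protein.plddt[indices.index(position)])
    return StructuralDescriptors(rsa, depth, ss, phi, psi, plddt)
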