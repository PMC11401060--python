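"""Synthetic data generation: toy structures, planted-signal mutation
datasets, and matching provider score tables.

Everything downstream (features, models, evaluation, saturation) is
testable against these fixtures without any external download. Structures
are built from idealized backbone geometry with requested phi/psi
torsions; datasets carry a planted labeling rule whose signal downstream
feature generation can recover.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (
    AA1,
    LABEL_DISEASE,
    LABEL_NEUTRAL,
    Atom,
    MutationRecord,
    ONE_TO_THREE,
    ProteinRecord,
    write_pdb,
)
from .geometry import place_atom
from .residues import build_sidechain, element_of
from .seq_features import FIVE_GROUP_SCHEME

__all__ = [
    "SynthConfig",
    "build_ideal_helix",
    "build_extended_chain",
    "build_two_helix_bundle",
    "synth_dataset",
    "synth_provider_tables",
    "write_toy_project",
]

# Engh-Huber-style idealized backbone parameters
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8


def _build_backbone(
    n_res: int, phi: float, psi: float, omega: float = 180.0
) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with uniform torsions."""
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("phi/psi must be finite")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_next = place_atom(prev["CA"], prev["C"], n_next, _B_N_CA, _A_C_N_CA, omega)
        c_next = place_atom(prev["C"], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens: trans to the next residue's N (torsion psi + 180)
    for i, r in enumerate(res):
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _assemble(
    protein_id: str,
    sequence: str,
    backbone: list[dict[str, np.ndarray]],
    bfactor: float | np.ndarray,
    start_index: int = 1,
    validate: bool = True,
) -> ProteinRecord:
    atoms: list[Atom] = []
    for i, (letter, bb) in enumerate(zip(sequence, backbone)):
        res3 = ONE_TO_THREE[letter]
        idx = start_index + i
        for name in ("N", "CA", "C", "O"):
            x, y, z = bb[name]
            atoms.append(Atom(name, element_of(name), idx, res3, x, y, z))
        for name, coord in build_sidechain(res3, bb["N"], bb["CA"], bb["C"]):
            atoms.append(Atom(name, element_of(name), idx, res3, *coord))
    plddt = np.full(len(sequence), bfactor, dtype=float) if np.isscalar(bfactor) else np.asarray(bfactor, float)
    rec = ProteinRecord(protein_id, sequence, atoms, plddt)
    if validate:
        rec.validate()
    return rec


def build_ideal_helix(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    protein_id: str = "HELIX",
    bfactor: float | np.ndarray = 90.0,
) -> ProteinRecord:
    """Build an idealized single-chain model with uniform backbone torsions.

    Defaults produce an alpha-helix; pass ``phi=psi=180`` for a fully
    extended chain. Side chains come from the idealized templates.
    """
    if len(sequence) < 4:
        raise ValueError("sequence must have at least 4 residues")
    backbone = _build_backbone(len(sequence), phi, psi)
    return _assemble(protein_id, sequence, backbone, bfactor)


def build_extended_chain(
    sequence: str, protein_id: str = "EXT", bfactor: float = 90.0
) -> ProteinRecord:
    return build_ideal_helix(sequence, phi=180.0, psi=180.0, protein_id=protein_id, bfactor=bfactor)


def build_two_helix_bundle(
    seq_a: str,
    seq_b: str,
    separation: float = 9.5,
    protein_id: str = "BUNDLE",
    bfactor: float = 90.0,
) -> ProteinRecord:
    """Two antiparallel idealized helices packed ``separation`` Angstrom apart.

    The chains are concatenated into one residue numbering (a chain break
    exists between them); residues facing the partner helix are buried
    relative to solvent-facing residues, which gives burial-sensitive
    descriptors a testable contrast.
    """
    bb_a = _build_backbone(len(seq_a), -57.0, -47.0)
    bb_b = _build_backbone(len(seq_b), -57.0, -47.0)

    def _axis(bb):
        cas = np.array([r["CA"] for r in bb])
        centered = cas - cas.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        return cas.mean(axis=0), vt[0]

    center_a, axis_a = _axis(bb_a)
    # rotate helix B to run antiparallel and translate it sideways
    center_b, axis_b = _axis(bb_b)
    rot = _rotation_between(axis_b, -axis_a)
    side = _any_perpendicular(axis_a)
    offset = center_a + separation * side
    bb_b2 = []
    for r in bb_b:
        bb_b2.append({k: rot @ (v - center_b) + offset for k, v in r.items()})

    rec_a = _assemble(protein_id, seq_a, bb_a, bfactor)
    rec_b = _assemble(protein_id, seq_b, bb_b2, bfactor, start_index=len(seq_a) + 1, validate=False)
    atoms = rec_a.atoms + rec_b.atoms
    plddt = np.concatenate([rec_a.plddt, rec_b.plddt])
    rec = ProteinRecord(protein_id, seq_a + seq_b, atoms, plddt)
    rec.validate()
    return rec


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-10:
        if c > 0:
            return np.eye(3)
        # 180-degree flip about any perpendicular axis
        p = _any_perpendicular(a)
        return 2.0 * np.outer(p, p) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# Planted-signal datasets
# ---------------------------------------------------------------------------

HYDROPHOBIC_FIVE = frozenset(
    a for a in AA1 if FIVE_GROUP_SCHEME.assignment[a] == "hydrophobic"
)


@dataclass
class SynthConfig:
    """Configuration of the synthetic mutation dataset generator.

    The planted rule labels a mutation Disease-causing iff the mutant
    residue is hydrophobic (five-group scheme), then flips each label with
    probability ``noise``; the rule is recoverable downstream through the
    ``hydrophobic_mt`` indicator feature.
    """

    seed: int = 0
    n_proteins: int = 3
    length: int = 40
    n_mutations: int = 40
    noise: float = 0.0
    ddg_effect: float = 1.0  # mean ddG shift (kcal/mol) for the pathogenic class
    inverted_proteins: tuple[str, ...] = ()  # proteins following the opposite rule

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must be in [0, 0.5)")
        if self.length < 12:
            raise ValueError("length must be >= 12")


def synth_dataset(config: SynthConfig):
    """Generate proteins (idealized helices), mutations, and labels.

    Returns ``(proteins, mutations)`` where proteins is a dict keyed by
    protein id. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(AA1))
    proteins: dict[str, ProteinRecord] = {}
    mutations: list[MutationRecord] = []
    for p in range(config.n_proteins):
        pid = f"SYN{p + 1}"
        seq = "".join(rng.choice(letters, size=config.length))
        proteins[pid] = build_ideal_helix(seq, protein_id=pid, bfactor=90.0)
        max_mut = 19 * config.length
        if config.n_mutations > max_mut:
            raise ValueError(f"requested {config.n_mutations} mutations > {max_mut} possible")
        chosen: set[tuple[int, str]] = set()
        while len(chosen) < config.n_mutations:
            pos = int(rng.integers(1, config.length + 1))
            wt = seq[pos - 1]
            mt = str(rng.choice(letters))
            if mt == wt or (pos, mt) in chosen:
                continue
            chosen.add((pos, mt))
            pathogenic = mt in HYDROPHOBIC_FIVE
            if pid in config.inverted_proteins:
                pathogenic = not pathogenic
            if rng.random() < config.noise:
                pathogenic = not pathogenic
            label = LABEL_DISEASE if pathogenic else LABEL_NEUTRAL
            mutations.append(MutationRecord(pid, pos, wt, mt, label))
    return proteins, mutations


def synth_provider_tables(
    mutations: list[MutationRecord], config: SynthConfig
) -> "pd.DataFrame":
    """Fabricate a complete provider score table for ``mutations``.

    ddG for the four stability columns is drawn with the pathogenic-class
    mean shifted negative by ``config.ddg_effect``; bounded scores are
    drawn inside their ranges.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for m in mutations:
        shift = -config.ddg_effect if m.label == LABEL_DISEASE else 0.0
        row = {
            "protein": m.protein_id,
            "position": m.position,
            "wt": m.wt,
            "mt": m.mt,
        }
        for col in ("ddg_mcsm", "ddg_saafecseq", "ddg_ddmut", "ddg_dynamut2"):
            row[col] = round(float(rng.normal(shift, 1.0)), 3)
        row["sift_score"] = round(float(rng.uniform(0.0, 1.0)), 3)
        row["snap2_score"] = round(float(rng.uniform(-100.0, 100.0)), 2)
        row["pssm_score"] = int(rng.integers(-8, 9))
        row["iupred_short"] = round(float(rng.uniform(0.0, 1.0)), 3)
        row["iupred_long"] = round(float(rng.uniform(0.0, 1.0)), 3)
        rows.append(row)
    return pd.DataFrame(rows)


def write_toy_project(out_dir: str | Path, config: SynthConfig | None = None) -> dict:
    """Emit a complete toy project directory: FASTA + PDB per protein,
    mutation CSV, and a provider TSV. Returns the paths written."""
    config = config or SynthConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, mutations = synth_dataset(config)
    paths: dict[str, object] = {"fasta": {}, "pdb": {}}
    for pid, rec in proteins.items():
        fasta = out / f"{pid}.fasta"
        fasta.write_text(f">{pid}\n{rec.sequence}\n")
        pdb = out / f"{pid}.pdb"
        write_pdb(rec, pdb)
        paths["fasta"][pid] = fasta
        paths["pdb"][pid] = pdb
    mut_csv = out / "mutations.csv"
    with open(mut_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein", "position", "wt", "mt", "label"])
        for m in mutations:
            writer.writerow([m.protein_id, m.position, m.wt, m.mt, m.label])
    provider_tsv = out / "providers.tsv"
    synth_provider_tables(mutations, config).to_csv(provider_tsv, sep="\t", index=False)
    paths["mutations"] = mut_csv
    paths["providers"] = provider_tsv
    return paths
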