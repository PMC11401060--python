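"""Reading and validation of sequences, structures, and mutation tables.

Conventions used throughout the package:

* residue numbering is 1-based and equal to the position in the canonical
  sequence (predicted monomer models are assumed renumbered that way);
* only the 20 canonical amino acids are supported;
* the per-residue confidence score (pLDDT, range 0-100) is read from the
  B-factor column of each residue's alpha-carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AA1",
    "AA3",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "LABEL_DISEASE",
    "LABEL_NEUTRAL",
    "LABEL_UNLABELED",
    "Atom",
    "ProteinRecord",
    "MutationRecord",
    "load_protein",
    "read_fasta",
    "read_pdb",
    "write_pdb",
    "parse_mutation_table",
    "check_mutation_maps",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AA3 = tuple(ONE_TO_THREE[a] for a in AA1)

LABEL_DISEASE = "Disease-causing"
LABEL_NEUTRAL = "Neutral"
LABEL_UNLABELED = "Unlabeled"

_LABEL_ALIASES = {
    "disease-causing": LABEL_DISEASE,
    "disease causing": LABEL_DISEASE,
    "disease_causing": LABEL_DISEASE,
    "pathogenic": LABEL_DISEASE,
    "positive": LABEL_DISEASE,
    "1": LABEL_DISEASE,
    "neutral": LABEL_NEUTRAL,
    "benign": LABEL_NEUTRAL,
    "negative": LABEL_NEUTRAL,
    "0": LABEL_NEUTRAL,
    "unlabeled": LABEL_UNLABELED,
    "unknown": LABEL_UNLABELED,
    "": LABEL_UNLABELED,
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_index: int  # 1-based canonical-sequence position
    res_name: str   # three-letter code
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class ProteinRecord:
    """Canonical sequence plus a single-chain monomer model.

    ``plddt`` holds one confidence value per modeled residue, indexed in
    residue order (``plddt[i]`` belongs to residue ``i + 1``).
    """

    protein_id: str
    sequence: str
    atoms: list[Atom] = field(default_factory=list)
    plddt: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-canonical residue letter(s) {sorted(set(bad))!r}"
            )

    # -- residue-level views -------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue_indices(self) -> list[int]:
        seen: list[int] = []
        for atom in self.atoms:
            if not seen or atom.res_index != seen[-1]:
                seen.append(atom.res_index)
        return seen

    def residue_atoms(self, position: int) -> list[Atom]:
        return [a for a in self.atoms if a.res_index == position]

    def atom(self, position: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.res_index == position and a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def validate(self) -> None:
        """Enforce the record invariants; raise ``ValueError`` on violation."""
        idx = self.residue_indices()
        if not idx:
            raise ValueError(f"{self.protein_id}: structure has no atoms")
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError(f"{self.protein_id}: residue indices not contiguous")
        if idx[0] < 1 or idx[-1] > self.length:
            raise ValueError(
                f"{self.protein_id}: residue indices {idx[0]}..{idx[-1]} fall "
                f"outside the canonical sequence (length {self.length})"
            )
        for i in idx:
            res_names = {a.res_name for a in self.residue_atoms(i)}
            if len(res_names) != 1:
                raise ValueError(f"{self.protein_id}: conflicting residue names at {i}")
            (name,) = res_names
            expected = ONE_TO_THREE[self.sequence[i - 1]]
            if name != expected:
                raise ValueError(
                    f"{self.protein_id}: sequence/structure mismatch at index {i}: "
                    f"sequence says {expected}, structure says {name}"
                )
        if len(self.plddt) != len(idx):
            raise ValueError(
                f"{self.protein_id}: {len(self.plddt)} pLDDT values for {len(idx)} residues"
            )


@dataclass(frozen=True)
class MutationRecord:
    """One missense variant on a protein's canonical sequence."""

    protein_id: str
    position: int
    wt: str
    mt: str
    label: str = LABEL_UNLABELED

    def __post_init__(self) -> None:
        if self.wt not in ONE_TO_THREE or self.mt not in ONE_TO_THREE:
            raise ValueError(f"non-canonical residue in {self.key()}")
        if self.wt == self.mt:
            raise ValueError(f"synonymous substitution {self.key()}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in (LABEL_DISEASE, LABEL_NEUTRAL, LABEL_UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")

    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt, self.mt)

    def __str__(self) -> str:  # e.g. "PSEN1 P117L"
        return f"{self.protein_id} {self.wt}{self.position}{self.mt}"


# ---------------------------------------------------------------------------
# FASTA / PDB
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA file; return (identifier, sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def read_pdb(path: str | Path) -> tuple[list[Atom], dict[int, float]]:
    """Parse ATOM records of a single-chain PDB file.

    Returns the atom list and a map residue index -> alpha-carbon B-factor.
    """
    atoms: list[Atom] = []
    ca_bfac: dict[int, float] = {}
    chains: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21]
        res_index = int(line[22:26])
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() or name[0]
        chains.add(chain)
        atoms.append(Atom(name, element, res_index, res_name, x, y, z))
        if name == "CA":
            ca_bfac[res_index] = bfac
    if len(chains) > 1:
        raise ValueError(f"{path}: multi-chain structure (chains {sorted(chains)})")
    return atoms, ca_bfac


def load_protein(fasta_path: str | Path, structure_path: str | Path) -> ProteinRecord:
    """Load one protein from FASTA + single-chain PDB and validate it.

    The per-residue confidence (pLDDT) is taken from the alpha-carbon
    B-factor; a residue without an alpha-carbon is an error.
    """
    protein_id, sequence = read_fasta(fasta_path)
    atoms, ca_bfac = read_pdb(structure_path)
    record = ProteinRecord(protein_id, sequence, atoms, np.zeros(0))
    indices = record.residue_indices()
    missing_ca = [i for i in indices if i not in ca_bfac]
    if missing_ca:
        raise ValueError(f"{structure_path}: residue(s) {missing_ca} missing alpha-carbon")
    record.plddt = np.array([ca_bfac[i] for i in indices])
    record.validate()
    return record


def write_pdb(record: ProteinRecord, path: str | Path, bfactors: dict[int, float] | None = None) -> None:
    """Write the record's atoms as a single-chain PDB file.

    By default the residue pLDDT is written to the B-factor column;
    ``bfactors`` overrides with explicit per-residue values.
    """
    indices = record.residue_indices()
    plddt_map = dict(zip(indices, record.plddt))
    lines = []
    for serial, atom in enumerate(record.atoms, start=1):
        if bfactors is not None:
            b = bfactors.get(atom.res_index, 0.0)
        else:
            b = plddt_map.get(atom.res_index, 0.0)
        lines.append(
            f"ATOM  {serial:5d} {atom.name:^4s}{atom.res_name:>4s} A{atom.res_index:4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.0:6.2f}{b:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

def normalize_label(raw: str) -> str | None:
    return _LABEL_ALIASES.get(raw.strip().lower())


def parse_mutation_table(
    csv_path: str | Path,
) -> tuple[list[MutationRecord], list[tuple[dict, str]]]:
    """Parse a mutation CSV with header ``protein,position,wt,mt,label``.

    Returns (accepted records, rejected rows); each rejected row is paired
    with a human-readable reason. The operation is a pure filter: every
    input row lands in exactly one of the two lists.
    """
    import csv

    accepted: list[MutationRecord] = []
    rejected: list[tuple[dict, str]] = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"protein", "position", "wt", "mt", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{csv_path}: header must contain {sorted(required)}")
        for row in reader:
            protein = (row["protein"] or "").strip()
            wt = (row["wt"] or "").strip().upper()
            mt = (row["mt"] or "").strip().upper()
            try:
                position = int((row["position"] or "").strip())
            except ValueError:
                rejected.append((row, f"malformed position {row['position']!r}"))
                continue
            if not protein:
                rejected.append((row, "missing protein id"))
                continue
            if wt not in ONE_TO_THREE or mt not in ONE_TO_THREE:
                rejected.append((row, f"non-canonical residue {wt!r}->{mt!r}"))
                continue
            if wt == mt:
                rejected.append((row, "synonymous"))
                continue
            if position < 1:
                rejected.append((row, f"malformed position {position}"))
                continue
            label = normalize_label(row["label"] or "")
            if label is None:
                rejected.append((row, f"unrecognized label {row['label']!r}"))
                continue
            accepted.append(MutationRecord(protein, position, wt, mt, label))
    return accepted, rejected


def check_mutation_maps(mutation: MutationRecord, protein: ProteinRecord) -> bool:
    """True iff the mutation's WT residue matches the canonical sequence."""
    if mutation.protein_id != protein.protein_id:
        raise ValueError(
            f"protein id mismatch: mutation {mutation.protein_id}, record {protein.protein_id}"
        )
    if mutation.position > protein.length:
        return False
    return protein.sequence[mutation.position - 1] == mutation.wt
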