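"""Interaction-contact typing at the mutation site and cumulative
pharmacophore graph-based signatures; includes the simplified
mutant-structure builder.

Contact criteria (editable defaults; thresholds in Angstrom):

* hydrogen bond: donor/acceptor heavy atoms <= 3.5 with the angle
  antecedent-donor-acceptor >= 90 degrees;
* polar: donor/acceptor pair <= 4.0;
* weak polar: carbon bearing at least one hydrogen to an acceptor <= 4.0;
* hydrophobic: two Hydrophobic-class atoms <= 4.5;
* aromatic: two ring centroids <= 6.0;
* ionic: opposite Ionizable classes <= 4.0.

Atoms of the site residue itself and of its backbone-bonded neighbors
(|sequence distance| <= 1) never count as contact partners: covalent
geometry is not an interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .core_io import Atom, MutationRecord, ONE_TO_THREE, ProteinRecord, check_mutation_maps
from .residues import build_sidechain, element_of

__all__ = [
    "CLASS_ABBREV",
    "CLASS_ORDER",
    "ContactThresholds",
    "PharmacophoreMap",
    "InteractionProfile",
    "INTERACTION_TYPES",
    "load_pharmacophore_map",
    "build_mutant_model",
    "type_contacts",
    "contact_delta",
    "graph_signature",
    "pharmacophore_change",
    "default_cutoff_grid",
    "signature_feature_names",
]

CLASS_ORDER = (
    "Hydrophobic",
    "Aromatic",
    "PositiveIonizable",
    "NegativeIonizable",
    "HydrogenDonor",
    "HydrogenAcceptor",
    "Sulfur",
    "Neutral",
)
CLASS_ABBREV = {
    "Hydrophobic": "Hyd",
    "Aromatic": "Aro",
    "PositiveIonizable": "Pos",
    "NegativeIonizable": "Neg",
    "HydrogenDonor": "Don",
    "HydrogenAcceptor": "Acc",
    "Sulfur": "Sul",
    "Neutral": "Neu",
}

INTERACTION_TYPES = ("HydrogenBond", "Polar", "WeakPolar", "Hydrophobic", "Aromatic", "Ionic")

# aromatic ring definitions by residue type
_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
}

# carbons without attached hydrogens (never weak-polar donors): backbone
# carbonyl plus side-chain carbonyl/carboxyl/guanidinium/ring-junction carbons
_H_LESS_CARBONS = {
    ("*", "C"),
    ("ASP", "CG"), ("ASN", "CG"), ("GLU", "CD"), ("GLN", "CD"),
    ("ARG", "CZ"), ("PHE", "CG"), ("TYR", "CG"), ("TYR", "CZ"),
    ("HIS", "CG"), ("TRP", "CG"), ("TRP", "CD2"), ("TRP", "CE2"),
}


@dataclass(frozen=True)
class ContactThresholds:
    hydrogen_bond: float = 3.5
    hbond_min_angle: float = 90.0
    polar: float = 4.0
    weak_polar: float = 4.0
    hydrophobic: float = 4.5
    aromatic: float = 6.0
    ionic: float = 4.0


@dataclass(frozen=True)
class PharmacophoreMap:
    """Map from (residue name, atom name) to a set of pharmacophore classes."""

    assignment: dict[tuple[str, str], frozenset[str]]

    def classes(self, res_name: str, atom_name: str) -> frozenset[str]:
        key = (res_name, atom_name)
        if key in self.assignment:
            return self.assignment[key]
        generic = ("*", atom_name)
        if generic in self.assignment:
            return self.assignment[generic]
        return frozenset()


def load_pharmacophore_map(path: str | None = None) -> PharmacophoreMap:
    """Load the pharmacophore table (bundled default or a user TSV)."""
    if path is None:
        text = resources.files("mutstruct.data").joinpath("pharmacophores.tsv").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    assignment: dict[tuple[str, str], frozenset[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("residue\t"):
            continue
        res, atom, classes = line.split("\t")
        cls = frozenset(classes.split(";"))
        unknown = cls - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown pharmacophore class(es) {sorted(unknown)}")
        assignment[(res, atom)] = cls
    return PharmacophoreMap(assignment)


@dataclass
class InteractionProfile:
    counts: dict[str, int] = field(default_factory=lambda: {t: 0 for t in INTERACTION_TYPES})

    def __getitem__(self, t: str) -> int:
        return self.counts[t]


# ---------------------------------------------------------------------------
# Mutant model (idealized side-chain swap)
# ---------------------------------------------------------------------------

def build_mutant_model(
    protein: ProteinRecord,
    mutation: MutationRecord,
    mutant_structure: ProteinRecord | None = None,
) -> ProteinRecord:
    """Approximate mutant structure by an idealized side-chain swap.

    The backbone is untouched; the site side chain is replaced by the
    mutant residue's idealized template aligned on N-CA-C, with no
    refinement. A user-supplied externally modeled ``mutant_structure``
    takes precedence over the approximation.
    """
    if not check_mutation_maps(mutation, protein):
        raise ValueError(f"mutation {mutation} does not map onto {protein.protein_id}")
    if mutant_structure is not None:
        return mutant_structure
    pos = mutation.position
    new_res3 = ONE_TO_THREE[mutation.mt]
    backbone = {a.name: a.coord for a in protein.residue_atoms(pos) if a.name in ("N", "CA", "C", "O")}
    for req in ("N", "CA", "C"):
        if req not in backbone:
            raise ValueError(f"residue {pos} missing backbone atom {req}")
    new_atoms: list[Atom] = []
    for a in protein.atoms:
        if a.res_index != pos:
            new_atoms.append(a)
        elif a.name in ("N", "CA", "C", "O"):
            new_atoms.append(replace(a, res_name=new_res3))
        # side-chain atoms of the WT residue are dropped
    sidechain = [
        Atom(name, element_of(name), pos, new_res3, *coord)
        for name, coord in build_sidechain(new_res3, backbone["N"], backbone["CA"], backbone["C"])
    ]
    insert_at = max(i for i, a in enumerate(new_atoms) if a.res_index == pos) + 1
    new_atoms[insert_at:insert_at] = sidechain
    seq = protein.sequence[: pos - 1] + mutation.mt + protein.sequence[pos:]
    mutant = ProteinRecord(protein.protein_id, seq, new_atoms, protein.plddt.copy())
    mutant.validate()
    return mutant


# ---------------------------------------------------------------------------
# Contact typing
# ---------------------------------------------------------------------------

def _covalent_antecedent(protein: ProteinRecord, atom: Atom) -> Atom | None:
    """Nearest heavy atom in the same residue (proxy for the bonded one)."""
    best = None
    best_d = 2.2
    for other in protein.residue_atoms(atom.res_index):
        if other.name == atom.name:
            continue
        d = float(np.linalg.norm(atom.coord - other.coord))
        if d < best_d:
            best, best_d = other, d
    return best


def _has_hydrogen(atom: Atom) -> bool:
    if atom.element != "C":
        return False
    return ("*", atom.name) not in _H_LESS_CARBONS and (atom.res_name, atom.name) not in _H_LESS_CARBONS


def _ring_centroids(protein: ProteinRecord, position: int) -> list[np.ndarray]:
    atoms = {a.name: a.coord for a in protein.residue_atoms(position)}
    res3 = protein.residue_atoms(position)[0].res_name if protein.residue_atoms(position) else None
    out = []
    for ring in _RINGS.get(res3, []):
        if all(name in atoms for name in ring):
            out.append(np.mean([atoms[name] for name in ring], axis=0))
    return out


def type_contacts(
    protein: ProteinRecord,
    position: int,
    pmap: PharmacophoreMap | None = None,
    thresholds: ContactThresholds = ContactThresholds(),
) -> InteractionProfile:
    """Count typed interactions between the site residue and its environment.

    Partners are atoms of residues at sequence distance >= 2. An empty
    neighborhood simply yields a zero profile.
    """
    pmap = pmap or load_pharmacophore_map()
    site = protein.residue_atoms(position)
    if not site:
        raise ValueError(f"no atoms at position {position}")
    env = [a for a in protein.atoms if abs(a.res_index - position) >= 2]
    profile = InteractionProfile()

    for s in site:
        s_cls = pmap.classes(s.res_name, s.name)
        for o in env:
            o_cls = pmap.classes(o.res_name, o.name)
            d = float(np.linalg.norm(s.coord - o.coord))
            if d > 6.5:
                continue
            # hydrogen bond (either direction)
            if d <= thresholds.hydrogen_bond:
                for donor, acceptor, d_cls, a_cls in (
                    (s, o, s_cls, o_cls),
                    (o, s, o_cls, s_cls),
                ):
                    if "HydrogenDonor" in d_cls and "HydrogenAcceptor" in a_cls:
                        ante = _covalent_antecedent(protein, donor)
                        if ante is None or _angle(ante.coord, donor.coord, acceptor.coord) >= thresholds.hbond_min_angle:
                            profile.counts["HydrogenBond"] += 1
                            break
            if d <= thresholds.polar and (
                ("HydrogenDonor" in s_cls and "HydrogenAcceptor" in o_cls)
                or ("HydrogenAcceptor" in s_cls and "HydrogenDonor" in o_cls)
            ):
                profile.counts["Polar"] += 1
            if d <= thresholds.weak_polar and (
                (_has_hydrogen(s) and "HydrogenAcceptor" in o_cls)
                or (_has_hydrogen(o) and "HydrogenAcceptor" in s_cls)
            ):
                profile.counts["WeakPolar"] += 1
            if d <= thresholds.hydrophobic and "Hydrophobic" in s_cls and "Hydrophobic" in o_cls:
                profile.counts["Hydrophobic"] += 1
            if d <= thresholds.ionic and (
                ("PositiveIonizable" in s_cls and "NegativeIonizable" in o_cls)
                or ("NegativeIonizable" in s_cls and "PositiveIonizable" in o_cls)
            ):
                profile.counts["Ionic"] += 1

    # aromatic: ring-centroid pairs
    site_rings = _ring_centroids(protein, position)
    if site_rings:
        for other_pos in protein.residue_indices():
            if abs(other_pos - position) < 2:
                continue
            for oc in _ring_centroids(protein, other_pos):
                for sc in site_rings:
                    if float(np.linalg.norm(sc - oc)) <= thresholds.aromatic:
                        profile.counts["Aromatic"] += 1
    return profile


def _angle(p1, p2, p3) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def contact_delta(wt: InteractionProfile, mut: InteractionProfile) -> dict[str, int]:
    """Per-type mutant minus WT counts (feature columns ``ITd_<Type>``)."""
    return {t: mut.counts[t] - wt.counts[t] for t in INTERACTION_TYPES}


# ---------------------------------------------------------------------------
# Graph-based signatures
# ---------------------------------------------------------------------------

def default_cutoff_grid() -> np.ndarray:
    """1.00 to 11.00 Angstrom in 0.50 steps."""
    return np.arange(1.0, 11.0 + 1e-9, 0.5)


def _class_pairs() -> list[tuple[str, str]]:
    pairs = []
    for i, a in enumerate(CLASS_ORDER):
        for b in CLASS_ORDER[i:]:
            pairs.append((a, b))
    return pairs


def signature_feature_names(cutoffs: np.ndarray | None = None) -> list[str]:
    cutoffs = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs)
    names = []
    for a, b in _class_pairs():
        for c in cutoffs:
            names.append(f"{CLASS_ABBREV[a]}:{CLASS_ABBREV[b]}-{c:.2f}")
    return names


def graph_signature(
    protein: ProteinRecord,
    position: int,
    pmap: PharmacophoreMap | None = None,
    cutoffs: np.ndarray | None = None,
    mutant: ProteinRecord | None = None,
) -> dict[str, float]:
    """Cumulative pharmacophore pair counts around the mutation site.

    For every unordered class pair and every cutoff, counts atom pairs
    (site-residue atom, environment atom at sequence distance >= 2) with
    matching classes and distance <= cutoff; components are named
    ``<ClsA>:<ClsB>-<cutoff>`` (e.g. ``Aro:Sul-11.00``). When ``mutant``
    is given, per-class WT->mutant atom-count changes at the site are
    appended under the bare class abbreviation (e.g. ``Neg``).
    """
    pmap = pmap or load_pharmacophore_map()
    cutoffs = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs, float)
    max_cut = float(cutoffs.max())
    site = protein.residue_atoms(position)
    if not site:
        raise ValueError(f"no atoms at position {position}")
    env = [a for a in protein.atoms if abs(a.res_index - position) >= 2]

    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    # per class pair, sorted list of qualifying pair distances
    dists: dict[tuple[str, str], list[float]] = {p: [] for p in _class_pairs()}
    for s in site:
        s_cls = pmap.classes(s.res_name, s.name)
        if not s_cls and s.name not in ("N", "CA", "C", "O"):
            warnings.warn(f"atom {s.res_name}/{s.name} absent from pharmacophore map; skipped")
        for o in env:
            d = float(np.linalg.norm(s.coord - o.coord))
            if d > max_cut:
                continue
            o_cls = pmap.classes(o.res_name, o.name)
            seen: set[tuple[str, str]] = set()
            for a in s_cls:
                for b in o_cls:
                    key = (a, b) if order[a] <= order[b] else (b, a)
                    seen.add(key)
            for key in seen:
                dists[key].append(d)

    out: dict[str, float] = {}
    for (a, b), ds in dists.items():
        arr = np.sort(np.asarray(ds))
        for c in cutoffs:
            out[f"{CLASS_ABBREV[a]}:{CLASS_ABBREV[b]}-{c:.2f}"] = float(
                np.searchsorted(arr, c, side="right")
            )
    if mutant is not None:
        out.update(pharmacophore_change(protein, mutant, position, pmap))
    return out


def pharmacophore_change(
    wt_protein: ProteinRecord,
    mut_protein: ProteinRecord,
    position: int,
    pmap: PharmacophoreMap | None = None,
) -> dict[str, float]:
    """Per-class atom-count change (mutant minus WT) at the site residue."""
    pmap = pmap or load_pharmacophore_map()

    def _counts(protein: ProteinRecord) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_ORDER}
        for a in protein.residue_atoms(position):
            for c in pmap.classes(a.res_name, a.name):
                counts[c] += 1
        return counts

    wt_counts = _counts(wt_protein)
    mt_counts = _counts(mut_protein)
    return {CLASS_ABBREV[c]: float(mt_counts[c] - wt_counts[c]) for c in CLASS_ORDER}
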