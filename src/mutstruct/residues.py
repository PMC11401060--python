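"""Idealized residue geometry templates.

Side-chain atoms are described by internal coordinates relative to atoms
already placed (backbone N/CA/C, then side-chain atoms in build order).
Bond lengths and angles are standard idealized values; default torsions
put chains extended (chi = 180) and rings planar. These templates are an
approximation used when no externally modeled structure is supplied; no
refinement or clash relief is performed.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom

__all__ = ["SIDE_CHAIN_TOPOLOGY", "sidechain_atom_names", "build_sidechain"]

# entry: (atom, (ref_a, ref_b, ref_c), bond, angle(ref_b-ref_c-atom),
#         torsion(ref_a-ref_b-ref_c-atom))
# CB placement uses the N-C-CA improper (~123 deg) giving L-configuration.
_CB = ("CB", ("N", "C", "CA"), 1.546, 111.1, 123.2)

SIDE_CHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, 180.0)],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
    ],
    "VAL": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.527, 110.4, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.4, 60.0),
    ],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, 60.0),
    ],
    "ILE": [
        _CB,
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, 180.0),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 180.0),
    ],
    "MET": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0),
    ],
    "PRO": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, -35.0),
    ],
    "PHE": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.5, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, -90.0),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.368, 121.1, 0.0),
    ],
    "HIS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, 180.0),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.354, 131.0, -90.0),
        ("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
        ("NE2", ("CG", "ND1", "CE1"), 1.321, 108.5, 0.0),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, 90.0),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, -90.0),
    ],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 90.0),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, -90.0),
    ],
    "GLU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 90.0),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, -90.0),
    ],
    "GLN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 90.0),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, -90.0),
    ],
    "LYS": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.508, 111.3, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "ARG": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
}


def sidechain_atom_names(res_name: str) -> list[str]:
    return [entry[0] for entry in SIDE_CHAIN_TOPOLOGY[res_name]]


def element_of(atom_name: str) -> str:
    """Element symbol from a standard protein heavy-atom name."""
    return atom_name[0]


def build_sidechain(
    res_name: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Place the idealized side chain of ``res_name`` on a backbone frame.

    Returns ``(atom_name, coordinate)`` pairs in build order (CB first).
    """
    placed: dict[str, np.ndarray] = {
        "N": np.asarray(n, float),
        "CA": np.asarray(ca, float),
        "C": np.asarray(c, float),
    }
    out: list[tuple[str, np.ndarray]] = []
    for name, (ra, rb, rc), bond, ang, tor in SIDE_CHAIN_TOPOLOGY[res_name]:
        coord = place_atom(placed[ra], placed[rb], placed[rc], bond, ang, tor)
        placed[name] = coord
        out.append((name, coord))
    return out
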