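"""Sequence-derived feature generators.

Covers residue-group classifications (a five-group biochemical scheme and
a seven-group neighborhood scheme), neighboring amino-acid group
frequencies over a 15-residue window, amino-acid property lookups with
sliding-window delta features, and substitution-matrix scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .core_io import AA1, ONE_TO_THREE

__all__ = [
    "PropertyTable",
    "SubstitutionTable",
    "GroupScheme",
    "FIVE_GROUP_SCHEME",
    "SEVEN_GROUP_SCHEME",
    "SEVEN_GROUP_ORDER",
    "assign_group",
    "neighbor_frequency",
    "window_delta",
    "substitution_score",
    "parse_aaindex1",
    "builtin_property_tables",
    "builtin_substitution_tables",
]


@dataclass(frozen=True)
class PropertyTable:
    """One amino-acid scalar property keyed by a table identifier."""

    table_id: str
    values: dict[str, float]
    description: str = ""

    def __post_init__(self) -> None:
        missing = set(AA1) - set(self.values)
        if missing:
            raise ValueError(f"{self.table_id}: missing residues {sorted(missing)}")
        if len(self.values) != 20:
            extra = set(self.values) - set(AA1)
            raise ValueError(f"{self.table_id}: unexpected keys {sorted(extra)}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class SubstitutionTable:
    """Pairwise residue scores (substitution matrix / contact potential)."""

    table_id: str
    scores: dict[tuple[str, str], float]
    symmetric: bool = True
    description: str = ""

    def score(self, wt: str, mt: str) -> float:
        if wt not in ONE_TO_THREE or mt not in ONE_TO_THREE:
            raise ValueError(f"non-canonical residue pair ({wt}, {mt})")
        if (wt, mt) in self.scores:
            return self.scores[(wt, mt)]
        if self.symmetric and (mt, wt) in self.scores:
            return self.scores[(mt, wt)]
        raise KeyError(f"{self.table_id}: no entry for pair ({wt}, {mt})")


@dataclass(frozen=True)
class GroupScheme:
    name: str
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(AA1) - set(self.assignment)
        if missing:
            raise ValueError(f"scheme {self.name}: unassigned residues {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.assignment.values():
            if g not in seen:
                seen.append(g)
        return seen


def _scheme(name: str, groups: dict[str, str]) -> GroupScheme:
    assignment = {aa: label for label, members in groups.items() for aa in members}
    return GroupScheme(name, assignment)


FIVE_GROUP_SCHEME = _scheme(
    "five",
    {
        "hydrophobic": "AFILMVWY",
        "polar": "NQST",
        "negative": "DE",
        "positive": "HKR",
        "special": "CGP",
    },
)

# seven-group neighborhood scheme; order fixed for feature naming
SEVEN_GROUP_ORDER = (
    "hydrophobic",
    "aliphatic",
    "aromatic",
    "long_polar",
    "short_polar",
    "short_charged_polar",
    "structure_breaking",
)
SEVEN_GROUP_SCHEME = _scheme(
    "seven",
    {
        "hydrophobic": "ALM",
        "aliphatic": "IV",
        "aromatic": "FYW",
        "long_polar": "EQKR",
        "short_polar": "HSTC",
        "short_charged_polar": "DN",
        "structure_breaking": "GP",
    },
)


def assign_group(residue: str, scheme: GroupScheme) -> str:
    """Group label of ``residue`` under ``scheme``."""
    try:
        return scheme.assignment[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r} for scheme {scheme.name}") from None


def neighbor_frequency(sequence: str, position: int) -> dict[str, float]:
    """Seven-group frequency of the 14 residues flanking ``position``.

    Counts group members among the seven residues before and seven after
    the site (site excluded, truncated at the termini) and normalizes by
    the FULL sequence length. Note the full-length normalization couples
    this local feature to global protein length; that behavior is
    deliberate and matched to the upstream definition.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    lo = max(0, position - 1 - 7)
    hi = min(len(sequence), position + 7)
    window = sequence[lo : position - 1] + sequence[position:hi]
    counts = {g: 0 for g in SEVEN_GROUP_ORDER}
    for aa in window:
        counts[assign_group(aa, SEVEN_GROUP_SCHEME)] += 1
    n = len(sequence)
    return {g: counts[g] / n for g in SEVEN_GROUP_ORDER}


def window_delta(
    sequence: str,
    position: int,
    mt: str,
    table: PropertyTable,
    half_width: int,
    normalized: bool = False,
) -> float:
    """Windowed WT-average property minus the mutant residue's property.

    The window spans ``position - half_width .. position + half_width``
    (1-based, clipped to the sequence; no padding at the termini). With
    ``half_width=0`` this collapses to ``table[wt] - table[mt]``. When
    ``normalized``, the delta is divided by the sequence length.
    """
    if half_width not in (0, 1, 2, 3):
        raise ValueError(f"half_width must be one of 0..3, got {half_width}")
    if mt not in ONE_TO_THREE:
        raise ValueError(f"non-canonical mutant residue {mt!r}")
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    lo = max(0, position - 1 - half_width)
    hi = min(len(sequence), position + half_width)
    window = sequence[lo:hi]
    wt_mean = float(np.mean([table[aa] for aa in window]))
    delta = wt_mean - table[mt]
    if normalized:
        delta /= len(sequence)
    return delta


def substitution_score(wt: str, mt: str, table: SubstitutionTable) -> float:
    """Score of the substitution ``wt -> mt`` from ``table``."""
    return table.score(wt, mt)


# ---------------------------------------------------------------------------
# AAindex flat-file parsing and built-in catalog
# ---------------------------------------------------------------------------

_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


def parse_aaindex1(path_or_text: str | Path) -> list[PropertyTable]:
    """Parse AAindex-1 style flat-file entries (H/D/I blocks, // separator).

    Entries containing NA values are skipped.
    """
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    tables: list[PropertyTable] = []
    for block in text.split("//"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        table_id = ""
        description = ""
        data_rows: list[list[str]] = []
        in_data = False
        for ln in lines:
            tag = ln[:1]
            if tag == "H":
                table_id = ln[1:].strip()
                in_data = False
            elif tag == "D":
                description = ln[1:].strip()
                in_data = False
            elif tag == "I":
                in_data = True
            elif in_data and ln[:1] == " ":
                data_rows.append(ln.split())
            else:
                in_data = False
        if not table_id or len(data_rows) < 2:
            continue
        flat = data_rows[0] + data_rows[1]
        if len(flat) != 20 or any(v == "NA" for v in flat):
            continue
        values = {
            aa: float(v)
            for aa, v in zip(_AAINDEX_ROW1 + _AAINDEX_ROW2, flat)
        }
        tables.append(PropertyTable(table_id, values, description))
    return tables


# basic physicochemical tables shipped in addition to the AAindex catalog:
# isoelectric point, molecular weight (Da) and residue volume (A^3) are
# aliases of the corresponding catalog entries under conventional names.
_BASIC_ALIASES = {"pI": "ZIMJ680104", "mol_weight": "FASG760101", "mol_volume": "BIGC670101"}


def builtin_property_tables() -> dict[str, PropertyTable]:
    """The bundled property-table catalog keyed by table id."""
    data = resources.files("mutstruct.data").joinpath("aaindex1_builtin.txt").read_text()
    catalog = {t.table_id: t for t in parse_aaindex1(data)}
    for alias, source in _BASIC_ALIASES.items():
        src = catalog[source]
        catalog[alias] = PropertyTable(alias, dict(src.values), src.description)
    return catalog


def builtin_substitution_tables() -> dict[str, SubstitutionTable]:
    """Bundled substitution matrices (BLOSUM62/PAM250 via Biopython)."""
    from Bio.Align import substitution_matrices

    out: dict[str, SubstitutionTable] = {}
    for name in ("BLOSUM62", "PAM250"):
        mat = substitution_matrices.load(name)
        scores: dict[tuple[str, str], float] = {}
        for a in AA1:
            for b in AA1:
                scores[(a, b)] = float(mat[a, b])
        out[name] = SubstitutionTable(name, scores, symmetric=True, description=name)
    return out
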