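"""Dataset curation, grouped splitting, and feature-matrix assembly."""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as ct
from . import seq_features as sf
from . import struct_features as stf
from .core_io import (
    LABEL_DISEASE,
    LABEL_NEUTRAL,
    LABEL_UNLABELED,
    MutationRecord,
    ProteinRecord,
    check_mutation_maps,
)
from .providers import ProviderScores

__all__ = [
    "Dataset",
    "FeatureMatrix",
    "FeatureConfig",
    "load_corrections",
    "builtin_corrections",
    "clean_dataset",
    "grouped_split",
    "assemble_matrix",
]


@dataclass
class Dataset:
    records: list[MutationRecord]
    proteins: dict[str, ProteinRecord]
    provenance: dict[tuple, str] = field(default_factory=dict)

    def labels(self) -> pd.Series:
        return pd.Series(
            [r.label for r in self.records],
            index=[str(r) for r in self.records],
        )

    def groups(self) -> list[tuple[str, int]]:
        return [(r.protein_id, r.position) for r in self.records]

    def subset(self, records: list[MutationRecord]) -> "Dataset":
        keys = {r.key() for r in records}
        return Dataset(
            [r for r in self.records if r.key() in keys],
            self.proteins,
            {k: v for k, v in self.provenance.items() if k in keys},
        )


@dataclass
class FeatureMatrix:
    """Aligned numeric features for a mutation set.

    ``provenance`` records the module of origin of every column;
    ``excluded`` lists mutations dropped during assembly with reasons.
    """

    X: pd.DataFrame
    y: pd.Series  # 1 = Disease-causing, 0 = Neutral, NaN = Unlabeled
    groups: list[tuple[str, int]]
    provenance: dict[str, str] = field(default_factory=dict)
    excluded: list[tuple[tuple, str]] = field(default_factory=list)

    def restrict(self, feature_subset: list[str]) -> "FeatureMatrix":
        missing = [f for f in feature_subset if f not in self.X.columns]
        if missing:
            raise KeyError(f"feature(s) produced by no module: {missing}")
        return FeatureMatrix(
            self.X[feature_subset].copy(),
            self.y,
            self.groups,
            {f: self.provenance.get(f, "unknown") for f in feature_subset},
            self.excluded,
        )


def load_corrections(csv_path: str | Path) -> list[MutationRecord]:
    out = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MutationRecord(
                    row["protein"], int(row["position"]), row["wt"], row["mt"], row["label"]
                )
            )
    return out


def builtin_corrections() -> list[MutationRecord]:
    """The shipped label-correction list (TREM2 relabelings)."""
    with resources.as_file(
        resources.files("mutstruct.data").joinpath("label_corrections.csv")
    ) as p:
        return load_corrections(p)


def clean_dataset(
    raw_records: list[MutationRecord],
    proteins: dict[str, ProteinRecord],
    corrections: list[MutationRecord] | None = None,
) -> tuple[Dataset, list[tuple[MutationRecord, str]]]:
    """Curate raw mutation records against their proteins.

    Removes duplicates and records that do not map onto the canonical
    sequence, then applies forced-label corrections. Returns the cleaned
    dataset and a rejection report; the operation is idempotent.
    """
    corrections = corrections if corrections is not None else []
    rejected: list[tuple[MutationRecord, str]] = []
    seen: set[tuple] = set()
    kept: list[MutationRecord] = []
    provenance: dict[tuple, str] = {}
    for rec in raw_records:
        if rec.key() in seen:
            rejected.append((rec, "duplicate of an earlier record"))
            continue
        protein = proteins.get(rec.protein_id)
        if protein is None:
            rejected.append((rec, f"unknown protein {rec.protein_id}"))
            continue
        if not check_mutation_maps(rec, protein):
            rejected.append((rec, "does not map to the canonical sequence"))
            continue
        seen.add(rec.key())
        kept.append(rec)
        provenance[rec.key()] = "accepted"
    by_key = {r.key(): i for i, r in enumerate(kept)}
    for corr in corrections:
        idx = by_key.get(corr.key())
        if idx is None:
            warnings.warn(f"correction {corr} references a mutation absent after cleaning")
            continue
        if kept[idx].label != corr.label:
            kept[idx] = MutationRecord(
                corr.protein_id, corr.position, corr.wt, corr.mt, corr.label
            )
            provenance[corr.key()] = f"label corrected to {corr.label}"
    return Dataset(kept, proteins, provenance), rejected


def grouped_split(
    dataset: Dataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[Dataset, Dataset, Dataset]:
    """Split into train/validation/test by unique (protein, position) groups.

    Groups are shuffled with the seeded generator and partitions filled
    greedily to their target group counts, so records sharing a position
    never span partitions and the same seed reproduces the same split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups = sorted({(r.protein_id, r.position) for r in dataset.records})
    if len(groups) < 3:
        raise ValueError(f"need at least 3 position-groups, have {len(groups)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    shuffled = [groups[i] for i in order]
    n = len(groups)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n - 2))
    n_val = max(1, min(n_val, n - n_train - 1))
    parts = (
        set(shuffled[:n_train]),
        set(shuffled[n_train : n_train + n_val]),
        set(shuffled[n_train + n_val :]),
    )
    out = []
    for part in parts:
        out.append(dataset.subset([r for r in dataset.records if (r.protein_id, r.position) in part]))
    return tuple(out)


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Which feature families to generate and with what settings.

    ``signature_cutoffs=None`` uses the full default 1.00..11.00 grid; a
    shorter grid keeps toy runs fast. ``provider_columns`` lists provider
    scores required per mutation; mutations missing any are excluded (no
    silent imputation; ``impute_median=True`` opts in explicitly).
    """

    property_tables: dict[str, sf.PropertyTable] | None = None
    substitution_tables: dict[str, sf.SubstitutionTable] | None = None
    include_structure: bool = True
    include_contacts: bool = True
    include_signatures: bool = True
    signature_cutoffs: np.ndarray | None = None
    provider_columns: tuple[str, ...] = ()
    impute_median: bool = False
    sasa_points: int = 100
    depth_points: int = 40
    mutant_structures: dict[tuple, ProteinRecord] = field(default_factory=dict)

    def resolved_property_tables(self) -> dict[str, sf.PropertyTable]:
        if self.property_tables is not None:
            return self.property_tables
        return sf.builtin_property_tables()

    def resolved_substitution_tables(self) -> dict[str, sf.SubstitutionTable]:
        if self.substitution_tables is not None:
            return self.substitution_tables
        return sf.builtin_substitution_tables()


_LABEL_NUM = {LABEL_DISEASE: 1.0, LABEL_NEUTRAL: 0.0, LABEL_UNLABELED: np.nan}


def _protein_cache(protein: ProteinRecord, config: FeatureConfig) -> dict:
    cache: dict = {}
    if config.include_structure:
        cache["rsa"] = stf.compute_rsa_all(protein, n_points=config.sasa_points)
        cache["depth"] = stf.compute_depth_all(protein, n_points=config.depth_points)
        cache["ss"] = stf.assign_secondary_structure(protein)
        cache["plddt"] = dict(zip(protein.residue_indices(), protein.plddt))
    return cache


def _row_features(
    rec: MutationRecord,
    protein: ProteinRecord,
    cache: dict,
    config: FeatureConfig,
    pmap: ct.PharmacophoreMap,
) -> dict[str, float]:
    row: dict[str, float] = {}
    seq = protein.sequence
    pos = rec.position

    for group in sf.FIVE_GROUP_SCHEME.groups:
        row[f"{group}_wt"] = float(sf.assign_group(rec.wt, sf.FIVE_GROUP_SCHEME) == group)
        row[f"{group}_mt"] = float(sf.assign_group(rec.mt, sf.FIVE_GROUP_SCHEME) == group)

    for group, freq in sf.neighbor_frequency(seq, pos).items():
        row[f"{group}_freq"] = freq

    for tid, table in config.resolved_property_tables().items():
        row[f"{tid}_wt"] = table[rec.wt]
        row[f"{tid}_mt"] = table[rec.mt]
        for k in (0, 1, 2, 3):
            row[f"{tid}_delta_{k}"] = sf.window_delta(seq, pos, rec.mt, table, k)
            row[f"{tid}_delta_{k}_norm"] = sf.window_delta(seq, pos, rec.mt, table, k, normalized=True)

    for tid, table in config.resolved_substitution_tables().items():
        row[f"{tid}_sub"] = sf.substitution_score(rec.wt, rec.mt, table)

    if config.include_structure:
        row["rsa"] = cache["rsa"][pos]
        row["depth"] = cache["depth"][pos]
        ss = cache["ss"][pos]
        for state in "HEC":
            row[f"ss_{state}"] = float(ss == state)
        phi, psi = stf.compute_torsions(protein, pos)
        row["phi"] = 0.0 if phi is None else phi
        row["psi"] = 0.0 if psi is None else psi
        row["plddt"] = cache["plddt"][pos]

    if config.include_contacts or config.include_signatures:
        mutant = ct.build_mutant_model(
            protein, rec, config.mutant_structures.get(rec.key())
        )
    if config.include_contacts:
        wt_profile = ct.type_contacts(protein, pos, pmap)
        mt_profile = ct.type_contacts(mutant, pos, pmap)
        for t in ct.INTERACTION_TYPES:
            row[f"IT{t}"] = float(wt_profile.counts[t])
        for t, d in ct.contact_delta(wt_profile, mt_profile).items():
            row[f"ITd_{t}"] = float(d)
    if config.include_signatures:
        row.update(
            ct.graph_signature(protein, pos, pmap, config.signature_cutoffs, mutant=mutant)
        )
    return row


_FAMILY = [
    ("_freq", "seq_features"),
    ("_wt", "seq_features"),
    ("_mt", "seq_features"),
    ("_delta", "seq_features"),
    ("_sub", "seq_features"),
    ("ITd_", "contacts"),
    ("IT", "contacts"),
]


def _provenance_of(col: str) -> str:
    if col in ("rsa", "depth", "phi", "psi", "plddt") or col.startswith("ss_"):
        return "struct_features"
    if ":" in col or col in ct.CLASS_ABBREV.values():
        return "contacts"
    for marker, module in _FAMILY:
        if marker in col or col.startswith(marker):
            return module
    return "providers"


def assemble_matrix(
    dataset: Dataset,
    config: FeatureConfig | None = None,
    provider_scores: ProviderScores | None = None,
    feature_subset: list[str] | None = None,
) -> FeatureMatrix:
    """Materialize one feature row per mutation.

    Mutations whose protein structure is unavailable or that lack a
    required provider score are excluded and reported, never imputed
    (unless ``config.impute_median`` is set).
    """
    config = config or FeatureConfig()
    pmap = ct.load_pharmacophore_map()
    caches: dict[str, dict] = {}
    rows: dict[str, dict[str, float]] = {}
    labels: dict[str, float] = {}
    groups: list[tuple[str, int]] = []
    excluded: list[tuple[tuple, str]] = []

    for rec in dataset.records:
        protein = dataset.proteins.get(rec.protein_id)
        if protein is None:
            excluded.append((rec.key(), "no protein record"))
            continue
        provider_row: dict[str, float] = {}
        if config.provider_columns:
            entry = provider_scores.get(rec.key()) if provider_scores else None
            missing = [
                c for c in config.provider_columns if entry is None or c not in entry
            ]
            if missing and not config.impute_median:
                excluded.append((rec.key(), f"missing provider score(s) {missing}"))
                continue
            for c in config.provider_columns:
                provider_row[c] = (entry or {}).get(c, np.nan)
        if rec.protein_id not in caches:
            caches[rec.protein_id] = _protein_cache(protein, config)
        row = _row_features(rec, protein, caches[rec.protein_id], config, pmap)
        row.update(provider_row)
        rows[str(rec)] = row
        labels[str(rec)] = _LABEL_NUM[rec.label]
        groups.append((rec.protein_id, rec.position))

    X = pd.DataFrame.from_dict(rows, orient="index")
    if config.impute_median and len(X):
        X = X.fillna(X.median(numeric_only=True))
    y = pd.Series(labels, index=X.index if len(X) else None, dtype=float)
    provenance = {c: _provenance_of(c) for c in X.columns}
    matrix = FeatureMatrix(X, y, groups, provenance, excluded)
    if feature_subset is not None:
        matrix = matrix.restrict(feature_subset)
    return matrix
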