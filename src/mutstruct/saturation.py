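"""In silico saturation mutagenesis: predictions for all 19 substitutions
at every modeled position, per-site summaries, and exports (long table,
heatmap matrix, structure annotated with per-site scores)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AA1, MutationRecord, ProteinRecord, write_pdb
from .dataset import Dataset, FeatureConfig, assemble_matrix
from .modeling import ModelBank

__all__ = ["SaturationTable", "saturate", "site_summary", "annotate_structure", "heatmap_matrix"]


@dataclass
class SaturationTable:
    protein_id: str
    rows: pd.DataFrame  # columns: position, wt, mt, probability, model, flagged

    def __post_init__(self) -> None:
        per_pos = self.rows.groupby("position").size()
        if not (per_pos == 19).all():
            bad = per_pos[per_pos != 19]
            raise ValueError(f"positions without exactly 19 rows: {dict(bad)}")
        probs = self.rows["probability"].dropna()
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("probabilities outside [0, 1]")


def saturate(
    protein: ProteinRecord,
    bank: ModelBank,
    config: FeatureConfig | None = None,
    provider_scores=None,
    positions: list[int] | None = None,
) -> SaturationTable:
    """Predict every possible substitution at every modeled position.

    The model is chosen by the bank's routing rule for this protein. Rows
    whose required features cannot be computed are flagged (probability
    NaN), never silently dropped.
    """
    model, route = bank.resolve(protein.protein_id)
    config = config or FeatureConfig()
    positions = positions or protein.residue_indices()
    records = []
    for pos in positions:
        wt = protein.sequence[pos - 1]
        for mt in AA1:
            if mt != wt:
                records.append(MutationRecord(protein.protein_id, pos, wt, mt))
    dataset = Dataset(records, {protein.protein_id: protein})
    matrix = assemble_matrix(dataset, config, provider_scores)
    present = matrix.X.index
    proba = pd.Series(
        model.predict_proba(matrix.X), index=present
    ) if len(present) else pd.Series(dtype=float)
    rows = []
    for rec in records:
        key = str(rec)
        if key in proba.index:
            rows.append((rec.position, rec.wt, rec.mt, float(proba[key]), route, False))
        else:
            rows.append((rec.position, rec.wt, rec.mt, np.nan, route, True))
    df = pd.DataFrame(
        rows, columns=["position", "wt", "mt", "probability", "model", "flagged"]
    )
    return SaturationTable(protein.protein_id, df)


def site_summary(table: SaturationTable) -> pd.DataFrame:
    """Per-position mean probability over the 19 substitutions.

    Positions containing flagged rows are marked ``partial`` and averaged
    over the rows that do have predictions.
    """
    grouped = table.rows.groupby("position")
    out = grouped.agg(
        mean_probability=("probability", "mean"),
        partial=("flagged", "any"),
        wt=("wt", "first"),
    ).reset_index()
    return out[["position", "wt", "mean_probability", "partial"]]


def heatmap_matrix(table: SaturationTable) -> pd.DataFrame:
    """Positions x 20 residues probability matrix; self-substitution blank."""
    pivot = table.rows.pivot(index="position", columns="mt", values="probability")
    for aa in AA1:
        if aa not in pivot.columns:
            pivot[aa] = np.nan
    return pivot[list(AA1)]


def annotate_structure(
    protein: ProteinRecord,
    per_position_values: dict[int, float],
    out_path: str | Path,
) -> None:
    """Write a PDB whose B-factor column carries per-residue values.

    Values are scaled from [0, 1] to [0, 100]; a residue without a value
    gets sentinel 0 with a warning. Coordinates are untouched and the
    file round-trips through the standard loader.
    """
    bfactors: dict[int, float] = {}
    for idx in protein.residue_indices():
        if idx in per_position_values:
            bfactors[idx] = 100.0 * float(per_position_values[idx])
        else:
            warnings.warn(f"no value for residue {idx}; sentinel 0 written")
            bfactors[idx] = 0.0
    write_pdb(protein, out_path, bfactors=bfactors)
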