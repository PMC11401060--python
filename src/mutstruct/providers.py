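"""Adapters for externally computed per-mutation scores.

Stability predictions (ddG from four predictors), SIFT, SNAP2, PSSM and
disorder scores are consumed from TSV tables rather than recomputed; the
convention for ddG follows the zero cutoff: positive stabilizing,
negative destabilizing, exactly zero neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core_io import MutationRecord

__all__ = [
    "DEFAULT_SCHEMA",
    "ProviderScores",
    "load_provider_table",
    "classify_stability",
    "destabilizing_fraction",
]

Key = tuple[str, int, str, str]

# column -> (lower bound, upper bound) or None for unbounded
DEFAULT_SCHEMA: dict[str, tuple[float, float] | None] = {
    "ddg_mcsm": None,
    "ddg_saafecseq": None,
    "ddg_ddmut": None,
    "ddg_dynamut2": None,
    "sift_score": (0.0, 1.0),
    "snap2_score": (-100.0, 100.0),
    "pssm_score": None,
    "iupred_short": (0.0, 1.0),
    "iupred_long": (0.0, 1.0),
}

_KEY_COLUMNS = ("protein", "position", "wt", "mt")


@dataclass
class ProviderScores:
    """Validated per-mutation score store keyed by (protein, position, wt, mt)."""

    scores: dict[Key, dict[str, float]] = field(default_factory=dict)
    columns: tuple[str, ...] = ()

    def get(self, key: Key) -> dict[str, float] | None:
        return self.scores.get(key)

    def coverage(self, mutations: list[MutationRecord]) -> tuple[float, list[Key]]:
        """Fraction of requested mutations present, plus the missing keys."""
        missing = [m.key() for m in mutations if m.key() not in self.scores]
        if not mutations:
            return 1.0, []
        return 1.0 - len(missing) / len(mutations), missing


def load_provider_table(
    tsv_path: str | Path,
    schema: dict[str, tuple[float, float] | None] | None = None,
) -> ProviderScores:
    """Read and validate a provider TSV (``protein position wt mt <scores>``).

    Duplicate keys, out-of-range bounded scores, and columns absent from
    the schema are hard errors.
    """
    schema = DEFAULT_SCHEMA if schema is None else schema
    df = pd.read_csv(tsv_path, sep="\t")
    missing_keys = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing_keys:
        raise ValueError(f"{tsv_path}: missing key column(s) {missing_keys}")
    score_cols = [c for c in df.columns if c not in _KEY_COLUMNS]
    unknown = [c for c in score_cols if c not in schema]
    if unknown:
        raise ValueError(f"{tsv_path}: column(s) {unknown} not in the declared schema")
    store: dict[Key, dict[str, float]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        key: Key = (str(rec["protein"]), int(rec["position"]), str(rec["wt"]), str(rec["mt"]))
        if key in store:
            raise ValueError(f"{tsv_path}: duplicate key {key}")
        values: dict[str, float] = {}
        for col in score_cols:
            val = rec[col]
            if pd.isna(val):
                continue
            val = float(val)
            bounds = schema[col]
            if bounds is not None and not (bounds[0] <= val <= bounds[1]):
                raise ValueError(
                    f"{tsv_path} row {row_no}: {col}={val} outside [{bounds[0]}, {bounds[1]}]"
                )
            values[col] = val
        store[key] = values
    return ProviderScores(store, tuple(score_cols))


def classify_stability(ddg: float) -> str:
    """Sign classification of a folding free-energy change (kcal/mol)."""
    if not math.isfinite(ddg):
        raise ValueError(f"non-finite ddG {ddg!r}")
    if ddg > 0:
        return "stabilizing"
    if ddg < 0:
        return "destabilizing"
    return "neutral"


def destabilizing_fraction(
    scores: ProviderScores,
    mutations: list[MutationRecord],
    ddg_column: str = "ddg_ddmut",
) -> dict[str, float | None]:
    """Per-protein fraction of scored mutations classified destabilizing.

    Proteins with zero scored mutations map to ``None`` (undefined).
    """
    counts: dict[str, list[int]] = {}
    for m in mutations:
        n_dest, n_tot = counts.setdefault(m.protein_id, [0, 0])
        entry = scores.get(m.key())
        if entry is None or ddg_column not in entry:
            continue
        counts[m.protein_id][1] += 1
        if classify_stability(entry[ddg_column]) == "destabilizing":
            counts[m.protein_id][0] += 1
    return {
        pid: (dest / tot if tot else None) for pid, (dest, tot) in counts.items()
    }
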