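# mutstruct

Structure-aware missense mutation analysis: feature generation for
single amino-acid substitutions (sequence context, structural
descriptors, interaction contacts, pharmacophore graph-based
signatures), weighted gradient-boosting classification of
disease-causing vs neutral variants, evaluation machinery, and in
silico saturation mutagenesis with per-site pathogenicity summaries.

## Layout

| module | role |
|---|---|
| `mutstruct.core_io` | FASTA/PDB/mutation-CSV reading and validation; `ProteinRecord` / `MutationRecord` conventions (1-based canonical numbering, pLDDT from CA B-factors) |
| `mutstruct.seq_features` | residue group schemes (5- and 7-group), neighboring amino-acid frequency (15-residue window), AAindex property tables and sliding-window deltas, substitution-matrix scores |
| `mutstruct.struct_features` | RSA (Shrake–Rupley, theoretical max-ASA normalization), residue depth, 3-state secondary structure (Kabsch–Sander hydrogen-bond criterion), phi/psi torsions |
| `mutstruct.contacts` | interaction-contact typing at the mutation site, contact deltas (`IT*` / `ITd_*` features), cumulative pharmacophore graph signatures (`Aro:Sul-11.00`-style), idealized side-chain-swap mutant builder |
| `mutstruct.providers` | adapters for externally computed scores (4× stability ΔΔG, SIFT, SNAP2, PSSM, disorder), stability sign classification, destabilizing fractions |
| `mutstruct.dataset` | curation (dedup, mapping check, shipped label corrections), grouped 60/20/20 splitting by (protein, position), feature-matrix assembly |
| `mutstruct.modeling` | gradient boosting (n_estimators=80, lr=0.1, max_depth=7), 11:1 target-protein sample weighting, greedy forward selection on validation MCC, generic + per-protein model bank with routing |
| `mutstruct.evaluation` | BACC/F1/MCC/AUC metrics, grouped 10-fold CV (pooled), leave-one-protein-out, MCC-maximizing cutoff calibration, two-sample rank tests |
| `mutstruct.saturation` | all-19-substitutions scans, per-site mean probabilities, heatmap matrix, B-factor-annotated PDB export |
| `mutstruct.fixtures` | synthetic data: idealized helix/extended/bundle structures, planted-signal mutation datasets, fabricated provider tables |

Notes on deliberate approximations (documented in the docstrings):

* mutant structures default to an idealized side-chain swap aligned on
  N–CA–C (no refinement); externally modeled mutant structures can be
  registered per mutation and take precedence;
* the neighbor-frequency feature normalizes local window counts by the
  **full** protein length, coupling a local feature to global length —
  implemented verbatim by design;
* contact-typing thresholds and the pharmacophore atom-class table are
  editable data (`src/mutstruct/data/pharmacophores.tsv`), with defaults
  pinned by the test suite.

## CLI

```bash
# emit a complete toy project (FASTA + PDB + mutations.csv + providers.tsv)
mutstruct fixtures --out toy/ --seed 1 --n-proteins 3 --length 40 --n-mutations 40

# assemble the feature matrix (TSV with a provenance comment header)
mutstruct features --project toy/ --out toy/matrix.tsv

# saturation mutagenesis for one protein (long table, site summary,
# heatmap CSV, B-factor-annotated PDB)
mutstruct saturate --project toy/ --protein SYN1 --out toy/sat/
```

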