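# hematlas

Toolkit for building and exploiting a **cell-type-resolved bead-array
expression atlas** of hematological malignancies, healthy hematopoietic
cells and the non-hematopoietic tissues attacked in graft-versus-host
disease — the data backbone for choosing immunotherapy targets (minor
histocompatibility antigens, CAR surface antigens) whose expression is
restricted to the hematopoietic compartment.

The pipeline covers:

* **Normalization** — a variance-stabilizing generalized-log transform
  fitted from bead-level summaries (`sd² = c1 + c2·mean + c3·mean²`,
  `h(x) → log2(x) + 1`), followed by quantile normalization; chip-version
  merging on the shared probe set.
* **Sample QC** — marker-panel identity checks, peripheral-blood
  contamination detection in non-hematopoietic samples, IFN-γ response
  verification of treated samples, and average-linkage clustering on
  correlation distance as an unsupervised confirmation.
* **Inflammation screen** — per-probe fold induction
  `FC = 2^(avg₁ − avg₂)` over paired treated/untreated samples, threshold
  screens (default: FC > 10), and cross-condition concordance between
  IFN-γ and T-cell-supernatant treatment.
* **qPCR cross-validation** — reference-corrected Cp
  (`Cp′ = Cp − Σ wᵣ·Cpᵣ`, per batch), censoring-aware imputation, per-gene
  quadratic fits `array = β₀ + β₁Cp′ + β₂Cp′²` with R², and a reliability
  gate: genes with maximum probe fluorescence > log 11 support quantitative
  array interpretation.
* **Target profiling** — per-gene group means/SDs across cell types
  (IFN-treated groups separate) and a restriction score
  `min(target means) − max(non-target means)` in log2 units.
* **Synthetic data** — seeded generators for every input (expression,
  bead summaries, annotations, qPCR) with machine-readable ground truth,
  so the whole chain is testable without any download.  An adapter for
  plain-text GEO series-matrix files is included for real data
  (e.g. GSE76340-style atlases).

## Worked example

```python
from hematlas import (SyntheticConfig, generate_atlas, screen_induced,
                      profile_gene, restriction_score)
from hematlas.published import induction_filter_count, reliability_counts

dataset, truth = generate_atlas(SyntheticConfig(), seed=0)

result = screen_induced(dataset, "ifn_gamma", fold_threshold=10.0, min_celltypes=5)
print(len(result.probe_ids))          # -> 12   probes >10-fold induced in all 5 cell types

prof = profile_gene(dataset, "PTPRC")
print(round(restriction_score(prof), 2))   # -> 3.78   log2 separation: pan-hematopoietic

print(induction_filter_count())       # -> 47   probes >10-fold in either condition
print(reliability_counts()["n_quantitative"])  # -> 11  genes above the log-11 gate
```

The screen recovers exactly the 12 planted 20-fold-inducible probes; the
PTPRC restriction score of ~3.8 log2 says every hematopoietic group sits
~14-fold above the highest non-hematopoietic group, including IFN-treated
ones.  The last two numbers recompute the bundled published validation
summaries: 47 probes pass the >10-fold inflammation filter, and 11 of 24
validation genes clear the reliability gate (all 11 with cross-platform
R² > 0.667).

The `examples/` directory holds one short script per capability
(normalization, QC, screen, validation, profiling); each prints the
numbers it computes and what they mean.  A thin CLI mirrors the pipeline:
`atlas simulate | normalize | qc | screen | validate | profile`.

## Layout

```
src/hematlas/    core, io, normalization, qc, induction, crossplatform,
                 targets, synthetic, published, cli
src/hematlas/data/   bundled published summary tables (TSV)
tests/           unit + property + acceptance suites
examples/        narrative scripts, one per capability
docs/methods.md  models, defaults, numerical choices, limitations
```
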