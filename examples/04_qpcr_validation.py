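"""Cross-platform validation: regress array signal on corrected qPCR Cp.

Cp values are reference-corrected per batch, missing wells imputed, and a
per-gene quadratic model array = b0 + b1*Cp' + b2*Cp'^2 is fitted.  The
reliability gate (max probe fluorescence > 11) is applied both to synthetic
data and to the bundled published 24-gene validation summary.
"""

from hematlas import (
    SyntheticConfig,
    classify_reliability,
    correct_cp,
    fit_quadratic_model,
    generate_atlas,
    generate_qpcr,
    impute_missing_cp,
)
from hematlas.published import reliability_counts

config = SyntheticConfig()
dataset, truth = generate_atlas(config, seed=0)
gene_map = {g: [p] for g, p in truth.gene_to_probe.items()}
genes = sorted(set().union(*map(set, config.markers.values())))[:12]

qpcr = generate_qpcr(config, dataset.matrix, gene_map, genes=genes, seed=1)
corrected = correct_cp(impute_missing_cp(qpcr))
fit = fit_quadratic_model(corrected, dataset.matrix, {g: gene_map[g] for g in genes})
print(f"{len(fit.per_gene)} genes fitted on {fit.n_samples_total} (gene, sample) points")
print(f"pooled R2 = {fit.pooled_r2:.3f}, adjusted = {fit.pooled_adjusted_r2:.3f}, "
      f"mean per-gene R2 = {fit.mean_gene_r2:.3f}")

classes = classify_reliability(dataset.matrix, {g: gene_map[g] for g in genes})
n_quant = sum(c.quantitative for c in classes)
print(f"reliability gate on synthetic genes: {n_quant}/{len(classes)} quantitative")

counts = reliability_counts()
print(f"published validation summary: {counts['n_quantitative']}/{counts['n_genes']} genes "
      f"above the gate, {counts['n_quantitative_r2_over_cut']} of them with R2 > 0.667; "
      f"{counts['n_qualitative_r2_over_cut']} below-gate genes also exceed the cut")
# above the gate the array is trusted quantitatively; below it qPCR is the
# recommended quantitative assay and the array supports qualitative calls only.
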