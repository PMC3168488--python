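"""Replicated quantitative stage: moderated t, FDR, diet-response labels.

Simulates the 4-replicate 2-line x 2-diet subcutaneous-fat design, runs
the four pairwise contrasts with empirical-Bayes variance shrinkage and
BH-FDR, applies the fold/significance/expression candidate filter, and
classifies each probe's line-by-diet pattern.
"""

import pandas as pd

from stratiq import (
    GeneratorConfig,
    classify_all,
    generate_quantitative,
    run_all_contrasts,
    quantitative_filter,
)

cfg = GeneratorConfig(n_probes=1000)
study, truth = generate_quantitative(cfg, seed=7)
results = run_all_contrasts(study)

print("moderated-t summary for the line contrast on control diet (FC vs LC):")
print(results["FCvsLC"].sort_values("padj").head(5).round(3).to_string())

selected = quantitative_filter(results, fold=2.0, alpha=0.05, floor=100.0)
counts = {c: (len(d["up"]), len(d["down"])) for c, d in selected.items()}
print(f"\ncandidates per contrast (up, down) at >2-fold, padj<0.05, >100 AU: {counts}")

labels = classify_all(results, alpha=0.05)
print("\ndiet-response classification vs planted truth:")
print(pd.crosstab(truth["class"], labels).to_string())
print(
    "\n'diet_amplified' probes carry a Fat-vs-Lean difference on the control"
    "\ndiet that grows under high-fat feeding — the gene-by-diet interaction"
    "\npattern the quantitative stage is designed to expose."
)
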