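"""Run the whole cascade end-to-end in simulation mode and print the funnel.

Stages: per-depot fold filter -> coordinate 3-WAT filter -> stringent
candidates (+ QTL stratification, quantitative contrasts and ORA), with
per-stage candidate counts logged as a funnel.
"""

from stratiq import GeneratorConfig, PipelineConfig, render_funnel, run_pipeline

cfg = PipelineConfig(simulate=GeneratorConfig(n_probes=1000), seed=5)
report = run_pipeline(cfg)

print(render_funnel(report).to_string(index=False))
print()
for line in report.log_lines:
    print(" ", line)
print(
    "\nCounts shrink down the cascade as criteria tighten; the stringent"
    "\nstage list is the candidate-obesity-gene set a study of this design"
    "\nwould take forward to validation."
)
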