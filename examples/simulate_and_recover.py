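"""Planted-truth recovery: how well does the cascade find what was planted?

Generates the default synthetic snapshot (4-fold adipose effects, 0.2
log2-unit chip noise, pools of 3), runs the stringent filter and scores
sensitivity and false-discovery proportion per candidate list.
"""

from stratiq import GeneratorConfig, generate_snapshot, recovery_by_class, stringent_candidates

cfg = GeneratorConfig()
study, truth = generate_snapshot(cfg, seed=1)
table = stringent_candidates(study)

metrics = recovery_by_class(
    {"up_F 3WAT": table.up_f["3WAT"], "up_L 3WAT": table.up_l["3WAT"]},
    truth,
    {"up_F 3WAT": ["adipose_F_up"], "up_L 3WAT": ["adipose_L_up"]},
)
print(metrics.round(3).to_string())
print(
    "\nsensitivity = planted genes recovered / planted; fdp = selected"
    "\nprobes outside the target class / selected. With 4-fold effects and"
    "\npooled noise ~0.12 log2 units the stringent stage recovers nearly"
    "\nevery planted adipose gene with few or no false discoveries."
)
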