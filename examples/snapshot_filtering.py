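"""Snapshot filter cascade on a worked example plus synthetic probes.

Builds a tiny pooled snapshot study containing the published all-tissue
divergent gene (Depdc6-style intensities), one clean adipose-specific
candidate and one flat probe, then runs the per-depot and coordinate
3-WAT filters with and without the non-adipose window.
"""

import pandas as pd

from stratiq import ExpressionStudy, FilterConfig, SampleInfo, coordinate_3wat_filter, sfc_table
from stratiq.data import TISSUES

rows = {
    # F-line intensities by SC, EPI, MES, LIV, MUS, KID; then L-line
    "all_tissue": ([1392, 1506, 947, 791, 888, 263], [10, 11, 14, 18, 12, 12]),
    "adipose_only": ([1600, 1500, 1400, 410, 390, 405], [400, 380, 420, 400, 400, 400]),
    "flat": ([500, 500, 500, 500, 500, 500], [500, 500, 500, 500, 500, 500]),
}

samples, columns = [], {}
for li, line in enumerate(("F", "L")):
    for ti, tissue in enumerate(TISSUES):
        sid = f"{line}_{tissue}"
        samples.append(SampleInfo(sample_id=sid, line=line, tissue=tissue))
        columns[sid] = [float(rows[p][li][ti]) for p in rows]
study = ExpressionStudy(pd.DataFrame(columns, index=pd.Index(rows, name="probe_id")), samples)

print("signed fold changes (+ = higher in the Fat line):")
print(sfc_table(study).round(1).to_string())

windowed = FilterConfig(adipose_threshold=1.5, nonadipose_window=1.5)
open_cfg = FilterConfig(adipose_threshold=1.5, nonadipose_window=None)
for cfg, label in ((open_cfg, "no window"), (windowed, "window 1.5")):
    up_f, up_l = coordinate_3wat_filter(study, cfg)
    print(f"coordinate 3-WAT filter ({label}): up in F = {up_f}, up in L = {up_l}")

print(
    "\nThe all-tissue probe is >40-fold divergent everywhere, so the"
    "\nnon-adipose window removes it: divergence shared by liver, muscle"
    "\nand kidney cannot be an adipose-specific obesity signal."
)
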