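"""Shared fixtures: hand-built studies and independent oracles."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from stratiq import ExpressionStudy, SampleInfo
from stratiq.data import TISSUES


def build_snapshot(rows: dict[str, tuple[list[float], list[float]]]) -> ExpressionStudy:
    """Snapshot study from {probe: (F intensities by tissue, L intensities)}.

    Tissue order is SC, EPI, MES, LIV, MUS, KID.
    """
    samples = []
    columns: dict[str, list[float]] = {}
    for line in ("F", "L"):
        for t_i, tissue in enumerate(TISSUES):
            sid = f"{line}_{tissue}"
            samples.append(SampleInfo(sample_id=sid, line=line, tissue=tissue, diet="chow"))
            columns[sid] = [
                (f_vals if line == "F" else l_vals)[t_i]
                for (f_vals, l_vals) in rows.values()
            ]
    mat = pd.DataFrame(columns, index=pd.Index(rows.keys(), name="probe_id"))
    return ExpressionStudy(intensities=mat, samples=samples, design="snapshot")


def build_quantitative(rows: dict[str, dict[str, list[float]]]) -> ExpressionStudy:
    """Quantitative study from {probe: {group FC/FF/LC/LF: replicate AUs}}."""
    group_meta = {
        "FC": ("F", "control"),
        "FF": ("F", "highfat"),
        "LC": ("L", "control"),
        "LF": ("L", "highfat"),
    }
    first = next(iter(rows.values()))
    samples = []
    columns: dict[str, list[float]] = {}
    for group, reps in first.items():
        line, diet = group_meta[group]
        for r in range(len(reps)):
            sid = f"{group}_{r + 1}"
            samples.append(
                SampleInfo(sample_id=sid, line=line, tissue="SC", diet=diet, replicate=r + 1)
            )
            columns[sid] = [rows[p][group][r] for p in rows]
    mat = pd.DataFrame(columns, index=pd.Index(rows.keys(), name="probe_id"))
    return ExpressionStudy(intensities=mat, samples=samples, design="quantitative")


#: Printed worked example: an all-tissue divergent ("bystander") gene —
#: strongly up in the Fat line in every tissue, including liver/muscle/kidney.
WORKED_EXAMPLE_F = [1392.0, 1506.0, 947.0, 791.0, 888.0, 263.0]
WORKED_EXAMPLE_L = [10.0, 11.0, 14.0, 18.0, 12.0, 12.0]


@pytest.fixture
def bystander_example_study() -> ExpressionStudy:
    return build_snapshot({"Depdc6": (WORKED_EXAMPLE_F, WORKED_EXAMPLE_L)})


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up adjustment, O(m log m), written from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def hypergeom_tail_comb(k: int, universe: int, category: int, selected: int) -> float:
    """P(X >= k) by a math.comb tail sum (no scipy)."""
    total = math.comb(universe, selected)
    hi = min(category, selected)
    acc = 0
    for j in range(k, hi + 1):
        acc += math.comb(category, j) * math.comb(universe - category, selected - j)
    return acc / total


def hypergeom_tail_enumerate(k: int, universe: int, category: int, selected: int) -> float:
    """P(X >= k) by exhaustive enumeration of every possible selected subset."""
    items = range(universe)
    cat = set(range(category))
    hits = sum(
        1 for draw in combinations(items, selected) if len(cat.intersection(draw)) >= k
    )
    return hits / math.comb(universe, selected)
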