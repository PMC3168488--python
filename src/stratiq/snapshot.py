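"""The 'snap-shot' fold-change filter cascade.

A snapshot study has one pooled chip per tissue per line, so there is no
replication and no p-value: candidate genes are selected purely by signed
fold-change thresholds, in successive stages of increasing stringency:

1. per-depot filter — divergent (> threshold-fold) between the Fat (F) and
   Lean (L) lines in a white adipose depot, optionally requiring the fold
   change in each non-adipose tissue (liver, muscle, kidney) to lie
   strictly inside a window (the "bystander" exclusion);
2. coordinate 3-WAT filter — divergent with a common sign in all three
   white adipose depots (SC, EPI, MES);
3. stringent candidates — >=2-fold in all three depots, non-adipose folds
   strictly inside (-2, +2), and mean 3-WAT intensity of the
   higher-expressing line above an AU floor (default 100).

Sign convention: positive fold = higher in F, negative = higher in L, and
the magnitude is always >= 1 (ratio of higher over lower intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_EPSILON,
    NON_ADIPOSE,
    TISSUES,
    WAT_DEPOTS,
    ExpressionStudy,
    ValidationError,
)


def signed_fold_change(intensity_f: float, intensity_l: float) -> float:
    """Signed ratio of two linear-AU intensities.

    Returns F/L when F >= L (positive, higher in the Fat line) and
    -(L/F) when F < L (negative, higher in the Lean line). Equal inputs
    give +1.0; the magnitude is never below 1.
    """
    f = float(intensity_f)
    l = float(intensity_l)
    if f <= 0 or l <= 0:
        raise ValidationError(
            f"signed fold change needs positive intensities, got ({f}, {l})"
        )
    return f / l if f >= l else -(l / f)


def sfc_table(study: ExpressionStudy, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Per-probe signed fold change (F vs L) for every tissue in the study.

    Intensities are floored at ``epsilon`` AU before the ratio. Vectorised
    equivalent of :func:`signed_fold_change` applied probe-by-probe.
    """
    if study.design != "snapshot":
        raise ValidationError("signed fold-change table requires a snapshot study")
    cols = {}
    for tissue in TISSUES:
        if tissue not in study.tissues_present():
            continue
        f = study.snapshot_column("F", tissue).clip(lower=epsilon).to_numpy(float)
        l = study.snapshot_column("L", tissue).clip(lower=epsilon).to_numpy(float)
        cols[tissue] = np.where(f >= l, f / l, -(l / f))
    return pd.DataFrame(cols, index=study.probe_ids)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for one snapshot filter stage.

    Parameters
    ----------
    adipose_threshold
        Minimum fold divergence required in the adipose depot(s). The
    relaxed stage uses a strict ``>`` comparison (default 1.5); set
        ``threshold_inclusive=True`` for the stringent stage's ``>=2``.
    nonadipose_window
        If not None, |fold| in each of liver, muscle and kidney must be
        strictly below this (excludes all-tissue "bystander" genes).
    intensity_floor
        Minimum mean AU intensity for candidate stages (default 100);
        genes below it are unlikely to be meaningfully expressed.
    floor_mode
        ``"mean_3wat"``: mean of the higher line's three WAT intensities;
        ``"higher_line"``: the higher line's intensity in the depot tested.
    """

    adipose_threshold: float = 1.5
    nonadipose_window: Optional[float] = 1.5
    intensity_floor: float = 100.0
    floor_mode: str = "mean_3wat"
    threshold_inclusive: bool = False
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.adipose_threshold <= 1:
            raise ValidationError("adipose_threshold must exceed 1")
        if self.nonadipose_window is not None and self.nonadipose_window <= 1:
            raise ValidationError("nonadipose_window must exceed 1 (or be None)")
        if self.intensity_floor < 0:
            raise ValidationError("intensity_floor must be >= 0")
        if self.floor_mode not in ("mean_3wat", "higher_line"):
            raise ValidationError(f"unknown floor_mode {self.floor_mode!r}")


#: Table-1-style relaxed criteria: >1.5-fold in the depot, non-adipose within 1.5.
RELAXED = FilterConfig()

#: Stringent candidate criteria: >=2-fold in all 3 WATs, window 2, 100 AU floor.
STRINGENT = FilterConfig(
    adipose_threshold=2.0,
    nonadipose_window=2.0,
    intensity_floor=100.0,
    floor_mode="mean_3wat",
    threshold_inclusive=True,
)


def _passes_threshold(sfc: np.ndarray, cfg: FilterConfig, direction: int) -> np.ndarray:
    signed = sfc * direction
    if cfg.threshold_inclusive:
        return signed >= cfg.adipose_threshold
    return signed > cfg.adipose_threshold


def _window_mask(sfcs: pd.DataFrame, cfg: FilterConfig) -> np.ndarray:
    """True where every non-adipose |fold| is strictly inside the window."""
    if cfg.nonadipose_window is None:
        return np.ones(len(sfcs), dtype=bool)
    missing = [t for t in NON_ADIPOSE if t not in sfcs.columns]
    if missing:
        raise ValidationError(f"study lacks non-adipose tissue column {missing[0]!r}")
    return (sfcs[list(NON_ADIPOSE)].abs() < cfg.nonadipose_window).all(axis=1).to_numpy()


def depot_filter(
    study: ExpressionStudy,
    depot: str,
    cfg: FilterConfig = RELAXED,
    sfcs: Optional[pd.DataFrame] = None,
) -> tuple[list[str], list[str]]:
    """Probes divergent in one white adipose depot, split by direction.

    Returns ``(up_in_F, up_in_L)`` probe-id lists, in matrix order.
    """
    if depot not in WAT_DEPOTS:
        raise ValidationError(f"depot must be one of {WAT_DEPOTS}, got {depot!r}")
    if sfcs is None:
        sfcs = sfc_table(study, epsilon=cfg.epsilon)
    if depot not in sfcs.columns:
        raise ValidationError(f"study lacks tissue column {depot!r}")
    window_ok = _window_mask(sfcs, cfg)
    sfc = sfcs[depot].to_numpy()
    up_f = _passes_threshold(sfc, cfg, +1) & window_ok
    up_l = _passes_threshold(sfc, cfg, -1) & window_ok
    probes = sfcs.index
    return list(probes[up_f]), list(probes[up_l])


def coordinate_3wat_filter(
    study: ExpressionStudy,
    cfg: FilterConfig = RELAXED,
    sfcs: Optional[pd.DataFrame] = None,
) -> tuple[list[str], list[str]]:
    """Probes passing the depot filter in all three WATs with a common sign."""
    if sfcs is None:
        sfcs = sfc_table(study, epsilon=cfg.epsilon)
    for depot in WAT_DEPOTS:
        if depot not in sfcs.columns:
            raise ValidationError(f"study lacks tissue column {depot!r}")
    window_ok = _window_mask(sfcs, cfg)
    wat = sfcs[list(WAT_DEPOTS)].to_numpy()
    up_f = _passes_threshold(wat, cfg, +1).all(axis=1) & window_ok
    up_l = _passes_threshold(wat, cfg, -1).all(axis=1) & window_ok
    probes = sfcs.index
    return list(probes[up_f]), list(probes[up_l])


def mean_3wat_fold(
    study: ExpressionStudy,
    probe_id: str,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Arithmetic mean of the three WAT signed fold changes for one probe.

    Defined only for sign-consistent folds (as reported for stringent
    candidates); sign-discordant folds raise :class:`ValidationError`.
    """
    sfcs = sfc_table(study, epsilon=epsilon)
    if probe_id not in sfcs.index:
        raise ValidationError(f"unknown probe {probe_id!r}")
    folds = sfcs.loc[probe_id, list(WAT_DEPOTS)].to_numpy(float)
    signs = np.sign(folds)
    if not (np.all(signs > 0) or np.all(signs < 0)):
        raise ValidationError(
            f"probe {probe_id!r}: sign-discordant WAT folds {folds.tolist()}; "
            "mean 3-WAT fold undefined"
        )
    return float(folds.mean())


@dataclass
class CandidateTable:
    """Probes surviving one named filter stage, with display metadata.

    ``up_f``/``up_l`` map a depot scope (``SC``, ``EPI``, ``MES`` or
    ``3WAT``) to the ordered probe-id list selected at that scope.
    ``mean_3wat`` holds the mean 3-WAT signed fold for probes in a 3WAT
    scope (unrounded; rounding is display-only).
    """

    stage: str
    config: FilterConfig
    up_f: dict[str, list[str]] = field(default_factory=dict)
    up_l: dict[str, list[str]] = field(default_factory=dict)
    mean_3wat: dict[str, float] = field(default_factory=dict)
    sfcs: Optional[pd.DataFrame] = None

    def lists(self) -> dict[tuple[str, str], list[str]]:
        out = {}
        for scope, probes in self.up_f.items():
            out[("up_F", scope)] = probes
        for scope, probes in self.up_l.items():
            out[("up_L", scope)] = probes
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: stage, direction, scope, probe, folds."""
        rows = []
        for (direction, scope), probes in self.lists().items():
            for p in probes:
                row = {
                    "stage": self.stage,
                    "direction": direction,
                    "scope": scope,
                    "probe_id": p,
                }
                if self.sfcs is not None:
                    for t in self.sfcs.columns:
                        row[f"sfc_{t}"] = self.sfcs.at[p, t]
                if p in self.mean_3wat:
                    row["mean_3wat_fold"] = self.mean_3wat[p]
                rows.append(row)
        return pd.DataFrame(rows)


def depot_candidates(
    study: ExpressionStudy, cfg: FilterConfig = RELAXED, stage: str = "depot"
) -> CandidateTable:
    """Run the per-depot filter for all three WATs into one candidate table."""
    sfcs = sfc_table(study, epsilon=cfg.epsilon)
    table = CandidateTable(stage=stage, config=cfg, sfcs=sfcs)
    for depot in WAT_DEPOTS:
        up_f, up_l = depot_filter(study, depot, cfg, sfcs=sfcs)
        table.up_f[depot] = up_f
        table.up_l[depot] = up_l
    return table


def coordinate_candidates(
    study: ExpressionStudy, cfg: FilterConfig = RELAXED, stage: str = "3wat"
) -> CandidateTable:
    """Run the coordinate 3-WAT filter into a candidate table (scope ``3WAT``)."""
    sfcs = sfc_table(study, epsilon=cfg.epsilon)
    up_f, up_l = coordinate_3wat_filter(study, cfg, sfcs=sfcs)
    table = CandidateTable(stage=stage, config=cfg, sfcs=sfcs)
    table.up_f["3WAT"] = up_f
    table.up_l["3WAT"] = up_l
    wat = sfcs[list(WAT_DEPOTS)]
    for p in [*up_f, *up_l]:
        table.mean_3wat[p] = float(wat.loc[p].mean())
    return table


def stringent_candidates(
    study: ExpressionStudy, cfg: FilterConfig = STRINGENT
) -> CandidateTable:
    """Stage-3 stringent candidates: >=2-fold in all WATs, window 2, AU floor.

    The floor applies to the higher-expressing line's intensity: by
    default its mean over the three WAT chips must exceed
    ``cfg.intensity_floor`` (100 AU). The resulting table records each
    candidate's unrounded mean 3-WAT fold.
    """
    sfcs = sfc_table(study, epsilon=cfg.epsilon)
    up_f, up_l = coordinate_3wat_filter(study, cfg, sfcs=sfcs)

    wat_f = study.intensities[
        [study.sample_ids(line="F", tissue=t)[0] for t in WAT_DEPOTS]
    ].to_numpy(float)
    wat_l = study.intensities[
        [study.sample_ids(line="L", tissue=t)[0] for t in WAT_DEPOTS]
    ].to_numpy(float)
    idx = {p: i for i, p in enumerate(study.probe_ids)}

    def passes_floor(probe: str, higher: np.ndarray) -> bool:
        if cfg.floor_mode == "mean_3wat":
            return float(higher[idx[probe]].mean()) > cfg.intensity_floor
        return bool((higher[idx[probe]] > cfg.intensity_floor).all())

    up_f = [p for p in up_f if passes_floor(p, wat_f)]
    up_l = [p for p in up_l if passes_floor(p, wat_l)]

    table = CandidateTable(stage="stringent", config=cfg, sfcs=sfcs)
    table.up_f["3WAT"] = up_f
    table.up_l["3WAT"] = up_l
    wat = sfcs[list(WAT_DEPOTS)]
    for p in [*up_f, *up_l]:
        table.mean_3wat[p] = float(wat.loc[p].mean())
    return table
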