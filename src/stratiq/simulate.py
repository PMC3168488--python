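"""Synthetic expression studies with planted truth.

The generator emulates the statistical structure the filter cascade
assumes, starting at the normalized-intensity abstraction (no microarray
physics):

* per-probe baselines on the log2-AU scale, drawn from a normal with
  mean 9 and sd 1.5 (so linear baselines are log-normal around ~500 AU);
* planted gene classes with configurable log2 effects —

  - ``adipose_F_up`` / ``adipose_L_up``: coordinate shift in all three
    white adipose depots, up in the Fat / Lean line respectively;
  - ``depot_specific``: shift in a single WAT depot (assigned cyclically
    over SC, EPI, MES);
  - ``all_tissue_bystander``: shift in all six tissues — the divergent
    but non-adipose-specific pattern a windowed filter must reject;
  - ``diet_amplified``: no snapshot effect; in the quantitative design a
    Fat-vs-Lean difference present on the control diet and larger under
    high-fat feeding;
  - ``null``: no effect anywhere;

* a snapshot design pooling ``pool_size`` individuals per chip (pooling
  modeled as the mean of individual log2 values, i.e. geometric-mean
  pooling of RNA);
* a quantitative design with ``replicates`` independent chips per
  FC/FF/LC/LF group on subcutaneous fat;
* probe placement on a synthetic genome, planted classes landing inside
  QTL intervals with a configured fraction (the remainder strictly
  outside), null/unplanted probes uniform.

All outputs are pure functions of (config, seed); per-stage substreams
are derived from the seed so e.g. annotation draws do not perturb
expression noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .data import (
    LINES,
    TISSUES,
    WAT_DEPOTS,
    ExpressionStudy,
    QtlInterval,
    SampleInfo,
    ValidationError,
)

PLANTED_CLASSES = (
    "adipose_F_up",
    "adipose_L_up",
    "depot_specific",
    "all_tissue_bystander",
    "diet_amplified",
)
CLASSES = PLANTED_CLASSES + ("null",)

# substream tags (second word of the rng seed sequence)
_STREAM_ANNOTATION = 1
_STREAM_BASELINE = 2
_STREAM_SNAPSHOT = 3
_STREAM_QUANTITATIVE = 4


def _default_counts() -> dict[str, int]:
    return {
        "adipose_F_up": 60,
        "adipose_L_up": 30,
        "depot_specific": 45,
        "all_tissue_bystander": 30,
        "diet_amplified": 40,
    }


def _default_effects() -> dict[str, float]:
    # log2 fold effects; 2.0 = 4-fold
    return {
        "adipose_F_up": 2.0,
        "adipose_L_up": 2.0,
        "depot_specific": 2.0,
        "all_tissue_bystander": 2.0,
    }


def _default_genome() -> dict[str, int]:
    return {f"chr{i}": 120_000_000 for i in range(1, 6)}


def _default_intervals() -> list[QtlInterval]:
    return [
        QtlInterval("Fob1", "chr1", 20_000_001, 50_000_000),
        QtlInterval("Fob2", "chr2", 60_000_001, 90_000_000),
        QtlInterval("Fob3", "chr3", 10_000_001, 35_000_000),
        QtlInterval("Fob4", "chr4", 70_000_001, 100_000_000),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the designs the pipeline was built for: a pooled
    (3 individuals/chip) snapshot over 6 tissues, a 4-replicate
    2-line x 2-diet quantitative design, 4-fold planted adipose effects
    and 0.2 log2 units of per-chip noise.
    """

    n_probes: int = 2000
    class_counts: Mapping[str, int] = field(default_factory=_default_counts)
    effects: Mapping[str, float] = field(default_factory=_default_effects)
    #: (control-diet, high-fat-diet) F-vs-L log2 effects for diet_amplified
    diet_amplified_effects: tuple[float, float] = (1.0, 2.0)
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.2
    pool_size: int = 3
    replicates: int = 4
    chromosomes: Mapping[str, int] = field(default_factory=_default_genome)
    qtl_intervals: list[QtlInterval] = field(default_factory=_default_intervals)
    #: fraction of each planted class placed inside QTL intervals
    qtl_fraction: float = 0.3
    #: share of probes given a gene_id (the "known"/"total" split)
    annotated_fraction: float = 0.85

    def __post_init__(self) -> None:
        bad = set(self.class_counts) - set(PLANTED_CLASSES)
        if bad:
            raise ValidationError(f"unknown planted class {sorted(bad)[0]!r}")
        if sum(self.class_counts.values()) > self.n_probes:
            raise ValidationError("planted class counts exceed n_probes")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValidationError("class counts must be non-negative")
        if self.baseline_log2_sd <= 0 or self.noise_sd <= 0:
            raise ValidationError("standard deviations must be positive")
        if not 0.0 <= self.qtl_fraction <= 1.0:
            raise ValidationError("qtl_fraction must lie in [0, 1]")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValidationError("annotated_fraction must lie in [0, 1]")
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")
        if self.qtl_fraction > 0 and not self.qtl_intervals:
            raise ValidationError("qtl_fraction > 0 requires QTL intervals")


def assign_classes(cfg: GeneratorConfig) -> pd.DataFrame:
    """Deterministic probe -> class assignment (no randomness).

    Probes are labelled in a fixed order (classes in :data:`PLANTED_CLASSES`
    order, then null), so the assignment depends only on the config.
    depot_specific probes get a ``depot`` cyclically over SC, EPI, MES.
    """
    n = cfg.n_probes
    probe_ids = [f"probe{i:05d}" for i in range(n)]
    labels = []
    depots = []
    for cls in PLANTED_CLASSES:
        labels.extend([cls] * cfg.class_counts.get(cls, 0))
    labels.extend(["null"] * (n - len(labels)))
    d_i = 0
    for lab in labels:
        if lab == "depot_specific":
            depots.append(WAT_DEPOTS[d_i % 3])
            d_i += 1
        else:
            depots.append("")
    return pd.DataFrame({"class": labels, "depot": depots}, index=pd.Index(probe_ids, name="probe_id"))


def _place_probes(cfg: GeneratorConfig, classes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Chromosome/position placement honouring the in-QTL fraction."""
    chroms = list(cfg.chromosomes)
    lengths = np.array([cfg.chromosomes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    intervals = cfg.qtl_intervals
    iv_lengths = np.array([iv.length_bp for iv in intervals], dtype=float)

    def uniform_position() -> tuple[str, int]:
        ci = rng.choice(len(chroms), p=probs)
        pos = int(rng.integers(1, int(lengths[ci]) + 1))
        return chroms[ci], pos

    def inside_qtl() -> tuple[str, int]:
        wi = rng.choice(len(intervals), p=iv_lengths / iv_lengths.sum())
        iv = intervals[wi]
        pos = int(rng.integers(iv.start_bp, iv.end_bp + 1))
        return iv.chromosome, pos

    def outside_qtl() -> tuple[str, int]:
        for _ in range(10_000):
            chrom, pos = uniform_position()
            if not any(iv.contains(chrom, pos) for iv in intervals):
                return chrom, pos
        raise ValidationError("QTL intervals cover (almost) the whole genome")

    rows = []
    for probe_id, row in classes.iterrows():
        planted = row["class"] != "null"
        if planted and intervals:
            in_qtl = bool(rng.random() < cfg.qtl_fraction)
            chrom, pos = inside_qtl() if in_qtl else outside_qtl()
        else:
            chrom, pos = uniform_position()
            in_qtl = any(iv.contains(chrom, pos) for iv in intervals)
        rows.append((chrom, pos, in_qtl))
    placed = pd.DataFrame(rows, columns=["chromosome", "position_bp", "in_qtl"], index=classes.index)
    return placed


def generate_annotation(
    cfg: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, list[QtlInterval], pd.DataFrame]:
    """Synthetic probe annotation plus the config's QTL intervals.

    Returns ``(annotation, intervals, placement)`` where ``annotation``
    is the probe_id-indexed table (gene_id/symbol blank for the
    unannotated share) and ``placement`` additionally carries the class
    label and in-QTL flag for truth-keeping.
    """
    classes = assign_classes(cfg)
    rng = np.random.default_rng([seed, _STREAM_ANNOTATION])
    placed = _place_probes(cfg, classes, rng)
    n = cfg.n_probes
    annotated = rng.random(n) < cfg.annotated_fraction
    gene_ids = np.where(annotated, [f"gene{i:05d}" for i in range(n)], "")
    symbols = np.where(annotated, [f"Gm{i:05d}" for i in range(n)], "")
    annotation = pd.DataFrame(
        {
            "gene_id": pd.Series(gene_ids, index=classes.index).replace("", np.nan),
            "symbol": pd.Series(symbols, index=classes.index).replace("", np.nan),
            "chromosome": placed["chromosome"],
            "position_bp": placed["position_bp"],
        },
        index=classes.index,
    )
    placement = pd.concat([classes, placed], axis=1)
    return annotation, list(cfg.qtl_intervals), placement


def _baselines(cfg: GeneratorConfig, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed, _STREAM_BASELINE])
    return rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_probes)


def _snapshot_effects(cfg: GeneratorConfig, classes: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-tissue true log2 F-line shift for the snapshot design."""
    eff = pd.DataFrame(0.0, index=classes.index, columns=list(TISSUES))
    for probe_id, row in classes.iterrows():
        cls = row["class"]
        if cls == "adipose_F_up":
            eff.loc[probe_id, list(WAT_DEPOTS)] = cfg.effects.get(cls, 0.0)
        elif cls == "adipose_L_up":
            eff.loc[probe_id, list(WAT_DEPOTS)] = -cfg.effects.get(cls, 0.0)
        elif cls == "depot_specific":
            eff.loc[probe_id, row["depot"]] = cfg.effects.get(cls, 0.0)
        elif cls == "all_tissue_bystander":
            eff.loc[probe_id, list(TISSUES)] = cfg.effects.get(cls, 0.0)
        # diet_amplified and null: no snapshot effect
    return eff


def _truth_frame(cfg: GeneratorConfig, seed: int, effects: pd.DataFrame) -> pd.DataFrame:
    annotation, _, placement = generate_annotation(cfg, seed)
    truth = placement.copy()
    truth["baseline_log2"] = _baselines(cfg, seed)
    for t in effects.columns:
        truth[f"effect_{t}"] = effects[t]
    truth["gene_id"] = annotation["gene_id"]
    truth["symbol"] = annotation["symbol"]
    return truth


def generate_snapshot(
    cfg: GeneratorConfig, seed: int
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """One pooled chip per (line, tissue): a 2 x 6 = 12-column snapshot study.

    Each chip value is the mean of ``pool_size`` individual log2 values
    ``baseline + class effect + N(0, noise_sd)``, exponentiated back to
    linear AU. Deterministic for a given (config, seed).
    """
    classes = assign_classes(cfg)
    effects = _snapshot_effects(cfg, classes)
    baselines = _baselines(cfg, seed)
    rng = np.random.default_rng([seed, _STREAM_SNAPSHOT])

    samples = []
    columns = {}
    for line in LINES:
        for tissue in TISSUES:
            sid = f"{line}_{tissue}"
            samples.append(SampleInfo(sample_id=sid, line=line, tissue=tissue, diet="chow"))
            shift = effects[tissue].to_numpy() if line == "F" else 0.0
            indiv = (
                baselines[:, None]
                + (shift[:, None] if line == "F" else 0.0)
                + rng.normal(0.0, cfg.noise_sd, (cfg.n_probes, cfg.pool_size))
            )
            columns[sid] = 2.0 ** indiv.mean(axis=1)
    intensities = pd.DataFrame(columns, index=classes.index)
    study = ExpressionStudy(intensities=intensities, samples=samples, design="snapshot")
    truth = _truth_frame(cfg, seed, effects)
    return study, truth


def generate_quantitative(
    cfg: GeneratorConfig, seed: int
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Replicated 2-line x 2-diet study of subcutaneous fat (FC/FF/LC/LF).

    The F-line log2 shift on each diet follows the class definition:
    diet_amplified probes use ``diet_amplified_effects`` (control,
    high-fat); other planted classes carry their SC-depot snapshot effect
    on both diets; null probes none. Each chip is an individual (no
    pooling) with independent noise.
    """
    if cfg.replicates < 2:
        raise ValidationError("quantitative design needs >= 2 replicates per group")
    classes = assign_classes(cfg)
    snap_eff = _snapshot_effects(cfg, classes)
    ctl_eff = snap_eff["SC"].to_numpy().copy()
    hf_eff = snap_eff["SC"].to_numpy().copy()
    amplified = (classes["class"] == "diet_amplified").to_numpy()
    ctl_eff[amplified] = cfg.diet_amplified_effects[0]
    hf_eff[amplified] = cfg.diet_amplified_effects[1]

    baselines = _baselines(cfg, seed)
    rng = np.random.default_rng([seed, _STREAM_QUANTITATIVE])

    diet_effects = {"control": ctl_eff, "highfat": hf_eff}
    samples = []
    columns = {}
    for line in LINES:
        for diet in ("control", "highfat"):
            group = f"{line}{'C' if diet == 'control' else 'F'}"
            for rep in range(1, cfg.replicates + 1):
                sid = f"{group}_{rep}"
                samples.append(
                    SampleInfo(sample_id=sid, line=line, tissue="SC", diet=diet, replicate=rep)
                )
                shift = diet_effects[diet] if line == "F" else 0.0
                log2_vals = baselines + shift + rng.normal(0.0, cfg.noise_sd, cfg.n_probes)
                columns[sid] = 2.0 ** log2_vals
    intensities = pd.DataFrame(columns, index=classes.index)
    study = ExpressionStudy(intensities=intensities, samples=samples, design="quantitative")

    truth = _truth_frame(cfg, seed, snap_eff)
    truth["effect_control"] = ctl_eff
    truth["effect_highfat"] = hf_eff
    return study, truth


@dataclass
class RecoveryMetrics:
    """Recovery of a planted class by one candidate list."""

    n_planted: int
    n_recovered: int
    n_selected: int
    sensitivity: float
    fdp: float
    fdp_defined: bool

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.n_planted, self.n_recovered, self.n_selected


def evaluate_recovery(
    selected: Iterable[str],
    truth: pd.DataFrame,
    positive_classes: Iterable[str] = ("adipose_F_up",),
) -> RecoveryMetrics:
    """Sensitivity and false-discovery proportion of a candidate list.

    ``positive_classes`` are the planted classes the list is supposed to
    recover; any selected probe outside them counts as a false discovery.
    An empty list has undefined FDP, reported as 0 with
    ``fdp_defined=False``.
    """
    sel = list(selected)
    stray = [p for p in sel if p not in truth.index]
    if stray:
        raise ValidationError(f"selected probe {stray[0]!r} absent from truth")
    positives = set(truth.index[truth["class"].isin(set(positive_classes))])
    n_planted = len(positives)
    hits = sum(1 for p in sel if p in positives)
    n_sel = len(sel)
    sensitivity = hits / n_planted if n_planted else 0.0
    if n_sel:
        return RecoveryMetrics(n_planted, hits, n_sel, sensitivity, (n_sel - hits) / n_sel, True)
    return RecoveryMetrics(n_planted, hits, 0, sensitivity, 0.0, False)


def recovery_by_class(
    lists: Mapping[str, Iterable[str]],
    truth: pd.DataFrame,
    positive_classes_per_list: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Recovery metrics for several lists at once, one row per list."""
    rows = {}
    for name, sel in lists.items():
        m = evaluate_recovery(sel, truth, positive_classes_per_list.get(name, ("adipose_F_up",)))
        rows[name] = {
            "n_planted": m.n_planted,
            "n_recovered": m.n_recovered,
            "n_selected": m.n_selected,
            "sensitivity": m.sensitivity,
            "fdp": m.fdp,
            "fdp_defined": m.fdp_defined,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "list"
    return out


def write_truth(truth: pd.DataFrame, path) -> None:
    t = truth.copy()
    t.index.name = "probe_id"
    t.to_csv(path, sep="\t")


def class_gene_sets(truth: pd.DataFrame):
    """Gene sets derived from planted classes (for exercising ORA).

    Uses gene symbols of annotated probes; classes with no annotated
    member are dropped.
    """
    from .data import GeneSetCollection

    sets = {}
    for cls in CLASSES:
        members = truth.loc[
            (truth["class"] == cls) & truth["symbol"].notna(), "symbol"
        ]
        if len(members):
            sets[f"planted_{cls}"] = frozenset(members)
    return GeneSetCollection(sets=sets, source="synthetic")
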