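"""End-to-end orchestration of the stratified enrichment pipeline.

Stages run in cascade order, each stage's input/output counts logged as a
"funnel":

1. per-depot fold filter (relaxed threshold, non-adipose window);
2. coordinate 3-WAT filter at the same thresholds;
3. stringent candidates (higher threshold + AU floor) with QTL
   stratification;
4. (optional) replicated quantitative stage: moderated-t contrasts,
   BH-FDR candidate filter and diet-response classification;
plus over-representation analysis of the 3-WAT lists against a supplied
gene-set collection.

Configuration is a single YAML document; all thresholds default to the
cascade's canonical values (1.5 / 2 / 100 AU / adjusted p 0.05 / fold 2).
Outputs are deterministic given inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import de, io, ora, qtl, simulate, snapshot
from .data import ExpressionStudy, GeneSetCollection, QtlInterval, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see :func:`load_config`)."""

    snapshot_matrix: Optional[Path] = None
    snapshot_samples: Optional[Path] = None
    quantitative_matrix: Optional[Path] = None
    quantitative_samples: Optional[Path] = None
    annotation: Optional[Path] = None
    intervals: Optional[Path] = None
    gene_sets: Optional[Path] = None
    out_dir: Optional[Path] = None
    relaxed: snapshot.FilterConfig = field(default_factory=lambda: snapshot.RELAXED)
    stringent: snapshot.FilterConfig = field(default_factory=lambda: snapshot.STRINGENT)
    quant_fold: float = 2.0
    quant_alpha: float = 0.05
    quant_floor: float = 100.0
    ora_min_category: int = 3
    simulate: Optional[simulate.GeneratorConfig] = None
    seed: int = 0


def _filter_config(block: dict[str, Any], base: snapshot.FilterConfig) -> snapshot.FilterConfig:
    kwargs = {}
    for key in ("adipose_threshold", "nonadipose_window", "intensity_floor",
                "floor_mode", "threshold_inclusive", "epsilon"):
        if key in block:
            kwargs[key] = block[key]
    return snapshot.FilterConfig(
        **{**{f: getattr(base, f) for f in (
            "adipose_threshold", "nonadipose_window", "intensity_floor",
            "floor_mode", "threshold_inclusive", "epsilon")}, **kwargs}
    )


def load_config(path) -> PipelineConfig:
    """Load a pipeline YAML config, validating referenced paths."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    root = Path(path).parent
    cfg = PipelineConfig()

    def resolve(key: str) -> Optional[Path]:
        if key not in doc.get("inputs", {}):
            return None
        p = root / doc["inputs"][key]
        if not p.exists():
            raise ValidationError(f"config input {key!r}: no such file {p}")
        return p

    cfg.snapshot_matrix = resolve("snapshot_matrix")
    cfg.snapshot_samples = resolve("snapshot_samples")
    cfg.quantitative_matrix = resolve("quantitative_matrix")
    cfg.quantitative_samples = resolve("quantitative_samples")
    cfg.annotation = resolve("annotation")
    cfg.intervals = resolve("intervals")
    cfg.gene_sets = resolve("gene_sets")
    if "out_dir" in doc:
        cfg.out_dir = root / doc["out_dir"]
    cfg.relaxed = _filter_config(doc.get("relaxed", {}), snapshot.RELAXED)
    cfg.stringent = _filter_config(doc.get("stringent", {}), snapshot.STRINGENT)
    quant = doc.get("quantitative", {})
    cfg.quant_fold = float(quant.get("fold", 2.0))
    cfg.quant_alpha = float(quant.get("alpha", 0.05))
    cfg.quant_floor = float(quant.get("floor", 100.0))
    cfg.ora_min_category = int(doc.get("ora", {}).get("min_category", 3))
    cfg.seed = int(doc.get("seed", 0))
    if "simulate" in doc:
        sim = dict(doc["simulate"])
        if "qtl_intervals" in sim:
            sim["qtl_intervals"] = [
                QtlInterval(**iv) for iv in sim["qtl_intervals"]
            ]
        cfg.simulate = simulate.GeneratorConfig(**sim)
    return cfg


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    depot_table: snapshot.CandidateTable
    coordinate_table: snapshot.CandidateTable
    stringent_table: snapshot.CandidateTable
    funnel: pd.DataFrame
    stratified: Optional[qtl.StratifiedSummary] = None
    de_results: Optional[dict[str, pd.DataFrame]] = None
    quant_selected: Optional[dict[str, dict[str, list[str]]]] = None
    diet_labels: Optional[pd.Series] = None
    enrichment: Optional[pd.DataFrame] = None
    log_lines: list[str] = field(default_factory=list)


def render_funnel(report: RunReport) -> pd.DataFrame:
    """Per-stage, per-direction candidate counts with their thresholds."""
    return report.funnel.copy()


def _funnel_rows(tables: list[snapshot.CandidateTable]) -> pd.DataFrame:
    rows = []
    for order, table in enumerate(tables, start=1):
        cfg = table.config
        for (direction, scope), probes in sorted(table.lists().items()):
            rows.append(
                {
                    "stage_order": order,
                    "stage": table.stage,
                    "direction": direction,
                    "scope": scope,
                    "count": len(probes),
                    "adipose_threshold": cfg.adipose_threshold,
                    "nonadipose_window": cfg.nonadipose_window,
                    "intensity_floor": cfg.intensity_floor
                    if table.stage == "stringent"
                    else None,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full cascade described by ``cfg``.

    In simulation mode (``cfg.simulate`` set) the studies, annotation,
    intervals and class-derived gene sets are generated from the seed;
    otherwise they are loaded from the configured paths (snapshot study
    mandatory, the rest optional).
    """
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    annotation = None
    intervals: list[QtlInterval] = []
    gene_sets: Optional[GeneSetCollection] = None
    quant_study: Optional[ExpressionStudy] = None

    if cfg.simulate is not None:
        say(f"simulation mode: {cfg.simulate.n_probes} probes, seed {cfg.seed}")
        snap_study, truth = simulate.generate_snapshot(cfg.simulate, cfg.seed)
        annotation, intervals, _ = simulate.generate_annotation(cfg.simulate, cfg.seed)
        quant_study, _ = simulate.generate_quantitative(cfg.simulate, cfg.seed)
        gene_sets = simulate.class_gene_sets(truth)
    else:
        if cfg.snapshot_matrix is None or cfg.snapshot_samples is None:
            raise ValidationError("a snapshot study (matrix + sample sheet) is mandatory")
        snap_study = io.load_study(cfg.snapshot_matrix, cfg.snapshot_samples)
        say(f"snapshot study: {snap_study.intensities.shape[0]} probes")
        if cfg.annotation is not None:
            annotation = io.load_annotation(cfg.annotation)
        if cfg.intervals is not None:
            intervals = io.load_intervals(cfg.intervals)
        if cfg.gene_sets is not None:
            gene_sets = io.load_gene_sets(cfg.gene_sets)
        if cfg.quantitative_matrix is not None and cfg.quantitative_samples is not None:
            quant_study = io.load_study(cfg.quantitative_matrix, cfg.quantitative_samples)

    # stage 1: per-depot relaxed filter
    depot_table = snapshot.depot_candidates(snap_study, cfg.relaxed)
    for (direction, scope), probes in sorted(depot_table.lists().items()):
        say(
            f"stage 1 depot {scope} {direction}: {len(probes)} probes "
            f"(> {cfg.relaxed.adipose_threshold}-fold, window {cfg.relaxed.nonadipose_window})"
        )

    # stage 2: coordinate 3-WAT filter
    coord_table = snapshot.coordinate_candidates(snap_study, cfg.relaxed)
    for (direction, scope), probes in sorted(coord_table.lists().items()):
        say(f"stage 2 coordinate {scope} {direction}: {len(probes)} probes")

    # stage 3: stringent candidates
    stringent_table = snapshot.stringent_candidates(snap_study, cfg.stringent)
    for (direction, scope), probes in sorted(stringent_table.lists().items()):
        say(
            f"stage 3 stringent {scope} {direction}: {len(probes)} probes "
            f">= {cfg.stringent.adipose_threshold}-fold, floor "
            f"{cfg.stringent.intensity_floor} AU"
        )

    stratified = None
    if annotation is not None and intervals:
        lists = {
            f"{direction} {scope} ({table.stage})": probes
            for table in (depot_table, coord_table, stringent_table)
            for (direction, scope), probes in table.lists().items()
        }
        stratified = qtl.stratify(lists, annotation, intervals)
        say(f"QTL stratification over {len(intervals)} intervals")

    de_results = None
    selected = None
    labels = None
    if quant_study is not None:
        de_results = de.run_all_contrasts(quant_study)
        selected = de.quantitative_filter(
            de_results, fold=cfg.quant_fold, alpha=cfg.quant_alpha, floor=cfg.quant_floor
        )
        for contrast, d in selected.items():
            say(
                f"stage 4 {contrast}: {len(d['up'])} up, {len(d['down'])} down "
                f"(> {cfg.quant_fold}-fold, padj < {cfg.quant_alpha}, "
                f"floor {cfg.quant_floor} AU)"
            )
        labels = de.classify_all(de_results, alpha=cfg.quant_alpha)
        counts = labels.value_counts().to_dict()
        say(f"diet-response classes: {counts}")

    enrichment = None
    if gene_sets is not None and annotation is not None:
        known = annotation["symbol"].notna()
        universe = set(annotation.loc[known, "symbol"])
        sel_probes = stringent_table.up_f.get("3WAT", [])
        sel_symbols = set(annotation.loc[
            [p for p in sel_probes if p in annotation.index], "symbol"
        ].dropna())
        enrichment = ora.enrich_all(
            sel_symbols & universe, gene_sets, universe, min_category=cfg.ora_min_category
        )
        say(f"ORA: {len(enrichment)} categories tested on {len(sel_symbols)} genes")

    funnel = _funnel_rows([depot_table, coord_table, stringent_table])
    report = RunReport(
        depot_table=depot_table,
        coordinate_table=coord_table,
        stringent_table=stringent_table,
        funnel=funnel,
        stratified=stratified,
        de_results=de_results,
        quant_selected=selected,
        diet_labels=labels,
        enrichment=enrichment,
        log_lines=log,
    )
    if cfg.out_dir is not None:
        write_report(report, cfg.out_dir)
    return report


def write_report(report: RunReport, out_dir) -> None:
    """Write all report tables as TSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.depot_table.to_frame().to_csv(out / "stage1_depot.tsv", sep="\t", index=False)
    report.coordinate_table.to_frame().to_csv(out / "stage2_3wat.tsv", sep="\t", index=False)
    report.stringent_table.to_frame().to_csv(out / "stage3_stringent.tsv", sep="\t", index=False)
    report.funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
    if report.stratified is not None:
        report.stratified.table.to_csv(out / "qtl_stratified.tsv", sep="\t")
    if report.de_results is not None:
        pd.concat(report.de_results.values()).to_csv(out / "quantitative_de.tsv", sep="\t")
    if report.diet_labels is not None:
        report.diet_labels.to_csv(out / "diet_response.tsv", sep="\t")
    if report.enrichment is not None:
        report.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    (out / "run.log").write_text("\n".join(report.log_lines) + "\n")
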