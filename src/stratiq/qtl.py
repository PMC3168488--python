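"""QTL positional filtering and Table-1-style stratified summaries.

Candidates whose gene midpoint falls inside the 95% confidence interval of
a mapped obesity QTL are "positional" (higher causal likelihood); the rest
are "likely secondary". Containment is tested for the gene midpoint only,
with 1-based inclusive interval ends, and all containing intervals are
reported when QTLs overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .data import QtlInterval, validate_annotation

logger = logging.getLogger(__name__)


@dataclass
class QtlAssignment:
    """Per-probe list of QTL names containing the gene midpoint."""

    assignments: dict[str, list[str]]

    def names_for(self, probe_id: str) -> list[str]:
        return self.assignments.get(probe_id, [])

    def in_any(self, probe_id: str) -> bool:
        return bool(self.assignments.get(probe_id))


def _build_trees(intervals: list[QtlInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        # intervaltree is half-open; widen the inclusive end by 1
        trees.setdefault(iv.chromosome, IntervalTree()).addi(
            iv.start_bp, iv.end_bp + 1, iv.name
        )
    return trees


def assign_to_qtls(
    annotation: pd.DataFrame, intervals: list[QtlInterval]
) -> QtlAssignment:
    """Assign every annotated probe to the QTL intervals containing it.

    Probes on chromosomes with no interval (or with missing position) get
    an empty assignment; an unknown chromosome is logged, not an error.
    """
    ann = validate_annotation(annotation)
    names = {iv.name for iv in intervals}
    if len(names) != len(intervals):
        raise ValueError("duplicate interval names")
    trees = _build_trees(intervals)
    known_chroms = set(trees)
    warned: set[str] = set()
    assignments: dict[str, list[str]] = {}
    for probe_id, row in ann.iterrows():
        chrom = row["chromosome"]
        pos = row["position_bp"]
        if pd.isna(chrom) or pd.isna(pos):
            assignments[probe_id] = []
            continue
        if chrom not in known_chroms:
            if intervals and chrom not in warned:
                logger.warning("chromosome %r has no QTL interval", chrom)
                warned.add(chrom)
            assignments[probe_id] = []
            continue
        hits = trees[chrom][int(pos)]
        assignments[probe_id] = sorted(h.data for h in hits)
    return QtlAssignment(assignments=assignments)


@dataclass
class StratifiedSummary:
    """Counts of candidates per (list, QTL) cell in total/known form.

    ``table`` has one row per candidate list and, per QTL plus the
    genome-wide column, the total probe count, the known-gene count
    (probes with a gene_id), and the percentage of the genome-wide value
    on both bases (known/known and total/total), mirroring the ambiguity
    of published summaries of this kind.
    """

    table: pd.DataFrame

    def cell(self, list_name: str, qtl: str) -> tuple[int, int]:
        row = self.table.loc[list_name]
        return int(row[f"{qtl}_total"]), int(row[f"{qtl}_known"])


def stratify(
    candidate_lists: dict[str, list[str]],
    annotation: pd.DataFrame,
    intervals: list[QtlInterval],
) -> StratifiedSummary:
    """Stratify candidate lists by QTL membership.

    Parameters
    ----------
    candidate_lists
        Map list name (e.g. ``"up_F 3WAT"``) -> probe ids.
    annotation
        Probe annotation (gene_id may be missing: such probes count in
        the "total" but not the "known" tallies).
    intervals
        QTL intervals; a probe inside several contributes to each.
    """
    ann = validate_annotation(annotation)
    assignment = assign_to_qtls(ann, intervals)
    known = ann["gene_id"].notna() & (ann["gene_id"].astype(str) != "")
    qtl_names = [iv.name for iv in intervals]

    rows = {}
    for list_name, probes in candidate_lists.items():
        missing = [p for p in probes if p not in ann.index]
        if missing:
            raise ValueError(f"candidate probe {missing[0]!r} missing from annotation")
        total_gw = len(probes)
        known_gw = sum(bool(known.get(p, False)) for p in probes)
        row: dict[str, float] = {
            "genomewide_total": total_gw,
            "genomewide_known": known_gw,
        }
        for q in qtl_names:
            in_q = [p for p in probes if q in assignment.names_for(p)]
            t = len(in_q)
            k = sum(bool(known.get(p, False)) for p in in_q)
            row[f"{q}_total"] = t
            row[f"{q}_known"] = k
            row[f"{q}_pct_known"] = round(100.0 * k / known_gw) if known_gw else 0
            row[f"{q}_pct_total"] = round(100.0 * t / total_gw) if total_gw else 0
        rows[list_name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "list"
    return StratifiedSummary(table=table)


def format_summary(summary: StratifiedSummary, percent_base: str = "known") -> pd.DataFrame:
    """Render a stratified summary as ``total/known (pct)`` display cells."""
    if percent_base not in ("known", "total"):
        raise ValueError("percent_base must be 'known' or 'total'")
    src = summary.table
    qtls = sorted(
        {
            c.rsplit("_", 1)[0]
            for c in src.columns
            if c.endswith("_total") and "_pct" not in c
        }
        - {"genomewide"}
    )
    out = pd.DataFrame(index=src.index)
    out["Genomewide"] = [
        f"{int(r['genomewide_total'])}/{int(r['genomewide_known'])}"
        for _, r in src.iterrows()
    ]
    for q in qtls:
        cells = []
        for _, r in src.iterrows():
            pct = int(r[f"{q}_pct_{percent_base}"])
            cells.append(f"{int(r[f'{q}_total'])}/{int(r[f'{q}_known'])} ({pct})")
        out[q] = cells
    return out
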