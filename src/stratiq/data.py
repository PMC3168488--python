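"""Core domain types for stratified expression studies.

The package operates on normalized (RMA-scale) expression intensities in
linear arbitrary units (AU). Two study designs are supported:

``snapshot``
    One pooled chip per tissue per line across six tissues — three white
    adipose depots (subcutaneous SC, epididymal EPI, mesenteric MES) and
    three non-adipose tissues (liver LIV, muscle MUS, kidney KID). No
    replication: inference is by fold-change thresholds only.

``quantitative``
    A replicated 2-line x 2-diet design on a single depot (subcutaneous
    fat), the four groups being FC, FF, LC, LF (Fat/Lean line x
    control/high-fat diet).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

LINES = ("F", "L")
TISSUES = ("SC", "EPI", "MES", "LIV", "MUS", "KID")
WAT_DEPOTS = ("SC", "EPI", "MES")
NON_ADIPOSE = ("LIV", "MUS", "KID")
DIETS = ("chow", "control", "highfat")

#: default AU floor applied before any ratio of intensities (RMA output is
#: positive; this only guards degenerate synthetic inputs)
DEFAULT_EPSILON = 1.0


class ValidationError(ValueError):
    """Raised when a study, sample sheet or annotation fails validation.

    The message always names the offending probe, sample or line.
    """


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one chip (column of the intensity matrix)."""

    sample_id: str
    line: str
    tissue: str
    diet: str = "chow"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.line not in LINES:
            raise ValidationError(
                f"sample {self.sample_id!r}: line {self.line!r} not in {LINES}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id!r}: tissue {self.tissue!r} not in {TISSUES}"
            )
        if self.diet not in DIETS:
            raise ValidationError(
                f"sample {self.sample_id!r}: diet {self.diet!r} not in {DIETS}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


@dataclass
class ExpressionStudy:
    """An annotated probes x samples intensity matrix for one design.

    Parameters
    ----------
    intensities
        Non-negative linear-AU matrix, index = probe ids, columns = sample
        ids (order matches ``samples``).
    samples
        One :class:`SampleInfo` per column.
    design
        ``"snapshot"`` or ``"quantitative"``. If ``None``, auto-detected:
        any (line, tissue, diet) group with two or more chips makes the
        study quantitative, otherwise it is a snapshot.
    """

    intensities: pd.DataFrame
    samples: list[SampleInfo]
    design: Optional[str] = None

    def __post_init__(self) -> None:
        mat = self.intensities
        if mat.index.duplicated().any():
            dup = mat.index[mat.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if mat.columns.duplicated().any():
            dup = mat.columns[mat.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
        missing = set(mat.columns) - set(ids)
        if missing:
            raise ValidationError(
                f"sample sheet missing matrix column {sorted(missing)[0]!r}"
            )
        extra = set(ids) - set(mat.columns)
        if extra:
            raise ValidationError(
                f"sample sheet describes unknown column {sorted(extra)[0]!r}"
            )
        # align column order to the sample sheet
        self.intensities = mat = mat.loc[:, ids]
        vals = mat.to_numpy()
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"missing intensity at probe {mat.index[r]!r}, sample {mat.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative intensity at probe {mat.index[r]!r}, sample {mat.columns[c]!r}"
            )
        if self.design is None:
            self.design = self._detect_design()
        if self.design not in ("snapshot", "quantitative"):
            raise ValidationError(f"unknown design {self.design!r}")
        self._check_design()

    # -- design handling -------------------------------------------------

    def _groups(self) -> dict[tuple[str, str, str], list[SampleInfo]]:
        groups: dict[tuple[str, str, str], list[SampleInfo]] = {}
        for s in self.samples:
            groups.setdefault((s.line, s.tissue, s.diet), []).append(s)
        return groups

    def _detect_design(self) -> str:
        if any(len(v) > 1 for v in self._groups().values()):
            return "quantitative"
        return "snapshot"

    def _check_design(self) -> None:
        groups = self._groups()
        if self.design == "snapshot":
            for (line, tissue, diet), members in groups.items():
                if len(members) > 1:
                    raise ValidationError(
                        f"snapshot design has {len(members)} chips for "
                        f"({line}, {tissue}, {diet}); expected one"
                    )

    # -- accessors --------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    def sample_ids(
        self,
        line: Optional[str] = None,
        tissue: Optional[str] = None,
        diet: Optional[str] = None,
    ) -> list[str]:
        """Sample ids matching the given (line, tissue, diet) restriction."""
        out = []
        for s in self.samples:
            if line is not None and s.line != line:
                continue
            if tissue is not None and s.tissue != tissue:
                continue
            if diet is not None and s.diet != diet:
                continue
            out.append(s.sample_id)
        return out

    def snapshot_column(self, line: str, tissue: str) -> pd.Series:
        """The single intensity column for (line, tissue) in a snapshot study."""
        ids = self.sample_ids(line=line, tissue=tissue)
        if len(ids) != 1:
            raise ValidationError(
                f"expected one chip for ({line}, {tissue}), found {len(ids)}"
            )
        return self.intensities[ids[0]]

    def log2(self, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
        """log2 intensities after flooring at ``epsilon`` AU."""
        return np.log2(self.intensities.clip(lower=epsilon))

    def tissues_present(self) -> set[str]:
        return {s.tissue for s in self.samples}


@dataclass(frozen=True)
class QtlInterval:
    """A named genomic interval, 1-based inclusive on both ends.

    Typically a QTL 95% confidence interval (Fob1..Fob4 in the obesity
    cross this package was designed around).
    """

    name: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0 or self.end_bp < 0:
            raise ValidationError(f"interval {self.name!r}: negative coordinate")
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"interval {self.name!r}: start {self.start_bp} > end {self.end_bp}"
            )

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start_bp <= position_bp <= self.end_bp
        )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


#: Probe annotation is carried as a DataFrame indexed by probe_id with
#: columns gene_id, symbol, chromosome, position_bp. gene_id/symbol may be
#: missing (probe then counts toward "total" but not "known" summaries).
ANNOTATION_COLUMNS = ("gene_id", "symbol", "chromosome", "position_bp")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a probe-annotation table.

    Accepts a DataFrame either indexed by probe_id or with a probe_id
    column; returns it indexed by probe_id with the canonical columns.
    """
    ann = annotation.copy()
    if "probe_id" in ann.columns:
        ann = ann.set_index("probe_id")
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise ValidationError(f"duplicate probe id {dup!r} in annotation")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    pos = ann["position_bp"]
    if (pos.dropna() < 0).any():
        bad = ann.index[pos < 0][0]
        raise ValidationError(f"negative position for probe {bad!r}")
    return ann[list(ANNOTATION_COLUMNS)]


@dataclass
class GeneSetCollection:
    """Named gene sets (symbols), e.g. GO or KEGG categories from a GMT file."""

    sets: dict[str, frozenset[str]]
    source: Optional[str] = None
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterable[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()
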