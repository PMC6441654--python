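"""Domain types shared by every stage of the pipeline.

The experimental design these types describe is a postharvest time-course:
fruit stored under a chilling control (0 °C) and under two chilling-injury
alleviating treatments — low-temperature conditioning (LTC) and heat
treatment (HT) — sampled at five timepoints (days 1, 2, 4, 6, 8) with three
biological replicates per (condition, timepoint) cell.  Expression is
measured as a gene × sample matrix of raw read counts over a de novo
transcript assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DegflowError

DEFAULT_TIMEPOINTS: tuple[int, ...] = (1, 2, 4, 6, 8)


class Condition(str, Enum):
    """Storage condition: chilling control or one of the two treatments."""

    CONTROL = "control"
    LTC = "LTC"
    HT = "HT"

    @classmethod
    def parse(cls, text: str) -> "Condition":
        t = str(text).strip()
        for c in cls:
            if t.lower() == c.value.lower() or t.upper() == c.name:
                return c
        raise DegflowError("bad-condition", f"unknown condition {text!r}")


TREATMENTS: tuple[Condition, Condition] = (Condition.LTC, Condition.HT)


@dataclass(frozen=True)
class SampleDesign:
    """One RNA-seq library: its condition, sampling day and replicate index."""

    sample_id: str
    condition: Condition
    timepoint_day: int
    replicate: int

    def __post_init__(self):
        if self.replicate < 1:
            raise DegflowError("bad-replicate", f"replicate must be >= 1, got {self.replicate}")


def validate_design(samples: list[SampleDesign]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise DegflowError("duplicate-sample", "sample_id values must be unique")


@dataclass
class CountMatrix:
    """Integer gene × sample raw-count matrix with its sample design."""

    gene_ids: list[str]
    samples: list[SampleDesign]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative integers

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DegflowError("duplicate-gene", "gene_id values must be unique")
        validate_design(self.samples)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise DegflowError(
                "malformed-counts",
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples",
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise DegflowError("malformed-counts", "counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DegflowError("malformed-counts", "counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition.value for s in self.samples],
                "timepoint_day": [s.timepoint_day for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def timepoints(self) -> list[int]:
        return sorted({s.timepoint_day for s in self.samples})

    def columns_for(self, condition: Condition, timepoint_day: int | None = None) -> list[int]:
        """Column indices of the samples in one condition (optionally one day)."""
        return [
            j
            for j, s in enumerate(self.samples)
            if s.condition == condition
            and (timepoint_day is None or s.timepoint_day == timepoint_day)
        ]

    def equals(self, other: "CountMatrix") -> bool:
        """Label-aware equality: invariant to row/column permutation."""
        if set(self.gene_ids) != set(other.gene_ids):
            return False
        if set(self.samples) != set(other.samples):
            return False
        a = self.to_frame().sort_index()
        b = other.to_frame().sort_index()[a.columns]
        return bool(a.equals(b)) and {
            s.sample_id: s for s in self.samples
        } == {s.sample_id: s for s in other.samples}


@dataclass
class ExpressionMatrix:
    """RPKM-normalized expression with the same layout as its source counts."""

    gene_ids: list[str]
    samples: list[SampleDesign]
    rpkm: np.ndarray

    def __post_init__(self):
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        if self.rpkm.shape != (len(self.gene_ids), len(self.samples)):
            raise DegflowError("malformed-counts", "rpkm shape mismatch")
        if np.any(self.rpkm < 0):
            raise DegflowError("malformed-counts", "rpkm must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rpkm, index=self.gene_ids, columns=self.sample_ids)

    def columns_for(self, condition: Condition, timepoint_day: int | None = None) -> list[int]:
        return [
            j
            for j, s in enumerate(self.samples)
            if s.condition == condition
            and (timepoint_day is None or s.timepoint_day == timepoint_day)
        ]

    def timepoints(self) -> list[int]:
        return sorted({s.timepoint_day for s in self.samples})


@dataclass
class GeneMeta:
    """Per-gene annotation: transcript length, TF family, structural-gene flag."""

    gene_id: str
    length_bp: int
    tf_family: str | None = None
    is_structural: bool = False
    annotation: str | None = None

    def __post_init__(self):
        if self.length_bp < 1:
            raise DegflowError("bad-length", f"length_bp must be >= 1 for {self.gene_id}")


@dataclass
class GOMap:
    """Gene → GO-term assignments with optional term labels."""

    pairs: set[tuple[str, str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def genes_for(self, go_id: str) -> set[str]:
        return {g for g, t in self.pairs if t == go_id}

    def terms_for(self, gene_id: str) -> set[str]:
        return {t for g, t in self.pairs if g == gene_id}

    def annotated_genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    def term_ids(self) -> set[str]:
        return {t for _, t in self.pairs}


@dataclass(frozen=True)
class ContigAlignmentSummary:
    """Sense/antisense read totals for one assembled contig.

    Contigs whose sense coverage is a small fraction of antisense coverage
    are likely false transcripts from incomplete second-strand digestion in
    strand-specific library construction.
    """

    contig_id: str
    sense_reads: int
    antisense_reads: int

    def __post_init__(self):
        if self.sense_reads < 0 or self.antisense_reads < 0:
            raise DegflowError("malformed-counts", "read counts must be non-negative")


class Call(str, Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


#: Column schema of the differential-expression results table.
DE_COLUMNS = ["gene_id", "treatment", "timepoint_day", "log2fc", "p_value", "fdr", "call"]


@dataclass
class DEGSet:
    """A filtered DEG list for one treatment.

    ``members`` has columns gene_id, direction ("up"/"down") and support
    (number of qualifying timepoints); ``filter_name`` records which rule
    produced the set.
    """

    treatment: Condition
    members: pd.DataFrame
    filter_name: str

    def __post_init__(self):
        need = {"gene_id", "direction", "support"}
        if not need.issubset(self.members.columns):
            raise DegflowError("malformed-degset", f"members must have columns {sorted(need)}")
        if self.members["gene_id"].duplicated().any():
            raise DegflowError("malformed-degset", "a gene may appear at most once per treatment")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.members["gene_id"])

    def direction_of(self, gene_id: str) -> str:
        row = self.members[self.members["gene_id"] == gene_id]
        return str(row["direction"].iloc[0])


@dataclass
class IndicatorMatrix:
    """The non-negative gene × indicator panel fed to the entropy weighting.

    Default indicators: five per-timepoint mean RPKM values under a treatment
    and five linear fold changes versus the chilling control at the matching
    timepoints (ten indicators per gene).
    """

    r: pd.DataFrame  # index gene_ids, columns indicator labels, all >= 0

    def __post_init__(self):
        if self.r.shape[0] < 2:
            raise DegflowError("too-few-genes", "entropy weighting needs n >= 2 genes")
        if (self.r.values < 0).any():
            raise DegflowError("negative-indicator", "indicator values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def indicator_labels(self) -> list[str]:
        return list(self.r.columns)


@dataclass
class EntropyRanking:
    """Entropy-weight output: per-indicator entropy and weight, per-gene score/rank."""

    matrix: IndicatorMatrix
    H: pd.Series
    w: pd.Series
    score: pd.Series | None = None
    rank: pd.Series | None = None
    sign_convention: str = "conventional"


@dataclass
class CoexpressionNetwork:
    """Bipartite TF ↔ structural-gene network thresholded on Pearson r.

    ``edges`` has columns tf_id, structural_id, r, sign ("pos"/"neg");
    only pairs with r >= pos or r <= neg are present.
    """

    treatment: Condition
    edges: pd.DataFrame
    tf_ids: list[str]
    structural_ids: list[str]
    pos: float = 0.9
    neg: float = -0.9
    n_constant_skipped: int = 0

    def tf_neighbors(self, structural_id: str) -> set[str]:
        sel = self.edges[self.edges["structural_id"] == structural_id]
        return set(sel["tf_id"])
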