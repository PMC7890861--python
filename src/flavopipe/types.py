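"""Core domain containers shared across the pipeline stages.

The central objects are an integer OTU count table (samples x OTUs), the
sample metadata record that drives all subject pairing (subject, study arm,
visit), and small result dataclasses for ANI estimates and gene-content
reports. Tables are backed by pandas DataFrames; everything validates its
invariants at construction time so downstream code can assume them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class Arm(str, enum.Enum):
    """Study arm of the two-beverage intervention."""

    CRANBERRY = "cranberry"
    PLACEBO = "placebo"


class Visit(str, enum.Enum):
    """Sample collection timepoint; UTI-event samples are excluded from analyses."""

    WEEK0 = "week0"
    WEEK24 = "week24"
    UTI_EVENT = "uti_event"


@dataclass(frozen=True)
class SampleRecord:
    """One stool sample: its subject, study arm and collection visit."""

    sample_id: str
    subject_id: str
    arm: Arm
    visit: Visit

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm", Arm(self.arm))
        object.__setattr__(self, "visit", Visit(self.visit))


def validate_metadata(records: Sequence[SampleRecord]) -> None:
    """Check metadata invariants: unique sample ids, one sample per
    (subject, non-UTI visit), and a constant arm within each subject."""
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    seen: dict[tuple[str, Visit], str] = {}
    arms: dict[str, Arm] = {}
    for r in records:
        if r.visit is not Visit.UTI_EVENT:
            key = (r.subject_id, r.visit)
            if key in seen:
                raise ValueError(
                    f"subject {r.subject_id} has two samples at visit {r.visit.value}"
                )
            seen[key] = r.sample_id
        prev = arms.setdefault(r.subject_id, r.arm)
        if prev is not r.arm:
            raise ValueError(f"subject {r.subject_id} appears in both arms")


class OtuTable:
    """Integer OTU count matrix, samples as rows and OTUs as columns.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers indexed by sample id with one
        column per OTU id. Labels must be unique.
    taxonomy
        Optional map from OTU id to a lineage string (free-form; per-rank
        confidences may be embedded by the upstream classifier).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        taxonomy: Optional[Mapping[str, str]] = None,
    ) -> None:
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValueError("OTU table must have at least one sample and one OTU")
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in OTU table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids in OTU table")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("OTU counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.taxonomy = dict(taxonomy) if taxonomy is not None else None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        tax = (
            {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        return OtuTable(self.counts[list(otu_ids)], tax)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative frequencies (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValueError(f"sample {bad!r} has zero total reads")
        return self.counts.div(totals, axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.taxonomy == other.taxonomy

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable({n} samples x {m} OTUs)"


@dataclass(frozen=True)
class PositionCall:
    """A summarized variant/reference call at one reference position.

    ``quality_sum`` is the summed base quality supporting the call and
    ``depth`` the number of high-quality reads (the DP4 sum in the upstream
    caller's terms).
    """

    position: int
    ref_allele: str
    called_allele: str
    quality_sum: int
    depth: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based (>= 1)")
        for allele in (self.ref_allele, self.called_allele):
            if allele not in {"A", "C", "G", "T"}:
                raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}")
        if self.depth < 1:
            raise ValueError("emitted calls must have depth >= 1")

    @property
    def is_variant(self) -> bool:
        return self.called_allele != self.ref_allele


@dataclass(frozen=True)
class AniEstimate:
    """Average nucleotide identity between a reference genome and the
    conspecific sequence in a metagenomic sample."""

    ani: float
    n_passing: int
    n_variant: int
    breadth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_variant > self.n_passing:
            raise ValueError("n_variant cannot exceed n_passing")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on the proxy reference genome.

    Coordinates are 0-based half-open. ``unique_to_reference`` is True when
    the gene's orthogroup contains no gene from any other genome in the
    comparative panel; None when the orthogroup information is unavailable.
    """

    gene_id: str
    start: int
    end: int
    product: str = ""
    cog: str = ""
    go: str = ""
    pfam: str = ""
    orthogroup_id: str = ""
    unique_to_reference: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneCoverage:
    """Breadth of coverage of one gene in one metagenomic sample."""

    gene_id: str
    sample_id: str
    covered_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ValueError("covered_fraction must be in [0, 1]")


class SampleClassLabel(str, enum.Enum):
    OTU41_POS = "otu41_pos"
    OTU41_NEG = "otu41_neg"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SampleClass:
    """Presence/absence class of the focal OTU in one metagenomic sample."""

    sample_id: str
    label: SampleClassLabel
    otu41_relabund: float


@dataclass(frozen=True)
class EnrichmentTable:
    """A 2x2 contingency table with its Fisher-exact result."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float


@dataclass
class AnalysisConfig:
    """Thresholds of the 16S/WMS differential-abundance pipeline.

    Defaults are the study's operating point: rarefy to 5000 reads, drop
    OTUs with < 10 total reads, require >= 25% sample prevalence for OTUs
    and >= 50% per-arm subject prevalence for functional features, add a
    pseudocount of 1 read to OTU fold-changes (0.001 / 0.0001 for pathway /
    gene-family relative abundances) and call significance at BH-adjusted
    p < 0.05.
    """

    rarefaction_depth: int = 5000
    min_total_reads_per_otu: int = 10
    prevalence_fraction: float = 0.25
    feature_prevalence_fraction: float = 0.50
    pathway_pseudocount: float = 0.001
    genefamily_pseudocount: float = 0.0001
    otu_pseudocount: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rarefaction_depth",
            "min_total_reads_per_otu",
            "pathway_pseudocount",
            "genefamily_pseudocount",
            "otu_pseudocount",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("prevalence_fraction", "feature_prevalence_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class CallFilterConfig:
    """Filters applied to per-position calls before ANI estimation.

    ``min_quality_sum`` drops low-confidence calls; positions whose
    high-quality depth exceeds mean + ``depth_sd_multiplier``*SD of the
    quality-passing calls are treated as cross-mapping from more abundant
    organisms and removed. ``min_mapq``/``max_softclip`` document the
    upstream alignment contract (enforced before the calls reach us).
    """

    min_quality_sum: int = 50
    depth_sd_multiplier: float = 3.0
    min_mapq: int = 5
    max_softclip: int = 5
    min_breadth_for_report: float = 0.5

    def __post_init__(self) -> None:
        if min(
            self.min_quality_sum,
            self.depth_sd_multiplier,
            self.min_mapq,
            self.max_softclip,
            self.min_breadth_for_report,
        ) <= 0:
            raise ValueError("all call-filter thresholds must be positive")
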