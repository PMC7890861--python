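"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the pipeline can be exercised without external data:

* a paired two-arm 16S cohort whose subjects have individual compositions
  (log-normal baseline, subject- and visit-level log-normal perturbations)
  with one planted taxon given an arm-specific week-24 multiplier;
* reads pre-aligned to a consensus with allele mixtures at chosen sites and
  independent per-base errors (for the entropy/oligotyping stage);
* per-position reference calls at a specified true divergence, Poisson
  depths, quality sums scaled to depth, and optional high-depth contaminant
  positions (for the ANI stage);
* per-gene coverage matrices with planted characteristic genes covered in
  all OTU-positive and no OTU-negative samples.

All generators are deterministic per seed and return truth records
sufficient to score recovery without re-deriving parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    GeneCoverage,
    GeneRecord,
    OtuTable,
    PositionCall,
    SampleClass,
    SampleClassLabel,
    SampleRecord,
)

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic paired cohort.

    Defaults mirror the analyzed trial subset: 18 cranberry / 16 placebo
    paired subjects, 219 prevalent taxa, per-sample depths between 5000 and
    150000 reads, one planted taxon at ~1% baseline abundance present in
    ~70% of subjects. Its week-24 expected counts are multiplied by
    2^planted_log2_effect in the planted arm (placebo, where the focal OTU
    rose over the trial) and by 2^opposing_log2_effect in the other arm
    (the focal OTU's differential was driven by an increase in one arm and
    a milder decrease in the other).
    Setting planted_log2_effect to 0 disables both, leaving the arms
    exchangeable for null calibration.
    """

    n_subjects_cranberry: int = 18
    n_subjects_placebo: int = 16
    n_taxa: int = 219
    depth_range: tuple[int, int] = (5000, 150_000)
    subject_effect_scale: float = 1.0
    time_effect_scale: float = 0.15
    baseline_sigma: float = 2.0
    planted_taxon_id: str = "OTU41"
    planted_log2_effect: float = 1.5
    opposing_log2_effect: float = -0.75
    planted_arm: str = "placebo"
    planted_prevalence: float = 0.7
    planted_base_abundance: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_cranberry, self.n_subjects_placebo, self.n_taxa) < 1:
            raise ValueError("cohort sizes must be positive")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")
        if self.planted_arm not in {"cranberry", "placebo"}:
            raise ValueError("planted_arm must be 'cranberry' or 'placebo'")
        if not 0 < self.planted_prevalence <= 1:
            raise ValueError("planted_prevalence must be in (0, 1]")

    @property
    def taxon_ids(self) -> list[str]:
        ids = [f"OTU{i + 1}" for i in range(self.n_taxa)]
        if self.planted_taxon_id not in ids:
            raise ValueError(
                f"planted taxon {self.planted_taxon_id!r} not among the {self.n_taxa} taxa"
            )
        return ids


@dataclass
class GenomeSpec:
    """Scaled-down proxy genome for the ANI and gene-content stages."""

    genome_length: int = 100_000
    n_genes: int = 200
    true_divergence: float = 0.007
    mean_depth: float = 20.0
    error_rate: float = 0.001
    n_contaminant_positions: int = 0
    contaminant_depth_factor: float = 10.0
    mean_base_quality: float = 30.0
    planted_characteristic_gene_ids: tuple[str, ...] = ()
    background_core_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_genes < 1:
            raise ValueError("genome_length and n_genes must be positive")
        if not 0 <= self.true_divergence < 0.1:
            raise ValueError("true_divergence must be in [0, 0.1)")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene{i + 1:04d}" for i in range(self.n_genes)]


# ------------------------------------------------------------------- cohort


def generate_cohort(spec: CohortSpec) -> tuple[OtuTable, list[SampleRecord]]:
    """Draw the paired two-arm OTU table and its sample metadata.

    Each subject has a log-normal composition (a shared baseline perturbed
    by a subject-level log-normal effect); week-0 and week-24 samples are
    independent multinomial draws at uniform depths after a smaller
    visit-level perturbation. The planted taxon is carried by roughly
    ``planted_prevalence`` of subjects and its week-24 expected abundance
    is multiplied by 2^planted_log2_effect in the planted arm.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxon_ids
    planted_idx = taxa.index(spec.planted_taxon_id)
    base_log = rng.normal(0.0, spec.baseline_sigma, spec.n_taxa)
    # pin the planted taxon's baseline relative abundance (detectable but
    # minor, like the focal OTU's <=1% share) instead of a random draw
    others = np.exp(np.delete(base_log, planted_idx)).sum()
    frac = spec.planted_base_abundance
    base_log[planted_idx] = np.log(frac / (1.0 - frac) * others)

    subjects = [f"C{i + 1:02d}" for i in range(spec.n_subjects_cranberry)] + [
        f"P{i + 1:02d}" for i in range(spec.n_subjects_placebo)
    ]
    arms = ["cranberry"] * spec.n_subjects_cranberry + [
        "placebo"
    ] * spec.n_subjects_placebo

    rows: dict[str, np.ndarray] = {}
    meta: list[SampleRecord] = []
    for subject, arm in zip(subjects, arms):
        subj_log = base_log + spec.subject_effect_scale * rng.normal(
            0.0, 1.0, spec.n_taxa
        )
        carries_planted = rng.random() < spec.planted_prevalence
        for visit in ("week0", "week24"):
            visit_log = subj_log + spec.time_effect_scale * rng.normal(
                0.0, 1.0, spec.n_taxa
            )
            weights = np.exp(visit_log - visit_log.max())
            if visit == "week24":
                effect = (
                    spec.planted_log2_effect
                    if arm == spec.planted_arm
                    else spec.opposing_log2_effect * (spec.planted_log2_effect != 0)
                )
                weights[planted_idx] *= 2.0 ** effect
            if not carries_planted:
                weights[planted_idx] = 0.0
            probs = weights / weights.sum()
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            sample_id = f"{subject}_{visit}"
            rows[sample_id] = rng.multinomial(depth, probs)
            meta.append(SampleRecord(sample_id, subject, arm, visit))
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    counts.index.name = "sample_id"
    return OtuTable(counts), meta


# ------------------------------------------------------------ aligned reads


def generate_aligned_reads(
    n_reads: int,
    length: int,
    allele_spec: Mapping[int, Mapping[str, float]],
    error_rate: float,
    seed: int,
) -> list[tuple[str, str]]:
    """Equal-length reads from an allele mixture with independent errors.

    ``allele_spec`` maps 1-based positions to {base: frequency} mixtures
    (frequencies summing to 1); all other positions carry the consensus
    base. Each base is then independently substituted with probability
    ``error_rate`` by a uniformly chosen different base.
    """
    if n_reads < 1 or length < 1:
        raise ValueError("n_reads and length must be positive")
    for pos, freqs in allele_spec.items():
        if not 1 <= pos <= length:
            raise ValueError(f"allele position {pos} outside read length")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies at position {pos} must sum to 1")
    rng = np.random.default_rng(seed)
    consensus = rng.choice(BASES, size=length)
    matrix = np.tile(consensus, (n_reads, 1))
    for pos, freqs in sorted(allele_spec.items()):
        alleles = np.array(list(freqs.keys()))
        probs = np.array(list(freqs.values()), dtype=float)
        matrix[:, pos - 1] = rng.choice(alleles, size=n_reads, p=probs / probs.sum())
    if error_rate > 0:
        err_mask = rng.random(matrix.shape) < error_rate
        # uniform among the three non-current bases via offset 1..3 in base order
        offsets = rng.integers(1, 4, size=matrix.shape)
        base_index = np.searchsorted(BASES, matrix)
        matrix = np.where(err_mask, BASES[(base_index + offsets) % 4], matrix)
    return [
        (f"read{i + 1}", "".join(matrix[i])) for i in range(n_reads)
    ]


# ----------------------------------------------------------- position calls


def generate_position_calls(
    spec: GenomeSpec,
) -> tuple[list[PositionCall], dict]:
    """Per-position calls against a reference at the spec's divergence.

    Variant positions are planted as independent Bernoulli(true_divergence)
    draws; depths are Poisson(mean_depth) (positions with zero depth emit
    no call, so breadth < 1 at low depth); the quality sum is the summed
    per-read quality (normal around mean_base_quality per read). The call
    is the consensus of the reads: it flips away from the true allele only
    when erroneous reads form a majority. Optional contaminant positions
    receive ``contaminant_depth_factor`` x mean depth and a variant allele,
    emulating cross-mapping from a more abundant relative.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.genome_length
    ref = rng.choice(BASES, size=length)
    is_variant = rng.random(length) < spec.true_divergence
    depth = rng.poisson(spec.mean_depth, size=length)

    contaminant = np.zeros(length, dtype=bool)
    if spec.n_contaminant_positions:
        idx = rng.choice(length, size=spec.n_contaminant_positions, replace=False)
        contaminant[idx] = True
        depth[idx] = np.maximum(
            depth[idx], (spec.mean_depth * spec.contaminant_depth_factor).__int__()
        )
        is_variant[idx] = True

    covered = depth > 0
    # consensus miscall only when errored reads outnumber correct ones
    n_err = rng.binomial(depth[covered], spec.error_rate)
    miscalled = n_err * 2 > depth[covered]

    true_allele = ref.copy()
    shift = rng.integers(1, 4, size=length)
    base_index = np.searchsorted(BASES, ref)
    variant_allele = BASES[(base_index + shift) % 4]
    true_allele[is_variant] = variant_allele[is_variant]

    called = true_allele[covered].copy()
    if miscalled.any():
        mis_positions = np.flatnonzero(covered)[miscalled]
        mis_shift = rng.integers(1, 4, size=mis_positions.size)
        called[miscalled] = BASES[
            (np.searchsorted(BASES, called[miscalled]) + mis_shift) % 4
        ]

    quality = np.rint(
        depth[covered] * spec.mean_base_quality
        + rng.normal(0.0, 3.0, covered.sum()) * np.sqrt(depth[covered])
    ).astype(int)
    quality = np.maximum(quality, 1)

    positions = np.flatnonzero(covered) + 1
    calls = [
        PositionCall(int(p), str(r), str(c), int(q), int(d))
        for p, r, c, q, d in zip(
            positions, ref[covered], called, quality, depth[covered]
        )
    ]
    truth = {
        "true_ani_nominal": 1.0 - spec.true_divergence,
        "true_ani_realized": 1.0 - float(is_variant.mean()),
        "n_variant_positions": int(is_variant.sum()),
        "genome_length": length,
        "contaminant_positions": set((np.flatnonzero(contaminant) + 1).tolist()),
    }
    return calls, truth


# ------------------------------------------------------------ gene coverage


def generate_gene_coverage(
    spec: GenomeSpec, classes: Sequence[SampleClass]
) -> tuple[list[GeneCoverage], dict]:
    """Per-gene covered fractions across classified samples.

    Planted characteristic genes are well covered (>= 0.8) in every
    OTU-positive sample and poorly covered (< 0.5) in every OTU-negative
    sample. Background genes ignore the classes: a core fraction is covered
    everywhere and the rest have uniform class-independent coverage.
    """
    pos = [c for c in classes if c.label is SampleClassLabel.OTU41_POS]
    neg = [c for c in classes if c.label is SampleClassLabel.OTU41_NEG]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative sample")
    planted = set(spec.planted_characteristic_gene_ids)
    unknown = planted - set(spec.gene_ids)
    if unknown:
        raise ValueError(f"planted gene ids not in genome: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    core = {
        g: rng.random() < spec.background_core_fraction
        for g in spec.gene_ids
        if g not in planted
    }
    coverage: list[GeneCoverage] = []
    for sample in classes:
        for gene_id in spec.gene_ids:
            if gene_id in planted:
                if sample.label is SampleClassLabel.OTU41_POS:
                    frac = rng.uniform(0.8, 1.0)
                elif sample.label is SampleClassLabel.OTU41_NEG:
                    frac = rng.uniform(0.0, 0.5)
                else:
                    frac = rng.uniform(0.0, 0.75)
            elif core[gene_id]:
                frac = rng.uniform(0.8, 1.0)
            else:
                frac = rng.uniform(0.0, 1.0)
            coverage.append(GeneCoverage(gene_id, sample.sample_id, float(frac)))
    truth = {
        "planted_characteristic": planted,
        "core_background": {g for g, flag in core.items() if flag},
    }
    return coverage, truth


def generate_gene_records(
    spec: GenomeSpec,
    transporter_fraction_background: float = 0.1,
    transporter_fraction_planted: float = 0.25,
    gene_length: int = 900,
    seed: Optional[int] = None,
) -> list[GeneRecord]:
    """Annotation records for the synthetic genome: tiled coordinates,
    transporter-keyword products at the given rates (enriched among the
    planted characteristic genes), and uniqueness flags set on planted
    genes plus a sprinkling of background genes."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    planted = set(spec.planted_characteristic_gene_ids)
    genes = []
    for i, gene_id in enumerate(spec.gene_ids):
        start = i * gene_length
        frac = (
            transporter_fraction_planted
            if gene_id in planted
            else transporter_fraction_background
        )
        is_transporter = rng.random() < frac
        product = (
            "ABC transporter permease" if is_transporter else "hypothetical protein"
        )
        unique = gene_id in planted or rng.random() < 0.3
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=start,
                end=start + gene_length,
                product=product,
                orthogroup_id=f"OG{i + 1:04d}",
                unique_to_reference=unique,
            )
        )
    return genes


def generate_sample_classes(
    n_pos: int = 19, n_neg: int = 44, n_unclassified: int = 0, seed: int = 0
) -> list[SampleClass]:
    """Convenience: a classified sample panel matching the study's 19
    OTU-positive / 44 OTU-negative split, with relative abundances drawn
    inside each class's defining band."""
    rng = np.random.default_rng(seed)
    classes = []
    for i in range(n_pos):
        classes.append(
            SampleClass(
                f"pos{i + 1:02d}",
                SampleClassLabel.OTU41_POS,
                float(rng.uniform(0.009, 0.05)),
            )
        )
    for i in range(n_neg):
        classes.append(
            SampleClass(
                f"neg{i + 1:02d}",
                SampleClassLabel.OTU41_NEG,
                float(rng.uniform(0.0, 0.0001)),
            )
        )
    for i in range(n_unclassified):
        classes.append(
            SampleClass(
                f"mid{i + 1:02d}",
                SampleClassLabel.UNCLASSIFIED,
                float(rng.uniform(0.0002, 0.008)),
            )
        )
    return classes
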