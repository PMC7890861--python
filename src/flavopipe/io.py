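"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular formats are TSV. OTU tables follow the convention of the
study's supplementary tables: first column is the OTU id, remaining columns
one per sample; a leading '#' on the header row is tolerated (as is the
HUMAnN2 habit of naming the first column "# Pathway" / "# Gene Family").
Output files start with '#'-prefixed provenance lines (version, seed,
config hash) which every reader skips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    Arm,
    GeneCoverage,
    GeneRecord,
    OtuTable,
    PositionCall,
    SampleRecord,
    Visit,
    validate_metadata,
)

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    """Read a TSV, skipping '#'-prefixed provenance lines but keeping a
    '#'-prefixed header row (first non-blank line with tab characters)."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    start = 0
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#") and "\t" not in line:
            continue
        start = i
        break
    header = lines[start].lstrip("#").lstrip()
    from io import StringIO

    buf = StringIO(header + "".join(lines[start + 1 :]))
    return pd.read_csv(buf, sep="\t", **kwargs)


def provenance_header(seed: Optional[int] = None, config: Optional[Mapping] = None) -> str:
    from . import __version__

    parts = [f"# flavopipe v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"# config_sha256: {digest}")
    return "\n".join(parts) + "\n"


def _write_with_header(path: PathLike, text: str, seed=None, config=None) -> None:
    Path(path).write_text(provenance_header(seed, config) + text)


# ---------------------------------------------------------------- OTU tables


def read_otu_table(path: PathLike) -> OtuTable:
    """Read an OTU count table (rows = OTUs, columns = samples) and return
    it oriented samples x OTUs."""
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "otu_id"
    return OtuTable(df.T)


def write_otu_table(table: OtuTable, path: PathLike, seed=None, config=None) -> None:
    df = table.counts.T
    df.index.name = "#OTU_ID"
    _write_with_header(path, df.to_csv(sep="\t"), seed, config)


# ------------------------------------------------------------------ metadata


def read_metadata(path: PathLike) -> list[SampleRecord]:
    df = _read_tsv(path, dtype=str)
    required = {"sample_id", "subject_id", "arm", "visit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    records = [
        SampleRecord(r.sample_id, r.subject_id, Arm(r.arm), Visit(r.visit))
        for r in df.itertuples()
    ]
    validate_metadata(records)
    return records


def write_metadata(records: Sequence[SampleRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "arm": [r.arm.value for r in records],
            "visit": [r.visit.value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- feature tables


def read_feature_table(path: PathLike) -> pd.DataFrame:
    """Read a functional feature table (features x samples), e.g. HUMAnN2
    pathway or gene-family output; first column is the feature id."""
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"
    return df.astype(float)


# --------------------------------------------------------- distance matrices


def read_distance_matrix(path: PathLike):
    from skbio import DistanceMatrix

    df = _read_tsv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index.astype(str)))


def write_distance_matrix(dm, path: PathLike, seed=None, config=None) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    _write_with_header(path, df.to_csv(sep="\t"), seed, config)


# -------------------------------------------------------------- FASTA/FASTQ


def read_sequences(path: PathLike) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ (by extension) into (id, uppercase sequence) pairs."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ------------------------------------------------------------ position calls


def read_calls_tsv(path: PathLike) -> list[PositionCall]:
    """Read summarized per-position calls: position, ref, alt ('.' when the
    call matches the reference), quality_sum, depth."""
    df = _read_tsv(path, dtype={"ref": str, "alt": str})
    calls = []
    for r in df.itertuples():
        alt = r.alt if isinstance(r.alt, str) and r.alt != "." else r.ref
        calls.append(
            PositionCall(int(r.position), r.ref, alt, int(r.quality_sum), int(r.depth))
        )
    return calls


def write_calls_tsv(calls: Sequence[PositionCall], path: PathLike, seed=None) -> None:
    rows = [
        (
            c.position,
            c.ref_allele,
            c.called_allele if c.is_variant else ".",
            c.quality_sum,
            c.depth,
        )
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["position", "ref", "alt", "quality_sum", "depth"])
    _write_with_header(path, df.to_csv(sep="\t", index=False), seed)


def read_calls_vcf(path: PathLike) -> list[PositionCall]:
    """Thin VCF reader mapping QUAL onto quality_sum and the DP4 sum onto
    depth. Only single-nucleotide records with A/C/G/T alleles are used."""
    calls: list[PositionCall] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        _, pos, _, ref, alt, qual = fields[:6]
        info = fields[7] if len(fields) > 7 else ""
        if len(ref) != 1 or ref not in "ACGT":
            continue
        called = ref if alt in {".", "<*>", ""} else alt.split(",")[0]
        if len(called) != 1 or called not in "ACGT":
            continue
        depth = None
        for kv in info.split(";"):
            if kv.startswith("DP4="):
                depth = sum(int(x) for x in kv[4:].split(","))
            elif kv.startswith("DP=") and depth is None:
                depth = int(kv[3:])
        if depth is None or depth < 1:
            continue
        qual_sum = int(round(float(qual))) if qual not in {".", ""} else 0
        calls.append(PositionCall(int(pos), ref, called, qual_sum, depth))
    return calls


# ------------------------------------------------------------- gene records


_GENE_COLUMNS = [
    "gene_id",
    "start",
    "end",
    "product",
    "cog",
    "go",
    "pfam",
    "orthogroup_id",
    "unique_to_reference",
]


def read_gene_table(path: PathLike) -> list[GeneRecord]:
    """Read a gene annotation table (TSV dialect of the proxy genome's
    annotation supplement). The unique_to_reference column is optional."""
    df = _read_tsv(path, dtype=str)
    missing = {"gene_id", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for r in df.itertuples():
        unique: Optional[bool] = None
        if "unique_to_reference" in df.columns and isinstance(
            getattr(r, "unique_to_reference", None), str
        ):
            unique = r.unique_to_reference.strip().lower() in {"1", "true", "yes"}
        genes.append(
            GeneRecord(
                gene_id=r.gene_id,
                start=int(r.start),
                end=int(r.end),
                product=_opt_str(getattr(r, "product", "")),
                cog=_opt_str(getattr(r, "cog", "")),
                go=_opt_str(getattr(r, "go", "")),
                pfam=_opt_str(getattr(r, "pfam", "")),
                orthogroup_id=_opt_str(getattr(r, "orthogroup_id", "")),
                unique_to_reference=unique,
            )
        )
    return genes


def _opt_str(value) -> str:
    return value if isinstance(value, str) else ""


def write_gene_table(genes: Sequence[GeneRecord], path: PathLike) -> None:
    rows = [
        (
            g.gene_id,
            g.start,
            g.end,
            g.product,
            g.cog,
            g.go,
            g.pfam,
            g.orthogroup_id,
            "" if g.unique_to_reference is None else str(g.unique_to_reference).lower(),
        )
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_records_gff3(path: PathLike) -> list[GeneRecord]:
    """Read gene coordinates + selected attributes from a GFF3 file.

    Uses ID (falling back to locus_tag) as the gene id and the product /
    cog / go / pfam attributes when present. GFF3 is 1-based inclusive;
    records are converted to 0-based half-open.
    """
    genes: list[GeneRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] not in {"gene", "CDS"}:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("locus_tag")
        if gene_id is None:
            continue
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=int(fields[3]) - 1,
                end=int(fields[4]),
                product=attrs.get("product", ""),
                cog=attrs.get("cog", ""),
                go=attrs.get("go", "") or attrs.get("Ontology_term", ""),
                pfam=attrs.get("pfam", ""),
                orthogroup_id=attrs.get("orthogroup", ""),
            )
        )
    return genes


# ------------------------------------------------------------ gene coverage


def read_gene_coverage(path: PathLike) -> list[GeneCoverage]:
    """Read a gene coverage table: gene_id, sample_id, covered_fraction."""
    df = _read_tsv(path)
    return [
        GeneCoverage(str(r.gene_id), str(r.sample_id), float(r.covered_fraction))
        for r in df.itertuples()
    ]


def write_gene_coverage(
    coverage: Sequence[GeneCoverage], path: PathLike, seed=None
) -> None:
    df = pd.DataFrame(
        [(c.gene_id, c.sample_id, c.covered_fraction) for c in coverage],
        columns=["gene_id", "sample_id", "covered_fraction"],
    )
    _write_with_header(path, df.to_csv(sep="\t", index=False), seed)


def coverage_from_depth_table(
    depth: pd.DataFrame, genes: Sequence[GeneRecord]
) -> list[GeneCoverage]:
    """Derive per-gene covered fractions from a per-base depth table.

    ``depth`` has columns position (0-based), sample_id, depth; a gene base
    is covered when its depth is >= 1.
    """
    out: list[GeneCoverage] = []
    for sample_id, sub in depth.groupby("sample_id"):
        covered_positions = set(sub.loc[sub["depth"] >= 1, "position"].astype(int))
        for g in genes:
            n_cov = sum(1 for p in range(g.start, g.end) if p in covered_positions)
            out.append(GeneCoverage(g.gene_id, str(sample_id), n_cov / g.length))
    return out


# ------------------------------------------------------------- result tables


def write_result_table(df: pd.DataFrame, path: PathLike, seed=None, config=None) -> None:
    _write_with_header(path, df.to_csv(sep="\t", index=False), seed, config)
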