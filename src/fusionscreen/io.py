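"""Readers and writers for the five input formats and the result tables.

Formats:

* annotation CSV — ``probeset_id,transcript_cluster_id,gene_symbol,seqname,strand,start,stop``
  (Affymetrix HuEx probeset.csv convention: 1-based inclusive coordinates,
  seqname without a ``chr`` prefix).
* expression TSV — ``probeset_id`` column plus one column of log2 values per
  sample.
* fusion report TSV — FusionMap-like dialect; ``Gene1`` is the 5' partner.
* cytoband file — UCSC ``cytoBand.txt`` (0-based half-open; ``chr`` prefix
  accepted and stripped).
* karyotype TSV — ``sample_id\tchromosome\tarm_band``.

Coordinate-convention conversions (1-based annotation vs 0-based cytobands)
happen only inside :func:`gene_to_cytoband`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Annotation,
    CytobandRecord,
    ExpressionMatrix,
    FusionCandidate,
    KaryotypeBreakpoint,
    ProbeSetAnnotation,
    is_composite_symbol,
)

logger = logging.getLogger(__name__)

FUSION_REPORT_COLUMNS = [
    "FusionID",
    "Sample",
    "Gene1",
    "Gene2",
    "Chr1",
    "Pos1",
    "Chr2",
    "Pos2",
    "SeedCount",
    "RescuedCount",
    "JunctionSeq",
]

ANNOTATION_COLUMNS = [
    "probeset_id",
    "transcript_cluster_id",
    "gene_symbol",
    "seqname",
    "strand",
    "start",
    "stop",
]


def read_annotation(path: str | Path) -> Annotation:
    """Read probe-set annotation and compute per-gene transcript order.

    Transcript order follows genomic start coordinates in 5'->3' transcript
    orientation: ascending on the plus strand, descending on the minus
    strand.  Composite symbols ("A // B", "---") are loaded and flagged, not
    dropped, so downstream filters remain observable.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path}: missing columns {missing}")
    dup = df["probeset_id"][df["probeset_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate probeset_id: {dup.iloc[0]}")

    records: list[ProbeSetAnnotation] = []
    for gene, grp in df.groupby("gene_symbol", sort=False):
        chroms = grp["seqname"].unique()
        strands = grp["strand"].unique()
        if len(chroms) > 1:
            raise ValueError(f"gene {gene!r} has probe sets on mixed chromosomes: {sorted(chroms)}")
        if len(strands) > 1:
            raise ValueError(f"gene {gene!r} has probe sets on mixed strands: {sorted(strands)}")
        strand = strands[0]
        starts = grp["start"].astype(int)
        order = starts.rank(method="first", ascending=(strand == "+")).astype(int)
        composite = is_composite_symbol(gene)
        for (_, row), k in zip(grp.iterrows(), order):
            records.append(
                ProbeSetAnnotation(
                    probeset_id=row["probeset_id"],
                    gene_symbol=gene,
                    chromosome=row["seqname"],
                    strand=strand,
                    start=int(row["start"]),
                    stop=int(row["stop"]),
                    transcript_order=int(k),
                    composite=composite,
                )
            )
    return Annotation(records)


def write_annotation(annotation: Annotation, path: str | Path) -> None:
    rows = [
        {
            "probeset_id": r.probeset_id,
            "transcript_cluster_id": r.gene_symbol,
            "gene_symbol": r.gene_symbol,
            "seqname": r.chromosome,
            "strand": r.strand,
            "start": r.start,
            "stop": r.stop,
        }
        for r in annotation.records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_expression(path: str | Path, annotation: Annotation) -> ExpressionMatrix:
    """Read the log2 expression TSV, restricted to annotated probe sets.

    Rows whose probe set is absent from the annotation are dropped with a
    logged warning giving their count; a non-numeric cell is a hard error
    naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "probeset_id" not in df.columns:
        raise ValueError(f"expression file {path}: missing 'probeset_id' column")
    df = df.set_index("probeset_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"expression file {path}: non-numeric value {df.iloc[i, j]!r} "
            f"at probe set {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    keep = numeric.index.to_series().apply(lambda p: p in annotation)
    n_unmatched = int((~keep).sum())
    if n_unmatched:
        logger.warning("expression file %s: dropped %d rows not present in annotation", path, n_unmatched)
    return ExpressionMatrix(numeric.loc[keep])


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.data.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_fusion_report(path: str | Path, sample_id: str) -> list[FusionCandidate]:
    """Read one sample's fusion candidates from a FusionMap-like TSV.

    Rows are filtered to ``sample_id`` (the report file may be a multi-sample
    concatenation).  Duplicate (gene5, gene3) pairs within the sample are
    collapsed to the record with the highest total read support; the number
    of collapsed rows is retained on the surviving record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FUSION_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fusion report {path}: missing columns {missing}")
    df = df[df["Sample"] == sample_id]
    candidates: list[FusionCandidate] = []
    for (g5, g3), grp in df.groupby(["Gene1", "Gene2"], sort=False):
        support = grp["SeedCount"].astype(int) + grp["RescuedCount"].astype(int)
        best = grp.loc[support.idxmax()]
        junction = best["JunctionSeq"]
        candidates.append(
            FusionCandidate(
                fusion_id=best["FusionID"],
                sample_id=sample_id,
                gene5=g5.strip(),
                gene3=g3.strip(),
                chrom5=best["Chr1"],
                chrom3=best["Chr2"],
                pos5=int(best["Pos1"]),
                pos3=int(best["Pos2"]),
                seed_reads=int(best["SeedCount"]),
                rescued_reads=int(best["RescuedCount"]),
                junction_seq=None if pd.isna(junction) or junction == "" else junction,
                collapsed_rows=len(grp),
            )
        )
    return candidates


def read_all_fusion_candidates(path: str | Path) -> list[FusionCandidate]:
    """All samples' fusion candidates, collapsed per sample as in
    :func:`read_fusion_report`."""
    samples = pd.read_csv(path, sep="\t", dtype=str, usecols=["Sample"])["Sample"].unique()
    out: list[FusionCandidate] = []
    for sample in samples:
        out.extend(read_fusion_report(path, sample))
    return out


def write_fusion_report(candidates: list[FusionCandidate], path: str | Path) -> None:
    rows = [
        {
            "FusionID": c.fusion_id,
            "Sample": c.sample_id,
            "Gene1": c.gene5,
            "Gene2": c.gene3,
            "Chr1": c.chrom5,
            "Chr2": c.chrom3,
            "Pos1": c.pos5,
            "Pos2": c.pos3,
            "SeedCount": c.seed_reads,
            "RescuedCount": c.rescued_reads,
            "JunctionSeq": c.junction_seq or "",
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=FUSION_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cytobands(path: str | Path) -> list[CytobandRecord]:
    """Read a UCSC cytoBand.txt file (chrom, chromStart, chromEnd, name, gieStain).

    A ``chr`` prefix on the chromosome name is stripped; intervals are
    0-based half-open.  Bands on each chromosome must be sorted and
    non-overlapping.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "chromStart", "chromEnd", "name", "gieStain"],
        dtype=str,
    )
    records = [
        CytobandRecord(
            chromosome=row["chrom"].removeprefix("chr"),
            start=int(row["chromStart"]),
            end=int(row["chromEnd"]),
            band_name=row["name"],
        )
        for _, row in df.iterrows()
    ]
    by_chrom: dict[str, list[CytobandRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom, bands in by_chrom.items():
        for a, b in zip(bands, bands[1:]):
            if b.start < a.end:
                raise ValueError(f"cytobands on chr{chrom} overlap or are unsorted: {a.band_name}, {b.band_name}")
    return records


def write_cytobands(records: list[CytobandRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"chr{rec.chromosome}\t{rec.start}\t{rec.end}\t{rec.band_name}\tgneg\n")


def read_karyotype(path: str | Path) -> list[KaryotypeBreakpoint]:
    """Read per-sample karyotype breakpoints (sample_id, chromosome, arm_band)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "chromosome", "arm_band") if c not in df.columns]
    if missing:
        raise ValueError(f"karyotype file {path}: missing columns {missing}")
    return [
        KaryotypeBreakpoint(
            sample_id=row["sample_id"],
            chromosome=row["chromosome"],
            arm_band=row["arm_band"],
        )
        for _, row in df.iterrows()
    ]


def write_karyotype(records: list[KaryotypeBreakpoint], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "chromosome": r.chromosome, "arm_band": r.arm_band}
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample_id", "chromosome", "arm_band"]).to_csv(path, sep="\t", index=False)


def gene_to_cytoband(
    gene_symbol: str,
    annotation: Annotation,
    cytobands: list[CytobandRecord],
) -> tuple[str, str]:
    """Cytoband containing the midpoint of the gene's probe-set span.

    The span is 1-based inclusive (annotation convention); the midpoint is
    converted to a 0-based position for lookup against the half-open band
    intervals, so a midpoint exactly at a band's start belongs to that band.
    """
    chrom = annotation.chromosome_of(gene_symbol)
    lo, hi = annotation.gene_span(gene_symbol)
    midpoint0 = (lo + hi) // 2 - 1  # 0-based
    for band in cytobands:
        if band.chromosome == chrom and band.start <= midpoint0 < band.end:
            return chrom, band.band_name
    raise ValueError(
        f"gene {gene_symbol!r}: midpoint {midpoint0} on chr{chrom} is outside all cytobands"
    )
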