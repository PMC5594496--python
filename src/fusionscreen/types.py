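"""Domain types for the exon-level fusion-candidate screen.

The screen operates on RMA-summarized log2 expression of exon-level probe
sets (Affymetrix Human Exon style: roughly one probe set per exon).  A gene
is represented by its probe sets ordered in transcript orientation, so that
"5' moiety" and "3' moiety" of a candidate split always refer to the
transcript, not the genome: on the minus strand the transcript order is the
reverse of the genomic order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeSetAnnotation",
    "Annotation",
    "ExpressionMatrix",
    "DeviationMatrix",
    "FusionCandidate",
    "KaryotypeBreakpoint",
    "CytobandRecord",
    "BreakpointCandidate",
    "IntegratedHit",
    "ARM_BAND_RE",
    "is_composite_symbol",
]

# arm+band designation: "p13", "q13.11", ...
ARM_BAND_RE = re.compile(r"^[pq]\d+(\.\d+)?$")

#: directions of the 3' moiety relative to the 5' moiety
DIRECTION_3PRIME_DOWN = "3prime_down"
DIRECTION_3PRIME_UP = "3prime_up"


def is_composite_symbol(symbol: str) -> bool:
    """True for multi-gene ("A // B") or placeholder ("---") symbols.

    Probe sets carrying such symbols cannot be attributed to a single gene
    and are excluded from the screen (they stay in the annotation so that
    I/O is lossless and the filter itself is testable).
    """
    return "//" in symbol or symbol.strip() == "---"


@dataclass(frozen=True)
class ProbeSetAnnotation:
    """One exon-level measurement unit mapped onto a gene.

    ``start``/``stop`` are 1-based inclusive genomic coordinates (the native
    convention of the Affymetrix probe-set CSV).  ``transcript_order`` is the
    1-based position of the probe set in 5'->3' transcript orientation within
    its gene; for minus-strand genes it decreases with genomic start.
    """

    probeset_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    start: int
    stop: int
    transcript_order: int = 0
    composite: bool = False

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(
                f"probe set {self.probeset_id}: start {self.start} > stop {self.stop}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"probe set {self.probeset_id}: strand must be '+' or '-', got {self.strand!r}"
            )


class Annotation:
    """Probe-set annotation indexed by gene and by probe set.

    Validates the per-gene invariants: a single chromosome and strand per
    gene, unique probe-set ids, and a transcript order that is a permutation
    of 1..m consistent with genomic order and strand.
    """

    def __init__(self, records: list[ProbeSetAnnotation]):
        by_id: dict[str, ProbeSetAnnotation] = {}
        by_gene: dict[str, list[ProbeSetAnnotation]] = {}
        for rec in records:
            if rec.probeset_id in by_id:
                raise ValueError(f"duplicate probeset_id: {rec.probeset_id}")
            by_id[rec.probeset_id] = rec
            by_gene.setdefault(rec.gene_symbol, []).append(rec)
        for gene, recs in by_gene.items():
            chroms = {r.chromosome for r in recs}
            strands = {r.strand for r in recs}
            if len(chroms) > 1:
                raise ValueError(f"gene {gene!r} has probe sets on mixed chromosomes: {sorted(chroms)}")
            if len(strands) > 1:
                raise ValueError(f"gene {gene!r} has probe sets on mixed strands: {sorted(strands)}")
            recs.sort(key=lambda r: r.transcript_order)
            orders = [r.transcript_order for r in recs]
            if orders != list(range(1, len(recs) + 1)):
                raise ValueError(f"gene {gene!r}: transcript_order is not a permutation of 1..{len(recs)}")
        self._by_id = by_id
        self._by_gene = by_gene

    def __contains__(self, probeset_id: str) -> bool:
        return probeset_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    @property
    def records(self) -> list[ProbeSetAnnotation]:
        out: list[ProbeSetAnnotation] = []
        for gene in self.genes:
            out.extend(self._by_gene[gene])
        return out

    def probeset(self, probeset_id: str) -> ProbeSetAnnotation:
        return self._by_id[probeset_id]

    def probesets_for(self, gene: str) -> list[ProbeSetAnnotation]:
        """Probe sets of *gene* in 5'->3' transcript order."""
        if gene not in self._by_gene:
            raise KeyError(f"unknown gene: {gene!r}")
        return list(self._by_gene[gene])

    def chromosome_of(self, gene: str) -> str:
        return self.probesets_for(gene)[0].chromosome

    def strand_of(self, gene: str) -> str:
        return self.probesets_for(gene)[0].strand

    def is_composite(self, gene: str) -> bool:
        return self.probesets_for(gene)[0].composite

    def gene_span(self, gene: str) -> tuple[int, int]:
        """(min start, max stop) over the gene's probe sets, 1-based inclusive."""
        recs = self.probesets_for(gene)
        return min(r.start for r in recs), max(r.stop for r in recs)


class ExpressionMatrix:
    """log2 probe-set x sample expression values.

    Thin wrapper around a pandas DataFrame (index = probe-set ids, columns =
    sample ids) enforcing finite values and unique labels.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe-set row labels: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample column labels: {dups}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at probe set "
                f"{data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


class DeviationMatrix(ExpressionMatrix):
    """Per-probe-set median-centered expression: each row's median is 0."""


@dataclass(frozen=True)
class FusionCandidate:
    """One RNA-seq-nominated fusion transcript in one sample.

    ``gene5`` contributes the upstream (promoter-proximal) part of the fusion
    transcript, ``gene3`` the downstream part.  Read support mirrors the
    FusionMap report fields (seed reads span the junction; rescued reads are
    re-aligned mates).
    """

    fusion_id: str
    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    pos5: int
    pos3: int
    seed_reads: int
    rescued_reads: int
    junction_seq: str | None = None
    collapsed_rows: int = 1

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError(f"fusion {self.fusion_id}: empty partner gene symbol")
        if self.seed_reads < 0 or self.rescued_reads < 0:
            raise ValueError(f"fusion {self.fusion_id}: negative read counts")
        if self.seed_reads + self.rescued_reads < 1:
            raise ValueError(f"fusion {self.fusion_id}: no supporting reads")


@dataclass(frozen=True)
class KaryotypeBreakpoint:
    """A cytogenetically observed breakpoint at arm+band resolution.

    ``arm_band`` is e.g. "p13" or "q13.1"; karyotypes typically report a
    coarser resolution than the sub-bands genes map to.
    """

    sample_id: str
    chromosome: str
    arm_band: str

    def __post_init__(self) -> None:
        if not ARM_BAND_RE.match(self.arm_band):
            raise ValueError(
                f"malformed cytoband designation {self.arm_band!r} "
                f"(sample {self.sample_id}, chr{self.chromosome})"
            )


@dataclass(frozen=True)
class CytobandRecord:
    """One band of a UCSC-style cytoband table; 0-based half-open interval."""

    chromosome: str
    start: int
    end: int
    band_name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"cytoband {self.chromosome}{self.band_name}: start {self.start} >= end {self.end}"
            )
        if not ARM_BAND_RE.match(self.band_name):
            raise ValueError(f"malformed band name {self.band_name!r} on chr{self.chromosome}")


@dataclass
class BreakpointCandidate:
    """A suggested transcript breakpoint: one gene, one sample, one split.

    The split lies between transcript positions ``split_after`` and
    ``split_after + 1``.  ``score`` is the absolute difference between the
    mean median-centered deviation of the 5' moiety (positions 1..k) and the
    3' moiety (positions k+1..m) in this sample, in log2 units.  ``direction``
    records which moiety is lower: ``3prime_down`` marks the truncation-like
    pattern (the gene would be the 5' partner of a fusion), ``3prime_up`` the
    promoter-capture-like pattern (3' partner).
    """

    gene_symbol: str
    sample_id: str
    split_after: int
    score: float
    direction: str
    rank: int | None = None
    chromosome: str | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("breakpoint score must be nonnegative")
        if self.direction not in (DIRECTION_3PRIME_DOWN, DIRECTION_3PRIME_UP):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass
class IntegratedHit:
    """A top-ranked expression breakpoint matched to an RNA-seq fusion candidate."""

    breakpoint: BreakpointCandidate
    fusion: FusionCandidate
    partner_role: str  # role of the breakpoint gene in the fusion: "5prime" | "3prime"
    orientation_consistent: bool | None = None
    karyotype_concordant: bool | None = None

    def __post_init__(self) -> None:
        if self.breakpoint.sample_id != self.fusion.sample_id:
            raise ValueError("integrated hit crosses samples")
        if self.breakpoint.gene_symbol not in (self.fusion.gene5, self.fusion.gene3):
            raise ValueError("breakpoint gene is not a partner of the matched fusion")
        if self.partner_role not in ("5prime", "3prime"):
            raise ValueError(f"invalid partner_role {self.partner_role!r}")

    @property
    def partner_gene(self) -> str:
        """The other gene of the fusion (not the breakpoint gene)."""
        return self.fusion.gene3 if self.partner_role == "5prime" else self.fusion.gene5
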