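"""Integration of expression breakpoints with RNA-seq fusion candidates
and karyotype breakpoints.

A top-ranked transcript breakpoint supports a fusion candidate when the
same gene, in the same sample, appears as one of the fusion's partners.
Two orthogonal consistency checks follow:

* orientation — a 5' fusion partner loses its 3' end, so its breakpoint
  direction should be ``3prime_down``; a 3' partner gains downstream
  expression from the new promoter, so ``3prime_up``.
* karyotype concordance — the gene's cytoband should match a karyotypically
  recorded breakpoint of the same sample at the karyotype's (coarser)
  band resolution.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import gene_to_cytoband
from .types import (
    Annotation,
    BreakpointCandidate,
    CytobandRecord,
    FusionCandidate,
    IntegratedHit,
    KaryotypeBreakpoint,
    DIRECTION_3PRIME_DOWN,
    DIRECTION_3PRIME_UP,
)

logger = logging.getLogger(__name__)

__all__ = [
    "match_fusions",
    "orientation_check",
    "band_prefix_match",
    "karyotype_concordance",
    "chromosome_subanalysis",
    "summarize",
    "FusionIntegration",
    "IntegrationResults",
]


def match_fusions(
    top_breakpoints: list[BreakpointCandidate],
    fusion_candidates: list[FusionCandidate],
) -> list[IntegratedHit]:
    """Join breakpoints with fusion candidates on (sample, gene).

    Emits one hit per (breakpoint, fusion, role) combination with equal
    sample_id and the breakpoint gene among the fusion's partners.  One
    breakpoint may yield several hits (reciprocal fusions, several
    partners); an intragenic candidate with gene5 == gene3 == the
    breakpoint gene yields one hit per role.  Gene symbols are compared
    after whitespace trimming; no alias resolution.
    """
    by_sample: dict[str, list[FusionCandidate]] = {}
    for fusion in fusion_candidates:
        by_sample.setdefault(fusion.sample_id, []).append(fusion)
    hits: list[IntegratedHit] = []
    for bp in top_breakpoints:
        gene = bp.gene_symbol.strip()
        for fusion in by_sample.get(bp.sample_id, []):
            if gene == fusion.gene5.strip():
                hits.append(IntegratedHit(bp, fusion, "5prime"))
            if gene == fusion.gene3.strip():
                hits.append(IntegratedHit(bp, fusion, "3prime"))
    return hits


def orientation_check(hit: IntegratedHit) -> bool:
    """Does the breakpoint direction fit the gene's role in the fusion?

    True iff the gene is the 5' partner and its 3' moiety is down
    (truncation pattern) or the 3' partner and its 3' moiety is up
    (promoter-capture pattern).
    """
    return (hit.partner_role == "5prime" and hit.breakpoint.direction == DIRECTION_3PRIME_DOWN) or (
        hit.partner_role == "3prime" and hit.breakpoint.direction == DIRECTION_3PRIME_UP
    )


def band_prefix_match(karyotype_band: str, gene_band: str) -> bool:
    """Cytoband match at the karyotype's resolution.

    The karyotype band matches the gene band when it is the same band or a
    coarser parent: "p13" matches "p13.11" (sub-band of p13) but not "p131";
    "p13.3" matches itself and sub-bands such as "p13.31".
    """
    if gene_band == karyotype_band:
        return True
    if not gene_band.startswith(karyotype_band):
        return False
    next_char = gene_band[len(karyotype_band)]
    # "p13" -> sub-bands continue with "."; "p13.3" -> sub-sub-bands append digits
    return next_char == "." or "." in karyotype_band


def karyotype_concordance(
    hit: IntegratedHit,
    annotation: Annotation,
    cytobands: list[CytobandRecord],
    karyotype_records: list[KaryotypeBreakpoint],
) -> bool:
    """Does a karyotype breakpoint of the same sample cover the gene's band?

    True iff some karyotype record of the hit's sample lies on the gene's
    chromosome and its arm+band designation prefix-matches the gene's
    cytoband.  A gene that cannot be mapped to a band yields False with a
    logged warning.
    """
    gene = hit.breakpoint.gene_symbol
    try:
        chrom, gene_band = gene_to_cytoband(gene, annotation, cytobands)
    except (ValueError, KeyError) as exc:
        logger.warning("karyotype concordance: cannot map gene %r to a cytoband (%s)", gene, exc)
        return False
    return any(
        rec.sample_id == hit.breakpoint.sample_id
        and rec.chromosome == chrom
        and band_prefix_match(rec.arm_band, gene_band)
        for rec in karyotype_records
    )


def chromosome_subanalysis(
    ranked: list[BreakpointCandidate],
    chromosome: str,
) -> list[BreakpointCandidate]:
    """Candidates whose gene lies on *chromosome*, global ranks preserved.

    This is the published chromosome-19 style sub-analysis: a restriction
    of the already-ranked list, not a re-ranking.
    """
    return [c for c in ranked if c.chromosome == chromosome]


def _summary_counts(
    breakpoints: list[BreakpointCandidate],
    hits: list[IntegratedHit],
    fusion_genes: set[str],
) -> dict:
    genes = [c.gene_symbol for c in breakpoints]
    unique = set(genes)
    recurrent = {g for g in unique if genes.count(g) >= 2}
    bp_keys = {(c.gene_symbol, c.sample_id, c.split_after) for c in breakpoints}
    events = {
        (h.breakpoint.gene_symbol, h.breakpoint.sample_id, h.fusion.fusion_id)
        for h in hits
        if (h.breakpoint.gene_symbol, h.breakpoint.sample_id, h.breakpoint.split_after) in bp_keys
    }
    matched_genes = {g for g, _, _ in events}
    return {
        "n_breakpoints": len(breakpoints),
        "n_unique_genes": len(unique),
        "n_recurrent_genes": len(recurrent),
        "n_genes_among_fusion_candidates": len(unique & fusion_genes),
        "n_matched_events": len(events),
        "n_matched_genes": len(matched_genes),
    }


def summarize(
    top_breakpoints: list[BreakpointCandidate],
    hits: list[IntegratedHit],
    fusion_candidates: list[FusionCandidate],
    chromosome: str | None = None,
) -> pd.DataFrame:
    """Integration summary for the total set and, optionally, one chromosome.

    Rows: breakpoints analyzed; unique genes; recurrent genes (appearing in
    >= 2 candidates); genes that occur anywhere among the RNA-seq fusion
    candidates; matched events (same gene both a top breakpoint and a fusion
    partner in the same sample, counted per (gene, sample, fusion)); matched
    genes (events de-duplicated by gene).
    """
    fusion_genes = set()
    for f in fusion_candidates:
        fusion_genes.add(f.gene5.strip())
        fusion_genes.add(f.gene3.strip())
    columns = {"total": _summary_counts(top_breakpoints, hits, fusion_genes)}
    if chromosome is not None:
        sub = chromosome_subanalysis(top_breakpoints, chromosome)
        columns[f"chr{chromosome}"] = _summary_counts(sub, hits, fusion_genes)
    return pd.DataFrame(columns)


class FusionIntegration:
    """Model object combining a fitted screen with RNA-seq and karyotype data.

    Parameters
    ----------
    screen_results : ScreenResults
        Fitted transcript-breakpoint screen (its top-K list is matched).
    fusion_candidates : list of FusionCandidate
    karyotype_records : list of KaryotypeBreakpoint, optional
    cytobands : list of CytobandRecord, optional
        Required for karyotype concordance and band annotation.
    """

    def __init__(
        self,
        screen_results,
        fusion_candidates: list[FusionCandidate],
        karyotype_records: list[KaryotypeBreakpoint] | None = None,
        cytobands: list[CytobandRecord] | None = None,
    ):
        self.screen_results = screen_results
        self.fusion_candidates = fusion_candidates
        self.karyotype_records = karyotype_records or []
        self.cytobands = cytobands

    def fit(self, chromosome: str | None = None) -> "IntegrationResults":
        hits = match_fusions(self.screen_results.top, self.fusion_candidates)
        for hit in hits:
            hit.orientation_consistent = orientation_check(hit)
            if self.cytobands is not None and self.karyotype_records:
                hit.karyotype_concordant = karyotype_concordance(
                    hit, self.screen_results.annotation, self.cytobands, self.karyotype_records
                )
        summary = summarize(self.screen_results.top, hits, self.fusion_candidates, chromosome)
        return IntegrationResults(self, hits, summary, chromosome)


class IntegrationResults:
    """Matched hits plus the integration summary table."""

    def __init__(self, model, hits, summary_table, chromosome):
        self.model = model
        self.hits = hits
        self.summary_table = summary_table
        self.chromosome = chromosome

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [h.breakpoint.rank for h in self.hits],
                "gene": [h.breakpoint.gene_symbol for h in self.hits],
                "sample": [h.breakpoint.sample_id for h in self.hits],
                "partner_role": [h.partner_role for h in self.hits],
                "partner_gene": [h.partner_gene for h in self.hits],
                "orientation_consistent": [h.orientation_consistent for h in self.hits],
                "karyotype_concordant": [h.karyotype_concordant for h in self.hits],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().sort_values("rank", kind="stable").to_csv(path, sep="\t", index=False)

    def summary(self) -> pd.DataFrame:
        return self.summary_table
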