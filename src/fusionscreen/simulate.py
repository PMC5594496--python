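"""Synthetic data generator for the fusion-candidate screen.

Emulates the statistical structure the analysis assumes, on a small
synthetic genome, so that every pipeline stage is testable without any
external data:

* an exon-level log2 expression matrix — a per-gene, per-probe-set baseline
  shared across samples plus homoscedastic Gaussian noise (RMA-summarized
  log2 intensities are approximately Gaussian);
* implanted fusion events as step changes in one sample downstream of a
  split, in transcript orientation: truncation events (negative step — the
  gene would be a 5' fusion partner losing its 3' end) and overexpression
  events (positive step — a 3' partner driven by a foreign promoter);
* isoform-switch confounders: the same downstream shift shared by two or
  more samples, mimicking alternative-transcript usage rather than a
  sample-private rearrangement;
* a FusionMap-like report with one supporting row per true event, in the
  correct partner role, plus decoy rows naming genes without any
  expression shift;
* karyotype breakpoint records at arm+band resolution for each true event;
* a cytoband table tiling each synthetic chromosome.

Every draw comes from one seeded generator, so identical configs and seeds
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .types import (
    Annotation,
    CytobandRecord,
    ExpressionMatrix,
    FusionCandidate,
    KaryotypeBreakpoint,
    ProbeSetAnnotation,
)

__all__ = ["SimulationConfig", "SimulatedData", "simulate"]

CHROMOSOMES = ("11", "19", "20")
BAND_NAMES = ("p13.3", "p13.2", "p13.1", "p12", "p11", "q11", "q12", "q13.1", "q13.2", "q13.3")

MANIFEST_COLUMNS = [
    "event_id",
    "event_class",
    "gene",
    "partner_gene",
    "samples",
    "split_after",
    "delta",
    "fusion_id",
    "karyotype_id",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small exon-array cohort: 200 genes of 8-12 probe
    sets on three chromosomes, 12 tumor samples, probe-level noise of
    0.3 log2 units, and 10 truncation plus 10 overexpression events with
    step sizes |Δ| between 2 and 4 log2 units — comfortably above noise,
    as the published example profiles are.  Three isoform confounders and
    eight decoy fusion rows exercise the false-positive paths; 5% of
    non-event genes carry composite symbols to exercise the symbol filter.
    """

    n_genes: int = 200
    probesets_per_gene: tuple[int, int] = (8, 12)
    n_samples: int = 12
    noise_sd: float = 0.3
    n_truncation_events: int = 10
    n_overexpression_events: int = 10
    effect_size_range: tuple[float, float] = (2.0, 4.0)
    n_isoform_confounders: int = 3
    n_decoy_fusions: int = 8
    composite_symbol_fraction: float = 0.05
    n_control_samples: int = 0
    control_shift_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.probesets_per_gene
        if lo < 4:
            raise ValueError("probesets_per_gene minimum must be >= 4 (event genes need a valid split)")
        if lo > hi:
            raise ValueError("probesets_per_gene range is inverted")
        if not 0.0 <= self.composite_symbol_fraction <= 1.0:
            raise ValueError("composite_symbol_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        d_lo, d_hi = self.effect_size_range
        if d_lo <= 0 or d_lo > d_hi:
            raise ValueError("effect_size_range must satisfy 0 < Δmin <= Δmax")


@dataclass
class SimulatedData:
    """All five inputs plus the ground-truth manifest."""

    config: SimulationConfig
    annotation: Annotation
    expression: ExpressionMatrix
    fusion_candidates: list[FusionCandidate]
    karyotype_records: list[KaryotypeBreakpoint]
    cytobands: list[CytobandRecord]
    manifest: pd.DataFrame

    @property
    def tumor_sample_ids(self) -> list[str]:
        return [s for s in self.expression.sample_ids if s.startswith("S")]

    def tumor_expression(self) -> ExpressionMatrix:
        """Expression restricted to tumor samples (the screen's input;
        control runs are only used for QC clustering)."""
        return ExpressionMatrix(self.expression.data[self.tumor_sample_ids])

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input in its native dialect; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.csv",
            "expression": outdir / "expression.tsv",
            "fusion_report": outdir / "fusion_report.tsv",
            "karyotype": outdir / "karyotype.tsv",
            "cytobands": outdir / "cytoBand.txt",
            "manifest": outdir / "manifest.tsv",
            "config": outdir / "sim_config.yaml",
        }
        fio.write_annotation(self.annotation, paths["annotation"])
        fio.write_expression(self.expression, paths["expression"])
        fio.write_fusion_report(self.fusion_candidates, paths["fusion_report"])
        fio.write_karyotype(self.karyotype_records, paths["karyotype"])
        fio.write_cytobands(self.cytobands, paths["cytobands"])
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(vars(self.config), fh, sort_keys=True)
        return paths


def _build_genome(config: SimulationConfig, rng: np.random.Generator):
    """Gene symbols, probe-set annotation and cytobands on 3 chromosomes."""
    n = config.n_genes
    lo, hi = config.probesets_per_gene
    sizes = rng.integers(lo, hi + 1, size=n)
    strands = rng.choice(["+", "-"], size=n)
    symbols = [f"GENE{i + 1:04d}" for i in range(n)]
    n_composite = int(round(config.composite_symbol_fraction * n))
    composite_idx = set(rng.choice(n, size=n_composite, replace=False).tolist()) if n_composite else set()
    for i in composite_idx:
        symbols[i] = f"GENE{i + 1:04d} // LOC{900000 + i}"

    records: list[ProbeSetAnnotation] = []
    cursors = {c: 10_000 for c in CHROMOSOMES}
    next_ps = 3_000_000
    gene_chrom = {}
    for i in range(n):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        gene_chrom[symbols[i]] = chrom
        m = int(sizes[i])
        strand = strands[i]
        starts = [cursors[chrom] + j * 600 for j in range(m)]
        orders = range(1, m + 1) if strand == "+" else range(m, 0, -1)
        for start, order in zip(starts, orders):
            records.append(
                ProbeSetAnnotation(
                    probeset_id=str(next_ps),
                    gene_symbol=symbols[i],
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    stop=start + 99,
                    transcript_order=order,
                    composite=i in composite_idx,
                )
            )
            next_ps += 1
        cursors[chrom] = starts[-1] + 600 + 10_000

    cytobands: list[CytobandRecord] = []
    for chrom in CHROMOSOMES:
        length = cursors[chrom] + 5_000
        width = -(-length // len(BAND_NAMES))  # ceil
        for b, name in enumerate(BAND_NAMES):
            cytobands.append(CytobandRecord(chrom, b * width, (b + 1) * width, name))
    return symbols, Annotation(records), cytobands, composite_idx


def _junction_position(annotation: Annotation, gene: str, split_after: int) -> int:
    """Genomic coordinate between the probe sets flanking the split."""
    recs = annotation.probesets_for(gene)
    a, b = recs[split_after - 1], recs[split_after]
    if annotation.strand_of(gene) == "+":
        return (a.stop + b.start) // 2
    return (b.stop + a.start) // 2


def _random_junction_seq(rng: np.random.Generator, length: int = 24) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate(config: SimulationConfig | None = None) -> SimulatedData:
    """Generate the five inputs and the ground-truth manifest.

    Raises if the config requests more event genes than there are eligible
    (non-composite) genes to host them.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    symbols, annotation, cytobands, composite_idx = _build_genome(config, rng)

    tumor_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    control_ids = [f"N{i + 1:02d}" for i in range(config.n_control_samples)]
    sample_ids = tumor_ids + control_ids

    # baseline per (gene, probe set), shared across samples
    probeset_ids = [r.probeset_id for r in annotation.records]
    base = {}
    control_offset = {}
    for gene in annotation.genes:
        gene_mean = rng.normal(7.0, 1.5)
        control_offset[gene] = rng.normal(0.0, config.control_shift_sd)
        for rec in annotation.probesets_for(gene):
            base[rec.probeset_id] = gene_mean + rng.normal(0.0, 0.5)
    baseline = np.array([base[p] for p in probeset_ids])

    values = np.tile(baseline[:, None], (1, len(sample_ids)))
    if control_ids:
        row_gene = [annotation.probeset(p).gene_symbol for p in probeset_ids]
        offsets = np.array([control_offset[g] for g in row_gene])
        values[:, len(tumor_ids):] += offsets[:, None]
    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    expr_df = pd.DataFrame(values, index=pd.Index(probeset_ids, name="probeset_id"), columns=sample_ids)

    eligible = [s for i, s in enumerate(symbols) if i not in composite_idx]
    n_event_genes = (
        config.n_truncation_events
        + config.n_overexpression_events
        + config.n_isoform_confounders
        + 2 * config.n_decoy_fusions
    )
    # true fusions also need one unshifted partner gene each
    n_needed = n_event_genes + config.n_truncation_events + config.n_overexpression_events
    if n_needed > len(eligible):
        raise ValueError(
            f"config requests {n_needed} distinct event/partner genes but only "
            f"{len(eligible)} eligible genes exist"
        )
    picked = list(rng.choice(eligible, size=n_needed, replace=False))
    n_t, n_o, n_c = config.n_truncation_events, config.n_overexpression_events, config.n_isoform_confounders
    trunc_genes = picked[:n_t]
    over_genes = picked[n_t:n_t + n_o]
    confounder_genes = picked[n_t + n_o:n_t + n_o + n_c]
    decoy_genes = picked[n_t + n_o + n_c:n_t + n_o + n_c + 2 * config.n_decoy_fusions]
    partner_genes = picked[n_t + n_o + n_c + 2 * config.n_decoy_fusions:]

    row_index = {p: i for i, p in enumerate(probeset_ids)}
    col_index = {s: j for j, s in enumerate(sample_ids)}
    d_lo, d_hi = config.effect_size_range

    def implant(gene: str, samples: list[str], delta: float) -> int:
        """Add *delta* to the downstream (3') moiety; returns split_after."""
        recs = annotation.probesets_for(gene)
        m = len(recs)
        split_after = int(rng.integers(2, m - 1))  # 2..m-2: >= 2 probe sets per side
        rows = [row_index[r.probeset_id] for r in recs[split_after:]]
        for s in samples:
            expr_df.iloc[rows, col_index[s]] += delta
        return split_after

    manifest_rows = []
    fusions: list[FusionCandidate] = []
    karyotypes: list[KaryotypeBreakpoint] = []
    event_no = fusion_no = karyo_no = 0

    def next_ids():
        nonlocal event_no, fusion_no, karyo_no
        event_no += 1
        fusion_no += 1
        karyo_no += 1
        return f"E{event_no:03d}", f"F{fusion_no:04d}", f"K{karyo_no:03d}"

    def band_of(gene: str) -> str:
        _, band = fio.gene_to_cytoband(gene, annotation, cytobands)
        return band.split(".")[0]  # karyotype reports arm+band resolution

    for kind, genes, partners_slice in (
        ("truncation", trunc_genes, partner_genes[:n_t]),
        ("overexpression", over_genes, partner_genes[n_t:]),
    ):
        for gene, partner in zip(genes, partners_slice):
            sample = tumor_ids[int(rng.integers(len(tumor_ids)))]
            delta = float(rng.uniform(d_lo, d_hi))
            if kind == "truncation":
                delta = -delta
            split_after = implant(gene, [sample], delta)
            event_id, fusion_id, karyo_id = next_ids()
            pos = _junction_position(annotation, gene, split_after)
            partner_recs = annotation.probesets_for(partner)
            partner_pos = (partner_recs[0].start + partner_recs[-1].stop) // 2
            gene5, gene3 = (gene, partner) if kind == "truncation" else (partner, gene)
            pos5, pos3 = (pos, partner_pos) if kind == "truncation" else (partner_pos, pos)
            fusions.append(
                FusionCandidate(
                    fusion_id=fusion_id,
                    sample_id=sample,
                    gene5=gene5,
                    gene3=gene3,
                    chrom5=annotation.chromosome_of(gene5),
                    chrom3=annotation.chromosome_of(gene3),
                    pos5=pos5,
                    pos3=pos3,
                    seed_reads=int(rng.integers(2, 20)),
                    rescued_reads=int(rng.integers(0, 10)),
                    junction_seq=_random_junction_seq(rng),
                )
            )
            karyotypes.append(
                KaryotypeBreakpoint(
                    sample_id=sample,
                    chromosome=annotation.chromosome_of(gene),
                    arm_band=band_of(gene),
                )
            )
            manifest_rows.append(
                dict(
                    event_id=event_id,
                    event_class=kind,
                    gene=gene,
                    partner_gene=partner,
                    samples=sample,
                    split_after=split_after,
                    delta=delta,
                    fusion_id=fusion_id,
                    karyotype_id=karyo_id,
                )
            )

    for gene in confounder_genes:
        n_shared = int(rng.integers(2, 4))  # >= 2 samples share the shift
        samples = sorted(rng.choice(tumor_ids, size=n_shared, replace=False).tolist())
        delta = float(rng.uniform(d_lo, d_hi)) * (1 if rng.random() < 0.5 else -1)
        split_after = implant(gene, samples, delta)
        event_no += 1
        manifest_rows.append(
            dict(
                event_id=f"E{event_no:03d}",
                event_class="isoform",
                gene=gene,
                partner_gene="",
                samples=";".join(samples),
                split_after=split_after,
                delta=delta,
                fusion_id="",
                karyotype_id="",
            )
        )

    for i in range(config.n_decoy_fusions):
        g5, g3 = decoy_genes[2 * i], decoy_genes[2 * i + 1]
        sample = tumor_ids[int(rng.integers(len(tumor_ids)))]
        fusion_no += 1
        event_no += 1
        recs5, recs3 = annotation.probesets_for(g5), annotation.probesets_for(g3)
        fusions.append(
            FusionCandidate(
                fusion_id=f"F{fusion_no:04d}",
                sample_id=sample,
                gene5=g5,
                gene3=g3,
                chrom5=annotation.chromosome_of(g5),
                chrom3=annotation.chromosome_of(g3),
                pos5=(recs5[0].start + recs5[-1].stop) // 2,
                pos3=(recs3[0].start + recs3[-1].stop) // 2,
                seed_reads=int(rng.integers(1, 6)),
                rescued_reads=int(rng.integers(0, 4)),
                junction_seq=_random_junction_seq(rng),
            )
        )
        manifest_rows.append(
            dict(
                event_id=f"E{event_no:03d}",
                event_class="decoy",
                gene=g5,
                partner_gene=g3,
                samples=sample,
                split_after="",
                delta="",
                fusion_id=f"F{fusion_no:04d}",
                karyotype_id="",
            )
        )

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return SimulatedData(
        config=config,
        annotation=annotation,
        expression=ExpressionMatrix(expr_df),
        fusion_candidates=fusions,
        karyotype_records=karyotypes,
        cytobands=cytobands,
        manifest=manifest,
    )
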