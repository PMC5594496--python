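"""The exon-level transcript-breakpoint outlier screen.

The screen looks for genes in which a single sample's expression changes
abruptly between the 5' and 3' moiety of the transcript relative to the
cohort — the signature of a fusion or truncation event.  Concretely, for
each gene the log2 probe-set expression is median-centered per probe set
across samples; for each sample and each admissible split position k the
statistic is

    score(k) = | mean(d[1..k]) - mean(d[k+1..m]) |

where d are that sample's median-centered deviations over the gene's m
probe sets in transcript order.  A split is admissible when at least
``min_probesets_per_side`` probe sets fall on each side.  Per (gene, sample)
only the best split is kept; candidates are then ranked globally by score
(descending) and the top K selected.

Exposed both as plain operations and as a statsmodels-style model:
:class:`TranscriptBreakpointScreen` built from data, whose :meth:`fit`
returns :class:`ScreenResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import gene_to_cytoband
from .types import (
    Annotation,
    BreakpointCandidate,
    CytobandRecord,
    DeviationMatrix,
    ExpressionMatrix,
    DIRECTION_3PRIME_DOWN,
    DIRECTION_3PRIME_UP,
)

__all__ = [
    "ScreenConfig",
    "median_center",
    "filter_genes",
    "score_splits",
    "rank_candidates",
    "select_top_k",
    "gene_profile",
    "cluster_samples",
    "TranscriptBreakpointScreen",
    "ScreenResults",
]


@dataclass
class ScreenConfig:
    """Tunable parameters of the screen.

    top_k: number of top-ranked breakpoints carried into integration.
    min_probesets_per_side: minimum probe sets required in each moiety;
        2 excludes single-probe-set moieties, which are indistinguishable
        from single-exon noise.
    exclude_composite_symbols: drop genes whose symbol names two genes
        ("A // B") or is the placeholder "---".
    chromosome_filter: if set, restrict the screen to genes on this
        chromosome before ranking (distinct from the post-hoc
        chromosome sub-analysis, which preserves global ranks).
    """

    top_k: int = 1000
    min_probesets_per_side: int = 2
    exclude_composite_symbols: bool = True
    chromosome_filter: str | None = None

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_probesets_per_side < 1:
            raise ValueError("min_probesets_per_side must be >= 1")


def median_center(expr: ExpressionMatrix) -> DeviationMatrix:
    """Subtract the per-probe-set median across samples from each row.

    With fewer than 3 samples the median carries no outlier-robust
    information, so that is a hard error.
    """
    if expr.n_samples < 3:
        raise ValueError(f"median centering requires >= 3 samples, got {expr.n_samples}")
    centered = expr.data.sub(expr.data.median(axis=1), axis=0)
    return DeviationMatrix(centered)


def filter_genes(annotation: Annotation, config: ScreenConfig) -> list[str]:
    """Genes eligible for the screen.

    Removes composite/placeholder symbols (when configured), genes with too
    few probe sets to admit any valid split (fewer than
    2 * min_probesets_per_side), and — when a chromosome filter is set —
    genes on other chromosomes.
    """
    eligible = []
    min_probesets = 2 * config.min_probesets_per_side
    for gene in annotation.genes:
        if config.exclude_composite_symbols and annotation.is_composite(gene):
            continue
        if len(annotation.probesets_for(gene)) < min_probesets:
            continue
        if config.chromosome_filter is not None and annotation.chromosome_of(gene) != config.chromosome_filter:
            continue
        eligible.append(gene)
    return eligible


def score_splits(
    gene: str,
    sample_id: str,
    dev: DeviationMatrix,
    annotation: Annotation,
    min_probesets_per_side: int = 2,
) -> list[tuple[int, float, str]]:
    """Score every admissible split of *gene* for one sample.

    Returns (split_after, score, direction) for each split k with at least
    ``min_probesets_per_side`` probe sets on each side, in increasing k.
    The direction is ``3prime_down`` when the 3' moiety mean is strictly
    below the 5' moiety mean, else ``3prime_up``.  A gene admitting no valid
    split yields an empty list.
    """
    probesets = annotation.probesets_for(gene)
    d = dev.data.loc[[p.probeset_id for p in probesets], sample_id].to_numpy()
    return _score_deviations(d, min_probesets_per_side)


def _score_deviations(d: np.ndarray, min_side: int) -> list[tuple[int, float, str]]:
    m = len(d)
    if m < 2 * min_side:
        return []
    csum = np.cumsum(d)
    total = csum[-1]
    out = []
    for k in range(min_side, m - min_side + 1):
        left = csum[k - 1] / k
        right = (total - csum[k - 1]) / (m - k)
        direction = DIRECTION_3PRIME_DOWN if right < left else DIRECTION_3PRIME_UP
        out.append((k, abs(left - right), direction))
    return out


def _best_split(d: np.ndarray, min_side: int) -> tuple[int, float, str] | None:
    """Best-scoring split for one sample's deviations; ties -> smallest k."""
    scored = _score_deviations(d, min_side)
    if not scored:
        return None
    return max(scored, key=lambda t: (t[1], -t[0]))


def rank_candidates(
    candidates: list[BreakpointCandidate],
    config: ScreenConfig | None = None,
) -> list[BreakpointCandidate]:
    """Globally rank breakpoint candidates by score, descending.

    Ties are broken by (gene_symbol, sample_id, split_after) ascending so
    identical input always produces the identical ranked output.  Ranks are
    assigned 1..N in place (on copies is unnecessary: candidates are mutable
    records owned by the pipeline).
    """
    ranked = sorted(
        candidates,
        key=lambda c: (-c.score, c.gene_symbol, c.sample_id, c.split_after),
    )
    for i, cand in enumerate(ranked, start=1):
        cand.rank = i
    return ranked


def select_top_k(
    ranked: list[BreakpointCandidate],
    config: ScreenConfig,
) -> tuple[list[BreakpointCandidate], dict]:
    """First min(K, N) candidates plus a summary of the selection.

    The reported ``fraction`` is 100 * k_effective / n_total, rounded to one
    decimal (e.g. the top 1000 of 120,099 suggested breakpoints is 0.8%).
    """
    if not ranked:
        raise ValueError("ranked candidate list is empty")
    k_eff = min(config.top_k, len(ranked))
    summary = {
        "n_total_breakpoints": len(ranked),
        "k": k_eff,
        "fraction": round(100.0 * k_eff / len(ranked), 1),
    }
    return ranked[:k_eff], summary


def gene_profile(
    gene: str,
    dev: DeviationMatrix,
    annotation: Annotation,
    flagged_splits: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample deviation series for one gene, in genomic order.

    One row per probe set sorted by genomic start (how the published
    profiles are drawn), one column per sample, plus probe-set metadata.
    ``flagged_splits`` maps sample_id -> split_after (transcript
    coordinates); the probe set immediately 5' of each flagged split is
    marked in a ``split_in:<sample>`` column.
    """
    probesets = annotation.probesets_for(gene)  # transcript order
    table = pd.DataFrame(
        {
            "probeset_id": [p.probeset_id for p in probesets],
            "transcript_order": [p.transcript_order for p in probesets],
            "start": [p.start for p in probesets],
            "stop": [p.stop for p in probesets],
        }
    )
    for sample in dev.sample_ids:
        table[sample] = dev.data.loc[table["probeset_id"], sample].to_numpy()
    for sample, split_after in (flagged_splits or {}).items():
        table[f"split_in:{sample}"] = table["transcript_order"] == split_after
    return table.sort_values("start", kind="stable").reset_index(drop=True)


def cluster_samples(
    expr: ExpressionMatrix,
    annotation: Annotation,
) -> tuple[np.ndarray, list[str]]:
    """QC hierarchical clustering of samples at gene level.

    Gene-level expression is the mean of each gene's probe-set values; the
    sample-sample distance is 1 - Pearson correlation; linkage is average.
    Returns (scipy linkage matrix, sample ids in column order).  A sample
    with zero variance across genes has no defined correlation and is a
    hard error.
    """
    if expr.n_samples < 3:
        raise ValueError(f"clustering requires >= 3 samples, got {expr.n_samples}")
    gene_rows = {}
    for gene in annotation.genes:
        ids = [p.probeset_id for p in annotation.probesets_for(gene) if p.probeset_id in expr.data.index]
        if ids:
            gene_rows[gene] = expr.data.loc[ids].mean(axis=0)
    gene_level = pd.DataFrame(gene_rows).T  # genes x samples
    stds = gene_level.std(axis=0, ddof=0)
    zero_var = stds[stds == 0]
    if not zero_var.empty:
        raise ValueError(f"zero-variance sample(s): {list(zero_var.index)}")
    corr = np.corrcoef(gene_level.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    return linkage, expr.sample_ids


class TranscriptBreakpointScreen:
    """Model object for the transcript-breakpoint outlier screen.

    Parameters
    ----------
    expression : ExpressionMatrix
        RMA-summarized log2 probe-set x sample expression.
    annotation : Annotation
        Probe-set annotation with per-gene transcript order.
    config : ScreenConfig, optional
        Screen parameters; defaults match the published analysis
        (top_k=1000, min 2 probe sets per side, composite symbols excluded).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        annotation: Annotation,
        config: ScreenConfig | None = None,
    ):
        self.expression = expression
        self.annotation = annotation
        self.config = config or ScreenConfig()
        missing = [p for p in expression.probeset_ids if p not in annotation]
        if missing:
            raise ValueError(f"{len(missing)} expression rows lack annotation (e.g. {missing[0]!r})")

    @classmethod
    def from_files(
        cls,
        expression_path,
        annotation_path,
        config: ScreenConfig | None = None,
    ) -> "TranscriptBreakpointScreen":
        from . import io

        annotation = io.read_annotation(annotation_path)
        expression = io.read_expression(expression_path, annotation)
        return cls(expression, annotation, config)

    def fit(self, cytobands: list[CytobandRecord] | None = None) -> "ScreenResults":
        """Run the full screen: center, score, filter, rank, select top K.

        When ``cytobands`` are supplied every candidate is annotated with
        the cytoband of its gene's midpoint.
        """
        dev = median_center(self.expression)
        eligible = filter_genes(self.annotation, self.config)
        min_side = self.config.min_probesets_per_side
        sample_ids = dev.sample_ids
        candidates: list[BreakpointCandidate] = []
        for gene in eligible:
            probesets = self.annotation.probesets_for(gene)
            ids = [p.probeset_id for p in probesets]
            if any(p not in dev.data.index for p in ids):
                continue  # gene not (fully) measured
            block = dev.data.loc[ids].to_numpy()  # m x n_samples, transcript order
            chrom = self.annotation.chromosome_of(gene)
            for j, sample in enumerate(sample_ids):
                best = _best_split(block[:, j], min_side)
                if best is None:
                    continue
                k, score, direction = best
                candidates.append(
                    BreakpointCandidate(
                        gene_symbol=gene,
                        sample_id=sample,
                        split_after=k,
                        score=score,
                        direction=direction,
                        chromosome=chrom,
                    )
                )
        ranked = rank_candidates(candidates, self.config)
        top, summary = select_top_k(ranked, self.config)
        if cytobands is not None:
            for cand in ranked:
                try:
                    _, cand.band = gene_to_cytoband(cand.gene_symbol, self.annotation, cytobands)
                except ValueError:
                    cand.band = None
        return ScreenResults(self, dev, ranked, top, summary)


class ScreenResults:
    """Results of a fitted :class:`TranscriptBreakpointScreen`.

    Attributes
    ----------
    deviations : DeviationMatrix
    ranked : all breakpoint candidates, globally ranked.
    top : the selected top-K candidates.
    selection : dict with n_total_breakpoints, k, fraction (percent).
    """

    def __init__(self, model, deviations, ranked, top, selection):
        self.model = model
        self.deviations = deviations
        self.ranked = ranked
        self.top = top
        self.selection = selection

    @property
    def annotation(self) -> Annotation:
        return self.model.annotation

    def to_frame(self, top_only: bool = True) -> pd.DataFrame:
        """Ranked candidates as a DataFrame in the ranked-candidates dialect."""
        cands = self.top if top_only else self.ranked
        return pd.DataFrame(
            {
                "rank": [c.rank for c in cands],
                "gene_symbol": [c.gene_symbol for c in cands],
                "sample_id": [c.sample_id for c in cands],
                "split_after": [c.split_after for c in cands],
                "score": [c.score for c in cands],
                "direction": [c.direction for c in cands],
                "chromosome": [c.chromosome for c in cands],
                "band": [c.band for c in cands],
            }
        )

    def to_tsv(self, path, top_only: bool = True) -> None:
        self.to_frame(top_only).to_csv(path, sep="\t", index=False, float_format="%.6f")

    def gene_profile(self, gene: str) -> pd.DataFrame:
        """Deviation profile of one gene with this screen's flagged splits."""
        flagged = {
            c.sample_id: c.split_after for c in self.top if c.gene_symbol == gene
        }
        return gene_profile(gene, self.deviations, self.annotation, flagged)

    def plot_gene_profile(self, gene: str, ax=None):
        """Median-centered exon-level profile of *gene*, probe sets in genomic
        order, flagged samples highlighted."""
        import matplotlib.pyplot as plt

        profile = self.gene_profile(gene)
        flagged = {c.sample_id for c in self.top if c.gene_symbol == gene}
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(profile))
        for sample in self.deviations.sample_ids:
            hot = sample in flagged
            ax.plot(
                x,
                profile[sample],
                color="crimson" if hot else "0.6",
                lw=1.8 if hot else 0.8,
                label=sample if hot else None,
                zorder=3 if hot else 2,
            )
        ax.set_xticks(x)
        ax.set_xticklabels(profile["probeset_id"], rotation=90, fontsize=6)
        ax.set_xlabel("probe sets (genomic order)")
        ax.set_ylabel("median-centered log2 expression")
        ax.set_title(gene)
        if flagged:
            ax.legend(fontsize=7)
        return ax

    def summary(self) -> str:
        sel = self.selection
        n_genes = len({c.gene_symbol for c in self.top})
        lines = [
            "Transcript-breakpoint screen",
            "=" * 28,
            f"samples screened:        {self.deviations.n_samples}",
            f"suggested breakpoints:   {sel['n_total_breakpoints']}",
            f"top-K selected:          {sel['k']} ({sel['fraction']}% of suggested)",
            f"unique genes in top-K:   {n_genes}",
            f"min probe sets per side: {self.model.config.min_probesets_per_side}",
        ]
        return "\n".join(lines)
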