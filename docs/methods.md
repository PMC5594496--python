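# Methods

## The screening model

The screen treats each gene as an ordered series of exon-level probe sets
and asks, per sample, whether the series splits into two moieties with
clearly different deviation from the cohort. Expression is assumed to be
RMA-summarized log2 intensity; upstream normalization (background
correction, quantile normalization, probe summarization) is out of scope
and assumed done.

Median-centering per probe set across samples turns each value into a
deviation from the cohort. The median is the robustness device: a single
aberrant sample barely moves it, so a sample-private fusion shows up as a
clean step in that sample's deviations while leaving the others near zero.
This also sets the screen's main assumption: an event must be rare within
the cohort. A shift shared by half the samples moves the median itself and
is attenuated — acceptable for fusion screening, where events are expected
in one or few samples, and the reason isoform switches shared by several
samples are an explicit confounder class in the simulator rather than a
detection target.

The split statistic is the absolute difference of moiety mean deviations,

    score(k, s) = | mean(d[1..k], s) − mean(d[k+1..m], s) |,

maximized over admissible splits k (at least `min_probesets_per_side`
probe sets on each side, default 2). Moiety means are unweighted: probe-set
probe counts are not modeled, as probe-level data is outside the package's
inputs. The statistic is exactly invariant (up to floating-point rounding)
under adding a constant to the whole matrix, and for a noiseless step of
height Δ its maximum is |Δ| at the true split — both are tested properties.

Splits are indexed in transcript orientation, so "3′ moiety" always means
the transcript's 3′ end: for minus-strand genes the probe-set order is the
reverse of genomic order. This is what makes the orientation logic of
fusion integration well-defined (a 5′ partner loses its transcript 3′ end
regardless of strand), while profile exports stay in genomic order, the
convention used for plotting.

## Filtering, ranking, selection

Genes are excluded when their symbol names two genes ("A // B") or is the
placeholder "---" (such probe sets cannot be attributed to one gene), or
when they have fewer than `2 × min_probesets_per_side` probe sets (no
admissible split). Exclusion happens at screen time, not read time: the
annotation loader keeps composite symbols and flags them, so I/O is
lossless and the filter observable.

Per (gene, sample) only the best-scoring split is kept (ties broken toward
the smallest split index): one breakpoint per putative event, so a single
strong event cannot occupy many top-K slots with variants of itself. The
global ranking sorts by score descending with deterministic lexicographic
tie-breaking on (gene, sample, split); byte-identical reruns are a tested
invariant. The selection summary reports K as a percentage of all suggested
breakpoints to one decimal — the worked example being the top 1000 of
120,099 ≈ 0.8%.

## Integration

Matching is an exact join on (sample, trimmed gene symbol) between the
top-K breakpoints and the fusion-candidate list; alias resolution is
deliberately absent, since both sides of the artifact are generated
against the same annotation. Orientation consistency uses the breakpoint's
stored direction only; a junction-position cross-check against the split
coordinate is intentionally left to profile inspection, matching how such
correspondence is normally verified. Karyotype concordance maps the gene
to the cytoband containing the midpoint of its probe-set span and accepts
any same-sample, same-chromosome karyotype breakpoint whose arm+band
designation is the same band or a coarser parent ("p13" covers "p13.11";
"p13.3" covers itself and "p13.31", but "p13" never covers "p131").
Annotation coordinates are treated as 1-based inclusive and the cytoband
table as 0-based half-open; the conversion lives in one function
(`gene_to_cytoband`) so each file format keeps its native convention.

The summary table counts, for the full top-K set and optionally one
chromosome's restriction (global ranks preserved): breakpoints analyzed,
unique genes, recurrent genes (≥ 2 candidates), genes appearing anywhere
among the fusion candidates, matched events (per (gene, sample, fusion))
and matched genes (events de-duplicated by gene).

## Synthetic data

The generator builds a three-chromosome genome ("11", "19", "20" — the
chromosomes where this analysis type concentrates), places genes
round-robin with non-overlapping spans and random strands, and tiles each
chromosome with ten cytobands (p13.3 … q13.3) so band-prefix matching at
both resolutions is exercised. Baselines are drawn per gene (N(7, 1.5²))
plus a per-probe-set offset (N(0, 0.5²)); noise is homoscedastic Gaussian
on the log2 scale, sd 0.3 by default.

Default conditions: 200 genes of 8–12 probe sets, 12 tumor samples, 10
truncation events (Δ ∈ [−4, −2], gene written as the 5′ fusion partner)
and 10 overexpression events (Δ ∈ [2, 4], gene as the 3′ partner), each in
one random sample at a random admissible split, each with one matching
fusion-report row (junction placed between the flanking probe sets) and
one karyotype record at arm+band resolution. Event effects are constant
across downstream probe sets — the idealized step; ramped or partial
effects are not modeled. Defaults the conditions leave open were fixed
once at values that mimic real screens: 3 isoform confounders (the same
downstream shift in ≥ 2 samples, emulating alternative-transcript starts
that masquerade as breakpoints), 8 decoy fusion rows (report entries with
no expression support — real fusion callers emit far more candidates than
have expression corroboration), and 5% composite gene symbols.

What passing tests on this data do *not* show: robustness to
heteroscedastic or correlated probe noise, to partial tumor purity
(diluted steps), to probe sets spanning isoform-specific exons in real
annotation, or to symbol mismatches between array annotation and fusion
caller output. The generator's events are also always sample-private,
so the screen's blindness to high-frequency events is not probed.

## Numerical and design choices

* Scores use prefix sums; equal-score splits resolve to the smallest k;
  direction ties (exactly equal moiety means, score 0) report `3prime_up`.
* Median centering requires ≥ 3 samples; missing values are a hard error
  (RMA output is complete; silent imputation would distort medians).
* The QC clustering uses gene-level means of probe-set values, distance
  1 − Pearson correlation, average linkage, with exact symmetrization of
  the distance matrix before linkage; a zero-variance sample is an error
  naming the sample. The screen itself runs on tumor samples only;
  control runs exist for this QC path.
* Problem sizes in tests and the acceptance script (1000 random oracle
  instances per operation, 20 simulation replicates, the 168-case
  noiseless sweep) were chosen as the smallest sets that exercise every
  code path and give stable rates.

## Known limitations

Promoter-swap fusions that preserve the coding series, fusions in genes
with a single probe set, and events shared by many samples are invisible
to the statistic by construction. The statistic assigns no significance:
ranking is by magnitude only, and K is a budget, not an error-rate
control. Karyotype concordance checks one gene's band; matching both
partners' bands to a rearrangement's two breakpoints is a possible
extension.
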