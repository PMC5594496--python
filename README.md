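# fusionscreen

Fusion genes — hybrids of two previously independent genes created by
chromosomal rearrangement — are hard to find in carcinomas with unstable
genomes: RNA-seq fusion callers nominate thousands of candidates per cohort,
most of them artifacts. `fusionscreen` implements an orthogonal,
expression-based screen for tumor cohorts profiled on exon-level microarrays
(Affymetrix Human Exon style, roughly one probe set per exon), and the
machinery to cross-check its hits against RNA-seq fusion reports and
karyotype breakpoints.

The idea: a transcribed fusion disrupts a gene part-way through its exon
series. In the affected sample, expression of one *moiety* (the 5′ or 3′ end
of the transcript) deviates from the cohort while the other moiety does not.
A 5′ fusion partner loses its 3′ end (expression drops downstream of the
junction); a 3′ partner gains a foreign promoter (expression rises
downstream).

## The statistic

Let `x_ps` be the RMA-summarized log2 expression of probe set `p` in sample
`s`, and `d_ps = x_ps − median_s(x_ps)` the per-probe-set median-centered
deviation. For a gene with probe sets `1..m` in 5′→3′ transcript order (on
the minus strand this reverses genomic order), a candidate *transcript
breakpoint* after position `k` in sample `s` is scored

```
score(k, s) = | mean(d_1s..d_ks) − mean(d_(k+1)s..d_ms) |
```

with direction `3prime_down` or `3prime_up` by which moiety is lower. Splits
need at least 2 probe sets per side; genes with composite ("A // B") or
placeholder ("---") symbols are excluded; per (gene, sample) only the best
split is kept; all candidates are ranked globally by score and the top K
(default 1000) carried forward. Top-ranked breakpoints are then joined with
RNA-seq fusion candidates on (gene, sample), checked for orientation
consistency (5′ partner ⇔ 3′ moiety down, 3′ partner ⇔ 3′ moiety up), and
for concordance with karyotype breakpoints at cytoband resolution
("p13" covers "p13.11").

No real cohort ships with the package. A first-class synthetic-data module
generates all five inputs — expression matrix, probe-set annotation,
FusionMap-like fusion report, karyotype records, UCSC-style cytoband file —
with implanted truncation/overexpression events, isoform-switch confounders
and decoy fusions, plus a ground-truth manifest.

## Worked example

```python
import fusionscreen as fs

sim = fs.simulate(fs.SimulationConfig(seed=1))   # 200 genes, 12 samples, 10+10 events
model = fs.TranscriptBreakpointScreen(sim.tumor_expression(), sim.annotation,
                                      fs.ScreenConfig(top_k=40))
res = model.fit(cytobands=sim.cytobands)
print(res.summary())
out = fs.FusionIntegration(res, sim.fusion_candidates,
                           sim.karyotype_records, sim.cytobands).fit(chromosome="19")
print(out.summary())
```

prints

```
Transcript-breakpoint screen
============================
samples screened:        12
suggested breakpoints:   2280
top-K selected:          40 (1.8% of suggested)
unique genes in top-K:   32
min probe sets per side: 2
                                 total  chr19
n_breakpoints                       40     14
n_unique_genes                      32     11
n_recurrent_genes                    6      2
n_genes_among_fusion_candidates     21      8
n_matched_events                    20      7
n_matched_genes                     20      7
```

The screen suggests one breakpoint per (gene, sample) — 2280 here — and keeps
the 40 best. All 20 implanted fusion events are among them and are matched to
their RNA-seq fusion rows (`n_matched_events`); the chr19 column restricts the
same counts to chromosome 19 genes while preserving global ranks, mirroring a
chromosome-focused sub-analysis. `res.gene_profile(gene)` /
`res.plot_gene_profile(gene)` export the per-gene median-centered profiles in
genomic order that make the step pattern visible.

The same run is available from the shell:

```sh
fusionscreen simulate --outdir sim/ --seed 1
fusionscreen run --config pipeline.yaml          # inputs or a simulation block
fusionscreen profile --gene GENE0042 --annotation sim/annotation.csv \
    --expression sim/expression.tsv --out profile.tsv
```

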