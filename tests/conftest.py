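import numpy as np
import pandas as pd
import pytest

from fusionscreen import (
    Annotation,
    ExpressionMatrix,
    ProbeSetAnnotation,
    SimulationConfig,
    simulate,
)


def make_annotation(genes):
    """Build an Annotation from {gene: (chrom, strand, [starts])} specs.

    Probe sets are 100 bp; transcript order follows strand convention.
    """
    records = []
    ps = 1000
    for gene, (chrom, strand, starts) in genes.items():
        m = len(starts)
        order_of = (
            {s: i + 1 for i, s in enumerate(sorted(starts))}
            if strand == "+"
            else {s: m - i for i, s in enumerate(sorted(starts))}
        )
        for start in starts:
            records.append(
                ProbeSetAnnotation(
                    probeset_id=str(ps),
                    gene_symbol=gene,
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    stop=start + 99,
                    transcript_order=order_of[start],
                    composite="//" in gene or gene.strip() == "---",
                )
            )
            ps += 1
    return Annotation(records)


def make_expression(annotation, sample_ids, fill=7.0):
    """Constant expression matrix covering every annotated probe set."""
    ids = [r.probeset_id for r in annotation.records]
    data = pd.DataFrame(
        np.full((len(ids), len(sample_ids)), fill),
        index=pd.Index(ids, name="probeset_id"),
        columns=sample_ids,
    )
    return ExpressionMatrix(data)


@pytest.fixture
def six_probeset_gene():
    """One + strand gene of six probe sets and three samples; deviations
    settable per test."""
    ann = make_annotation({"GENEA": ("19", "+", [100, 700, 1300, 1900, 2500, 3100])})
    expr = make_expression(ann, ["S1", "S2", "S3"])
    return ann, expr


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic data set, reused read-only."""
    return simulate(SimulationConfig(seed=11))
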