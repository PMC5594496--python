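"""The transcript-breakpoint screen: median-centering, split scoring against
a brute-force oracle, filtering, deterministic ranking, and QC clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given, settings, strategies as st

from fusionscreen import (
    BreakpointCandidate,
    ExpressionMatrix,
    ScreenConfig,
    TranscriptBreakpointScreen,
    cluster_samples,
    filter_genes,
    gene_profile,
    median_center,
    rank_candidates,
    score_splits,
    select_top_k,
)
from fusionscreen.screen import _best_split

from conftest import make_annotation, make_expression


def brute_force_scores(deviations, min_side):
    """Independent oracle: moiety means recomputed with plain Python sums."""
    m = len(deviations)
    out = []
    for k in range(min_side, m - min_side + 1):
        left = sum(deviations[:k]) / k
        right = sum(deviations[k:]) / (m - k)
        out.append((k, abs(left - right), "3prime_down" if right < left else "3prime_up"))
    return out


class TestMedianCenter:
    @pytest.mark.parametrize(
        "row, expected",
        [([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]), ([1.0, 2.0, 10.0], [-1.0, 0.0, 8.0])],
        ids=["constant_row", "asymmetric_row"],
    )
    def test_rows_centered_on_their_median(self, row, expected):
        expr = ExpressionMatrix(pd.DataFrame([row], index=["p"], columns=["S1", "S2", "S3"]))
        dev = median_center(expr)
        np.testing.assert_allclose(dev.values[0], expected)

    def test_global_constant_shift_is_absorbed(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(7, 1, (5, 4)), index=list("abcde"), columns=list("WXYZ"))
        dev1 = median_center(ExpressionMatrix(data))
        dev2 = median_center(ExpressionMatrix(data + 3.7))
        np.testing.assert_allclose(dev1.values, dev2.values, atol=1e-12)

    def test_fewer_than_three_samples_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["S1", "S2"]))
        with pytest.raises(ValueError, match=">= 3 samples"):
            median_center(expr)

    @given(
        st.lists(
            st.lists(st.floats(-30, 30), min_size=3, max_size=9),
            min_size=1,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_row_medians_are_zero(self, rows):
        """Invariant: every centered row has median 0 (|median| < 1e-9 even n)."""
        n = len(rows[0])
        data = pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))], columns=[f"S{j}" for j in range(n)])
        dev = median_center(ExpressionMatrix(data))
        med = np.median(dev.values, axis=1)
        assert np.all(np.abs(med) < 1e-9)


class TestScoreSplits:
    def test_noiseless_step_recovers_split_and_height(self, six_probeset_gene):
        """The truncation signature: a -4 step after probe set 3 scores 4.0
        at exactly that split, with the 3' moiety down."""
        ann, expr = six_probeset_gene
        ids = [r.probeset_id for r in ann.probesets_for("GENEA")]
        expr.data.loc[ids, "S2"] = [7, 7, 7, 3, 3, 3]
        dev = median_center(expr)
        scored = score_splits("GENEA", "S2", dev, ann, min_probesets_per_side=2)
        assert [k for k, _, _ in scored] == [2, 3, 4]
        best = max(scored, key=lambda t: t[1])
        assert best[0] == 3
        assert best[1] == pytest.approx(4.0, abs=1e-12)
        assert best[2] == "3prime_down"

    def test_flat_deviations_score_zero(self, six_probeset_gene):
        ann, expr = six_probeset_gene
        dev = median_center(expr)
        scored = score_splits("GENEA", "S1", dev, ann)
        assert all(s == pytest.approx(0.0) for _, s, _ in scored)

    def test_no_valid_split_yields_empty_list(self):
        ann = make_annotation({"TINY": ("19", "+", [100, 700, 1300])})
        expr = make_expression(ann, ["S1", "S2", "S3"])
        dev = median_center(expr)
        assert score_splits("TINY", "S1", dev, ann, min_probesets_per_side=2) == []

    def test_matches_brute_force_oracle_on_random_deviations(self):
        """Exhaustive oracle over all valid splits, many random instances."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = int(rng.integers(4, 14))
            min_side = int(rng.integers(1, m // 2 + 1))
            d = rng.normal(0, 2, m)
            ann = make_annotation({"G": ("19", "+", list(range(100, 100 + 600 * m, 600)))})
            ids = [r.probeset_id for r in ann.probesets_for("G")]
            data = pd.DataFrame({"S1": d, "S2": np.zeros(m), "S3": np.zeros(m)}, index=ids)
            dev = median_center(ExpressionMatrix(data))
            observed = score_splits("G", "S1", dev, ann, min_probesets_per_side=min_side)
            centered = dev.data.loc[ids, "S1"].to_numpy()
            expected = brute_force_scores(list(centered), min_side)
            assert [k for k, _, _ in observed] == [k for k, _, _ in expected]
            for (k1, s1, d1), (k2, s2, d2) in zip(observed, expected):
                assert s1 == pytest.approx(s2, abs=1e-12)
                assert d1 == d2

    def test_minus_strand_split_is_in_transcript_coordinates(self):
        """On a - strand gene the 3' moiety is the genomically-left block."""
        ann = make_annotation({"G": ("19", "-", [100, 700, 1300, 1900, 2500, 3100])})
        expr = make_expression(ann, ["S1", "S2", "S3"])
        # drop expression in the genomically-left half = the transcript 3' end
        left_ids = [r.probeset_id for r in ann.probesets_for("G") if r.start <= 1300]
        expr.data.loc[left_ids, "S1"] -= 4.0
        dev = median_center(expr)
        best = max(score_splits("G", "S1", dev, ann), key=lambda t: t[1])
        assert best[0] == 3 and best[2] == "3prime_down"

    @given(
        delta=st.floats(0.5, 8.0),
        m=st.integers(4, 12),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_noiseless_step_exact_for_all_heights_and_splits(self, delta, m, data):
        """Property: for any step height and any valid split, the argmax split
        is the true one and the max score equals the height exactly."""
        k_star = data.draw(st.integers(2, m - 2))
        d = np.zeros(m)
        d[k_star:] -= delta
        best = _best_split(d, min_side=2)
        assert best[0] == k_star
        assert best[1] == pytest.approx(delta, abs=1e-9)
        assert best[2] == "3prime_down"

    def test_true_split_score_monotone_in_step_height(self):
        """With the noise realization held fixed, growing |Δ| never lowers
        the true split's score."""
        rng = np.random.default_rng(21)
        noise = rng.normal(0, 0.3, 10)
        k_star = 5
        prev = -np.inf
        for delta in np.linspace(0.5, 6.0, 12):
            d = noise.copy()
            d[k_star:] += delta
            scored = dict((k, s) for k, s, _ in brute_force_scores(list(d), 2))
            assert scored[k_star] >= prev - 1e-12
            assert _best_split(d, 2)[1] == pytest.approx(max(scored.values()), abs=1e-12)
            prev = scored[k_star]


class TestFilterGenes:
    def make(self):
        return make_annotation(
            {
                "DCAF8L2 // LOC101928481": ("19", "+", [100, 700, 1300, 1900]),
                "---": ("19", "+", [3000, 3600, 4200, 4800]),
                "SHORT": ("19", "+", [6000, 6600, 7200]),
                "OK19": ("19", "+", [9000, 9600, 10200, 10800]),
                "OK11": ("11", "+", [100, 700, 1300, 1900]),
            }
        )

    def test_composite_and_placeholder_symbols_excluded(self):
        eligible = filter_genes(self.make(), ScreenConfig())
        assert "DCAF8L2 // LOC101928481" not in eligible
        assert "---" not in eligible
        assert "OK19" in eligible

    def test_composite_kept_when_filter_disabled(self):
        eligible = filter_genes(self.make(), ScreenConfig(exclude_composite_symbols=False))
        assert "DCAF8L2 // LOC101928481" in eligible

    def test_gene_without_valid_split_excluded(self):
        """3 probe sets cannot host a split with 2 on each side."""
        assert "SHORT" not in filter_genes(self.make(), ScreenConfig())

    def test_chromosome_filter_restricts(self):
        eligible = filter_genes(self.make(), ScreenConfig(chromosome_filter="11"))
        assert eligible == ["OK11"]


def cand(gene, sample="S1", split=2, score=1.0, direction="3prime_down"):
    return BreakpointCandidate(gene, sample, split, score, direction)


class TestRankAndSelect:
    def test_descending_scores_rank_in_order(self):
        ranked = rank_candidates([cand("A", score=2.0), cand("B", score=4.0)])
        assert [(c.gene_symbol, c.rank) for c in ranked] == [("B", 1), ("A", 2)]

    def test_score_ties_broken_lexicographically(self):
        ranked = rank_candidates([cand("BBB", score=1.0), cand("AAA", score=1.0)])
        assert [c.gene_symbol for c in ranked] == ["AAA", "BBB"]

    def test_matches_stable_sort_oracle_on_random_candidates(self):
        rng = np.random.default_rng(13)
        cands = [
            cand(
                f"G{rng.integers(40):02d}",
                sample=f"S{rng.integers(6)}",
                split=int(rng.integers(2, 9)),
                score=float(rng.choice([0.5, 1.0, 2.0, rng.uniform(0, 3)])),
            )
            for _ in range(500)
        ]
        expected = sorted(cands, key=lambda c: (-c.score, c.gene_symbol, c.sample_id, c.split_after))
        ranked = rank_candidates(list(cands))
        assert ranked == expected
        assert [c.rank for c in ranked] == list(range(1, 501))

    def test_top_k_fraction_matches_worked_example(self):
        """Top 1000 of 120,099 suggested breakpoints is 0.8% to one decimal."""
        ranked = rank_candidates([cand(f"G{i:06d}", score=float(i)) for i in range(120_099)])
        top, summary = select_top_k(ranked, ScreenConfig(top_k=1000))
        assert len(top) == 1000
        assert summary["n_total_breakpoints"] == 120_099
        assert summary["fraction"] == 0.8

    def test_k_larger_than_n_returns_all(self):
        ranked = rank_candidates([cand(f"G{i}", score=float(i)) for i in range(10)])
        top, summary = select_top_k(ranked, ScreenConfig(top_k=1000))
        assert len(top) == 10 and summary["fraction"] == 100.0

    def test_small_top_k(self):
        ranked = rank_candidates([cand(f"G{i}", score=float(i)) for i in range(4)])
        top, _ = select_top_k(ranked, ScreenConfig(top_k=2))
        assert [c.score for c in top] == [3.0, 2.0]


class TestGeneProfile:
    def test_genomic_order_and_split_flag(self):
        ann = make_annotation({"G": ("19", "-", [100, 700, 1300, 1900])})
        expr = make_expression(ann, ["S1", "S2", "S3"])
        dev = median_center(expr)
        table = gene_profile("G", dev, ann, flagged_splits={"S2": 3})
        assert list(table["start"]) == [100, 700, 1300, 1900]
        # - strand: transcript order 3 is the second probe set genomically
        assert list(table["split_in:S2"]) == [False, True, False, False]

    def test_unknown_gene_is_error(self, six_probeset_gene):
        ann, expr = six_probeset_gene
        dev = median_center(expr)
        with pytest.raises(KeyError):
            gene_profile("NOPE", dev, ann)


class TestClusterSamples:
    def test_identical_samples_merge_first_at_zero_distance(self):
        ann = make_annotation({f"G{i}": ("19", "+", [100 + 5000 * i, 700 + 5000 * i]) for i in range(6)})
        rng = np.random.default_rng(3)
        expr = make_expression(ann, ["S1", "S2", "S3", "S4"])
        expr.data.iloc[:, :] = rng.normal(7, 1, expr.data.shape)
        expr.data["S2"] = expr.data["S1"]
        linkage, samples = cluster_samples(expr, ann)
        i, j, dist, _ = linkage[0]
        assert {samples[int(i)], samples[int(j)]} == {"S1", "S2"}
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_recovered_at_two_cluster_cut(self):
        """Distinct per-gene group means separate tumors from controls,
        like the published tumor/normal QC dendrogram."""
        ann = make_annotation({f"G{i}": ("19", "+", [100 + 5000 * i, 700 + 5000 * i]) for i in range(30)})
        rng = np.random.default_rng(5)
        samples = [f"T{i}" for i in range(5)] + [f"N{i}" for i in range(4)]
        expr = make_expression(ann, samples)
        base = rng.normal(7, 1.5, (expr.data.shape[0], 1))
        shift = rng.normal(0, 1.5, (expr.data.shape[0], 1))
        expr.data.iloc[:, :5] = base + rng.normal(0, 0.3, (expr.data.shape[0], 5))
        expr.data.iloc[:, 5:] = base + shift + rng.normal(0, 0.3, (expr.data.shape[0], 4))
        linkage, ids = cluster_samples(expr, ann)
        labels = sch.fcluster(linkage, t=2, criterion="maxclust")
        groups = {lab: {ids[i][0] for i in range(len(ids)) if labels[i] == lab} for lab in set(labels)}
        assert {frozenset(g) for g in groups.values()} == {frozenset({"T"}), frozenset({"N"})}

    def test_zero_variance_sample_is_error(self):
        ann = make_annotation({"G1": ("19", "+", [100, 700]), "G2": ("19", "+", [9000, 9600])})
        expr = make_expression(ann, ["S1", "S2", "S3"])
        rng = np.random.default_rng(1)
        expr.data[["S1", "S2"]] = rng.normal(7, 1, (4, 2))
        with pytest.raises(ValueError, match="S3"):
            cluster_samples(expr, ann)


class TestScreenModel:
    def test_candidates_respect_min_side_and_symbol_filters(self, default_sim):
        res = TranscriptBreakpointScreen(
            default_sim.tumor_expression(), default_sim.annotation, ScreenConfig(top_k=100)
        ).fit()
        for c in res.ranked:
            m = len(default_sim.annotation.probesets_for(c.gene_symbol))
            assert 2 <= c.split_after <= m - 2
            assert "//" not in c.gene_symbol and c.gene_symbol != "---"

    def test_global_constant_invariance_of_full_screen(self, default_sim):
        expr = default_sim.tumor_expression()
        shifted = ExpressionMatrix(expr.data + 2.5)
        r1 = TranscriptBreakpointScreen(expr, default_sim.annotation, ScreenConfig(top_k=50)).fit()
        r2 = TranscriptBreakpointScreen(shifted, default_sim.annotation, ScreenConfig(top_k=50)).fit()
        f1, f2 = r1.to_frame(), r2.to_frame()
        keys = ["gene_symbol", "sample_id", "split_after", "direction"]
        assert f1[keys].values.tolist() == f2[keys].values.tolist()
        np.testing.assert_allclose(f1["score"], f2["score"], atol=1e-9)

    def test_identical_runs_are_byte_identical(self, default_sim, tmp_path):
        model = TranscriptBreakpointScreen(
            default_sim.tumor_expression(), default_sim.annotation, ScreenConfig(top_k=50)
        )
        model.fit(cytobands=default_sim.cytobands).to_tsv(tmp_path / "a.tsv")
        model.fit(cytobands=default_sim.cytobands).to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_one_candidate_per_gene_sample(self, default_sim):
        res = TranscriptBreakpointScreen(
            default_sim.tumor_expression(), default_sim.annotation, ScreenConfig(top_k=100)
        ).fit()
        keys = [(c.gene_symbol, c.sample_id) for c in res.ranked]
        assert len(keys) == len(set(keys))
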