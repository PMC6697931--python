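"""Ranked-retrieval metrics against hand computations and brute-force oracles."""

import itertools
import math

import pytest

from clinrank.corpus_io import JudgmentSet
from clinrank.ir_metrics import (
    RankedResult,
    average_precision,
    compare_rankers,
    ndcg,
    per_gene_gold_eval,
    reciprocal_rank,
    rel_vs_irrel,
    rel_vs_irrel_from_ranking,
    restricted_pr_at_k,
)

from oracles import (
    brute_average_precision,
    brute_ndcg,
    brute_reciprocal_rank,
    brute_restricted_pr,
)


class TestAveragePrecision:
    def test_hand_computation(self):
        assert average_precision(["r1", "n1", "r2"], {"r1", "r2"}) == pytest.approx(
            (1 / 1 + 2 / 3) / 2
        )

    def test_perfect_ranking(self):
        assert average_precision(["r1", "r2", "n"], {"r1", "r2"}) == 1.0

    def test_nothing_retrieved(self):
        assert average_precision(["n1", "n2"], {"r1", "r2", "r3"}) == 0.0

    def test_unretrieved_relevant_contribute_zero(self):
        # r2 missing from the ranking: divide by |relevant| = 2
        assert average_precision(["r1"], {"r1", "r2"}) == pytest.approx(0.5)

    def test_no_relevant_is_null(self):
        assert average_precision(["a"], set()) is None


class TestReciprocalRank:
    @pytest.mark.parametrize("ranking, expected", [
        (["r", "n", "n", "n"], 1.0),
        (["n", "n", "n", "r"], 0.25),
        (["n", "n"], 0.0),
    ])
    def test_closed_form(self, ranking, expected):
        assert reciprocal_rank(ranking, {"r"}) == expected


class TestNdcg:
    def test_perfect_ranking(self):
        assert ndcg(["r1", "r2", "n"], {"r1", "r2"}) == pytest.approx(1.0)

    def test_single_relevant_at_rank_two(self):
        assert ndcg(["n", "r"], {"r"}) == pytest.approx(1 / math.log2(3))

    def test_no_relevant_retrieved(self):
        assert ndcg(["n1", "n2"], {"r"}) == 0.0

    def test_cutoff_truncates_both_lists(self):
        assert ndcg(["n", "r"], {"r"}, cutoff=1) == 0.0


class TestRelVsIrrel:
    def test_worked_example(self):
        ratio = rel_vs_irrel([1, 5, 10], [3, 6, 12])
        assert sum([1, 5, 10]) / 3 == pytest.approx(16 / 3)
        assert round(ratio, 2) == 0.76

    def test_second_example_means(self):
        ratio = rel_vs_irrel([55, 103, 116], [44, 201, 240])
        assert ratio == pytest.approx((274 / 3) / (485 / 3))

    def test_two_documents(self):
        assert rel_vs_irrel([1], [2]) == 0.5

    def test_empty_irrelevant_is_null(self):
        assert rel_vs_irrel([1, 2], []) is None

    def test_swapping_adjacent_pair_strictly_improves(self):
        # irrelevant above a relevant document; swapping them lowers the ratio
        before = rel_vs_irrel_from_ranking(["i1", "r1", "r2", "i2"],
                                           JudgmentSet("q", {"r1", "r2"}, {"i1", "i2"}))
        after = rel_vs_irrel_from_ranking(["r1", "i1", "r2", "i2"],
                                          JudgmentSet("q", {"r1", "r2"}, {"i1", "i2"}))
        assert after < before

    def test_interleaved_lists_approach_one(self):
        n = 500
        rel = list(range(1, 2 * n, 2))
        irr = list(range(2, 2 * n + 1, 2))
        assert rel_vs_irrel(rel, irr) == pytest.approx(1.0, abs=0.05)


class TestRestrictedPr:
    def test_hand_count(self):
        ranked = ["r1", "n1", "r2", "n2"]
        p, r = restricted_pr_at_k(ranked, {"r1", "r2"}, {"n1", "n2"}, 3)
        assert p == pytest.approx(2 / 3) and r == 1.0

    def test_all_relevant(self):
        for k in (1, 2, 3):
            p, _ = restricted_pr_at_k(["r1", "r2", "r3"], {"r1", "r2", "r3"}, set(), k)
            assert p == 1.0

    def test_unjudged_documents_ignored(self):
        ranked = [f"u{i}" for i in range(1000)] + ["r1", "n1", "r2", "n2"]
        p, r = restricted_pr_at_k(ranked, {"r1", "r2"}, {"n1", "n2"}, 4)
        assert p == 0.5 and r == 1.0
        assert restricted_pr_at_k(ranked, {"r1", "r2"}, {"n1", "n2"}, 5) == (None, None)


class TestOracleEquivalence:
    """Exhaustive agreement with brute-force definitions on small rankings."""

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_all_permutations_small(self, n):
        docs = [f"d{i}" for i in range(n)]
        for n_rel in range(1, n):
            relevant = set(docs[:n_rel])
            irrelevant = set(docs[n_rel:])
            for perm in itertools.permutations(docs):
                ranked = list(perm)
                assert average_precision(ranked, relevant) == pytest.approx(
                    brute_average_precision(ranked, relevant))
                assert reciprocal_rank(ranked, relevant) == pytest.approx(
                    brute_reciprocal_rank(ranked, relevant))
                assert ndcg(ranked, relevant) == pytest.approx(
                    brute_ndcg(ranked, relevant))
                for k in range(1, n + 1):
                    assert restricted_pr_at_k(ranked, relevant, irrelevant, k) == \
                        pytest.approx(brute_restricted_pr(ranked, relevant, irrelevant, k))

    def test_metrics_invariant_to_appended_unjudged_tail(self):
        ranked = ["r1", "n1", "r2"]
        relevant = {"r1", "r2"}
        padded = ranked + [f"u{i}" for i in range(50)]
        assert average_precision(padded, relevant) == average_precision(ranked, relevant)
        assert reciprocal_rank(padded, relevant) == reciprocal_rank(ranked, relevant)


class TestRankedResult:
    def test_duplicate_doc_ids_rejected(self):
        with pytest.raises(ValueError):
            RankedResult("q", ["a", "a"])


class TestCompareRankers:
    def _judgments(self):
        return [JudgmentSet(f"q{i}", {f"r{i}"}, {f"i{i}"}) for i in range(3)]

    def test_dominating_ranker_wins_every_query(self):
        good = {f"q{i}": [f"r{i}", f"i{i}"] for i in range(3)}
        bad = {f"q{i}": [f"i{i}", f"r{i}"] for i in range(3)}
        comp = compare_rankers(self._judgments(), {"good": good, "bad": bad})
        assert comp.table["good"]["n_best_rel_vs_irrel"] == 3
        assert comp.table["bad"]["n_best_rel_vs_irrel"] == 0
        assert comp.table["good"]["map"] == 1.0

    def test_identical_rankers_share_credit(self):
        same = {f"q{i}": [f"r{i}", f"i{i}"] for i in range(3)}
        comp = compare_rankers(self._judgments(), {"a": dict(same), "b": dict(same)})
        assert comp.table["a"]["n_best_rel_vs_irrel"] == 3
        assert comp.table["b"]["n_best_rel_vs_irrel"] == 3

    def test_partial_wins_counted(self):
        a = {"q0": ["r0", "i0"], "q1": ["r1", "i1"], "q2": ["i2", "r2"]}
        b = {"q0": ["i0", "r0"], "q1": ["i1", "r1"], "q2": ["r2", "i2"]}
        comp = compare_rankers(self._judgments(), {"a": a, "b": b})
        assert comp.table["a"]["n_best_rel_vs_irrel"] == 2
        assert comp.table["b"]["n_best_rel_vs_irrel"] == 1

    def test_fewer_than_two_rankers_is_error(self):
        with pytest.raises(ValueError):
            compare_rankers(self._judgments(), {"only": {}})


class TestPerGeneGoldEval:
    def test_gold_on_top_gives_perfect_map(self, small_bundle):
        from clinrank.rank import ScoredDocument

        # construct scores that put every gold document first
        gold_ids = set().union(*small_bundle.gold.values())
        scored = {
            d.doc_id: ScoredDocument(d.doc_id, 1.0 if d.doc_id in gold_ids else 0.1,
                                     1.0, pub_year_int=d.pub_year)
            for d in small_bundle.documents
        }
        reports = per_gene_gold_eval(
            small_bundle.documents, scored, small_bundle.gold,
            small_bundle.gene_lexicon, ["rank_score"])
        means = reports["rank_score"]["mean"]
        assert means["ap"] == pytest.approx(1.0)
        assert means["recall"] == pytest.approx(1.0)

    def test_identical_scores_give_identical_reports(self, small_bundle):
        from clinrank.rank import ScoredDocument

        scored = {
            d.doc_id: ScoredDocument(d.doc_id, 0.5, 0.5, pub_year_int=d.pub_year)
            for d in small_bundle.documents
        }
        reports = per_gene_gold_eval(
            small_bundle.documents, scored, small_bundle.gold,
            small_bundle.gene_lexicon, ["rank_score", "cancer_score"])
        assert reports["rank_score"]["mean"] == reports["cancer_score"]["mean"]
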