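"""Ranked-retrieval evaluation: AP, RR, nDCG, restricted P@k/R@k,
the relevant-vs-irrelevant mean-rank ratio, per-gene gold evaluation and
multi-ranker comparison.

Conventions: ranks are 1-based; gains are binary; relevant documents
missing from a ranking contribute zero to average precision (the
divisor is the total number of relevant documents); queries without
relevant documents yield ``None`` and are excluded from means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .annotate import GeneLexicon
from .corpus_io import Document, JudgmentSet
from .rank import Query, ScoredDocument, filter_candidates, rank_documents


@dataclass
class RankedResult:
    """An ordered document list for one query (rank 1 = first)."""

    query_id: str
    doc_ids: list[str]
    sort_key: str = ""

    def __post_init__(self) -> None:
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError(f"query {self.query_id}: duplicate doc_ids in ranking")


def average_precision(ranked: Sequence[str], relevant: set[str]) -> float | None:
    """Mean precision at the ranks of retrieved relevant documents.

    Relevant documents absent from the ranking contribute 0: the sum is
    divided by ``len(relevant)``.  ``None`` when there are no relevant
    documents.
    """
    if not relevant:
        return None
    hits = 0
    total = 0.0
    for i, did in enumerate(ranked, start=1):
        if did in relevant:
            hits += 1
            total += hits / i
    return total / len(relevant)


def reciprocal_rank(ranked: Sequence[str], relevant: set[str]) -> float | None:
    """1 / rank of the first relevant document; 0 if none retrieved."""
    if not relevant:
        return None
    for i, did in enumerate(ranked, start=1):
        if did in relevant:
            return 1.0 / i
    return 0.0


def ndcg(ranked: Sequence[str], relevant: set[str], cutoff: int | None = None) -> float | None:
    """Binary-gain nDCG with ``log2(rank + 1)`` discount.

    The ideal DCG places every relevant document first; ``cutoff``
    truncates both the observed and ideal lists.
    """
    if not relevant:
        return None
    upto = len(ranked) if cutoff is None else min(cutoff, len(ranked))
    dcg = sum(
        1.0 / math.log2(i + 1)
        for i, did in enumerate(ranked[:upto], start=1)
        if did in relevant
    )
    n_ideal = min(len(relevant), upto) if cutoff is not None else len(relevant)
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, n_ideal + 1))
    return dcg / idcg if idcg > 0 else 0.0


def rel_vs_irrel(
    relevant_positions: Sequence[int], irrelevant_positions: Sequence[int]
) -> float | None:
    """Ratio of the mean rank of relevant to the mean rank of irrelevant
    documents; lower means relevant documents sit higher in the list.

    Positions are 1-based ranks in the full ranked result.  ``None``
    when either side is empty (e.g. judgment sets with no irrelevant
    documents).
    """
    if not relevant_positions or not irrelevant_positions:
        return None
    if min(relevant_positions) < 1 or min(irrelevant_positions) < 1:
        raise ValueError("positions are 1-based ranks")
    mean_rel = sum(relevant_positions) / len(relevant_positions)
    mean_irr = sum(irrelevant_positions) / len(irrelevant_positions)
    return mean_rel / mean_irr


def rel_vs_irrel_from_ranking(ranked: Sequence[str], judgments: JudgmentSet) -> float | None:
    rel = [i for i, d in enumerate(ranked, start=1) if d in judgments.relevant]
    irr = [i for i, d in enumerate(ranked, start=1) if d in judgments.irrelevant]
    return rel_vs_irrel(rel, irr)


def restricted_pr_at_k(
    ranked: Sequence[str],
    judged_relevant: set[str],
    judged_irrelevant: set[str],
    k: int,
) -> tuple[float | None, float | None]:
    """Precision/recall at k over the ranking restricted to judged documents.

    The ranking is first reduced to documents present in either judged
    set (order preserved); k then indexes this restricted list.  Returns
    ``(None, None)`` when k exceeds the restricted length.
    """
    if judged_relevant & judged_irrelevant:
        raise ValueError("judged sets must be disjoint")
    restricted = [d for d in ranked if d in judged_relevant or d in judged_irrelevant]
    if k < 1 or k > len(restricted):
        return None, None
    hits = sum(1 for d in restricted[:k] if d in judged_relevant)
    prec = hits / k
    rec = hits / len(judged_relevant) if judged_relevant else None
    return prec, rec


def pr_curves(
    ranked: Sequence[str], judged_relevant: set[str], judged_irrelevant: set[str]
) -> list[tuple[int, float, float]]:
    """(k, P@k, R@k) for every k up to the restricted length."""
    restricted = [d for d in ranked if d in judged_relevant or d in judged_irrelevant]
    out = []
    for k in range(1, len(restricted) + 1):
        p, r = restricted_pr_at_k(ranked, judged_relevant, judged_irrelevant, k)
        out.append((k, p, r))
    return out


def _mean(values: Iterable[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return sum(vals) / len(vals) if vals else None


# ---------------------------------------------------------------------------
# Per-gene gold-standard evaluation
# ---------------------------------------------------------------------------

def per_gene_gold_eval(
    docs: Sequence[Document],
    scored: Mapping[str, ScoredDocument],
    gold: Mapping[str, set[str]],
    lexicon: GeneLexicon,
    sort_keys: Sequence[str],
) -> dict[str, dict]:
    """Evaluate sort keys against per-gene gold document sets.

    For each gold gene a one-gene query retrieves every document
    mentioning it (synonym-expanded); each sort key ranks the retrieved
    set and recall of gold documents among them, AP, RR and nDCG are
    computed with the gold set as the relevant set.  Genes retrieving
    nothing yield null metrics and are counted.
    """
    reports: dict[str, dict] = {}
    for key in sort_keys:
        per_gene: dict[str, dict] = {}
        n_empty = 0
        for gene, gold_docs in sorted(gold.items()):
            candidates = filter_candidates(docs, Query(genes={gene}), lexicon)
            if not candidates:
                n_empty += 1
                per_gene[gene] = {"recall": None, "ap": None, "rr": None, "ndcg": None}
                continue
            sdocs = [scored[d.doc_id] for d in candidates]
            ranked = [s.doc_id for s in rank_documents(sdocs, key)]
            retrieved = set(ranked)
            per_gene[gene] = {
                "recall": len(gold_docs & retrieved) / len(gold_docs) if gold_docs else None,
                "ap": average_precision(ranked, gold_docs),
                "rr": reciprocal_rank(ranked, gold_docs),
                "ndcg": ndcg(ranked, gold_docs),
            }
        reports[key] = {
            "per_gene": per_gene,
            "n_genes_without_candidates": n_empty,
            "mean": {
                m: _mean(g[m] for g in per_gene.values())
                for m in ("recall", "ap", "rr", "ndcg")
            },
        }
    return reports


# ---------------------------------------------------------------------------
# Multi-ranker comparison
# ---------------------------------------------------------------------------

@dataclass
class RankerComparison:
    """Per-ranker means plus the count of queries each ranker wins on the
    relevant-vs-irrelevant ratio (ties credit all tied rankers)."""

    table: dict[str, dict] = field(default_factory=dict)


def compare_rankers(
    judgments: Sequence[JudgmentSet],
    rankers: Mapping[str, Mapping[str, Sequence[str]]],
) -> RankerComparison:
    """Compare named rankers over a shared set of judged queries.

    ``rankers`` maps ranker name -> {query_id -> ordered doc_id list}.
    Reports per-ranker MAP, MRR, mean nDCG, mean rel-vs-irrel, and the
    number of queries on which the ranker's rel-vs-irrel is minimal.
    """
    if len(rankers) < 2:
        raise ValueError("need >= 2 rankers to compare")
    per: dict[str, dict] = {
        name: {"ap": [], "rr": [], "ndcg": [], "rvi": {}} for name in rankers
    }
    for js in judgments:
        for name, rankings in rankers.items():
            ranked = list(rankings.get(js.query_id, []))
            per[name]["ap"].append(average_precision(ranked, js.relevant))
            per[name]["rr"].append(reciprocal_rank(ranked, js.relevant))
            per[name]["ndcg"].append(ndcg(ranked, js.relevant))
            per[name]["rvi"][js.query_id] = rel_vs_irrel_from_ranking(ranked, js)

    best_counts = {name: 0 for name in rankers}
    for js in judgments:
        vals = {
            name: per[name]["rvi"][js.query_id]
            for name in rankers
            if per[name]["rvi"][js.query_id] is not None
        }
        if not vals:
            continue
        best = min(vals.values())
        for name, v in vals.items():
            if v == best:
                best_counts[name] += 1

    comp = RankerComparison()
    for name in rankers:
        comp.table[name] = {
            "map": _mean(per[name]["ap"]),
            "mrr": _mean(per[name]["rr"]),
            "ndcg": _mean(per[name]["ndcg"]),
            "mean_rel_vs_irrel": _mean(per[name]["rvi"].values()),
            "n_best_rel_vs_irrel": best_counts[name],
        }
    return comp
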