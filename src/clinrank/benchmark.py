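"""End-to-end experiments on synthetic corpora.

Two reusable experiment drivers:

* :func:`classification_recovery` — train task models on generated
  corpora across vocabulary-overlap levels and seeds, reporting test F1
  (parameter recovery: disjoint class vocabularies should be learned
  almost perfectly, rising overlap should erode performance).
* :func:`ranking_benchmark` — train the cancer/clinical scorers, score
  the corpus, and compare sort keys (the composed rank score against
  the plain keyword VSM baseline) on the generated per-query judgments.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .classify import FeatureConfig, evaluate_classifier, split_train_test, train_task_model
from .ir_metrics import average_precision, ndcg
from .rank import KeywordScorer, Query, filter_candidates, rank_documents, score_corpus
from .synth import GeneratorConfig, SyntheticBundle, generate_corpus

#: Feature configuration used throughout the synthetic experiments:
#: unigrams and a min-df of 1 suit short bag-of-words documents with a
#: few hundred distinct terms.
SYNTH_FEATURES = FeatureConfig(ngram_range=(1, 1), min_doc_freq=1, max_features_chi2=5000)


def classification_recovery(
    overlaps: Sequence[float] = (0.0,),
    seeds: Sequence[int] = (0,),
    learners: Sequence[str] = ("linear_svm",),
    tasks: Sequence[str] = ("cancer", "clinical"),
    n_docs: int = 1000,
    search_budget: int = 3,
) -> dict:
    """Test-set F1 for every (overlap, seed, learner, task) combination.

    Returns ``{"runs": [...], "mean_f1": {(overlap, learner, task): f}}``
    where the mean is over seeds.
    """
    runs: list[dict] = []
    for overlap in overlaps:
        for seed in seeds:
            cfg = GeneratorConfig(n_docs=n_docs, overlap=overlap, seed=seed)
            bundle = generate_corpus(cfg)
            train, test = split_train_test(bundle.labeled_corpus(), seed=seed)
            for learner in learners:
                for task in tasks:
                    model = train_task_model(
                        task, learner, train, SYNTH_FEATURES,
                        search_budget=search_budget, seed=seed,
                    )
                    report = evaluate_classifier(model, test)
                    runs.append(
                        {
                            "overlap": overlap,
                            "seed": seed,
                            "learner": learner,
                            "task": task,
                            "f1_macro": report["macro"]["f1"],
                        }
                    )
    mean_f1: dict = {}
    for overlap in overlaps:
        for learner in learners:
            for task in tasks:
                vals = [
                    r["f1_macro"]
                    for r in runs
                    if r["overlap"] == overlap and r["learner"] == learner and r["task"] == task
                ]
                mean_f1[(overlap, learner, task)] = float(np.mean(vals))
    return {"runs": runs, "mean_f1": mean_f1}


def _query_metrics(bundle: SyntheticBundle, scored, scorer: KeywordScorer, sort_key: str):
    """Per-query AP and nDCG for one sort key on a bundle's judgments."""
    aps, ndcgs = [], []
    for js in bundle.judgments:
        query = Query(genes={js.query_id})
        candidates = filter_candidates(bundle.documents, query, bundle.gene_lexicon)
        if not candidates:
            continue
        sdocs = []
        if sort_key == "keyword_score":
            qtext = scorer.query_terms(query, bundle.gene_lexicon)
            kw = scorer.score(qtext, [d.doc_id for d in candidates])
            for d in candidates:
                sdocs.append(replace(scored[d.doc_id], keyword_score=kw[d.doc_id]))
        else:
            sdocs = [scored[d.doc_id] for d in candidates]
        ranked = [s.doc_id for s in rank_documents(sdocs, sort_key)]
        ap = average_precision(ranked, js.relevant)
        nd = ndcg(ranked, js.relevant)
        if ap is not None:
            aps.append(ap)
        if nd is not None:
            ndcgs.append(nd)
    return (float(np.mean(aps)) if aps else None, float(np.mean(ndcgs)) if ndcgs else None)


def ranking_benchmark(
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_docs: int = 600,
    learner: str = "linear_svm",
    sort_keys: Sequence[str] = ("rank_score", "keyword_score"),
    search_budget: int = 3,
) -> dict:
    """Mean MAP and nDCG per sort key, per seed and averaged over seeds.

    Relevance labels come from the generator's clinically-relevant
    class, so a sort key aware of the clinical/cancer signal should beat
    the query-term VSM baseline.
    """
    per_seed: list[dict] = []
    for seed in seeds:
        cfg = GeneratorConfig(n_docs=n_docs, seed=seed)
        bundle = generate_corpus(cfg)
        train, _ = split_train_test(bundle.labeled_corpus(), seed=seed)
        models = {
            task: train_task_model(task, learner, train, SYNTH_FEATURES,
                                   search_budget=search_budget, seed=seed)
            for task in ("cancer", "clinical")
        }
        scored = score_corpus(bundle.documents, models, assign_ctype=False)
        scorer = KeywordScorer(bundle.documents)
        entry: dict = {"seed": seed}
        for key in sort_keys:
            m, n = _query_metrics(bundle, scored, scorer, key)
            entry[key] = {"map": m, "ndcg": n}
        per_seed.append(entry)
    summary = {
        key: {
            metric: float(np.mean([e[key][metric] for e in per_seed]))
            for metric in ("map", "ndcg")
        }
        for key in sort_keys
    }
    return {"per_seed": per_seed, "mean": summary}
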