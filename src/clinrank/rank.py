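"""Query semantics, score normalization and result ordering.

A query is a set of genes and/or variants and/or keywords, optionally
restricted to a cancer type.  Candidate documents must match at least
one queried entity or keyword (OR semantics).  Candidates are ordered by
one of four sort keys:

* ``rank_score`` — product of the min-max-normalized cancer and clinical
  scores (the production default),
* ``pubdate_x_rankscore`` — publication year (as an integer) times the
  rank score,
* ``cancer_score`` — the normalized cancer score alone,
* ``keyword_score`` — plain vector-space-model cosine between query
  terms and document text (the baseline).

Normalization is corpus-wide min-max: the classifier scores are
query-independent and precomputed over the whole indexed corpus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .annotate import GeneLexicon, canonical_variant, expand_gene_query, resolve_gene_ids
from .classify import TaskModel
from .corpus_io import Document

SORT_KEYS = ("rank_score", "pubdate_x_rankscore", "cancer_score", "keyword_score")
DEFAULT_SORT_KEY = "rank_score"

_WORD = re.compile(r"\w+")


@dataclass
class Query:
    """Genes, variants and free-text keywords; all but one may be empty."""

    genes: set[str] = field(default_factory=set)
    variants: set[str] = field(default_factory=set)
    keywords: set[str] = field(default_factory=set)
    cancer_type: str | None = None

    def __post_init__(self) -> None:
        if not (self.genes or self.variants or self.keywords):
            raise ValueError("query needs at least one gene, variant or keyword")


@dataclass
class ScoredDocument:
    """Per-document scores on the [0,1] scale plus sort metadata."""

    doc_id: str
    cancer_score: float
    clinical_score: float
    keyword_score: float = 0.0
    pub_year_int: int = 0
    ctype_label: str | None = None

    @property
    def rank_score(self) -> float:
        return self.cancer_score * self.clinical_score


def normalize_scores(raw: Sequence[float]) -> np.ndarray:
    """Min-max normalize raw scores over an indexed corpus to [0, 1].

    When every raw score is identical (max == min) all documents get
    score 1.0; in particular a single-document corpus scores 1.0.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty corpus")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


def score_corpus(
    docs: Sequence[Document],
    models: dict[str, TaskModel],
    assign_ctype: bool = True,
) -> dict[str, ScoredDocument]:
    """Score every document with the task models, normalized corpus-wide.

    With ``assign_ctype`` and a fitted ctype model, documents predicted
    cancer-positive get a type label (used for type filtering); other
    documents keep their existing ``type_label``.
    """
    texts = [d.text for d in docs]
    cancer = normalize_scores(models["cancer"].raw_scores(texts))
    clinical = normalize_scores(models["clinical"].raw_scores(texts))
    ctype_labels: list[str | None] = [d.type_label for d in docs]
    if assign_ctype and "ctype" in models:
        pred, _ = models["ctype"].type_predictions(texts)
        cancer_pred = models["cancer"].predict_labels(texts)
        ctype_labels = [
            str(p) if bool(cpos) else d.type_label
            for p, cpos, d in zip(pred, cancer_pred, docs)
        ]
    return {
        d.doc_id: ScoredDocument(
            doc_id=d.doc_id,
            cancer_score=float(cancer[i]),
            clinical_score=float(clinical[i]),
            pub_year_int=int(d.pub_year),
            ctype_label=ctype_labels[i],
        )
        for i, d in enumerate(docs)
    }


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def filter_candidates(
    docs: Sequence[Document],
    query: Query,
    gene_lexicon: GeneLexicon | None = None,
) -> list[Document]:
    """Apply the query's filter semantics to a corpus.

    Step 1: if a cancer type is queried, keep only documents carrying
    that type label.  Step 2: keep documents containing at least one
    queried gene (by normalized id, after synonym expansion), OR one
    queried variant (by canonical form), OR one keyword
    (case-insensitive token match in title+abstract).
    """
    gene_ids: set[str] = set()
    if query.genes and gene_lexicon is not None:
        gene_ids = resolve_gene_ids(query.genes, gene_lexicon)
    elif query.genes:
        gene_ids = set(query.genes)  # no lexicon: treat symbols as ids
    variant_canon = {canonical_variant(v) for v in query.variants}
    keywords = {k.lower() for k in query.keywords}

    out: list[Document] = []
    for doc in docs:
        if query.cancer_type is not None and doc.type_label != query.cancer_type:
            continue
        hit = False
        if gene_ids and any(
            m.etype == "gene" and m.norm_id in gene_ids for m in doc.mentions
        ):
            hit = True
        if not hit and variant_canon and any(
            m.etype == "variant" and m.norm_id in variant_canon for m in doc.mentions
        ):
            hit = True
        if not hit and keywords:
            tokens = {t.lower() for t in _WORD.findall(doc.text)}
            hit = bool(tokens & keywords)
        if hit:
            out.append(doc)
    return out


# ---------------------------------------------------------------------------
# Keyword score (vector space model)
# ---------------------------------------------------------------------------

class KeywordScorer:
    """Classic VSM: L2-normalized tf-idf cosine between query and document.

    Uses the same tf-idf definition as the classification features
    (smoothed idf ``ln((1+N)/(1+df)) + 1``), with idf statistics fit on
    the indexed corpus.  Scores are in [0, 1].
    """

    def __init__(self, docs: Sequence[Document]):
        self._vec = TfidfVectorizer(norm="l2", smooth_idf=True, sublinear_tf=False, min_df=1)
        self._X = self._vec.fit_transform([d.text for d in docs])
        self._index = {d.doc_id: i for i, d in enumerate(docs)}

    def query_terms(self, query: Query, gene_lexicon: GeneLexicon | None = None) -> str:
        genes = query.genes
        if gene_lexicon is not None and query.genes:
            genes, _ = expand_gene_query(query.genes, gene_lexicon)
        return " ".join(sorted(genes) + sorted(query.variants) + sorted(query.keywords))

    def score(self, query_text: str, doc_ids: Iterable[str]) -> dict[str, float]:
        q = self._vec.transform([query_text])
        out: dict[str, float] = {}
        for did in doc_ids:
            i = self._index[did]
            out[did] = float(self._X[i].multiply(q).sum())
        return out


# ---------------------------------------------------------------------------
# Sorting
# ---------------------------------------------------------------------------

def compose_sort_value(sdoc: ScoredDocument, key: str) -> float:
    """The scalar a document is sorted by under the given key."""
    if key == "rank_score":
        return sdoc.rank_score
    if key == "pubdate_x_rankscore":
        return sdoc.pub_year_int * sdoc.rank_score
    if key == "cancer_score":
        return sdoc.cancer_score
    if key == "keyword_score":
        return sdoc.keyword_score
    raise ValueError(f"unknown sort key {key!r}")


def rank_documents(candidates: Sequence[ScoredDocument], key: str = DEFAULT_SORT_KEY) -> list[ScoredDocument]:
    """Deterministic descending order; ties broken by doc_id ascending."""
    return sorted(candidates, key=lambda s: (-compose_sort_value(s, key), s.doc_id))
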