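# clinrank

Clinical-relevance ranking of biomedical abstracts for precision
oncology.

Clinicians preparing a molecular tumor board need publications with
*clinical* impact for a patient's mutated genes and variants —
drug–variant associations, trials, treatment reports — while the vast
majority of matching literature is basic science. General-purpose
search engines rank by recency or plain term similarity and do not know
the difference. `clinrank` implements a retrieval pipeline that does:

1. **Entity annotation.** Gene and drug mentions are found by synonym
   dictionaries (token-boundary, longest-match, case-sensitive for
   short gene symbols) and normalized to identifiers; variant mentions
   (`V600E`, `p.Val600Glu`, `c.35G>A`, rsIDs) by a small regex grammar.
   Precomputed annotations can be ingested through the JSONL corpus
   format instead.
2. **Query-independent relevance scores.** Two binary classifiers score
   every document for cancer-relatedness (*CancerScore*) and clinical
   relevance (*ClinicalScore*); a multi-class model assigns a cancer
   type (melanoma, head & neck, colorectal, general cancer). Training
   uses a silver standard: records from a curated variant-interpretation
   resource as positives, literature sampled away from cancer terms as
   negatives. Features are word n-gram tf–idf vectors with χ² feature
   selection; learners are a linear SVM and a random forest tuned by
   seeded randomized search in 5-fold CV.
3. **Ranking.** A query is a set of genes (synonym-expanded), variants
   and keywords, optionally restricted to a cancer type; candidates
   must match at least one queried item. With scores min–max-normalized
   over the corpus, documents are ordered by

   `RankScore = CancerScore_norm × ClinicalScore_norm`

   (alternatives: `PubYear × RankScore`, `CancerScore` alone, or the
   plain vector-space-model `KeywordScore` baseline).
4. **Evaluation.** MAP, MRR, nDCG, restricted P@k/R@k (computed on the
   ranking reduced to judged documents), and the *Rel-vs-IrRel* ratio —
   mean rank of relevant documents over mean rank of irrelevant ones,
   lower is better — plus per-gene gold-standard evaluation and a
   multi-ranker comparison table. Multi-rater 5-point Likert
   assessments can be consolidated into binary judgments by majority
   vote (contested pairs removed, ties discarded).

A seeded synthetic-corpus generator (`clinrank.synth`) produces
class-conditional bag-of-words corpora with injected gene/variant/drug
mentions, lexicons, per-gene gold sets and judgments, so the whole
pipeline is testable without any downloads.

## Worked example

```bash
clinrank simulate --n-docs 250 --seed 3 --out bundle
clinrank train --corpus bundle/corpus.jsonl --labels bundle/labels.tsv \
    --task cancer   --learner linear_svm --ngram-max 1 --min-df 1 --seed 3 --out models/cancer
clinrank train --corpus bundle/corpus.jsonl --labels bundle/labels.tsv \
    --task clinical --learner linear_svm --ngram-max 1 --min-df 1 --seed 3 --out models/clinical
clinrank search --corpus bundle/corpus.jsonl --models models \
    --lexicon bundle/gene_lexicon.tsv --genes BGS68 --sort rank_score --top 5
```

prints (truncated):

```
rank  doc_id   sort_value  rank_score  cancer_score  clinical_score  keyword_score  pub_year
1     S000207  0.934591    0.934591    0.976538      0.957044        0.115786       2000
2     S000086  0.870354    0.870354    0.980663      0.887516        0.091421       2013
3     S000126  0.857194    0.857194    0.962922      0.890200        0.087834       2016
...
```

`sort_value` is the rank score — the product of the two normalized
classifier scores — so the top documents are those the models consider
both cancer-related and clinically relevant; `keyword_score` shows how
little plain term similarity separates them. In the library, the same
pipeline is `generate_corpus` → `train_task_model` → `score_corpus` →
`filter_candidates` → `rank_documents`.

Comparing rankers against judgments:

```bash
clinrank evaluate --judgments bundle/judgments.tsv \
    --ranking good=good.tsv --ranking bad=bad.tsv --report report.json
```

reports per ranker MAP/MRR/nDCG, the mean Rel-vs-IrRel ratio and the
number of queries on which it achieves the best ratio.

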