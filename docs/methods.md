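# Methods

## Problem setting

Given a patient's mutated genes and variants, rank the matching
abstract-level literature so that clinically actionable work (treatment
and trial evidence) appears above basic science. The system decomposes
this into query-independent document scoring (learned once per corpus)
and cheap per-query filtering and sorting, so scores can be precomputed
for an indexed collection.

## Entity annotation

Gene and drug mentions are dictionary matches against TSV lexicons
(`id`, canonical name, `|`-separated synonyms). Matching is
token-boundary aligned, where token characters are `[A-Za-z0-9-]`;
the hyphen is token-internal so `B-RAF1` matches whole while
`paclitaxel` inside `nab-paclitaxel` does not. Overlaps are resolved
longest-match-first, leftmost on ties, so mentions of one entity type
never overlap. Gene symbols of ≤ 4 characters match case-sensitively
(short symbols collide with ordinary words); longer symbols and all
drug names match case-insensitively. Variant mentions come from an
ordered regex grammar covering one-letter protein substitutions
(`V600E`), HGVS-like `p.` forms with 1- and 3-letter codes, `c.`
substitutions and small indels, and rsIDs; fusions and CNVs are out of
scope. The canonical form strips whitespace and uppercases bare short
forms; an optional folding maps 3-letter codes to 1-letter
(`p.Val600Glu` → `V600E`). Every annotator is pure: identical inputs
give identical spans.

These annotators are deliberately desk-scale stand-ins for full NER
systems; corpora annotated by external tools can be ingested directly
through the JSONL `mentions` field.

## Silver-standard corpus construction

Positive records (curated, hence clinical=+) are labeled cancer=+ with
a mapped cancer type — melanoma, head-and-neck and colorectal kept,
every other type folded into `general_cancer` — except records flagged
with a non-cancer disease annotation, which become cancer=− and carry
no type. Negatives are a seeded uniform sample from a document pool
after removing anything containing a cancer term (case-insensitive,
token-boundary; the term list is an input — a canonical list is not
part of the package). The construction is biased by design: the
clinical classifier separates "clinically relevant cancer document"
from "non-cancer document" because no large corpus of clinically
*irrelevant* cancer documents exists; this limitation is inherited by
anything trained on the output.

Train/test splitting is stratified on the joint label triple
(cancer, clinical, ctype), default 85/15, per-stratum sizes within one
document of the exact fraction.

## Features and learners

Documents are vectorized as word n-gram tf–idf with the smoothed idf
`ln((1+N)/(1+df)) + 1` and L2 normalization. χ² statistics are computed
per feature from its present/absent × class contingency table (no
continuity correction; features present in all or no documents score
0), and the top-K features are kept, ties broken by feature index.
Vectors are re-normalized to unit L2 norm after selection so the norm
invariant holds on what the learners see. Defaults: n-grams (1,2),
min document frequency 2, K = 20,000, lowercasing on — standard for
abstract-length text; the synthetic experiments use unigrams with
min-df 1 because generated documents are short bags of a few hundred
distinct terms.

Learners are a linear-kernel SVM (raw score = signed decision value)
and a random forest (raw score = positive-class vote fraction), the
type task one-vs-rest for the SVM. Hyper-parameters are chosen by
seeded randomized search — SVM regularization C log-uniform on
[1e-3, 1e3]; forest size {100…500}, depth {∞,10,20}, min leaf {1,2,5} —
maximizing macro F1 over 5 stratified folds, refit on the full training
set. Macro F1 is used because the negative class dominates the silver
standard.

## Ranking

Raw classifier scores are min–max normalized to [0,1] **corpus-wide**
(the scores are query-independent and precomputed; per-result-set
normalization would make a document's score depend on the query). The
degenerate all-equal case maps to 1.0. `RankScore` is the product of
the normalized cancer and clinical scores; it is monotone in each
factor. Publication year enters the `pubdate_x_rankscore` key as a
plain integer; the unknown-year sentinel 0 sorts such documents last.

Filtering is two-step: an optional cancer-type equality filter, then OR
semantics over queried genes (matched by normalized id after synonym
expansion), variants (canonical form), and keywords (case-insensitive
token match, no stemming). OR keyword semantics mirrors how multi-gene
queries are evaluated downstream.

The `KeywordScore` baseline is classic L2-normalized tf–idf cosine
between the concatenated query terms and the document, with idf fit on
the indexed corpus — a vanilla vector-space model, not an emulation of
any particular search server's practical scoring.

Sorting is descending with ties broken by ascending doc id, giving a
deterministic total order.

## Evaluation suite

All ranks are 1-based. Average precision divides by the total number of
relevant documents, so relevant-but-unretrieved items contribute zero;
nDCG uses binary gains with `log2(rank+1)` discount; queries with no
relevant documents yield nulls and are excluded from means. Restricted
P@k/R@k first reduce the ranking to judged documents — appropriate when
judgment sets are far smaller than result lists, where conventional
P@k is uniformly near zero. The Rel-vs-IrRel ratio (mean rank of
relevant over mean rank of irrelevant documents, lower better)
normalizes away the list-shrinking effect of entity filtering when
comparing engines with different candidate sets; it is null when a
query has no judged irrelevant documents. In the ranker-comparison
table, ties for the best ratio credit every tied ranker.

Multi-rater Likert consolidation removes pairs rated 5 by one rater and
1 by another, binarizes each remaining vote at a threshold (default 4;
the mapping is a parameter because no canonical choice exists) and
majority-votes, discarding exact ties.

## Synthetic generator

Documents are unigram bags over class-conditional vocabularies for
three classes (clinically relevant cancer, basic-science cancer,
non-cancer; default mixture 0.35/0.25/0.40) sharing an `overlap`
fraction of terms; cancer documents mix in cancer-type marker terms at
rate 0.15 so the type task is learnable. Defaults — 80 content terms
per class, ~50-token documents, gene/variant/drug injection rates
0.6/0.3/0.3, 20 genes with 1–2 synonyms, years 2000–2020 — are chosen
as realistic for abstract-scale triage experiments. Gene symbols are
letter-runs plus digits (`GQX12`), guaranteed disjoint from content
vocabulary; injected variants are drawn from the annotation grammar's
own productions. Ground-truth spans are recorded, so the annotators are
exactly recoverable on generated corpora. Gold sets and judgments
derive from the class structure: for each gene, clinically-relevant
documents containing it are the relevant pool.

What the generator does *not* emulate: real term distributions (Zipf),
syntax, abbreviations, homonymous gene symbols, rater noise, or any
correlation between recency and relevance. Passing tests on it
demonstrate that the pipeline recovers planted structure under its own
modeling assumptions — not performance on real literature.

One empirical note from the recovery experiments: at these defaults,
test F1 for the binary tasks stays at ceiling across vocabulary overlap
up to 0.9, because ~10% class-exclusive vocabulary at 50 tokens per
document still yields a near-certain discriminative term per document;
the overlap sweep therefore verifies *non-degradation-free*
monotonicity (non-increasing means) rather than a visible decline.

## Problem sizes and numerics

The end-to-end experiments run at n = 1000 documents (classifier
recovery; 5 seeds for the overlap sweep) and n = 600 (ranking
benchmark, 5 seeds), with randomized-search budget 3 — sizes at which
the planted signal is unambiguous and the full suite stays fast.
Determinism is end-to-end: every sampling, split, search and generation
step is driven by an explicit integer seed through `numpy`'s
`default_rng` and scikit-learn `random_state`, and repeated runs are
bit-identical. Degenerate inputs are defined rather than accidental:
constant score vectors normalize to 1.0, empty judgment sides yield
null metrics, empty candidate sets are valid results, and empty
vocabularies or undersized strata raise informative errors.

## Known limitations

- The clinical/cancer classifiers share most of their negatives, so
  their scores are correlated; the RankScore product partially
  compensates but cannot separate "clinically irrelevant cancer" well.
- Variant matching is string-canonical; `Val600Glu` equals `V600E` only
  when the optional folding is applied at both ends.
- The keyword VSM shares no vocabulary pruning with the classifiers and
  is fit per corpus; scores are comparable within, not across, corpora.
- Absolute metric values on synthetic corpora say nothing about
  absolute performance on real search logs; only relative statements
  (e.g. RankScore > KeywordScore under class-driven relevance) are
  supported.
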