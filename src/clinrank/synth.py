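"""Seeded synthetic corpora with the statistical structure the
classifiers and rankers assume.

Documents are unigram bags of words drawn from class-conditional
vocabularies for three document classes — clinically relevant cancer,
basic-science cancer, and non-cancer — whose vocabularies share a
configurable overlap fraction (0 = disjoint = maximal separability).
Cancer documents additionally mix in cancer-type marker terms so the
multi-class type task is learnable.  Synthetic gene symbols (with
synonyms registered in an emitted lexicon), variant strings drawn from
the annotation grammar's own productions, and drug names are injected
at token boundaries with ground-truth spans recorded, which makes the
dictionary annotators exactly recoverable.  Per-gene gold sets and
per-query binary judgments are derived from the class structure:
clinically-relevant cancer documents are the relevant pool.

Everything is a deterministic function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotate import DrugLexicon, GeneLexicon, canonical_variant
from .classify import CANCER_TYPES, CTYPE_NONE, DocLabels, LabeledCorpus
from .corpus_io import Document, EntityMention, JudgmentSet, write_documents_jsonl, write_lexicon_tsv
from .ir_metrics import RankedResult

CLASSES = ("clinical_cancer", "basic_cancer", "non_cancer")

_TITLE_TOKENS = 8
_CTYPE_MARKER_RATE = 0.15
_CTYPE_MARKER_WORDS = 6


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    The class mixture mirrors a triage setting where a bit under half of
    the matching literature is non-cancer and clinically relevant work
    is a minority; vocabulary sizes and document lengths are scaled to
    abstract-like text at desk scale.
    """

    n_docs: int = 1000
    class_mixture: tuple[float, float, float] = (0.35, 0.25, 0.40)  # CLASSES order
    ctype_mixture: tuple[float, float, float, float] = (0.25, 0.20, 0.20, 0.35)  # CANCER_TYPES order
    vocab_size: int = 80  # content terms per class
    overlap: float = 0.0  # fraction of vocabulary shared across classes
    doc_length: int = 50  # mean tokens per document
    gene_injection_rate: float = 0.6
    variant_injection_rate: float = 0.3
    drug_injection_rate: float = 0.3
    n_genes_in_lexicon: int = 20
    n_drugs_in_lexicon: int = 10
    year_range: tuple[int, int] = (2000, 2020)
    max_relevant_per_query: int = 10
    max_irrelevant_per_query: int = 10
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if abs(sum(self.ctype_mixture) - 1.0) > 1e-9:
            raise ValueError("ctype_mixture must sum to 1")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must be in [0,1]")
        for name in ("n_docs", "vocab_size", "doc_length", "n_genes_in_lexicon", "n_drugs_in_lexicon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")


@dataclass
class SyntheticBundle:
    """A generated corpus plus everything needed to test the pipeline."""

    config: GeneratorConfig
    documents: list[Document]
    labels: list[DocLabels]
    gene_lexicon: GeneLexicon
    drug_lexicon: DrugLexicon
    gold: dict[str, set[str]]  # canonical gene symbol -> relevant doc ids
    judgments: list[JudgmentSet]

    def labeled_corpus(self) -> LabeledCorpus:
        return LabeledCorpus(self.documents, self.labels)


# ---------------------------------------------------------------------------
# Vocabulary and lexicon construction
# ---------------------------------------------------------------------------

def _random_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(5, 9))
        w = "".join(rng.choice(letters, size=length))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def _gene_symbol(rng: np.random.Generator, taken: set[str]) -> str:
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    while True:
        sym = "".join(rng.choice(letters, size=3)) + str(int(rng.integers(10, 100)))
        if sym not in taken:
            taken.add(sym)
            return sym


def _make_gene_lexicon(rng: np.random.Generator, n_genes: int) -> GeneLexicon:
    lex = GeneLexicon(kind="gene")
    taken: set[str] = set()
    for i in range(n_genes):
        sym = _gene_symbol(rng, taken)
        syns = [sym]
        n_syn = int(rng.integers(1, 3))
        for _ in range(n_syn):
            alt = f"{sym[:2]}-{sym[2:]}" if rng.random() < 0.5 else sym + "L"
            if alt not in taken:
                taken.add(alt)
                syns.append(alt)
        lex.add(str(1000 + i), sym, syns)
    return lex


def _make_drug_lexicon(rng: np.random.Generator, n_drugs: int) -> DrugLexicon:
    lex = DrugLexicon(kind="drug")
    taken: set[str] = set()
    stems = _random_words(rng, n_drugs, taken)
    for i, stem in enumerate(stems):
        name = stem.capitalize() + "inib"
        lex.add(f"D{i:03d}", name, [name])
    return lex


def _variant_surface(rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    u = rng.random()
    if u < 0.6:
        return f"{aas[rng.integers(len(aas))]}{int(rng.integers(1, 1000))}{aas[rng.integers(len(aas))]}"
    if u < 0.8:
        bases = "ACGT"
        b1 = bases[rng.integers(4)]
        b2 = bases[(int(rng.integers(1, 4)) + bases.index(b1)) % 4]
        return f"c.{int(rng.integers(1, 5000))}{b1}>{b2}"
    return f"rs{int(rng.integers(1000, 10**7))}"


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate a fully deterministic synthetic bundle for ``cfg``.

    Raises when the configuration leaves a required stratum empty (a
    class with positive mixture weight but no documents, or — with a
    zero gene-injection rate — universally empty per-gene gold sets).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_shared = int(round(cfg.overlap * cfg.vocab_size))
    n_own = cfg.vocab_size - n_shared
    taken: set[str] = set()
    shared = _random_words(rng, n_shared, taken)
    class_vocab = {
        cls: shared + _random_words(rng, n_own, taken) for cls in CLASSES
    }
    ctype_vocab = {
        ct: _random_words(rng, _CTYPE_MARKER_WORDS, taken) for ct in CANCER_TYPES
    }

    gene_lex = _make_gene_lexicon(rng, cfg.n_genes_in_lexicon)
    drug_lex = _make_drug_lexicon(rng, cfg.n_drugs_in_lexicon)
    gene_ids = sorted(gene_lex.canonical)
    drug_ids = sorted(drug_lex.canonical)

    class_idx = rng.choice(len(CLASSES), size=cfg.n_docs, p=list(cfg.class_mixture))
    documents: list[Document] = []
    labels: list[DocLabels] = []
    docs_with_gene: dict[str, dict[str, list[str]]] = {
        gid: {"clinical_cancer": [], "other": []} for gid in gene_ids
    }

    for d in range(cfg.n_docs):
        cls = CLASSES[int(class_idx[d])]
        is_cancer = cls != "non_cancer"
        is_clinical = cls == "clinical_cancer"
        ctype = (
            CANCER_TYPES[int(rng.choice(len(CANCER_TYPES), p=list(cfg.ctype_mixture)))]
            if is_cancer
            else CTYPE_NONE
        )

        length = max(10, int(rng.poisson(cfg.doc_length)))
        vocab = class_vocab[cls]
        tokens = [vocab[int(i)] for i in rng.integers(0, len(vocab), size=length)]
        if is_cancer:
            markers = ctype_vocab[ctype]
            for i in range(length):
                if rng.random() < _CTYPE_MARKER_RATE:
                    tokens[i] = markers[int(rng.integers(len(markers)))]

        # entity injections: (token insert position, surface, etype, norm_id)
        injections: list[tuple[int, str, str, str]] = []
        doc_gene: str | None = None
        if rng.random() < cfg.gene_injection_rate:
            doc_gene = gene_ids[int(rng.integers(len(gene_ids)))]
            surfaces = sorted(gene_lex.synonyms[doc_gene])
            surface = surfaces[int(rng.integers(len(surfaces)))]
            injections.append((int(rng.integers(0, length + 1)), surface, "gene", doc_gene))
        if rng.random() < cfg.variant_injection_rate:
            surface = _variant_surface(rng)
            injections.append((int(rng.integers(0, length + 1)), surface, "variant", canonical_variant(surface)))
        if rng.random() < cfg.drug_injection_rate:
            did = drug_ids[int(rng.integers(len(drug_ids)))]
            injections.append((int(rng.integers(0, length + 1)), drug_lex.canonical[did], "drug", did))

        # splice injected surfaces into the token stream
        inj_map: dict[int, list[tuple[str, str, str]]] = {}
        for pos, surface, etype, norm in injections:
            inj_map.setdefault(pos, []).append((surface, etype, norm))
        final_tokens: list[str] = []
        placed: list[tuple[int, str, str, str]] = []  # final token index, surface, etype, norm
        for i in range(length + 1):
            for surface, etype, norm in inj_map.get(i, []):
                placed.append((len(final_tokens), surface, etype, norm))
                final_tokens.append(surface)
            if i < length:
                final_tokens.append(tokens[i])

        title = " ".join(final_tokens[:_TITLE_TOKENS])
        abstract = " ".join(final_tokens[_TITLE_TOKENS:])
        doc_id = f"S{d:06d}"

        # char offset of each token in the single-space join
        offsets: list[int] = []
        cursor = 0
        for t in final_tokens:
            offsets.append(cursor)
            cursor += len(t) + 1

        mentions = [
            EntityMention(etype, offsets[ti], offsets[ti] + len(surface), surface, norm)
            for ti, surface, etype, norm in placed
        ]
        mentions.sort(key=lambda m: m.start)

        doc = Document(
            doc_id=doc_id,
            title=title,
            abstract=abstract,
            pub_year=int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1)),
            journal="synthetic",
            mentions=mentions,
            type_label=ctype if is_cancer else None,
        )
        doc.validate()
        documents.append(doc)
        labels.append(DocLabels(cancer=is_cancer, clinical=is_clinical, ctype=ctype))
        if doc_gene is not None:
            bucket = "clinical_cancer" if is_clinical else "other"
            docs_with_gene[doc_gene][bucket].append(doc_id)

    for i, cls in enumerate(CLASSES):
        if cfg.class_mixture[i] > 0 and not any(int(c) == i for c in class_idx):
            raise ValueError(f"stratum {cls!r} is empty at n_docs={cfg.n_docs}")

    gold = {
        gene_lex.canonical[gid]: set(buckets["clinical_cancer"])
        for gid, buckets in docs_with_gene.items()
    }
    if all(not s for s in gold.values()):
        raise ValueError(
            "every per-gene gold set is empty "
            "(gene_injection_rate too low or no clinically relevant documents)"
        )

    judgments: list[JudgmentSet] = []
    for gid in gene_ids:
        rel_pool = docs_with_gene[gid]["clinical_cancer"]
        irr_pool = docs_with_gene[gid]["other"]
        if not rel_pool or not irr_pool:
            continue
        n_rel = min(len(rel_pool), cfg.max_relevant_per_query)
        n_irr = min(len(irr_pool), cfg.max_irrelevant_per_query)
        rel = rng.choice(rel_pool, size=n_rel, replace=False)
        irr = rng.choice(irr_pool, size=n_irr, replace=False)
        judgments.append(
            JudgmentSet(
                query_id=gene_lex.canonical[gid],
                relevant=set(map(str, rel)),
                irrelevant=set(map(str, irr)),
            )
        )

    return SyntheticBundle(
        config=cfg,
        documents=documents,
        labels=labels,
        gene_lexicon=gene_lex,
        drug_lexicon=drug_lex,
        gold=gold,
        judgments=judgments,
    )


# ---------------------------------------------------------------------------
# Ranked fixtures for the metrics suite
# ---------------------------------------------------------------------------

def generate_ranked_fixture(
    n_rel: int = 0,
    n_irrel: int = 0,
    pattern: str | dict = "top_block",
    seed: int = 0,
) -> tuple[RankedResult, JudgmentSet]:
    """Build a ranking with judged documents placed per ``pattern``.

    ``pattern`` is one of ``top_block`` (all relevant first),
    ``bottom_block``, ``alternating`` (starting relevant), ``random``
    (seeded shuffle), or an explicit mapping
    ``{"relevant_positions": [...], "irrelevant_positions": [...]}``
    of 1-based ranks (gaps are filled with unjudged documents).
    """
    if isinstance(pattern, dict):
        rel_pos = sorted(pattern["relevant_positions"])
        irr_pos = sorted(pattern["irrelevant_positions"])
        if set(rel_pos) & set(irr_pos):
            raise ValueError("relevant and irrelevant positions overlap")
        if min(rel_pos + irr_pos) < 1:
            raise ValueError("positions are 1-based")
        total = max(rel_pos + irr_pos)
        ids = []
        rel_ids, irr_ids = set(), set()
        r = i = 0
        for pos in range(1, total + 1):
            if pos in set(rel_pos):
                r += 1
                did = f"R{r}"
                rel_ids.add(did)
            elif pos in set(irr_pos):
                i += 1
                did = f"I{i}"
                irr_ids.add(did)
            else:
                did = f"U{pos}"
            ids.append(did)
        return (
            RankedResult("fixture", ids, sort_key="fixture"),
            JudgmentSet("fixture", rel_ids, irr_ids),
        )

    if n_rel <= 0 or n_irrel <= 0:
        raise ValueError("n_rel and n_irrel must be positive")
    rel_ids = [f"R{i+1}" for i in range(n_rel)]
    irr_ids = [f"I{i+1}" for i in range(n_irrel)]
    if pattern == "top_block":
        ids = rel_ids + irr_ids
    elif pattern == "bottom_block":
        ids = irr_ids + rel_ids
    elif pattern == "alternating":
        ids = []
        for a, b in zip(rel_ids, irr_ids):
            ids.extend([a, b])
        ids.extend(rel_ids[n_irrel:] or irr_ids[n_rel:])
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        ids = rel_ids + irr_ids
        rng.shuffle(ids)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return (
        RankedResult("fixture", ids, sort_key=str(pattern)),
        JudgmentSet("fixture", set(rel_ids), set(irr_ids)),
    )


# ---------------------------------------------------------------------------
# Serialization of a bundle (used by the command-line `simulate`)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write corpus.jsonl, lexicon TSVs, labels, gold and judgments."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_documents_jsonl(bundle.documents, out / "corpus.jsonl")
    write_lexicon_tsv(
        (
            (gid, bundle.gene_lexicon.canonical[gid], sorted(bundle.gene_lexicon.synonyms[gid]))
            for gid in sorted(bundle.gene_lexicon.canonical)
        ),
        out / "gene_lexicon.tsv",
    )
    write_lexicon_tsv(
        (
            (did, bundle.drug_lexicon.canonical[did], sorted(bundle.drug_lexicon.synonyms[did]))
            for did in sorted(bundle.drug_lexicon.canonical)
        ),
        out / "drug_lexicon.tsv",
    )
    with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tcancer\tclinical\tctype\n")
        for doc, lab in zip(bundle.documents, bundle.labels):
            fh.write(f"{doc.doc_id}\t{int(lab.cancer)}\t{int(lab.clinical)}\t{lab.ctype}\n")
    with open(out / "gold.tsv", "w", encoding="utf-8") as fh:
        for gene in sorted(bundle.gold):
            for did in sorted(bundle.gold[gene]):
                fh.write(f"{gene}\t{did}\n")
    with open(out / "judgments.tsv", "w", encoding="utf-8") as fh:
        for js in bundle.judgments:
            for did in sorted(js.relevant):
                fh.write(f"{js.query_id}\t{did}\trelevant\n")
            for did in sorted(js.irrelevant):
                fh.write(f"{js.query_id}\t{did}\tirrelevant\n")
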