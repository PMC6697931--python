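"""Document, judgment and assessment containers plus readers/writers.

All entity offsets in this package refer to the *annotated text* of a
document, defined as ``title + " " + abstract`` (a single-space join).
Offsets are 0-based, half-open.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: Sentinel publication year for documents without a usable date.  It sorts
#: below every real 4-digit year, which is all the ranking layer needs.
UNKNOWN_YEAR = 0

ENTITY_TYPES = ("gene", "variant", "drug")


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed, normalized span inside a document's annotated text.

    ``norm_id`` holds a gene identifier for genes, the canonical variant
    string for variants and a lexicon identifier for drugs.
    """

    etype: str
    start: int
    end: int
    surface: str
    norm_id: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start},{self.end})")


@dataclass
class Document:
    """One abstract-level record with metadata and entity annotations."""

    doc_id: str
    title: str
    abstract: str = ""
    pub_year: int = UNKNOWN_YEAR
    journal: str = ""
    mentions: list[EntityMention] = field(default_factory=list)
    type_label: str | None = None

    @property
    def text(self) -> str:
        """Annotated text: title and abstract joined by a single space."""
        return f"{self.title} {self.abstract}"

    def validate(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        n = len(self.text)
        for m in self.mentions:
            if m.end > n:
                raise ValueError(
                    f"{self.doc_id}: mention [{m.start},{m.end}) outside text of length {n}"
                )
            if self.text[m.start : m.end] != m.surface:
                raise ValueError(
                    f"{self.doc_id}: surface {m.surface!r} does not match slice "
                    f"{self.text[m.start:m.end]!r}"
                )


@dataclass
class JudgmentSet:
    """Binary relevance judgments for one query."""

    query_id: str
    relevant: set[str] = field(default_factory=set)
    irrelevant: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.relevant & self.irrelevant
        if overlap:
            raise ValueError(
                f"query {self.query_id}: documents judged both ways: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class RawAssessment:
    """A single rater's 5-point Likert judgment of a (query, document) pair.

    1 means "not relevant at all", 5 means "highly relevant".
    """

    query_id: str
    doc_id: str
    rater_id: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"score must be in 1..5, got {self.score}")


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def read_pubmed_xml(path: str | Path) -> list[Document]:
    """Parse a PubMed article-set XML file into :class:`Document` records.

    Only a small dialect is consumed: PMID, ArticleTitle, AbstractText
    (possibly multiple, concatenated in document order with a single
    space), Journal/Title and PubDate/Year.  Articles without a PMID or
    without a non-empty title are skipped (a warning reports the count).
    The publication year is the earliest complete year found in any
    PubDate; absent that, :data:`UNKNOWN_YEAR`.
    """
    tree = etree.parse(str(path))  # raises XMLSyntaxError with position info
    docs: list[Document] = []
    skipped = 0
    for art in tree.getroot().iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        title = _all_text(art.find(".//ArticleTitle"))
        if not pmid or not title.strip():
            skipped += 1
            continue
        sections = [_all_text(el) for el in art.iter("AbstractText")]
        abstract = " ".join(s.strip() for s in sections if s.strip())
        years = []
        for pd in art.iter("PubDate"):
            y = pd.findtext("Year")
            if y and y.strip().isdigit() and len(y.strip()) == 4:
                years.append(int(y.strip()))
        journal = art.findtext(".//Journal/Title") or ""
        docs.append(
            Document(
                doc_id=pmid.strip(),
                title=title.strip(),
                abstract=abstract,
                pub_year=min(years) if years else UNKNOWN_YEAR,
                journal=journal.strip(),
            )
        )
    if skipped:
        logger.warning("skipped %d article(s) without PMID or title", skipped)
    _check_unique_ids(docs)
    return docs


def _all_text(el) -> str:
    return "".join(el.itertext()) if el is not None else ""


def _check_unique_ids(docs: Sequence[Document]) -> None:
    counts = Counter(d.doc_id for d in docs)
    dupes = [k for k, v in counts.items() if v > 1]
    if dupes:
        raise ValueError(f"duplicate doc_id(s): {dupes[:5]}")


# ---------------------------------------------------------------------------
# JSONL document store
# ---------------------------------------------------------------------------

def write_documents_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    """Serialize documents, one JSON object per line (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = asdict(d)
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_documents_jsonl(path: str | Path) -> list[Document]:
    """Read a JSONL document store written by :func:`write_documents_jsonl`.

    The ``mentions`` and ``type_label`` keys are optional; ``doc_id`` and
    ``title`` are required and their absence is reported with the line
    number.  Round-trips losslessly, including mention offsets.
    """
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            for key in ("doc_id", "title"):
                if key not in rec:
                    raise ValueError(f"{path}:{lineno}: missing required key {key!r}")
            mentions = [EntityMention(**m) for m in rec.get("mentions", [])]
            docs.append(
                Document(
                    doc_id=rec["doc_id"],
                    title=rec["title"],
                    abstract=rec.get("abstract", ""),
                    pub_year=int(rec.get("pub_year", UNKNOWN_YEAR)),
                    journal=rec.get("journal", ""),
                    mentions=mentions,
                    type_label=rec.get("type_label"),
                )
            )
    _check_unique_ids(docs)
    return docs


# ---------------------------------------------------------------------------
# Relevance judgments
# ---------------------------------------------------------------------------

_LABELS = {"relevant", "irrelevant"}


def read_judgments_tsv(path: str | Path) -> list[JudgmentSet]:
    """Read ``query_id<TAB>doc_id<TAB>label`` triples into judgment sets.

    ``label`` must be ``relevant`` or ``irrelevant``.  Duplicate
    (query, doc) rows with conflicting labels are an error.
    """
    seen: dict[tuple[str, str], str] = {}
    order: list[str] = []
    sets: dict[str, JudgmentSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            qid, did, label = parts
            if label not in _LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            key = (qid, did)
            if key in seen:
                if seen[key] != label:
                    raise ValueError(
                        f"{path}:{lineno}: conflicting labels for query {qid}, doc {did}"
                    )
                continue
            seen[key] = label
            if qid not in sets:
                sets[qid] = JudgmentSet(query_id=qid)
                order.append(qid)
            (sets[qid].relevant if label == "relevant" else sets[qid].irrelevant).add(did)
    return [sets[q] for q in order]


def read_raw_assessments_tsv(path: str | Path) -> list[RawAssessment]:
    """Read ``query_id<TAB>doc_id<TAB>rater_id<TAB>score`` rows."""
    out: list[RawAssessment] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            qid, did, rater, score = parts
            try:
                out.append(RawAssessment(qid, did, rater, int(score)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


@dataclass
class ConsolidationSummary:
    """Bookkeeping for :func:`consolidate_assessments`."""

    n_pairs: int = 0
    n_removed: int = 0
    n_relevant: int = 0
    n_irrelevant: int = 0
    n_ties: int = 0


def consolidate_assessments(
    raw: Iterable[RawAssessment],
    threshold: int = 4,
    summary: ConsolidationSummary | None = None,
) -> list[JudgmentSet]:
    """Consolidate multi-rater Likert assessments into binary judgments.

    A (query, document) pair rated "highly relevant" (5) by at least one
    rater and "not relevant at all" (1) by at least one other is removed
    as contested.  Every remaining pair is decided by majority vote after
    binarizing each rater's score (``score >= threshold`` counts as a
    relevant vote; default threshold 4).  Exact ties are discarded.
    """
    by_pair: dict[tuple[str, str], list[int]] = defaultdict(list)
    order: list[str] = []
    for a in raw:
        if a.query_id not in order:
            order.append(a.query_id)
        by_pair[(a.query_id, a.doc_id)].append(a.score)

    sets: dict[str, JudgmentSet] = {}
    summ = summary if summary is not None else ConsolidationSummary()
    summ.n_pairs = len(by_pair)
    for (qid, did), scores in by_pair.items():
        if 5 in scores and 1 in scores:
            summ.n_removed += 1
            continue
        pos = sum(1 for s in scores if s >= threshold)
        neg = len(scores) - pos
        if pos == neg:
            summ.n_ties += 1
            continue
        js = sets.setdefault(qid, JudgmentSet(query_id=qid))
        if pos > neg:
            js.relevant.add(did)
            summ.n_relevant += 1
        else:
            js.irrelevant.add(did)
            summ.n_irrelevant += 1
    return [sets[q] for q in order if q in sets]


# ---------------------------------------------------------------------------
# Lexicon TSV (shared with the annotate module)
# ---------------------------------------------------------------------------

def read_lexicon_rows(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read lexicon rows ``id<TAB>canonical<TAB>syn1|syn2|...``.

    Returns raw rows; the annotate module enforces the lexicon invariants.
    An empty synonym column means the canonical name is the only surface.
    """
    rows: list[tuple[str, str, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            ident, canonical = parts[0], parts[1]
            syns = [s for s in (parts[2].split("|") if len(parts) > 2 else []) if s]
            rows.append((ident, canonical, syns))
    return rows


def write_lexicon_tsv(rows: Iterable[tuple[str, str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ident, canonical, syns in rows:
            fh.write(f"{ident}\t{canonical}\t{'|'.join(syns)}\n")
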