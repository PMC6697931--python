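"""Lexicon- and rule-based entity annotation.

Desk-scale named-entity recognition for gene, variant and drug mentions
in abstracts.  Gene and drug mentions come from dictionary matching with
synonym support; variant mentions from a small ordered regex grammar
covering protein substitutions (short form and HGVS-like ``p.`` forms),
HGVS-like coding ``c.`` substitutions/indels, and dbSNP rsIDs.
Precomputed annotations can instead be supplied through the JSONL
``mentions`` field, bypassing these annotators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import Document, EntityMention, read_lexicon_rows

# Token characters for boundary checks.  "-" is allowed inside a symbol so
# that surfaces like "B-RAF1" match whole while substring hits inside
# larger tokens ("xBRAFx", "nab-paclitaxel" vs "paclitaxel") are rejected.
_TOKEN_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-")

#: Gene symbols of at most this length are matched case-sensitively;
#: short symbols are too often ordinary English words.
CASE_SENSITIVE_MAX_LEN = 4


@dataclass
class Lexicon:
    """Identifier -> {canonical, synonyms} with a global synonym->id map.

    Every surface (synonym) must resolve to exactly one identifier; the
    canonical name is always a member of its own synonym set.
    """

    kind: str  # "gene" | "drug"
    canonical: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, set[str]] = field(default_factory=dict)
    surface_to_id: dict[str, str] = field(default_factory=dict)

    def add(self, ident: str, canonical: str, synonyms: list[str]) -> None:
        surfaces = {canonical, *synonyms}
        for s in surfaces:
            owner = self.surface_to_id.get(s)
            if owner is not None and owner != ident:
                raise ValueError(
                    f"synonym {s!r} maps to both {owner!r} and {ident!r}"
                )
        self.canonical[ident] = canonical
        self.synonyms[ident] = surfaces
        for s in surfaces:
            self.surface_to_id[s] = ident

    def __len__(self) -> int:
        return len(self.canonical)


GeneLexicon = Lexicon
DrugLexicon = Lexicon


def load_lexicon(path: str | Path, kind: str) -> Lexicon:
    """Load a TSV lexicon (``id<TAB>canonical<TAB>syn1|syn2|...``).

    Raises if two entries share a surface, naming the colliding synonym.
    """
    if kind not in ("gene", "drug"):
        raise ValueError(f"kind must be 'gene' or 'drug', got {kind!r}")
    lex = Lexicon(kind=kind)
    for ident, canonical, syns in read_lexicon_rows(path):
        lex.add(ident, canonical, syns)
    return lex


def _boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and text[start - 1] in _TOKEN_CHARS:
        return False
    if end < len(text) and text[end] in _TOKEN_CHARS:
        return False
    return True


def _find_surface(text: str, lowered: str, surface: str, case_sensitive: bool):
    """Yield (start, end) of token-boundary-aligned occurrences."""
    hay = text if case_sensitive else lowered
    needle = surface if case_sensitive else surface.lower()
    pos = 0
    while True:
        i = hay.find(needle, pos)
        if i < 0:
            return
        j = i + len(needle)
        if _boundary_ok(text, i, j):
            yield i, j
        pos = i + 1


def _resolve_overlaps(cands: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Greedy longest-match-first, leftmost on ties; output sorted by start."""
    chosen: list[tuple[int, int, str]] = []
    for start, end, ident in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[0])):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, ident))
    return sorted(chosen)


def _annotate_lexicon(doc: Document, lex: Lexicon, etype: str, short_sensitive: bool) -> list[EntityMention]:
    text = doc.text
    lowered = text.lower()
    cands: list[tuple[int, int, str]] = []
    for surface, ident in lex.surface_to_id.items():
        cs = short_sensitive and len(surface) <= CASE_SENSITIVE_MAX_LEN
        for i, j in _find_surface(text, lowered, surface, cs):
            cands.append((i, j, ident))
    return [
        EntityMention(etype, i, j, text[i:j], ident)
        for i, j, ident in _resolve_overlaps(cands)
    ]


def annotate_genes(doc: Document, lex: GeneLexicon) -> list[EntityMention]:
    """Dictionary-match gene mentions and normalize them to gene ids.

    Symbols of length <= 4 match case-sensitively, longer ones
    case-insensitively; matches must be token-boundary aligned and the
    output is non-overlapping (longest match wins).
    """
    return _annotate_lexicon(doc, lex, "gene", short_sensitive=True)


def annotate_drugs(doc: Document, lex: DrugLexicon) -> list[EntityMention]:
    """Dictionary-match drug mentions, case-insensitive throughout."""
    return _annotate_lexicon(doc, lex, "drug", short_sensitive=False)


# ---------------------------------------------------------------------------
# Variant grammar
# ---------------------------------------------------------------------------

_AA3 = "(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter)"


@dataclass(frozen=True)
class VariantPattern:
    name: str
    regex: re.Pattern


def _default_patterns() -> tuple[VariantPattern, ...]:
    b_l = r"(?<![A-Za-z0-9.])"
    b_r = r"(?![A-Za-z0-9])"
    return (
        VariantPattern(
            "protein_p_form",
            re.compile(rf"{b_l}p\.\s?(?:{_AA3}\d+{_AA3}|[A-Z]\d+[A-Z*]){b_r}"),
        ),
        VariantPattern(
            "coding_c_form",
            re.compile(
                rf"{b_l}c\.\s?\d+(?:_\d+)?"
                rf"(?:\s?[ACGT]\s?>\s?[ACGT]|del[ACGT]*|ins[ACGT]+|dup[ACGT]*|delins[ACGT]+){b_r}"
            ),
        ),
        VariantPattern("rsid", re.compile(rf"{b_l}rs\d+{b_r}")),
        VariantPattern("protein_short_form", re.compile(rf"{b_l}[A-Z]\d+[A-Z*]{b_r}")),
    )


@dataclass
class VariantGrammar:
    """Ordered variant patterns; overlaps resolved longest-match-first.

    Covers the variant classes that dominate abstract-level mention
    recognizers: one-letter protein substitutions (``V600E``), HGVS-like
    protein ``p.`` forms (1- and 3-letter), coding ``c.`` substitutions
    and small indels, and rsIDs.  Fusions and CNVs are out of scope.
    """

    patterns: tuple[VariantPattern, ...] = field(default_factory=_default_patterns)


def canonical_variant(surface: str) -> str:
    """Canonical form: whitespace stripped; bare short forms uppercased."""
    s = re.sub(r"\s+", "", surface)
    if re.fullmatch(r"[A-Za-z]\d+[A-Za-z*]", s):
        return s.upper()
    return s


def annotate_variants(doc: Document, grammar: VariantGrammar | None = None) -> list[EntityMention]:
    """Match the variant grammar against a document's annotated text.

    ``norm_id`` is the canonical form (see :func:`canonical_variant`);
    duplicate matches at identical spans are deduplicated and overlapping
    matches resolved longest-first, leftmost, then pattern order.
    """
    grammar = grammar or VariantGrammar()
    text = doc.text
    cands: list[tuple[int, int, int]] = []  # start, end, pattern index
    seen_spans: set[tuple[int, int]] = set()
    for p_idx, pat in enumerate(grammar.patterns):
        for m in pat.regex.finditer(text):
            span = m.span()
            if span in seen_spans:
                continue
            seen_spans.add(span)
            cands.append((span[0], span[1], p_idx))
    chosen: list[tuple[int, int]] = []
    for start, end, _ in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        if all(end <= s or start >= e for s, e in chosen):
            chosen.append((start, end))
    return [
        EntityMention("variant", i, j, text[i:j], canonical_variant(text[i:j]))
        for i, j in sorted(chosen)
    ]


_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}


def fold_three_letter(variant: str) -> str:
    """Optional normalization: fold 3-letter amino-acid codes to 1-letter.

    ``p.Val600Glu`` -> ``V600E``; strings without a 3-letter protein
    substitution are returned unchanged (minus a ``p.`` prefix on
    1-letter forms).
    """
    m = re.fullmatch(rf"(?:p\.)?({_AA3})(\d+)({_AA3})", variant)
    if m:
        return _AA3_TO_1[m.group(1)] + m.group(2) + _AA3_TO_1[m.group(3)]
    m = re.fullmatch(r"p\.([A-Z]\d+[A-Z*])", variant)
    if m:
        return m.group(1)
    return variant


# ---------------------------------------------------------------------------
# Query-side synonym expansion
# ---------------------------------------------------------------------------

def expand_gene_query(symbols: set[str], lex: GeneLexicon) -> tuple[set[str], set[str]]:
    """Expand query gene symbols with all lexicon synonyms.

    Returns ``(expanded_surfaces, unresolved)``.  A symbol resolves by
    exact surface match first, then case-insensitively if unambiguous;
    unresolved symbols are passed through verbatim and flagged.
    """
    lowered: dict[str, set[str]] = {}
    for surface, ident in lex.surface_to_id.items():
        lowered.setdefault(surface.lower(), set()).add(ident)
    expanded: set[str] = set()
    unresolved: set[str] = set()
    for sym in symbols:
        ident = lex.surface_to_id.get(sym)
        if ident is None:
            ids = lowered.get(sym.lower(), set())
            ident = next(iter(ids)) if len(ids) == 1 else None
        if ident is None:
            expanded.add(sym)
            unresolved.add(sym)
        else:
            expanded |= lex.synonyms[ident]
    return expanded, unresolved


def resolve_gene_ids(symbols: set[str], lex: GeneLexicon) -> set[str]:
    """Map query gene symbols to lexicon identifiers (unresolved dropped)."""
    ids: set[str] = set()
    lowered: dict[str, set[str]] = {}
    for surface, ident in lex.surface_to_id.items():
        lowered.setdefault(surface.lower(), set()).add(ident)
    for sym in symbols:
        ident = lex.surface_to_id.get(sym)
        if ident is None:
            cands = lowered.get(sym.lower(), set())
            ident = next(iter(cands)) if len(cands) == 1 else None
        if ident is not None:
            ids.add(ident)
    return ids
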