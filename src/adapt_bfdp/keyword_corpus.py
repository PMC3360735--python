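"""Per-gene literature corpora and keyword-group classification.

Each gene carries a set of documents (PubMed-style abstracts or short
curated summaries). Keywords are organised in three tiers: G1 holds terms
specific to the phenotype of interest, G2 terms that are strongly relevant
to it, and G3 generically relevant terms. A gene's literature is reduced to
three binary flags — does any retained document contain any phrase of the
tier, matched on morphological roots? Match frequency is deliberately
ignored; the signal is presence, not abundance.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field

from .stem import porter_stem

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")

__all__ = [
    "Document",
    "GeneDocument",
    "KeywordConfig",
    "GroupFlags",
    "normalize_text",
    "match_phrase",
    "classify_gene",
    "read_corpus",
    "write_corpus",
    "read_keyword_config",
]


@dataclass(frozen=True)
class Document:
    """One abstract or curated summary linked to a gene."""

    doc_id: str
    text: str
    date: _dt.date | None = None


@dataclass
class GeneDocument:
    """A gene with genomic coordinates and its linked literature.

    Coordinates are 1-based and the interval [start, end] is closed.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class GroupFlags:
    """Binary presence flags for the three keyword tiers."""

    g1: bool = False
    g2: bool = False
    g3: bool = False

    def __or__(self, other: "GroupFlags") -> "GroupFlags":
        return GroupFlags(
            self.g1 or other.g1, self.g2 or other.g2, self.g3 or other.g3
        )


class KeywordConfig:
    """Three keyword tiers plus an optional publication-date cutoff.

    Phrases are normalized to stem sequences once, at construction.
    A cutoff restricts classification to literature published strictly
    before that date (e.g. before the first GWAS of the phenotype, to
    avoid circular priors).
    """

    def __init__(
        self,
        g1: list[str],
        g2: list[str],
        g3: list[str],
        date_cutoff: _dt.date | None = None,
    ) -> None:
        self.g1 = list(g1)
        self.g2 = list(g2)
        self.g3 = list(g3)
        self.date_cutoff = date_cutoff
        self._stems: dict[str, list[tuple[str, ...]]] = {}
        for name, phrases in (("g1", self.g1), ("g2", self.g2), ("g3", self.g3)):
            compiled = []
            for phrase in phrases:
                stems = tuple(normalize_text(phrase))
                if not stems:
                    raise ValueError(
                        f"keyword phrase {phrase!r} in {name} is empty after "
                        "normalization"
                    )
                compiled.append(stems)
            self._stems[name] = compiled

    def phrase_stems(self, group: str) -> list[tuple[str, ...]]:
        return self._stems[group]


def normalize_text(text: str) -> list[str]:
    """Lowercase, tokenize and stem free text; order preserved.

    Tokens are maximal runs of ASCII letters/digits; punctuation-only
    content disappears. Empty input yields an empty list.
    """
    return [porter_stem(tok) for tok in _TOKEN_RE.findall(text.lower())]


def match_phrase(doc_stems: list[str], phrase: str | tuple[str, ...]) -> bool:
    """True iff the phrase's stem sequence occurs contiguously in doc_stems.

    ``phrase`` may be raw text (normalized here) or an already-normalized
    stem tuple. A phrase that normalizes to nothing is an invalid keyword.
    """
    if isinstance(phrase, str):
        target: tuple[str, ...] = tuple(normalize_text(phrase))
    else:
        target = tuple(phrase)
    if not target:
        raise ValueError("keyword phrase is empty after normalization")
    k = len(target)
    if k > len(doc_stems):
        return False
    if k == 1:
        return target[0] in doc_stems
    first = target[0]
    for i in range(len(doc_stems) - k + 1):
        if doc_stems[i] == first and tuple(doc_stems[i : i + k]) == target:
            return True
    return False


def _retained_documents(
    gene: GeneDocument, cutoff: _dt.date | None
) -> list[Document]:
    if cutoff is None:
        return gene.documents
    kept = []
    for doc in gene.documents:
        if doc.date is None:
            logger.warning(
                "gene %s: document %s has no date; retained despite cutoff %s",
                gene.gene_id,
                doc.doc_id,
                cutoff,
            )
            kept.append(doc)
        elif doc.date < cutoff:
            kept.append(doc)
    return kept


def classify_gene(gene: GeneDocument, config: KeywordConfig) -> GroupFlags:
    """Classify one gene's literature into tier presence flags.

    A flag is set iff any phrase of the tier matches any retained document.
    Document order, duplication and match counts do not matter; adding a
    document can only switch flags on, never off.
    """
    docs = _retained_documents(gene, config.date_cutoff)
    flags = {"g1": False, "g2": False, "g3": False}
    for doc in docs:
        stems = normalize_text(doc.text)
        for group in ("g1", "g2", "g3"):
            if flags[group]:
                continue
            if any(match_phrase(stems, p) for p in config.phrase_stems(group)):
                flags[group] = True
        if all(flags.values()):
            break
    return GroupFlags(**flags)


# ---------------------------------------------------------------------------
# I/O: JSON Lines corpus, JSON keyword config


def _parse_date(value: str | None) -> _dt.date | None:
    if value is None:
        return None
    return _dt.date.fromisoformat(value)


def read_corpus(path: str) -> list[GeneDocument]:
    """Read a JSONL corpus, one gene per line."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                docs = [
                    Document(
                        doc_id=str(d["doc_id"]),
                        text=d["text"],
                        date=_parse_date(d.get("date")),
                    )
                    for d in rec.get("documents", [])
                ]
                genes.append(
                    GeneDocument(
                        gene_id=str(rec["gene_id"]),
                        symbol=rec.get("symbol", str(rec["gene_id"])),
                        chrom=str(rec["chrom"]),
                        start=int(rec["start"]),
                        end=int(rec["end"]),
                        documents=docs,
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed corpus line: {exc}")
    return genes


def write_corpus(genes: list[GeneDocument], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            rec = {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "documents": [
                    {
                        "doc_id": d.doc_id,
                        "text": d.text,
                        "date": d.date.isoformat() if d.date else None,
                    }
                    for d in g.documents
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_keyword_config(path: str) -> KeywordConfig:
    """Read a JSON keyword configuration with keys g1, g2, g3, date_cutoff."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return KeywordConfig(
        g1=raw["g1"],
        g2=raw["g2"],
        g3=raw["g3"],
        date_cutoff=_parse_date(raw.get("date_cutoff")),
    )
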