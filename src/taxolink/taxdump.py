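"""Reading and indexing NCBI taxonomy dump ("taxdump") files.

The taxdump dialect is line-oriented text: fields are separated by
``\\t|\\t`` and each line is terminated by ``\\t|``.  Three files are
consumed:

* ``nodes.dmp``  — the taxonomy tree: tax_id, parent tax_id, rank and the
  GenBank division code (columns 1, 2, 3 and 5; the remaining columns are
  preserved opaquely so a parsed dump can be re-serialised byte-identically).
* ``names.dmp``  — every name attached to a tax_id with its name class.
  Exactly one name per taxon carries the class ``scientific name``; the
  others (synonyms, misspellings, common names, authorities...) are what
  name reconciliation falls back to.
* ``citations.dmp`` — bibliographic records, each linked to zero or more
  tax_ids.

:class:`Taxonomy` assembles nodes and names into an indexed structure with
lineage walks, homonym lookups (one scientific name borne by several
tax_ids, e.g. the frog genus *Rana* and its nominotypical subgenus) and
name-class queries.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

SCIENTIFIC_NAME = "scientific name"

_FIELD_SEP = "\t|\t"
_LINE_TERM = "\t|"
_WS_RUN = re.compile(r"\s+")


def normalize_name(text: str) -> str:
    """Whitespace- and Unicode-normalise a taxon name.

    Leading/trailing whitespace is stripped, internal runs collapse to a
    single space, and the result is NFC-normalised.  Name comparison
    throughout the package is exact and case-sensitive after this.
    """
    return unicodedata.normalize("NFC", _WS_RUN.sub(" ", text.strip()))


def split_line(line: str, lineno: int) -> list[str]:
    """Split one taxdump line into its raw fields."""
    line = line.rstrip("\n").rstrip("\r")
    if line.endswith(_LINE_TERM):
        line = line[: -len(_LINE_TERM)]
    elif line.endswith("|"):  # tolerate a missing tab before the final pipe
        line = line[:-1].rstrip("\t")
    else:
        raise ParseError("line not terminated by tab-pipe", line=lineno)
    return line.split(_FIELD_SEP)


def join_fields(fields: Iterable[str]) -> str:
    return _FIELD_SEP.join(fields) + _LINE_TERM


def _int_field(value: str, what: str, lineno: int) -> int:
    try:
        return int(value.strip())
    except ValueError:
        raise ParseError(f"non-integer {what}: {value!r}", line=lineno) from None


@dataclass(frozen=True)
class TaxonNode:
    """One row of nodes.dmp.

    ``extra`` holds the unmodelled trailing columns verbatim so that
    serialisation round-trips.
    """

    tax_id: int
    parent_tax_id: int
    rank: str
    division_id: int
    embl_code: str = ""
    extra: tuple[str, ...] = ()

    def to_line(self) -> str:
        fields = [str(self.tax_id), str(self.parent_tax_id), self.rank,
                  self.embl_code, str(self.division_id), *self.extra]
        return join_fields(fields)


@dataclass(frozen=True)
class TaxonName:
    """One row of names.dmp (a name attached to a taxon)."""

    tax_id: int
    name_text: str
    name_class: str
    unique_name: str = ""

    def to_line(self) -> str:
        return join_fields([str(self.tax_id), self.name_text,
                            self.unique_name, self.name_class])


@dataclass(frozen=True)
class CitationRecord:
    """One row of citations.dmp; ``pubmed_id`` of 0 is stored as absent."""

    cit_id: int
    citation_key: str
    pubmed_id: int | None
    url: str | None
    free_text: str
    tax_ids: tuple[int, ...]

    def to_line(self) -> str:
        return join_fields([
            str(self.cit_id), self.citation_key, "0",
            str(self.pubmed_id or 0), self.url or "", self.free_text,
            " ".join(str(t) for t in self.tax_ids),
        ])


def _lines(stream: IO[str] | str | Iterable[str]) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        stream = stream.splitlines(keepends=True)
    for i, line in enumerate(stream, start=1):
        if line.strip():
            yield i, line


def parse_nodes(stream: IO[str] | str | Iterable[str]) -> list[TaxonNode]:
    """Parse nodes.dmp. Columns 1, 2, 3, 5 become tax_id, parent, rank,
    division_id; everything else is carried opaquely."""
    nodes = []
    for lineno, line in _lines(stream):
        f = split_line(line, lineno)
        if len(f) < 5:
            raise ParseError(f"nodes.dmp line has {len(f)} fields, expected >= 5",
                             line=lineno)
        nodes.append(TaxonNode(
            tax_id=_int_field(f[0], "tax_id", lineno),
            parent_tax_id=_int_field(f[1], "parent tax_id", lineno),
            rank=f[2].strip(),
            division_id=_int_field(f[4], "division_id", lineno),
            embl_code=f[3],
            extra=tuple(f[5:]),
        ))
    return nodes


def parse_names(stream: IO[str] | str | Iterable[str]) -> list[TaxonName]:
    """Parse names.dmp; name text is whitespace/NFC normalised."""
    names = []
    seen_scientific: dict[int, str] = {}
    for lineno, line in _lines(stream):
        f = split_line(line, lineno)
        if len(f) < 4:
            raise ParseError(f"names.dmp line has {len(f)} fields, expected 4",
                             line=lineno)
        rec = TaxonName(
            tax_id=_int_field(f[0], "tax_id", lineno),
            name_text=normalize_name(f[1]),
            unique_name=f[2].strip(),
            name_class=f[3].strip(),
        )
        if rec.name_class == SCIENTIFIC_NAME:
            if rec.tax_id in seen_scientific:
                raise ValidationError(
                    f"tax_id {rec.tax_id} has more than one accepted "
                    f"scientific name ({seen_scientific[rec.tax_id]!r} and "
                    f"{rec.name_text!r})")
            seen_scientific[rec.tax_id] = rec.name_text
        names.append(rec)
    return names


def parse_citations(stream: IO[str] | str | Iterable[str]) -> list[CitationRecord]:
    """Parse citations.dmp (classic 7-column layout: cit_id, key,
    medline_id, pubmed_id, url, text, tax_id list)."""
    records = []
    for lineno, line in _lines(stream):
        f = split_line(line, lineno)
        if len(f) < 7:
            raise ParseError(f"citations.dmp line has {len(f)} fields, expected 7",
                             line=lineno)
        pubmed = _int_field(f[3] or "0", "pubmed_id", lineno)
        tax_ids = tuple(_int_field(tok, "tax_id list entry", lineno)
                        for tok in f[6].split())
        records.append(CitationRecord(
            cit_id=_int_field(f[0], "cit_id", lineno),
            citation_key=f[1].strip(),
            pubmed_id=pubmed or None,
            url=f[4].strip() or None,
            free_text=f[5].strip(),
            tax_ids=tax_ids,
        ))
    return records


def serialize_nodes(nodes: Iterable[TaxonNode]) -> str:
    return "".join(n.to_line() + "\n" for n in nodes)


def serialize_names(names: Iterable[TaxonName]) -> str:
    return "".join(n.to_line() + "\n" for n in names)


def serialize_citations(citations: Iterable[CitationRecord]) -> str:
    return "".join(c.to_line() + "\n" for c in citations)


@dataclass
class Taxonomy:
    """An indexed NCBI taxonomy.

    Built by :func:`assemble_taxonomy`; do not mutate after construction.
    """

    nodes: dict[int, TaxonNode] = field(default_factory=dict)
    names: dict[int, list[TaxonName]] = field(default_factory=dict)
    by_scientific_name: dict[str, set[int]] = field(default_factory=dict)
    by_any_name: dict[str, set[tuple[int, str]]] = field(default_factory=dict)
    root_id: int = 0

    def scientific_name(self, tax_id: int) -> str:
        for n in self.names.get(tax_id, ()):
            if n.name_class == SCIENTIFIC_NAME:
                return n.name_text
        raise KeyError(f"tax_id {tax_id} has no scientific name")

    def other_names(self, tax_id: int) -> list[TaxonName]:
        """All names of a taxon except its accepted scientific name
        (synonyms, misspellings, common names, authority forms...)."""
        return [n for n in self.names.get(tax_id, ())
                if n.name_class != SCIENTIFIC_NAME]

    def lineage(self, tax_id: int) -> list[int]:
        """Root-first chain of tax_ids ending at ``tax_id``."""
        chain = []
        seen = set()
        cur = tax_id
        while True:
            if cur in seen:
                raise ValidationError(f"cycle in parent chain at tax_id {cur}")
            seen.add(cur)
            chain.append(cur)
            node = self.nodes[cur]
            if node.parent_tax_id == cur:
                break
            cur = node.parent_tax_id
        chain.reverse()
        return chain

    def depth(self, tax_id: int) -> int:
        return len(self.lineage(tax_id))

    def is_ancestor(self, ancestor: int, descendant: int) -> bool:
        return ancestor in self.lineage(descendant)

    def children(self, tax_id: int) -> list[int]:
        return sorted(n.tax_id for n in self.nodes.values()
                      if n.parent_tax_id == tax_id and n.tax_id != tax_id)


def homonym_taxa(taxonomy: Taxonomy, name_text: str) -> set[int]:
    """tax_ids whose *accepted* scientific name equals ``name_text``.

    More than one member means the name is a homonym (e.g. both the genus
    Rana and the subgenus Rana carry the bare name "Rana" in NCBI, and the
    same spelling can be a plant in one code and an animal in another).
    """
    return set(taxonomy.by_scientific_name.get(normalize_name(name_text), ()))


def assemble_taxonomy(nodes: Iterable[TaxonNode],
                      names: Iterable[TaxonName],
                      strict: bool = True) -> Taxonomy:
    """Index nodes and names into a validated :class:`Taxonomy`.

    With ``strict=False`` dangling references (a name whose tax_id has no
    node, a parent pointer to a missing node) are logged and dropped
    instead of raising, because real dumps are occasionally inconsistent
    mid-release.
    """
    tax = Taxonomy()
    for node in nodes:
        if node.tax_id in tax.nodes:
            raise ValidationError(f"duplicate tax_id {node.tax_id} in nodes")
        tax.nodes[node.tax_id] = node

    roots = [n.tax_id for n in tax.nodes.values() if n.parent_tax_id == n.tax_id]
    if len(roots) != 1:
        raise ValidationError(f"expected exactly one root node, found {roots}")
    tax.root_id = roots[0]

    for node in tax.nodes.values():
        if node.parent_tax_id not in tax.nodes:
            msg = (f"tax_id {node.tax_id} has dangling parent "
                   f"{node.parent_tax_id}")
            if strict:
                raise ValidationError(msg)
            log.warning("%s; reattaching to root", msg)
            tax.nodes[node.tax_id] = TaxonNode(
                node.tax_id, tax.root_id, node.rank, node.division_id,
                node.embl_code, node.extra)

    sci_count: dict[int, int] = {}
    for name in names:
        if name.tax_id not in tax.nodes:
            msg = f"name {name.name_text!r} references unknown tax_id {name.tax_id}"
            if strict:
                raise ValidationError(msg)
            log.warning("%s; dropped", msg)
            continue
        tax.names.setdefault(name.tax_id, []).append(name)
        tax.by_any_name.setdefault(name.name_text, set()).add(
            (name.tax_id, name.name_class))
        if name.name_class == SCIENTIFIC_NAME:
            sci_count[name.tax_id] = sci_count.get(name.tax_id, 0) + 1
            tax.by_scientific_name.setdefault(name.name_text, set()).add(name.tax_id)

    bad = sorted(t for t, c in sci_count.items() if c > 1)
    if bad:
        raise ValidationError(
            f"tax_ids with more than one accepted scientific name: {bad}")
    missing = sorted(t for t in tax.nodes if sci_count.get(t, 0) == 0)
    if missing:
        msg = f"tax_ids with no scientific name: {missing[:10]}"
        if strict:
            raise ValidationError(msg)
        log.warning(msg)

    for tax_id in tax.nodes:  # acyclicity check
        tax.lineage(tax_id)
    return tax


def load_taxdump(directory: str | Path, strict: bool = True
                 ) -> tuple[Taxonomy, list[CitationRecord]]:
    """Load nodes.dmp + names.dmp (+ citations.dmp if present) from a
    directory and assemble the taxonomy."""
    directory = Path(directory)
    with open(directory / "nodes.dmp", encoding="utf-8") as fh:
        nodes = parse_nodes(fh)
    with open(directory / "names.dmp", encoding="utf-8") as fh:
        names = parse_names(fh)
    citations: list[CitationRecord] = []
    cit_path = directory / "citations.dmp"
    if cit_path.exists():
        with open(cit_path, encoding="utf-8") as fh:
            citations = parse_citations(fh)
        if strict:
            known = {t for c in citations for t in c.tax_ids}
            unknown = sorted(t for t in known if t not in {n.tax_id for n in nodes})
            if unknown:
                log.warning("citations reference unknown tax_ids: %s", unknown[:10])
    return assemble_taxonomy(nodes, names, strict=strict), citations
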