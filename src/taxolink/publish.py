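"""Publishing the mapping: wiki pages, NCBI LinkOut XML and RDF.

Every taxon gets a wiki page named ``Ncbi:<tax_id>`` whose body is a
``TaxonConcept`` template — a flat key=value block recording the taxon,
its NCBI context (rank, division, parent, synonyms) and, when mapped, the
Wikipedia page title, stable numeric page id, a lead snippet and the
Taxobox image.  Name pages (redirects for unique names, disambiguation
pages for homonyms) and ``Citation:<cit_id>`` pages complete the wiki.

The same records export as:

* an NCBI LinkOut resource file — one ``<Link>`` per mapped taxon in the
  ``taxonomy`` database, labelled "Wikipedia";
* RDF — parent relations as ``rdfs:subClassOf`` (following UniProt's
  modelling of the NCBI taxonomy), identity links to the UniProt and
  Bio2RDF URIs for the tax_id via ``owl:sameAs``, the DBpedia resource for
  the mapped page, page-name and page-id URLs, a FOAF depiction for the
  image, and name/rank via the TDWG taxon-name vocabulary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence
from xml.sax.saxutils import escape

from rdflib import RDFS, OWL, Graph, Literal, Namespace, URIRef

from .errors import ValidationError
from .reconcile import Mapping, MappingSet, WikiIndexes
from .taxdump import CitationRecord, Taxonomy, homonym_taxa
from .wikitext import lead_snippet, url_form

log = logging.getLogger(__name__)

#: Template keys in canonical page order.
TAXON_CONCEPT_KEYS = (
    "ncbi", "name", "homonym", "wikipedia_en", "wikipedia_en_id",
    "wikipedia_en_snippet", "wikipedia_image", "rank", "division_id",
    "parent", "synonyms",
)

TEMPLATE_NAME = "TaxonConcept"


@dataclass(frozen=True)
class TaxonConceptRecord:
    """The key-value schema of one published taxon page."""

    ncbi: int
    name: str
    homonym: bool = False
    wikipedia_en: str | None = None       # url-form title
    wikipedia_en_id: int | None = None
    wikipedia_en_snippet: str | None = None
    wikipedia_image: str | None = None    # url-form file name
    rank: str = ""
    division_id: int = 0
    parent: int | None = None             # parent tax_id (rendered "ncbi:<id>")
    synonyms: tuple[str, ...] = ()
    extra: tuple[tuple[str, str], ...] = ()  # unknown keys, preserved

    def __post_init__(self):
        if (self.wikipedia_en is None) != (self.wikipedia_en_id is None):
            raise ValidationError(
                "wikipedia_en and wikipedia_en_id must be present together")

    @property
    def page_title(self) -> str:
        return f"Ncbi:{self.ncbi}"


def _one_line(value: str) -> str:
    return re.sub(r"\s*\n\s*", " ", value).strip()


def render_taxon_page(record: TaxonConceptRecord,
                      citations: Sequence[CitationRecord] = ()) -> str:
    """Emit the TaxonConcept template, one ``|key=value`` per line in
    canonical key order, omitting absent optional keys; linked citation
    pages are transcluded after the template."""
    lines = ["{{" + TEMPLATE_NAME]
    values: dict[str, str | None] = {
        "ncbi": str(record.ncbi),
        "name": record.name,
        "homonym": "Yes" if record.homonym else "No",
        "wikipedia_en": record.wikipedia_en,
        "wikipedia_en_id": (str(record.wikipedia_en_id)
                            if record.wikipedia_en_id is not None else None),
        "wikipedia_en_snippet": record.wikipedia_en_snippet,
        "wikipedia_image": record.wikipedia_image,
        "rank": record.rank or None,
        "division_id": str(record.division_id),
        "parent": f"ncbi:{record.parent}" if record.parent is not None else None,
        "synonyms": ";".join(record.synonyms) if record.synonyms else None,
    }
    for key in TAXON_CONCEPT_KEYS:
        value = values[key]
        if value is not None:
            lines.append(f"|{key}={_one_line(value)}")
    for key, value in record.extra:
        lines.append(f"|{key}={_one_line(value)}")
    lines.append("}}")
    for cit in citations:
        lines.append(f"{{{{:Citation:{cit.cit_id}}}}}")
    return "\n".join(lines) + "\n"


_OPEN_RE = re.compile(r"^\{{1,2}\s*" + TEMPLATE_NAME + r"\s*$")
_CLOSE_RE = re.compile(r"^\}{1,2}\s*$")
_PAIR_RE = re.compile(r"^\|\s*([A-Za-z_][\w ]*?)\s*=(.*)$")


def parse_taxon_page(wikitext: str) -> TaxonConceptRecord:
    """Parse a TaxonConcept page back into a record.

    Line-oriented: the template opens on its own line; each parameter is a
    ``|key=value`` line, continuation lines are joined with a space; blank
    lines are ignored.  Unknown keys are preserved in ``extra``.  Missing
    ``ncbi`` or ``name`` raises :class:`ValidationError`.
    """
    fields: dict[str, str] = {}
    order: list[str] = []
    in_template = False
    current: str | None = None
    for raw in wikitext.splitlines():
        line = raw.rstrip()
        if not in_template:
            if _OPEN_RE.match(line.strip()):
                in_template = True
            continue
        if _CLOSE_RE.match(line.strip()):
            break
        if not line.strip():
            continue
        m = _PAIR_RE.match(line)
        if m:
            current = m.group(1).strip()
            if current not in fields:
                order.append(current)
                fields[current] = m.group(2).strip()
        elif current:
            fields[current] = (fields[current] + " " + line.strip()).strip()
    else:
        if not in_template:
            raise ValidationError("no TaxonConcept template found")

    if "ncbi" not in fields or "name" not in fields:
        raise ValidationError("TaxonConcept page lacks mandatory ncbi/name keys")

    def opt(key: str) -> str | None:
        v = fields.get(key, "").strip()
        return v or None

    parent_txt = opt("parent")
    parent = None
    if parent_txt:
        m = re.fullmatch(r"(?:ncbi:)?(\d+)", parent_txt.strip(), re.IGNORECASE)
        if not m:
            raise ValidationError(f"malformed parent field: {parent_txt!r}")
        parent = int(m.group(1))
    synonyms = tuple(s.strip() for s in fields.get("synonyms", "").split(";")
                     if s.strip())
    wikipedia_en_id = opt("wikipedia_en_id")
    extra = tuple((k, fields[k]) for k in order if k not in TAXON_CONCEPT_KEYS)
    return TaxonConceptRecord(
        ncbi=int(fields["ncbi"]),
        name=fields["name"].strip(),
        homonym=fields.get("homonym", "No").strip().lower() == "yes",
        wikipedia_en=opt("wikipedia_en"),
        wikipedia_en_id=int(wikipedia_en_id) if wikipedia_en_id else None,
        wikipedia_en_snippet=opt("wikipedia_en_snippet"),
        wikipedia_image=opt("wikipedia_image"),
        rank=fields.get("rank", "").strip(),
        division_id=int(fields.get("division_id", "0") or 0),
        parent=parent,
        synonyms=synonyms,
        extra=extra,
    )


def record_from_mapping(taxonomy: Taxonomy,
                        tax_id: int,
                        mapping: Mapping | None,
                        indexes: WikiIndexes | None = None,
                        snippet_chars: int = 300) -> TaxonConceptRecord:
    """Assemble the published record for one taxon from the taxonomy and
    (optionally) its mapping plus the dump indexes for snippet/image."""
    node = taxonomy.nodes[tax_id]
    name = taxonomy.scientific_name(tax_id)
    snippet = image = None
    title = page_id = None
    if mapping is not None:
        title = url_form(mapping.wikipedia_title)
        page_id = mapping.wikipedia_page_id
        if indexes is not None:
            box = indexes.taxoboxes.get(page_id)
            if box is not None and box.image:
                image = box.image.replace(" ", "_")
            page = indexes.pages_by_id.get(page_id)
            if page is not None:
                snippet = lead_snippet(page.wikitext, snippet_chars) or None
    return TaxonConceptRecord(
        ncbi=tax_id,
        name=name,
        homonym=len(homonym_taxa(taxonomy, name)) > 1,
        wikipedia_en=title,
        wikipedia_en_id=page_id,
        wikipedia_en_snippet=snippet,
        wikipedia_image=image,
        rank=node.rank,
        division_id=node.division_id,
        parent=node.parent_tax_id if node.parent_tax_id != tax_id else None,
        synonyms=tuple(n.name_text for n in taxonomy.other_names(tax_id)),
    )


def render_name_pages(taxonomy: Taxonomy) -> dict[str, str]:
    """Name-to-taxon pages: a redirect for a name borne by one taxon, a
    disambiguation page listing the Ncbi: pages for a homonym."""
    pages: dict[str, str] = {}
    for name in sorted(taxonomy.by_scientific_name):
        tax_ids = sorted(taxonomy.by_scientific_name[name])
        if len(tax_ids) == 1:
            pages[name] = f"#REDIRECT [[Ncbi:{tax_ids[0]}]]\n"
        else:
            lines = [f"'''{name}''' may refer to:", ""]
            for t in tax_ids:
                rank = taxonomy.nodes[t].rank
                lines.append(f"* [[Ncbi:{t}]] ({rank})")
            lines += ["", "{{disambiguation}}"]
            pages[name] = "\n".join(lines) + "\n"
    return pages


#: A resolver maps a CitationRecord to extra identifiers ({"doi": ...});
#: the default resolver is a no-op.
Resolver = Callable[[CitationRecord], dict[str, str]]


def noop_resolver(citation: CitationRecord) -> dict[str, str]:
    return {}


def render_citation_page(citation: CitationRecord,
                         resolver: Resolver = noop_resolver
                         ) -> tuple[str, str]:
    """Page ``Citation:<cit_id>`` carrying the bibliographic text, the
    PMID when present, and any resolver-supplied identifiers."""
    title = f"Citation:{citation.cit_id}"
    lines = [citation.free_text or citation.citation_key]
    if citation.pubmed_id:
        lines.append(f"PMID: [https://pubmed.ncbi.nlm.nih.gov/"
                     f"{citation.pubmed_id} {citation.pubmed_id}]")
    if citation.url:
        lines.append(citation.url)
    try:
        for key, value in sorted(resolver(citation).items()):
            lines.append(f"{key.upper()}: {value}")
    except Exception as exc:  # resolver failures must not block publishing
        log.warning("resolver failed for cit_id %s: %s", citation.cit_id, exc)
    return title, "\n\n".join(lines) + "\n"


def citations_by_taxon(citations: Iterable[CitationRecord]
                       ) -> dict[int, list[CitationRecord]]:
    out: dict[int, list[CitationRecord]] = {}
    for cit in citations:
        for t in cit.tax_ids:
            out.setdefault(t, []).append(cit)
    for lst in out.values():
        lst.sort(key=lambda c: c.cit_id)
    return out


@dataclass(frozen=True)
class ProviderConfig:
    """LinkOut provider identity; placeholders until registered with NCBI."""

    provider_id: int = 9999
    name: str = "taxolink"
    name_abbr: str = "taxolink"
    url_base: str = "https://en.wikipedia.org/wiki/"


LINKOUT_DOCTYPE = ('<!DOCTYPE LinkSet PUBLIC "-//NLM//DTD LinkOut 1.0//EN" '
                   '"https://www.ncbi.nlm.nih.gov/projects/linkout/doc/'
                   'LinkOut.dtd">')


def export_linkout(mappings: Sequence[Mapping],
                   provider: ProviderConfig | None = None) -> str:
    """NCBI LinkOut resource file: one Link per mapping, object database
    ``taxonomy``, link label "Wikipedia"."""
    provider = provider or ProviderConfig()
    parts = ['<?xml version="1.0"?>', LINKOUT_DOCTYPE, "<LinkSet>"]
    link_id = 0
    for m in mappings:
        if not m.wikipedia_title or not m.wikipedia_page_id:
            log.warning("mapping for tax_id %s lacks a page; skipped", m.tax_id)
            continue
        link_id += 1
        parts += [
            "  <Link>",
            f"    <LinkId>{link_id}</LinkId>",
            f"    <ProviderId>{provider.provider_id}</ProviderId>",
            "    <ObjectSelector>",
            "      <Database>taxonomy</Database>",
            "      <ObjectList>",
            f"        <ObjId>{m.tax_id}</ObjId>",
            "      </ObjectList>",
            "    </ObjectSelector>",
            "    <ObjectUrl>",
            f"      <Base>{escape(provider.url_base)}</Base>",
            f"      <Rule>{escape(url_form(m.wikipedia_title))}</Rule>",
            "      <UrlName>Wikipedia</UrlName>",
            "    </ObjectUrl>",
            "  </Link>",
        ]
    parts.append("</LinkSet>")
    return "\n".join(parts) + "\n"


@dataclass(frozen=True)
class UriConfig:
    """URI bases for the RDF export."""

    base: str = "http://iphylo.org/linkout/"
    wikipedia: str = "http://en.wikipedia.org/wiki/"
    wikipedia_curid: str = "http://en.wikipedia.org/wiki?curid="
    dbpedia: str = "http://dbpedia.org/resource/"
    uniprot: str = "http://purl.uniprot.org/taxonomy/"
    bio2rdf: str = "http://bio2rdf.org/taxonomy:"


FOAF = Namespace("http://xmlns.com/foaf/0.1/")
TDWG_TN = Namespace("http://rs.tdwg.org/ontology/voc/TaxonName#")


def export_rdf(record: TaxonConceptRecord,
               uris: UriConfig | None = None) -> Graph:
    """RDF statements for one published record.

    Statement count is a closed-form function of the populated fields:
    4 fixed (two owl:sameAs identity links, name, rank) + 1 if the taxon
    has a parent + 3 if mapped (DBpedia sameAs, page-name URL, page-id
    URL) + 1 if an image is present.
    """
    uris = uris or UriConfig()
    g = Graph()
    g.bind("owl", OWL)
    g.bind("rdfs", RDFS)
    g.bind("foaf", FOAF)
    g.bind("tn", TDWG_TN)
    s = URIRef(f"{uris.base}Ncbi:{record.ncbi}")
    g.add((s, OWL.sameAs, URIRef(f"{uris.uniprot}{record.ncbi}")))
    g.add((s, OWL.sameAs, URIRef(f"{uris.bio2rdf}{record.ncbi}")))
    g.add((s, TDWG_TN.nameComplete, Literal(record.name)))
    g.add((s, TDWG_TN.rankString, Literal(record.rank)))
    if record.parent is not None:
        g.add((s, RDFS.subClassOf, URIRef(f"{uris.base}Ncbi:{record.parent}")))
    if record.wikipedia_en:
        title = url_form(record.wikipedia_en)
        g.add((s, OWL.sameAs, URIRef(f"{uris.dbpedia}{title}")))
        g.add((s, FOAF.page, URIRef(f"{uris.wikipedia}{title}")))
        g.add((s, FOAF.page,
               URIRef(f"{uris.wikipedia_curid}{record.wikipedia_en_id}")))
    if record.wikipedia_image:
        g.add((s, FOAF.depiction,
               URIRef(f"{uris.wikipedia}File:"
                      f"{record.wikipedia_image.replace(' ', '_')}")))
    return g


def rdf_xml(graph: Graph) -> str:
    return graph.serialize(format="pretty-xml")


def rdf_triples(graph: Graph) -> list[tuple[str, str, str]]:
    """Sorted line-friendly triple dump for diffing and testing."""
    return sorted((str(s), str(p), str(o)) for s, p, o in graph)


def expected_rdf_statement_count(record: TaxonConceptRecord) -> int:
    """Closed-form statement count used as the export's self-check."""
    return (4 + (1 if record.parent is not None else 0)
            + (3 if record.wikipedia_en else 0)
            + (1 if record.wikipedia_image else 0))
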