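"""Synthetic paired corpora: a taxdump, a wiki XML export and the
ground-truth mapping manifest.

Every reconciliation scenario the pipeline must handle is planted with
known outcomes, so recovery can be scored exactly:

* taxa matched by each of the four mapping types, in configurable
  proportions, with redirect chains of configurable length for the
  redirect-mediated types;
* homonym pairs — one scientific name borne by two taxa in different
  GenBank divisions, each with its own page whose Taxobox regnum permits
  division-based disambiguation;
* monotypic chains — nested taxa (e.g. family > genus > species) all
  resolving to the single species page via name redirects, which the
  collapse step must reduce to the deepest taxon;
* unmatched taxa and non-taxon filler pages.

Names are drawn from a syllable grammar and kept globally unique, so no
accidental collisions occur beyond the planted ones.  Generation is a
pure function of the spec: the same :class:`CorpusSpec` (including its
seed) yields byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .taxdump import (
    CitationRecord, TaxonName, TaxonNode,
    serialize_citations, serialize_names, serialize_nodes,
)

_SYLLABLES = ("ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "na",
              "pe", "qui", "ro", "sa", "tu", "ve", "xi", "zo", "ly", "chor")

#: (division_id, regnum) pairs cycled over generated taxa.
_DIVISIONS = ((10, "Animalia"), (4, "Plantae"), (1, "Animalia"),
              (2, "Animalia"), (4, "Fungi"))

_EPONYMS = ("Smith", "Garcia", "Tanaka", "Okoye", "Laurent", "Novak")


@dataclass(frozen=True)
class CorpusSpec:
    """Composition of a synthetic corpus.

    ``type_fractions`` give the share of ``n_taxa`` matched by each
    mapping type; the remainder is unmatched.  Homonym pairs and the
    deepest members of monotypic chains are carved out of the type-1
    share; chain ancestors are generated in addition to ``n_taxa`` (they
    occupy the collapsed role).
    """

    n_taxa: int = 500
    type_fractions: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25})
    n_homonym_pairs: int = 5
    n_monotypic_chains: int = 5
    chain_length: tuple[int, int] = (2, 4)
    redirect_chain_length: tuple[int, int] = (1, 3)
    n_nontaxon_pages: int = 3
    n_citations: int = 5
    seed: int = 42

    def validate(self) -> None:
        total = sum(self.type_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError("type fractions sum to more than 1")
        if any(t not in (1, 2, 3, 4) for t in self.type_fractions):
            raise ValueError("mapping types must be 1-4")
        n1 = round(self.type_fractions.get(1, 0.0) * self.n_taxa)
        if n1 < 2 * self.n_homonym_pairs + self.n_monotypic_chains:
            raise ValueError(
                "type-1 share too small for the planted homonym pairs "
                "and monotypic chains")
        if self.chain_length[0] < 2:
            raise ValueError("monotypic chains need length >= 2")
        if self.redirect_chain_length[0] < 1:
            raise ValueError("redirect chains need at least one hop")


@dataclass
class Manifest:
    """Ground truth for a generated corpus."""

    true_mapping: list[tuple[int, int, int]] = field(default_factory=list)
    homonym_names: list[str] = field(default_factory=list)
    collapsed_expect: list[tuple[int, list[int]]] = field(default_factory=list)
    unmatched: list[int] = field(default_factory=list)
    taxon_page_ids: list[int] = field(default_factory=list)
    nontaxon_page_ids: list[int] = field(default_factory=list)
    page_titles: dict[int, str] = field(default_factory=dict)
    citation_tax_ids: dict[int, list[int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        d = json.loads(text)
        m = cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})
        m.true_mapping = [tuple(x) for x in m.true_mapping]
        m.collapsed_expect = [(k, list(v)) for k, v in m.collapsed_expect]
        m.page_titles = {int(k): v for k, v in m.page_titles.items()}
        m.citation_tax_ids = {int(k): list(v)
                              for k, v in m.citation_tax_ids.items()}
        return m

    def type_counts(self) -> dict[int, int]:
        counts = {1: 0, 2: 0, 3: 0, 4: 0}
        for _, _, t in self.true_mapping:
            counts[t] += 1
        return counts


@dataclass
class Corpus:
    """In-memory corpus; :meth:`write` lays it out on disk."""

    nodes_dmp: str
    names_dmp: str
    citations_dmp: str
    wiki_xml: str
    manifest: Manifest

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        taxdump = directory / "taxdump"
        taxdump.mkdir(parents=True, exist_ok=True)
        (taxdump / "nodes.dmp").write_text(self.nodes_dmp, encoding="utf-8")
        (taxdump / "names.dmp").write_text(self.names_dmp, encoding="utf-8")
        (taxdump / "citations.dmp").write_text(self.citations_dmp,
                                               encoding="utf-8")
        (directory / "wiki.xml").write_text(self.wiki_xml, encoding="utf-8")
        (directory / "manifest.json").write_text(self.manifest.to_json(),
                                                 encoding="utf-8")
        return directory


class _NameFactory:
    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int, capital: bool) -> str:
        w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables))
        return w.capitalize() if capital else w

    def unique(self, maker) -> str:
        for _ in range(1000):
            name = maker()
            if name not in self.used:
                self.used.add(name)
                return name
        raise RuntimeError("name space exhausted")

    def genus(self) -> str:
        return self.unique(lambda: self.word(self.rng.randint(2, 4), True))

    def binomial(self, genus: str | None = None) -> str:
        g = genus or self.genus()
        return self.unique(
            lambda: f"{g} {self.word(self.rng.randint(2, 4), False)}")

    def common(self) -> str:
        return self.unique(
            lambda: f"{self.word(2, True)} {self.word(self.rng.randint(2, 3), False)}")


def _taxobox(name: str, regnum: str, rng: random.Random,
             title: str, with_image: bool) -> str:
    genus, _, epithet = name.partition(" ")
    lines = ["{{Taxobox", f"| name = {title}"]
    if with_image:
        lines.append(f"| image = {name}.jpg")
    lines.append(f"| regnum = [[{regnum}]]")
    lines.append(f"| genus = ''[[{genus}]]''")
    if epithet:
        lines.append(f"| species = '''''{genus[0]}. {epithet}'''''")
        lines.append(f"| binomial = ''{name}''")
        lines.append(f"| binomial_authority = {rng.choice(_EPONYMS)}, "
                     f"{rng.randint(1758, 2008)}")
    lines.append("}}")
    return "\n".join(lines)


def _taxon_article(name: str, title: str, regnum: str,
                   rng: random.Random, with_image: bool) -> str:
    box = _taxobox(name, regnum, rng, title, with_image)
    lead = (f"The '''{title.lower()}''', ''{name}'', is a synthetic taxon "
            f"generated for pipeline testing. It belongs to the kingdom "
            f"[[{regnum}]]. Nothing further is known about it.")
    return f"{box}\n{lead}\n\n== Description ==\nGenerated text.\n"


def _wiki_xml(pages: list[tuple[str, int, int, str]]) -> str:
    """Serialize (title, page_id, ns, wikitext) tuples as a MediaWiki
    XML export."""
    out = ['<mediawiki xmlns="http://www.mediawiki.org/xml/export-0.10/" '
           'xml:lang="en">',
           "  <siteinfo><sitename>SyntheticWiki</sitename></siteinfo>"]
    for title, page_id, ns, text in pages:
        out += [
            "  <page>",
            f"    <title>{escape(title)}</title>",
            f"    <ns>{ns}</ns>",
            f"    <id>{page_id}</id>",
            "    <revision>",
            f"      <id>{page_id * 10}</id>",
            f"      <text xml:space=\"preserve\">{escape(text)}</text>",
            "    </revision>",
            "  </page>",
        ]
    out.append("</mediawiki>")
    return "\n".join(out) + "\n"


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Deterministically synthesise a taxdump + wiki dump + manifest."""
    spec.validate()
    rng = random.Random(spec.seed)
    namer = _NameFactory(rng)
    manifest = Manifest()

    nodes: list[TaxonNode] = [TaxonNode(1, 1, "no rank", 0)]
    names: list[TaxonName] = [TaxonName(1, "root", "scientific name")]
    pages: list[tuple[str, int, int, str]] = []

    next_tax = 2
    next_page = 100001

    def new_tax(name: str, rank: str, division: int, parent: int = 1) -> int:
        nonlocal next_tax
        t = next_tax
        next_tax += 1
        nodes.append(TaxonNode(t, parent, rank, division))
        names.append(TaxonName(t, name, "scientific name"))
        return t

    def new_page(title: str, text: str, ns: int = 0) -> int:
        nonlocal next_page
        p = next_page
        next_page += 1
        pages.append((title, p, ns, text))
        manifest.page_titles[p] = title
        return p

    def taxon_page(name: str, regnum: str, title: str | None = None) -> int:
        title = title or name
        with_image = rng.random() < 0.5
        p = new_page(title, _taxon_article(name, title, regnum, rng, with_image))
        manifest.taxon_page_ids.append(p)
        return p

    def redirect_chain(start_title: str, final_title: str) -> None:
        hops = rng.randint(*spec.redirect_chain_length)
        titles = [start_title]
        for _ in range(hops - 1):
            titles.append(namer.common())
        titles.append(final_title)
        for a, b in zip(titles, titles[1:]):
            p = new_page(a, f"#REDIRECT [[{b}]]\n")
            manifest.nontaxon_page_ids.append(p)

    def division(i: int) -> tuple[int, str]:
        return _DIVISIONS[i % len(_DIVISIONS)]

    counts = {t: round(spec.type_fractions.get(t, 0.0) * spec.n_taxa)
              for t in (1, 2, 3, 4)}
    n_plain1 = (counts[1] - 2 * spec.n_homonym_pairs
                - spec.n_monotypic_chains)

    i = 0  # taxon serial, drives division cycling

    # --- homonym pairs (type 1, division-disambiguated) ---
    for _ in range(spec.n_homonym_pairs):
        shared = namer.genus()
        manifest.homonym_names.append(shared)
        for div, regnum in ((10, "Animalia"), (4, "Plantae")):
            t = new_tax(shared, "genus", div)
            title = namer.common()  # distinct page titles
            p = taxon_page(shared, regnum, title=title)
            manifest.true_mapping.append((t, p, 1))
        i += 2

    # --- monotypic chains (deepest is type 1; ancestors collapse) ---
    chain_ranks = ("ordo", "familia", "genus", "species")
    for _ in range(spec.n_monotypic_chains):
        length = rng.randint(*spec.chain_length)
        div, regnum = division(i)
        i += 1
        ranks = chain_ranks[-length:]
        parent = 1
        chain: list[int] = []
        genus_name = None
        for rank in ranks:
            if rank == "species":
                name = namer.binomial(genus_name)
            else:
                name = namer.genus()
                if rank == "genus":
                    genus_name = name
            parent = new_tax(name, rank, div, parent)
            chain.append(parent)
        deepest = chain[-1]
        deepest_name = names[-1].name_text
        page = taxon_page(deepest_name, regnum)
        manifest.true_mapping.append((deepest, page, 1))
        manifest.collapsed_expect.append((deepest, chain[:-1]))
        for ancestor in chain[:-1]:
            anc_name = next(n.name_text for n in names if n.tax_id == ancestor)
            redirect_chain(anc_name, deepest_name)

    # --- plain type-1 taxa ---
    for _ in range(n_plain1):
        div, regnum = division(i)
        i += 1
        name = namer.binomial()
        t = new_tax(name, "species", div)
        p = taxon_page(name, regnum)
        manifest.true_mapping.append((t, p, 1))

    # --- type 2: NCBI accepted name is a wiki redirect ---
    for _ in range(counts[2]):
        div, regnum = division(i)
        i += 1
        ncbi_name = namer.binomial()
        wiki_name = namer.binomial()
        t = new_tax(ncbi_name, "species", div)
        p = taxon_page(wiki_name, regnum)
        redirect_chain(ncbi_name, wiki_name)
        manifest.true_mapping.append((t, p, 2))

    # --- type 3: NCBI synonym is the wiki accepted name ---
    for _ in range(counts[3]):
        div, regnum = division(i)
        i += 1
        ncbi_name = namer.binomial()
        synonym = namer.binomial()
        t = new_tax(ncbi_name, "species", div)
        names.append(TaxonName(t, synonym, "synonym"))
        p = taxon_page(synonym, regnum)
        manifest.true_mapping.append((t, p, 3))

    # --- type 4: NCBI synonym redirects to the wiki page ---
    for _ in range(counts[4]):
        div, regnum = division(i)
        i += 1
        ncbi_name = namer.binomial()
        synonym = namer.binomial()
        wiki_name = namer.binomial()
        t = new_tax(ncbi_name, "species", div)
        names.append(TaxonName(t, synonym, "synonym"))
        p = taxon_page(wiki_name, regnum)
        redirect_chain(synonym, wiki_name)
        manifest.true_mapping.append((t, p, 4))

    # --- unmatched taxa ---
    n_unmatched = spec.n_taxa - sum(counts.values())
    for _ in range(n_unmatched):
        div, _regnum = division(i)
        i += 1
        t = new_tax(namer.binomial(), "species", div)
        manifest.unmatched.append(t)

    # sprinkle common names on a third of the taxa (never match-relevant:
    # common names are unique strings absent from the wiki)
    for node in nodes[1:]:
        if rng.random() < 0.33:
            names.append(TaxonName(node.tax_id, namer.common(),
                                   "genbank common name"))

    # --- non-taxon filler pages ---
    for _ in range(spec.n_nontaxon_pages):
        title = namer.common()
        p = new_page(title, f"'''{title}''' is a plain article with no "
                            f"infobox. It exists to exercise filtering.\n")
        manifest.nontaxon_page_ids.append(p)

    # --- citations ---
    citations: list[CitationRecord] = []
    all_tax = [n.tax_id for n in nodes if n.tax_id != 1]
    for c in range(spec.n_citations):
        linked = tuple(sorted(rng.sample(all_tax, rng.randint(1, 3))))
        pm = rng.randint(1000000, 9999999) if rng.random() < 0.6 else None
        cit = CitationRecord(
            cit_id=1000 + c,
            citation_key=f"Synthetic reference {c} ({1990 + c}).",
            pubmed_id=pm, url=None,
            free_text=f"Synthetic reference {c} describing generated taxa.",
            tax_ids=linked)
        citations.append(cit)
        manifest.citation_tax_ids[cit.cit_id] = list(linked)

    return Corpus(
        nodes_dmp=serialize_nodes(nodes),
        names_dmp=serialize_names(names),
        citations_dmp=serialize_citations(citations),
        wiki_xml=_wiki_xml(pages),
        manifest=manifest,
    )
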