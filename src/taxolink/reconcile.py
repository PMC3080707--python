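"""Reconciling NCBI taxa with Wikipedia pages.

Four routes can link a taxon to a page, tried in strict priority order:

1. the NCBI accepted scientific name is the accepted name of a taxon page;
2. the NCBI accepted name is a redirect whose target is a taxon page
   (Wikipedia treats the NCBI name as a synonym);
3. an NCBI synonym-class name is the accepted name of a taxon page
   (NCBI treats Wikipedia's name as a synonym);
4. an NCBI synonym-class name is a redirect to a taxon page
   (the databases disagree on the accepted name, linked via synonyms on
   both sides).

Homonyms — the same spelling used for, say, a lizard genus and a plant
genus (*Abronia*), possible because zoological and botanical nomenclature
are governed by separate codes — are resolved by checking the GenBank
division of the NCBI taxon against the ``regnum`` (kingdom) field of the
candidate page's Taxobox.

Nested monotypic taxa (a genus with a single species, etc.) share one
Wikipedia page; only the lowest-ranked taxon keeps the mapping
(:func:`collapse_monotypic`), so no page id is ever mapped twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .taxdump import Taxonomy, homonym_taxa
from .wikitext import (
    DEFAULT_DISAMBIG_TEMPLATES,
    DEFAULT_TAXOBOX_ALIASES,
    Taxobox,
    WikiPage,
    extract_taxobox,
    is_disambiguation,
    page_scientific_name,
    url_form,
)

log = logging.getLogger(__name__)

#: Default compatibility between Taxobox regnum values and GenBank
#: division codes. Unknown regna are compatible with everything.
DEFAULT_COMPAT_RULES: dict[str, frozenset[int]] = {
    "Animalia": frozenset({1, 2, 5, 6, 10}),   # inv, mammals, primates, rodents, vert
    "Plantae": frozenset({4}),                 # plants and fungi
    "Fungi": frozenset({4}),
    "Bacteria": frozenset({0}),
    "Archaea": frozenset({0}),
    "Viruses": frozenset({3, 9}),              # phages, viruses
}


@dataclass(frozen=True)
class CompatibilityTable:
    """regnum → set of compatible GenBank division codes."""

    rules: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_COMPAT_RULES))

    def compatible(self, regnum: str | None, division_id: int) -> bool:
        if regnum is None:
            return True
        allowed = self.rules.get(regnum)
        if allowed is None:  # unknown regnum: no filtering
            return True
        return division_id in allowed


@dataclass(frozen=True)
class Mapping:
    """One NCBI tax_id linked to one Wikipedia page."""

    tax_id: int
    wikipedia_title: str
    wikipedia_page_id: int
    mapping_type: int  # 1..4
    matched_name: str
    via_redirect_title: str | None = None
    notes: str = ""

    def __post_init__(self):
        if self.mapping_type not in (1, 2, 3, 4):
            raise ValueError(f"mapping_type must be 1-4, got {self.mapping_type}")
        if (self.mapping_type in (2, 4)) != (self.via_redirect_title is not None):
            raise ValueError("via_redirect_title present iff mapping_type is 2 or 4")


@dataclass(frozen=True)
class Ambiguity:
    """A taxon whose name matched several pages that division filtering
    could not separate; left for manual curation."""

    tax_id: int
    candidates: tuple[tuple[str, int], ...]  # (title, page_id)
    note: str = ""


@dataclass
class MappingSet:
    """Outcome of a reconciliation run; each tax_id appears in at most one
    of the four buckets."""

    mappings: list[Mapping] = field(default_factory=list)
    unmatched: list[int] = field(default_factory=list)
    ambiguous: list[Ambiguity] = field(default_factory=list)
    collapsed: list[tuple[int, int]] = field(default_factory=list)  # (dropped, kept)

    def by_tax_id(self) -> dict[int, Mapping]:
        return {m.tax_id: m for m in self.mappings}


@dataclass
class WikiIndexes:
    """Name and redirect indexes over a dump, built once per run."""

    accepted: dict[str, list[WikiPage]] = field(default_factory=dict)
    redirects: dict[str, WikiPage] = field(default_factory=dict)
    taxoboxes: dict[int, Taxobox] = field(default_factory=dict)  # by page_id
    pages_by_id: dict[int, WikiPage] = field(default_factory=dict)

    def is_taxon_page(self, page: WikiPage) -> bool:
        return page.page_id in self.taxoboxes


def build_wiki_indexes(pages: Iterable[WikiPage],
                       *,
                       disambig_templates=DEFAULT_DISAMBIG_TEMPLATES,
                       taxobox_aliases=DEFAULT_TAXOBOX_ALIASES,
                       max_redirect_depth: int = 8) -> WikiIndexes:
    """Single streaming pass over a dump.

    ``accepted`` maps each page's scientific name to the non-redirect,
    non-disambiguation article(s) bearing it; ``redirects`` maps every
    redirect title to its final non-redirect target, following chains to a
    fixed point (cycles and over-deep chains are dropped with a warning).
    """
    idx = WikiIndexes()
    by_title: dict[str, WikiPage] = {}
    redirect_titles: dict[str, str] = {}
    for page in pages:
        if page.namespace != 0:
            continue
        by_title[page.title] = page
        idx.pages_by_id[page.page_id] = page
        if page.is_redirect:
            redirect_titles[page.title] = page.redirect_target
            continue
        if is_disambiguation(page.wikitext, disambig_templates):
            continue
        box = extract_taxobox(page.wikitext, taxobox_aliases)
        if box is None:
            continue
        idx.taxoboxes[page.page_id] = box
        name = page_scientific_name(box)
        if name:
            idx.accepted.setdefault(name, []).append(page)

    for title in redirect_titles:
        target = title
        for _ in range(max_redirect_depth):
            target = redirect_titles.get(target)
            if target is None:
                break
            final = by_title.get(target)
            if final is not None and not final.is_redirect:
                idx.redirects[title] = final
                break
            if final is None and target not in redirect_titles:
                break  # dangling redirect: target not in dump
        else:
            log.warning("redirect chain from %r too deep or cyclic; skipped", title)
    for pages_for_name in idx.accepted.values():
        pages_for_name.sort(key=lambda p: p.page_id)
    return idx


def disambiguate_by_division(candidates: Sequence[WikiPage],
                             division_id: int,
                             compat: CompatibilityTable,
                             indexes: WikiIndexes) -> tuple[list[WikiPage], str]:
    """Keep candidates whose Taxobox regnum is compatible with the taxon's
    GenBank division; pages without a regnum are kept.  If filtering would
    empty the set, the unfiltered set is returned flagged "incompatible".
    """
    kept = []
    for page in candidates:
        box = indexes.taxoboxes.get(page.page_id)
        regnum = box.regnum if box else None
        if compat.compatible(regnum, division_id):
            kept.append(page)
    if not kept and candidates:
        return list(candidates), "incompatible"
    return kept, ""


def classify_match(tax_id: int,
                   taxonomy: Taxonomy,
                   indexes: WikiIndexes,
                   compat: CompatibilityTable | None = None
                   ) -> Mapping | Ambiguity | None:
    """Match one taxon against the dump, trying types 1-4 in order and
    stopping at the first type with at least one candidate."""
    compat = compat or CompatibilityTable()
    node = taxonomy.nodes[tax_id]
    accepted = taxonomy.scientific_name(tax_id)
    synonyms = [n.name_text for n in taxonomy.other_names(tax_id)]

    # each candidate: (page, matched_name, via_redirect_title)
    levels: list[tuple[int, list[tuple[WikiPage, str, str | None]]]] = []

    direct = [(p, accepted, None) for p in indexes.accepted.get(accepted, ())]
    levels.append((1, direct))

    via = indexes.redirects.get(accepted)
    levels.append((2, [(via, accepted, accepted)]
                   if via is not None and indexes.is_taxon_page(via) else []))

    syn_direct = []
    for name in synonyms:
        for p in indexes.accepted.get(name, ()):
            syn_direct.append((p, name, None))
    levels.append((3, syn_direct))

    syn_via = []
    for name in synonyms:
        target = indexes.redirects.get(name)
        if target is not None and indexes.is_taxon_page(target):
            syn_via.append((target, name, name))
    levels.append((4, syn_via))

    for mtype, cands in levels:
        if not cands:
            continue
        # deduplicate by page, keeping first matched name
        seen: dict[int, tuple[WikiPage, str, str | None]] = {}
        for page, name, via_title in cands:
            seen.setdefault(page.page_id, (page, name, via_title))
        pages = [v[0] for v in sorted(seen.values(), key=lambda v: v[0].page_id)]
        kept, note = disambiguate_by_division(pages, node.division_id,
                                              compat, indexes)
        notes = []
        if note:
            notes.append(note)
        if len(homonym_taxa(taxonomy, accepted)) > 1:
            notes.append("homonym")
        if len(kept) == 1:
            page, name, via_title = seen[kept[0].page_id]
            return Mapping(
                tax_id=tax_id,
                wikipedia_title=page.title,
                wikipedia_page_id=page.page_id,
                mapping_type=mtype,
                matched_name=name,
                via_redirect_title=via_title,
                notes=";".join(notes),
            )
        return Ambiguity(
            tax_id=tax_id,
            candidates=tuple((p.title, p.page_id) for p in kept),
            note=";".join(notes) or f"{len(kept)} candidates",
        )
    return None


def collapse_monotypic(mappings: Sequence[Mapping],
                       taxonomy: Taxonomy) -> MappingSet:
    """Resolve several taxa mapped to one page.

    Nested monotypic taxa (aardvark-style: order, family, genus and sole
    species sharing one article) form an ancestor-descendant chain; only
    the deepest taxon keeps the mapping.  Groups that are not a chain are
    genuine conflicts and go to ``ambiguous``.
    """
    result = MappingSet()
    groups: dict[int, list[Mapping]] = {}
    for m in mappings:
        groups.setdefault(m.wikipedia_page_id, []).append(m)
    for page_id in sorted(groups):
        group = sorted(groups[page_id], key=lambda m: m.tax_id)
        if len(group) == 1:
            result.mappings.append(group[0])
            continue
        deepest = max(group, key=lambda m: taxonomy.depth(m.tax_id))
        chain = all(m is deepest or taxonomy.is_ancestor(m.tax_id, deepest.tax_id)
                    for m in group)
        if chain:
            result.mappings.append(deepest)
            for m in group:
                if m is not deepest:
                    result.collapsed.append((m.tax_id, deepest.tax_id))
        else:
            for m in group:
                result.ambiguous.append(Ambiguity(
                    tax_id=m.tax_id,
                    candidates=((m.wikipedia_title, m.wikipedia_page_id),),
                    note="page shared by unrelated taxa",
                ))
    result.mappings.sort(key=lambda m: m.tax_id)
    return result


@dataclass
class RunReport:
    """Per-run counters: matches per type, unmatched, ambiguous, collapsed
    and homonym-flagged taxa."""

    counts: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["reconciliation report"]
        for key in ("taxa", "matched", "type_1", "type_2", "type_3", "type_4",
                    "unmatched", "ambiguous", "collapsed", "homonym_flagged"):
            lines.append(f"  {key:16s} {self.counts.get(key, 0)}")
        return "\n".join(lines)


def reconcile_all(taxonomy: Taxonomy,
                  pages: Iterable[WikiPage],
                  compat: CompatibilityTable | None = None,
                  *,
                  include_root: bool = False,
                  max_redirect_depth: int = 8,
                  disambig_templates=DEFAULT_DISAMBIG_TEMPLATES,
                  taxobox_aliases=DEFAULT_TAXOBOX_ALIASES
                  ) -> tuple[MappingSet, RunReport]:
    """End-to-end reconciliation of every taxon against a dump.

    Deterministic: taxa are processed in tax_id order and all indexes use
    stable orderings, so identical inputs give identical MappingSets.
    """
    compat = compat or CompatibilityTable()
    indexes = build_wiki_indexes(
        pages, disambig_templates=disambig_templates,
        taxobox_aliases=taxobox_aliases, max_redirect_depth=max_redirect_depth)

    raw: list[Mapping] = []
    unmatched: list[int] = []
    ambiguous: list[Ambiguity] = []
    homonym_flagged = 0
    tax_ids = sorted(taxonomy.nodes)
    for tax_id in tax_ids:
        if not include_root and tax_id == taxonomy.root_id:
            continue
        if len(homonym_taxa(taxonomy, taxonomy.scientific_name(tax_id))) > 1:
            homonym_flagged += 1
        outcome = classify_match(tax_id, taxonomy, indexes, compat)
        if outcome is None:
            unmatched.append(tax_id)
        elif isinstance(outcome, Ambiguity):
            ambiguous.append(outcome)
        else:
            raw.append(outcome)

    result = collapse_monotypic(raw, taxonomy)
    result.unmatched = unmatched
    result.ambiguous = ambiguous + result.ambiguous

    counts = {
        "taxa": len(tax_ids) - (0 if include_root else 1),
        "matched": len(result.mappings),
        "unmatched": len(result.unmatched),
        "ambiguous": len(result.ambiguous),
        "collapsed": len(result.collapsed),
        "homonym_flagged": homonym_flagged,
    }
    for t in (1, 2, 3, 4):
        counts[f"type_{t}"] = sum(1 for m in result.mappings if m.mapping_type == t)
    return result, RunReport(counts=counts)


TSV_HEADER = ("tax_id", "name", "wikipedia_title", "wikipedia_page_id",
              "mapping_type", "matched_name", "notes")


def mapping_table_tsv(mapping_set: MappingSet, taxonomy: Taxonomy) -> str:
    """Tab-separated mapping table (titles in url form)."""
    lines = ["\t".join(TSV_HEADER)]
    for m in mapping_set.mappings:
        lines.append("\t".join([
            str(m.tax_id),
            taxonomy.scientific_name(m.tax_id),
            url_form(m.wikipedia_title),
            str(m.wikipedia_page_id),
            str(m.mapping_type),
            m.matched_name,
            m.notes,
        ]))
    return "\n".join(lines) + "\n"


def parse_mapping_table(text: str) -> list[Mapping]:
    """Read back a TSV mapping table written by :func:`mapping_table_tsv`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(TSV_HEADER):
        raise ValueError("not a taxolink mapping table")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        mtype = int(f[4])
        out.append(Mapping(
            tax_id=int(f[0]),
            wikipedia_title=f[2].replace("_", " "),
            wikipedia_page_id=int(f[3]),
            mapping_type=mtype,
            matched_name=f[5],
            via_redirect_title=f[5] if mtype in (2, 4) else None,
            notes=f[6] if len(f) > 6 else "",
        ))
    return out
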