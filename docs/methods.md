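# Methods

## Inputs and their dialects

**NCBI taxdump.** `nodes.dmp`, `names.dmp` and `citations.dmp` are
line-oriented text with fields delimited by `\t|\t` and lines terminated
by `\t|`. From `nodes.dmp` columns 1, 2, 3 and 5 are modelled (tax_id,
parent tax_id, rank, GenBank division code); the remaining columns are
preserved opaquely so a parsed dump re-serialises byte-identically.
`citations.dmp` is read in the classic 7-column layout (cit_id, key,
medline id, pubmed id, url, text, tax_id list); a PubMed id of 0 is
treated as absent, following taxdump convention. `merged.dmp` and
`delnodes.dmp` are not consumed.

Validation enforces: unique tax_ids, exactly one root (a node that is its
own parent), no dangling parent pointers, acyclic lineages, and exactly
one name of class `scientific name` per taxon. A permissive mode
downgrades dangling references to logged warnings and reattaches orphans
to the root, because live dumps are occasionally inconsistent
mid-release; duplicate accepted names remain a hard error in both modes.

**Wikipedia.** Input is the MediaWiki XML export schema
(`Special:Export` / the public dump files), streamed with `lxml`
iterparse in constant memory. Only namespace 0 (articles) is considered.
A page is a redirect iff its wikitext opens with a `#REDIRECT [[...]]`
directive (case-insensitive, optional colon and whitespace); it is a
disambiguation page if it transcludes a template from a configurable
list (`disambiguation`, `disambig`, `dab`, ...). Only the template
literally named `Taxobox` is parsed by default; successor infoboxes
(`Automatic taxobox`, `Speciesbox`) can be enabled through the
`taxobox_aliases` configuration but are off by default, matching the
template era this pipeline targets. When a page carries several
Taxoboxes, the first is used.

## Name handling

Names are compared exactly and case-sensitively after whitespace
normalisation (strip, collapse internal runs) and Unicode NFC. No fuzzy
matching is attempted: scientific names are case-conventional, and
approximate matching would trade silent wrong links for coverage —
exactly what a manually curatable mapping is meant to avoid.

The scientific name of a wiki page is the Taxobox `binomial` value when
present, otherwise the value of the lowest populated classification
field (regnum > phylum > classis > subclassis > ordo > familia > genus >
species, lowest wins). A species value of the form `X. epithet` is
expanded against the genus field when the initials agree; on initial
mismatch the abbreviation is kept verbatim rather than guessed.

## The matching procedure

For each taxon the four routes are tried in strict priority order
1 > 2 > 3 > 4 (accepted→accepted, accepted→redirect, synonym→accepted,
synonym→redirect), stopping at the first route with at least one
candidate page. A taxon reachable by several routes (the Abo bat is
reachable via both 2 and 3) is therefore recorded under the
lowest-numbered one; the route is stored in each mapping. "Synonym"
means every NCBI name whose class is not `scientific name` — the
synonyms attached to real records mix classes (`synonym`,
`misspelling`, `authority`, `genbank common name`), and restricting to
the literal class `synonym` would silently drop usable names. Common
names are *not* matched against page titles (e.g. "Giant freshwater
stingray"); titles of taxon pages are frequently vernacular, and
title-matching them would bypass the Taxobox-derived accepted name that
anchors the whole procedure. This is a deliberate precision/recall
trade-off and a possible extension.

Redirect chains are resolved to a fixed point with a maximum depth of 8
(configurable); cycles and over-deep chains are logged and excluded.
Redirect targets that are disambiguation pages or lack a Taxobox never
produce mappings.

**Homonym disambiguation.** Candidates are filtered by compatibility
between the taxon's GenBank division and the candidate Taxobox `regnum`.
The default table is Animalia ↔ {1, 2, 5, 6, 10}, Plantae/Fungi ↔ {4},
Bacteria/Archaea ↔ {0}, Viruses ↔ {3, 9}; it is fully overridable in
configuration, and an unknown regnum (or a missing one) never filters.
If filtering would empty the candidate set, the unfiltered set is
returned flagged `incompatible` rather than silently dropped. A taxon
whose accepted name is borne by more than one tax_id is flagged
`homonym` (this drives the template's yes/no homonym key). Ambiguities
surviving division filtering are never auto-resolved; they are emitted
for manual curation, which is the point of storing the mapping in an
editable wiki.

**Monotypic collapse.** Mappings are grouped by Wikipedia page id. A
group whose tax_ids all lie on one ancestor–descendant chain keeps only
the deepest node (longest lineage); the others are recorded as
collapsed. This implements mapping only the lowest taxonomic rank when
nested monotypic taxa (a monotypic genus and its sole species, up to
aardvark-style order–family–genus–species chains) share one article.
Groups that do not form a chain are genuine conflicts and are moved to
the ambiguous bucket wholesale. Two taxa at equal depth can never be
ancestor and descendant, so ties need no separate rule.

Processing order is ascending tax_id and all indexes use stable
orderings, so runs are deterministic.

## Published artifacts

* **Taxon pages** `Ncbi:<tax_id>`: a `TaxonConcept` template with keys
  ncbi, name, homonym, wikipedia_en, wikipedia_en_id,
  wikipedia_en_snippet, wikipedia_image, rank, division_id, parent,
  synonyms — absent optional keys omitted, one `|key=value` per line.
  The parser accepts one or two opening braces, arbitrary key order,
  blank and continuation lines; unknown keys are preserved. Values are
  rendered on one line, so render∘parse is the identity on every valid
  record (the round-trip suite checks 1,000 random records). Snippets
  default to 300 characters, truncated at a sentence boundary (last
  word boundary if the first sentence alone overflows) with a trailing
  ellipsis.
* **Name pages**: a `#REDIRECT [[Ncbi:<tax_id>]]` page per uniquely
  held scientific name; a disambiguation page listing all `Ncbi:` pages
  for names held by several taxa.
* **Citation pages** `Citation:<cit_id>`, transcluded into the pages of
  every linked taxon so an edit (say, adding a DOI) propagates. External
  identifier resolution is a pluggable hook shipping as a no-op; a
  resolver failure degrades to a page without extra identifiers.
* **LinkOut**: one `<Link>` per mapped taxon against the `taxonomy`
  database, labelled "Wikipedia", URL built from the url-form title.
  Provider id/name are configuration placeholders pending registration.
* **RDF** (via `rdflib`): parent relations as `rdfs:subClassOf`
  (following UniProt's modelling of the taxonomy), `owl:sameAs` to the
  UniProt-taxonomy and Bio2RDF URIs for the tax_id and — when mapped —
  to the DBpedia resource for the title, page-name and page-id URLs as
  `foaf:page`, the Taxobox image as `foaf:depiction`, and name/rank via
  the TDWG taxon-name vocabulary. Exactly this statement set is emitted
  and its size is a closed-form function of the populated fields,
  asserted in tests. URI bases are configurable with the defaults above.

## The synthetic corpus

`taxolink.corpus` generates paired taxdump + wiki-export fixtures with a
ground-truth manifest, as a pure function of a `CorpusSpec` (identical
spec ⇒ byte-identical files). Defaults: 500 taxa, 25% per mapping type
(remainder unmatched — zero at these defaults), 5 homonym pairs and 5
monotypic chains of length 2–4 carved out of the type-1 share, redirect
chains of 1–3 hops, 3 non-taxon filler pages, 5 citation records, seed
42. Chain ancestors are generated in addition to `n_taxa` since they
occupy the collapsed role rather than the mapped/unmatched partition.
Names come from a syllable grammar with global uniqueness, so the only
collisions are the planted homonyms; a third of taxa get a vernacular
name of class `genbank common name` that never occurs in the wiki.

What the generator emulates: the taxdump dialect, Taxobox markup
(links, bold/italic, abbreviated species epithets, optional images),
redirect chains, homonymy across divisions, nested monotypy, filler
articles. What it does not: markup pathologies of real articles
(multi-template clutter, HTML tables, broken braces at scale), name
strings that differ only by orthography or authority formatting,
cross-namespace redirects, and the sheer scale of a full dump. Passing
recovery tests therefore demonstrates the correctness of the matching
logic under controlled naming, not robustness to every real-world
wikitext artefact; the markup stripper is exercised separately on real
Taxobox material in the bundled worked example.

## Problem sizes and numerical conventions

The test suite runs corpora of 30–80 taxa for unit-level checks and a
500-taxon corpus (25/25/25/25) for the end-to-end recovery check —
ample to exercise every planted scenario multiple times while keeping
the suite fast. `scripts/acceptance.py` uses the same 500-taxon
conditions with the caller's seed. Full dumps (tens of thousands of
linked taxa) are out of scope for the bundled fixtures but the streaming
dump reader and index structures are built for them.

There are no floating-point tolerances anywhere: every comparison in the
pipeline is exact (string or integer), and recovery scores are exact set
comparisons.

## Known limitations

* English Wikipedia only (`wikipedia_en`); no cross-language support.
* No fuzzy name matching; orthographic variants link only when NCBI
  carries them as name rows (e.g. class `misspelling`).
* Common names are not title-matched (see above).
* No live-wiki population, no incremental dump updates, no network
  resolver for citation identifiers; the resolver hook is a no-op.
* The Taxobox era is the classic single-template one; `Speciesbox`-era
  pages require enabling the alias switch and inherit its field naming.
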