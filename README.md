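# taxolink

Link NCBI taxonomy identifiers to Wikipedia pages.

The NCBI taxonomy `tax_id` is the default taxon identifier across
bioinformatics, but an NCBI record says little about what a taxon looks
like or how it lives — the kind of information a Wikipedia article
provides. `taxolink` is a *knuckle* service for biodiversity informatics:
it parses the NCBI taxonomy dump and an English-Wikipedia XML export,
reconciles each `tax_id` with the article about the same taxon, and
publishes the mapping as wiki template pages, an NCBI LinkOut resource
file, and RDF, so both databases (and anything built on them, such as
phylogeny databases keyed by `tax_id`) can cross-reference the other.

## The reconciliation model

Taxon articles are recognised by their `{{Taxobox}}` infobox, from which
the page's accepted scientific name is extracted (the `binomial` field,
else the lowest populated classification field, expanding abbreviated
epithets such as *H. chaophraya* against the genus). Both databases carry
synonyms — NCBI as extra name rows per `tax_id`, Wikipedia as redirect
pages — giving four link routes, tried in strict priority order:

| type | NCBI side | Wikipedia side |
|------|-----------|----------------|
| 1 | accepted scientific name | accepted page name |
| 2 | accepted scientific name | redirect → taxon page |
| 3 | synonym-class name | accepted page name |
| 4 | synonym-class name | redirect → taxon page |

Two safeguards handle the ways names collide:

* **Homonyms** — the same spelling can name a plant and an animal
  (*Abronia* is both a lizard and a sand-verbena genus) because the
  nomenclatural codes are independent; candidates are filtered by
  checking the taxon's GenBank `division_id` against the Taxobox
  `regnum` (kingdom). Unresolvable cases are emitted for manual
  curation, never guessed.
* **Nested monotypic taxa** — a monotypic genus and its sole species
  share one article; within each ancestor–descendant chain mapped to one
  page only the deepest taxon keeps the link, so no page id is mapped
  twice.

## Worked example

The package bundles a miniature corpus (`taxolink.examples`) built around
the giant freshwater stingray *Himantura chaophraya* (tax_id 87131), the
Abo bat, and the homonym genera *Rana*, *Abronia* and *Morus*:

```python
import io
from taxolink import examples, reconcile, publish
from taxolink.wikitext import iterate_pages

tax = examples.example_taxonomy()
pages = list(iterate_pages(io.BytesIO(examples.example_wiki_xml().encode())))
result, report = reconcile.reconcile_all(tax, pages)
for m in result.mappings:
    print(m.tax_id, tax.scientific_name(m.tax_id), "->", m.wikipedia_title,
          f"(page {m.wikipedia_page_id}, type {m.mapping_type})")
```

prints

```
34879 Abronia -> Abronia (plant) (page 500004, type 1)
52184 Abronia -> Abronia (lizard) (page 500003, type 1)
87131 Himantura chaophraya -> Giant freshwater stingray (page 8224153, type 1)
153297 Chalinolobus poensis -> Abo bat (page 500001, type 2)
```

The two *Abronia* genera are type-1 matches separated by division/regnum
filtering. The Abo bat is a type-2 match: NCBI's accepted name
*Chalinolobus poensis* exists on the wiki only as a redirect to the
article whose accepted name is *Glauconycteris poensis*. The *Rana*
genus and subgenus (both bearing the bare name "Rana" in NCBI) stay
unmatched but homonym-flagged. Rendering the stingray's published record:

```python
idx = reconcile.build_wiki_indexes(pages)
rec = publish.record_from_mapping(tax, 87131, result.by_tax_id()[87131], idx)
print(publish.render_taxon_page(rec))
```

```
{{TaxonConcept
|ncbi=87131
|name=Himantura chaophraya
|homonym=No
|wikipedia_en=Giant_freshwater_stingray
|wikipedia_en_id=8224153
|wikipedia_en_snippet=The giant freshwater stingray, Himantura chaophraya, is a species of stingray in the family Dasyatidae. It is found in large rivers and estuaries of Southeast Asia and northern Australia. One of the largest freshwater fishes in the world, it can weigh several hundred kilograms.
|wikipedia_image=Himantura_chaophraya.jpg
|rank=species
|division_id=10
|parent=ncbi:86362
|synonyms=Himantura chaophraya Monkolprasit and Roberts, 1990;Himantura chaophyraya;freshwater whipray
}}
```

The page name convention is `Ncbi:<tax_id>`; the Wikipedia page *id* is
stored alongside the title because titles change while ids are stable.

## Command line

```sh
taxolink fixture --out corpus --seed 11            # synthetic test corpus
taxolink validate --taxdump corpus/taxdump
taxolink reconcile --taxdump corpus/taxdump --wiki corpus/wiki.xml --out run
taxolink export linkout    --taxdump corpus/taxdump --wiki corpus/wiki.xml \
    --mapping run/mapping.tsv --out run
taxolink export wiki-pages --taxdump corpus/taxdump --wiki corpus/wiki.xml \
    --mapping run/mapping.tsv --out run
taxolink export rdf        --taxdump corpus/taxdump --wiki corpus/wiki.xml \
    --mapping run/mapping.tsv --out run
```

`reconcile` writes `mapping.tsv` (tax_id, name, url-form title, page id,
mapping type, matched name, notes) and `report.json` with per-type counts
and the effective configuration. Exports are byte-for-byte idempotent.

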