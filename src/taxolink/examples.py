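"""Hand-built worked example: the giant freshwater stingray and friends.

A miniature taxonomy and wiki dump exercising every reconciliation
scenario on real taxon names:

* *Himantura chaophraya* (tax_id 87131, the giant freshwater stingray) —
  the straightforward case where both databases use the same accepted
  name (mapping type 1);
* *Chalinolobus poensis* (the Abo bat) — NCBI's accepted name exists on
  the wiki only as a redirect to the article whose accepted name is
  *Glauconycteris poensis*, which NCBI in turn lists as a synonym, so the
  link is reachable both via the redirect (type 2) and via the synonym
  (type 3);
* *Rana* — a genus and its nominotypical subgenus share one name in NCBI
  (tax_ids 8399 and 121175), a within-database homonym;
* *Abronia* — a lizard genus and a plant genus with the same spelling,
  disambiguated by GenBank division vs Taxobox regnum;
* *Morus* — a plant genus and a bird genus, driving a disambiguation
  page in the published wiki.

Used throughout the documentation and tests.
"""

from __future__ import annotations

from .corpus import _wiki_xml
from .taxdump import TaxonName, TaxonNode, Taxonomy, assemble_taxonomy

STINGRAY_TAX_ID = 87131
HIMANTURA_TAX_ID = 86362
STINGRAY_PAGE_ID = 8224153
STINGRAY_TITLE = "Giant freshwater stingray"

STINGRAY_TAXOBOX = """{{Taxobox
| name = Giant freshwater stingray
| image = Himantura chaophraya.jpg
| image_width = 240 px
| status = VU | status_system = IUCN3.1
| status_ref = <ref name="iucn">{{IUCN2008 |assessors=Shark Specialist Group |year=2000 |id=10048 |title=Himantura chaophraya |downloaded=March 24, 2009}}</ref>
| regnum = [[Animalia]]
| phylum = [[Chordata]]
| classis = [[Chondrichthyes]]
| subclassis = [[Elasmobranchii]]
| ordo = [[Myliobatiformes]]
| familia = [[Dasyatidae]]
| genus = ''[[Himantura]]''
| species = '''''H. chaophraya'''''
| binomial = ''Himantura chaophraya''
| binomial_authority = Monkolprasit & Roberts, 1990
}}"""

STINGRAY_ARTICLE = STINGRAY_TAXOBOX + """
The '''giant freshwater stingray''', ''Himantura chaophraya'', is a species of stingray in the family [[Dasyatidae]]. It is found in large rivers and estuaries of Southeast Asia and northern Australia. One of the largest freshwater fishes in the world, it can weigh several hundred kilograms.

== Distribution ==
Rivers of Southeast Asia.
"""

STINGRAY_SYNONYMS = (
    "Himantura chaophraya Monkolprasit and Roberts, 1990",
    "Himantura chaophyraya",
    "freshwater whipray",
)

#: The published wiki page for tax_id 87131.
STINGRAY_TAXON_CONCEPT = """{{TaxonConcept
|ncbi=87131
|name=Himantura chaophraya
|homonym=No
|wikipedia_en=Giant_freshwater_stingray
|wikipedia_en_id=8224153
|wikipedia_en_snippet=The giant freshwater stingray, Himantura chaophraya...
|wikipedia_image=Himantura_chaophraya.jpg
|rank=species
|division_id=10
|parent=ncbi:86362
|synonyms=Himantura chaophraya Monkolprasit and Roberts, 1990;Himantura chaophyraya;freshwater whipray
}}
"""

ABO_BAT_TAX_ID = 153297
ABO_BAT_PAGE_ID = 500001
RANA_GENUS_TAX_ID = 8399
RANA_SUBGENUS_TAX_ID = 121175
ABRONIA_LIZARD_TAX_ID = 52184
ABRONIA_PLANT_TAX_ID = 34879
MORUS_PLANT_TAX_ID = 3497
MORUS_BIRD_TAX_ID = 56257


def example_taxonomy() -> Taxonomy:
    """The miniature taxonomy described in the module docstring."""
    nodes = [
        TaxonNode(1, 1, "no rank", 0),
        TaxonNode(HIMANTURA_TAX_ID, 1, "genus", 10),
        TaxonNode(STINGRAY_TAX_ID, HIMANTURA_TAX_ID, "species", 10),
        TaxonNode(ABO_BAT_TAX_ID, 1, "species", 2),
        TaxonNode(RANA_GENUS_TAX_ID, 1, "genus", 10),
        TaxonNode(RANA_SUBGENUS_TAX_ID, RANA_GENUS_TAX_ID, "subgenus", 10),
        TaxonNode(ABRONIA_LIZARD_TAX_ID, 1, "genus", 10),
        TaxonNode(ABRONIA_PLANT_TAX_ID, 1, "genus", 4),
        TaxonNode(MORUS_PLANT_TAX_ID, 1, "genus", 4),
        TaxonNode(MORUS_BIRD_TAX_ID, 1, "genus", 10),
    ]
    names = [
        TaxonName(1, "root", "scientific name"),
        TaxonName(HIMANTURA_TAX_ID, "Himantura", "scientific name"),
        TaxonName(STINGRAY_TAX_ID, "Himantura chaophraya", "scientific name"),
        TaxonName(STINGRAY_TAX_ID, STINGRAY_SYNONYMS[0], "authority"),
        TaxonName(STINGRAY_TAX_ID, STINGRAY_SYNONYMS[1], "misspelling"),
        TaxonName(STINGRAY_TAX_ID, STINGRAY_SYNONYMS[2], "genbank common name"),
        TaxonName(ABO_BAT_TAX_ID, "Chalinolobus poensis", "scientific name"),
        TaxonName(ABO_BAT_TAX_ID, "Glauconycteris poensis", "synonym"),
        TaxonName(RANA_GENUS_TAX_ID, "Rana", "scientific name"),
        TaxonName(RANA_SUBGENUS_TAX_ID, "Rana", "scientific name"),
        TaxonName(ABRONIA_LIZARD_TAX_ID, "Abronia", "scientific name"),
        TaxonName(ABRONIA_PLANT_TAX_ID, "Abronia", "scientific name"),
        TaxonName(MORUS_PLANT_TAX_ID, "Morus", "scientific name"),
        TaxonName(MORUS_BIRD_TAX_ID, "Morus", "scientific name"),
    ]
    return assemble_taxonomy(nodes, names)


ABO_BAT_ARTICLE = """{{Taxobox
| name = Abo bat
| regnum = [[Animalia]]
| phylum = [[Chordata]]
| classis = [[Mammalia]]
| ordo = [[Chiroptera]]
| familia = [[Vespertilionidae]]
| genus = ''[[Glauconycteris]]''
| species = '''''G. poensis'''''
| binomial = ''Glauconycteris poensis''
| binomial_authority = (Gray, 1842)
}}
The '''Abo bat''', ''Glauconycteris poensis'', is a species of vesper bat found in Africa.
"""

ABRONIA_LIZARD_ARTICLE = """{{Taxobox
| name = Abronia
| regnum = [[Animalia]]
| classis = [[Reptilia]]
| familia = [[Anguidae]]
| genus = ''[[Abronia]]''
}}
'''Abronia''' is a genus of arboreal alligator lizards.
"""

ABRONIA_PLANT_ARTICLE = """{{Taxobox
| name = Abronia
| regnum = [[Plantae]]
| familia = [[Nyctaginaceae]]
| genus = ''[[Abronia]]''
}}
'''Abronia''' is a genus of sand verbenas.
"""


def example_wiki_pages() -> list[tuple[str, int, int, str]]:
    """(title, page_id, namespace, wikitext) tuples for the example dump."""
    return [
        (STINGRAY_TITLE, STINGRAY_PAGE_ID, 0, STINGRAY_ARTICLE),
        ("Abo bat", ABO_BAT_PAGE_ID, 0, ABO_BAT_ARTICLE),
        ("Chalinolobus poensis", 500002, 0, "#REDIRECT [[Abo bat]]\n"),
        ("Abronia (lizard)", 500003, 0, ABRONIA_LIZARD_ARTICLE),
        ("Abronia (plant)", 500004, 0, ABRONIA_PLANT_ARTICLE),
    ]


def example_wiki_xml() -> str:
    """The example dump serialised as a MediaWiki XML export."""
    return _wiki_xml(example_wiki_pages())
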