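import io
import itertools
import random

import pytest

from taxolink import examples, reconcile
from taxolink.corpus import CorpusSpec, generate_corpus
from taxolink.taxdump import TaxonName, TaxonNode, assemble_taxonomy
from taxolink.wikitext import Taxobox, WikiPage, iterate_pages


def _page(title, page_id, text):
    from taxolink.wikitext import detect_redirect
    return WikiPage(title, page_id, 0, text, detect_redirect(text))


def _taxon_page_text(name, regnum=None):
    lines = ["{{Taxobox"]
    if regnum:
        lines.append(f"| regnum = [[{regnum}]]")
    if " " in name:
        lines.append(f"| genus = ''{name.split()[0]}''")
        lines.append(f"| binomial = ''{name}''")
    else:
        lines.append(f"| genus = ''{name}''")
    lines.append("}}")
    lines.append(f"'''{name}''' is a taxon.")
    return "\n".join(lines)


@pytest.fixture(scope="module")
def example_indexes(example_pages):
    return reconcile.build_wiki_indexes(example_pages)


class TestBuildWikiIndexes:
    def test_redirect_resolves_to_abo_bat(self, example_indexes):
        target = example_indexes.redirects["Chalinolobus poensis"]
        assert target.title == "Abo bat"
        assert not target.is_redirect

    def test_accepted_index_keys(self, example_indexes):
        assert set(example_indexes.accepted) == {
            "Himantura chaophraya", "Glauconycteris poensis", "Abronia"}
        assert len(example_indexes.accepted["Abronia"]) == 2

    def test_no_redirects(self):
        idx = reconcile.build_wiki_indexes(
            [_page("A b", 1, _taxon_page_text("A b"))])
        assert idx.redirects == {}

    def test_chain_followed_to_fixed_point(self):
        pages = [_page("A", 1, "#REDIRECT [[B]]"),
                 _page("B", 2, "#REDIRECT [[C]]"),
                 _page("C", 3, _taxon_page_text("C"))]
        idx = reconcile.build_wiki_indexes(pages)
        # brute-force iterative resolution oracle
        raw = {"A": "B", "B": "C"}
        for start in ("A", "B"):
            cur = start
            while cur in raw:
                cur = raw[cur]
            assert idx.redirects[start].title == cur == "C"

    def test_redirect_cycle_dropped(self):
        pages = [_page("A", 1, "#REDIRECT [[B]]"),
                 _page("B", 2, "#REDIRECT [[A]]")]
        idx = reconcile.build_wiki_indexes(pages)
        assert idx.redirects == {}

    def test_disambiguation_pages_excluded(self):
        text = "{{Taxobox\n| genus = ''X''\n}}\n{{disambiguation}}"
        idx = reconcile.build_wiki_indexes([_page("X", 1, text)])
        assert idx.accepted == {}


class TestClassifyMatch:
    def test_type1_stingray(self, example_taxonomy, example_indexes):
        m = reconcile.classify_match(87131, example_taxonomy, example_indexes)
        assert isinstance(m, reconcile.Mapping)
        assert m.mapping_type == 1
        assert m.wikipedia_title == "Giant freshwater stingray"
        assert m.via_redirect_title is None

    def test_type2_abo_bat_via_redirect(self, example_taxonomy,
                                        example_indexes):
        m = reconcile.classify_match(examples.ABO_BAT_TAX_ID,
                                     example_taxonomy, example_indexes)
        assert m.mapping_type == 2
        assert m.via_redirect_title == "Chalinolobus poensis"
        assert m.wikipedia_title == "Abo bat"

    def test_type3_when_redirect_absent(self, example_taxonomy,
                                        example_pages):
        pages = [p for p in example_pages if p.title != "Chalinolobus poensis"]
        idx = reconcile.build_wiki_indexes(pages)
        m = reconcile.classify_match(examples.ABO_BAT_TAX_ID,
                                     example_taxonomy, idx)
        assert m.mapping_type == 3
        assert m.matched_name == "Glauconycteris poensis"
        assert m.via_redirect_title is None

    def test_type4_synonym_via_redirect(self):
        tax = assemble_taxonomy(
            [TaxonNode(1, 1, "no rank", 0), TaxonNode(2, 1, "species", 10)],
            [TaxonName(1, "root", "scientific name"),
             TaxonName(2, "Aaa bbb", "scientific name"),
             TaxonName(2, "Ccc ddd", "synonym")])
        pages = [_page("Eee fff", 10, _taxon_page_text("Eee fff")),
                 _page("Ccc ddd", 11, "#REDIRECT [[Eee fff]]")]
        idx = reconcile.build_wiki_indexes(pages)
        m = reconcile.classify_match(2, tax, idx)
        assert m.mapping_type == 4
        assert m.via_redirect_title == "Ccc ddd"

    def test_priority_type1_beats_all(self):
        # taxon reachable via all four routes must come out type 1
        tax = assemble_taxonomy(
            [TaxonNode(1, 1, "no rank", 0), TaxonNode(2, 1, "species", 10)],
            [TaxonName(1, "root", "scientific name"),
             TaxonName(2, "Aaa bbb", "scientific name"),
             TaxonName(2, "Ccc ddd", "synonym")])
        pages = [
            _page("Aaa bbb", 10, _taxon_page_text("Aaa bbb")),
            _page("Ccc ddd page", 11, _taxon_page_text("Ccc ddd")),
            _page("Ccc ddd", 12, "#REDIRECT [[Ccc ddd page]]"),
        ]
        idx = reconcile.build_wiki_indexes(pages)
        m = reconcile.classify_match(2, tax, idx)
        assert m.mapping_type == 1
        assert m.wikipedia_page_id == 10

    def test_unmatched(self, example_taxonomy, example_indexes):
        assert reconcile.classify_match(
            examples.MORUS_BIRD_TAX_ID, example_taxonomy,
            example_indexes) is None

    def test_homonym_note_on_rana(self, example_taxonomy, example_pages):
        pages = example_pages + [
            _page("Rana", 600001, _taxon_page_text("Rana", "Animalia"))]
        idx = reconcile.build_wiki_indexes(pages)
        out = reconcile.classify_match(examples.RANA_GENUS_TAX_ID,
                                       example_taxonomy, idx)
        # genus and subgenus share the name: division cannot separate them
        # from one page, but the homonym flag must be raised
        assert "homonym" in (out.notes if isinstance(out, reconcile.Mapping)
                             else out.note)


class TestDisambiguateByDivision:
    def test_abronia_lizard_vs_plant(self, example_taxonomy, example_indexes):
        m = reconcile.classify_match(examples.ABRONIA_LIZARD_TAX_ID,
                                     example_taxonomy, example_indexes)
        assert m.wikipedia_title == "Abronia (lizard)"
        m = reconcile.classify_match(examples.ABRONIA_PLANT_TAX_ID,
                                     example_taxonomy, example_indexes)
        assert m.wikipedia_title == "Abronia (plant)"

    def test_single_candidate_unchanged(self, example_indexes):
        compat = reconcile.CompatibilityTable()
        (page,) = example_indexes.accepted["Himantura chaophraya"]
        for div in (0, 4, 10):
            kept, note = reconcile.disambiguate_by_division(
                [page], div, compat, example_indexes)
            if note:
                assert kept == [page]  # incompatible set returned unfiltered
            else:
                assert kept == [page]

    def test_emptying_filter_returns_unfiltered_with_note(
            self, example_indexes):
        compat = reconcile.CompatibilityTable()
        (page,) = example_indexes.accepted["Glauconycteris poensis"]
        kept, note = reconcile.disambiguate_by_division(
            [page], 4, compat, example_indexes)  # bat page vs plant division
        assert kept == [page] and note == "incompatible"

    def test_randomized_assignments_match_bruteforce(self):
        rng = random.Random(5)
        compat = reconcile.CompatibilityTable()
        regna = ["Animalia", "Plantae", "Fungi", "Viruses", "Unknownia", None]
        for trial in range(50):
            idx = reconcile.WikiIndexes()
            pages = []
            for pid in range(1, rng.randint(2, 6)):
                regnum = rng.choice(regna)
                page = _page(f"P{trial}_{pid}", pid, "x")
                box = Taxobox()
                if regnum:
                    box.rank_fields["regnum"] = regnum
                idx.taxoboxes[pid] = box
                pages.append(page)
            div = rng.choice([0, 1, 2, 3, 4, 5, 6, 9, 10])
            kept, note = reconcile.disambiguate_by_division(
                pages, div, compat, idx)
            # exhaustive filter oracle over the rule table
            rules = reconcile.DEFAULT_COMPAT_RULES
            expected = [p for p in pages
                        if (idx.taxoboxes[p.page_id].regnum is None
                            or idx.taxoboxes[p.page_id].regnum not in rules
                            or div in rules[idx.taxoboxes[p.page_id].regnum])]
            if expected:
                assert kept == expected and note == ""
            else:
                assert kept == pages and note == "incompatible"


def _chain_taxonomy(length):
    nodes = [TaxonNode(1, 1, "no rank", 0)]
    names = [TaxonName(1, "root", "scientific name")]
    for i in range(length):
        t = i + 2
        nodes.append(TaxonNode(t, t - 1 if i else 1, "clade", 10))
        names.append(TaxonName(t, f"Taxon {t}", "scientific name"))
    return assemble_taxonomy(nodes, names)


class TestCollapseMonotypic:
    @pytest.mark.parametrize("length", [2, 3, 4])
    def test_deepest_kept(self, length):
        tax = _chain_taxonomy(length)
        mappings = [reconcile.Mapping(t, "Shared", 77, 1, f"Taxon {t}")
                    for t in range(2, length + 2)]
        result = reconcile.collapse_monotypic(mappings, tax)
        assert [m.tax_id for m in result.mappings] == [length + 1]
        assert sorted(result.collapsed) == \
            [(t, length + 1) for t in range(2, length + 1)]

    def test_distinct_pages_unchanged(self):
        tax = _chain_taxonomy(3)
        mappings = [reconcile.Mapping(t, f"P{t}", t * 10, 1, "n")
                    for t in (2, 3, 4)]
        result = reconcile.collapse_monotypic(mappings, tax)
        assert result.mappings == sorted(mappings, key=lambda m: m.tax_id)
        assert result.collapsed == []

    def test_non_chain_group_goes_ambiguous(self):
        # two siblings mapped to one page are a conflict, not monotypy
        nodes = [TaxonNode(1, 1, "no rank", 0),
                 TaxonNode(2, 1, "species", 10),
                 TaxonNode(3, 1, "species", 10)]
        names = [TaxonName(1, "root", "scientific name"),
                 TaxonName(2, "Aaa bbb", "scientific name"),
                 TaxonName(3, "Ccc ddd", "scientific name")]
        tax = assemble_taxonomy(nodes, names)
        mappings = [reconcile.Mapping(2, "Shared", 77, 1, "Aaa bbb"),
                    reconcile.Mapping(3, "Shared", 77, 1, "Ccc ddd")]
        result = reconcile.collapse_monotypic(mappings, tax)
        assert result.mappings == []
        assert {a.tax_id for a in result.ambiguous} == {2, 3}

    def test_generated_chains_keep_manifest_deepest(self, small_corpus,
                                                    small_spec):
        from taxolink.taxdump import parse_names, parse_nodes
        tax = assemble_taxonomy(parse_nodes(small_corpus.nodes_dmp),
                                parse_names(small_corpus.names_dmp))
        pages = iterate_pages(io.BytesIO(small_corpus.wiki_xml.encode()))
        result, _ = reconcile.reconcile_all(tax, pages)
        collapsed = {}
        for dropped, kept in result.collapsed:
            collapsed.setdefault(kept, []).append(dropped)
        expected = {k: sorted(v)
                    for k, v in small_corpus.manifest.collapsed_expect}
        assert {k: sorted(v) for k, v in collapsed.items()} == expected
        # brute-force depth check: kept node is deepest in its group
        for kept, dropped in expected.items():
            assert all(tax.depth(kept) > tax.depth(d) for d in dropped)


class TestReconcileAll:
    def test_worked_example_counts(self, example_taxonomy, example_pages):
        result, report = reconcile.reconcile_all(example_taxonomy,
                                                 example_pages)
        by_tax = result.by_tax_id()
        assert by_tax[87131].mapping_type == 1
        assert by_tax[examples.ABO_BAT_TAX_ID].mapping_type == 2
        assert report.counts["homonym_flagged"] >= 2  # both Rana nodes
        # Rana has no page: both homonym nodes stay unmatched
        assert examples.RANA_GENUS_TAX_ID in result.unmatched
        assert examples.RANA_SUBGENUS_TAX_ID in result.unmatched

    def test_empty_dump_all_unmatched(self, example_taxonomy):
        result, report = reconcile.reconcile_all(example_taxonomy, [])
        assert result.mappings == []
        assert report.counts["unmatched"] == report.counts["taxa"]

    def test_synthetic_recovery_matches_manifest(self, small_corpus):
        from taxolink.taxdump import parse_names, parse_nodes
        tax = assemble_taxonomy(parse_nodes(small_corpus.nodes_dmp),
                                parse_names(small_corpus.names_dmp))
        result, report = reconcile.reconcile_all(
            tax, iterate_pages(io.BytesIO(small_corpus.wiki_xml.encode())))
        got = {(m.tax_id, m.wikipedia_page_id, m.mapping_type)
               for m in result.mappings}
        assert got == set(small_corpus.manifest.true_mapping)
        assert sorted(result.unmatched) == small_corpus.manifest.unmatched
        for t, n in small_corpus.manifest.type_counts().items():
            assert report.counts[f"type_{t}"] == n

    def test_determinism(self, small_corpus):
        from taxolink.taxdump import parse_names, parse_nodes
        tax = assemble_taxonomy(parse_nodes(small_corpus.nodes_dmp),
                                parse_names(small_corpus.names_dmp))

        def run():
            return reconcile.reconcile_all(
                tax, iterate_pages(io.BytesIO(small_corpus.wiki_xml.encode())))

        r1, rep1 = run()
        r2, rep2 = run()
        assert r1 == r2 and rep1.counts == rep2.counts

    def test_page_ids_unique_post_collapse(self, small_corpus):
        from taxolink.taxdump import parse_names, parse_nodes
        tax = assemble_taxonomy(parse_nodes(small_corpus.nodes_dmp),
                                parse_names(small_corpus.names_dmp))
        result, _ = reconcile.reconcile_all(
            tax, iterate_pages(io.BytesIO(small_corpus.wiki_xml.encode())))
        ids = [m.wikipedia_page_id for m in result.mappings]
        assert len(ids) == len(set(ids))

    def test_buckets_are_disjoint(self, small_corpus):
        from taxolink.taxdump import parse_names, parse_nodes
        tax = assemble_taxonomy(parse_nodes(small_corpus.nodes_dmp),
                                parse_names(small_corpus.names_dmp))
        result, _ = reconcile.reconcile_all(
            tax, iterate_pages(io.BytesIO(small_corpus.wiki_xml.encode())))
        buckets = [
            {m.tax_id for m in result.mappings},
            set(result.unmatched),
            {a.tax_id for a in result.ambiguous},
            {t for t, _ in result.collapsed},
        ]
        for a, b in itertools.combinations(buckets, 2):
            assert not (a & b)


class TestMappingTable:
    def test_tsv_round_trip(self, example_taxonomy, example_pages):
        result, _ = reconcile.reconcile_all(example_taxonomy, example_pages)
        tsv = reconcile.mapping_table_tsv(result, example_taxonomy)
        parsed = reconcile.parse_mapping_table(tsv)
        assert [(m.tax_id, m.wikipedia_page_id, m.mapping_type)
                for m in parsed] == \
            [(m.tax_id, m.wikipedia_page_id, m.mapping_type)
             for m in result.mappings]

    def test_rejects_foreign_text(self):
        with pytest.raises(ValueError):
            reconcile.parse_mapping_table("not a table")
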