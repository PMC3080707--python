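import io
import random
import string

import pytest
from hypothesis import HealthCheck, settings

from taxolink import corpus, examples
from taxolink.publish import TaxonConceptRecord
from taxolink.wikitext import iterate_pages

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def example_taxonomy():
    return examples.example_taxonomy()


@pytest.fixture(scope="session")
def example_pages():
    xml = examples.example_wiki_xml().encode()
    return list(iterate_pages(io.BytesIO(xml)))


@pytest.fixture(scope="session")
def small_spec():
    return corpus.CorpusSpec(
        n_taxa=40, n_homonym_pairs=2, n_monotypic_chains=2,
        n_nontaxon_pages=2, n_citations=3, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return corpus.generate_corpus(small_spec)


def random_record(rng: random.Random) -> TaxonConceptRecord:
    """A random but valid TaxonConceptRecord for round-trip testing.

    Values stay within what the renderer guarantees to round-trip: no
    newlines, no semicolons inside individual synonyms, no leading pipes.
    """
    def word(lo=3, hi=10):
        return "".join(rng.choice(string.ascii_lowercase)
                       for _ in range(rng.randint(lo, hi)))

    def name():
        return word().capitalize() + " " + word()

    mapped = rng.random() < 0.7
    title = word().capitalize() + "_" + word() if mapped else None
    return TaxonConceptRecord(
        ncbi=rng.randint(2, 10**7),
        name=name(),
        homonym=rng.random() < 0.2,
        wikipedia_en=title,
        wikipedia_en_id=rng.randint(1, 10**8) if mapped else None,
        wikipedia_en_snippet=(f"The {word()}, {name()}, is a {word()}. "
                              f"It lives in {word()}..." if mapped else None),
        wikipedia_image=f"{name().replace(' ', '_')}.jpg"
                        if mapped and rng.random() < 0.5 else None,
        rank=rng.choice(["species", "genus", "family", "no rank"]),
        division_id=rng.choice([0, 1, 2, 3, 4, 5, 6, 9, 10]),
        parent=rng.randint(1, 10**6) if rng.random() < 0.9 else None,
        synonyms=tuple(f"{name()} {word().capitalize()}, {rng.randint(1758, 2010)}"
                       for _ in range(rng.randint(0, 3))),
    )
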