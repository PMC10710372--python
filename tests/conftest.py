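"""Shared fixtures: the worked-example matrix, toy lexicon, and a matrix
trained on seed-deterministic single-error typos of the toy vocabulary."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pytest

from tblat.kmers import TokenPairCorpus, profile_errors
from tblat.lexicon import load_ontology, toy_ontology_path
from tblat.matrix import build_matrix, load_matrix
from tblat.recognize import Recognizer
from tblat.synthetic import GENERATABLE_CATEGORIES, make_typo

# Per-position transition values of the worked example for the token
# "abnormal": row values, identity target first.
EXAMPLE_ROWS = {
    "abn": {"abn": 0.49, "bno": 0.20, "abo": 0.03, "bnr": 0.02, "bon": 0.02,
            "abd": 0.01, "bor": 0.01},
    "bno": {"bno": 0.32, "abn": 0.18, "nor": 0.13, "abo": 0.02, "bnr": 0.01,
            "bon": 0.01, "nro": 0.01, "abd": 0.01, "dno": 0.01},
    "nor": {"nor": 0.41, "orm": 0.06, "orr": 0.04, "eno": 0.04, "bno": 0.02,
            "ino": 0.02, "ono": 0.02, "ort": 0.01, "sno": 0.01},
    "orm": {"orm": 0.34, "for": 0.09, "nor": 0.08, "rma": 0.06, "rmo": 0.01,
            "hor": 0.01, "rmi": 0.01, "rom": 0.01},
    "rma": {"rma": 0.34, "orm": 0.08, "erm": 0.06, "mal": 0.04, "mat": 0.04,
            "arm": 0.02, "man": 0.02, "nor": 0.01, "mac": 0.01},
    "mal": {"mal": 0.40, "rma": 0.07, "all": 0.03, "ali": 0.02, "ala": 0.02,
            "sma": 0.02, "ima": 0.02, "orm": 0.02, "oma": 0.01},
}


@pytest.fixture(scope="session")
def example_matrix():
    path = resources.files("tblat.data").joinpath("example_matrix.tsv")
    return load_matrix(str(path))


@pytest.fixture(scope="session")
def toy_lexicon():
    return load_ontology(toy_ontology_path(), root_filter="HP:0000118")


@pytest.fixture(scope="session")
def training_corpus(toy_lexicon):
    """Single-error typos (30 per token, mixed categories) of the toy vocabulary."""
    rng = np.random.default_rng(7)
    cats = list(GENERATABLE_CATEGORIES)
    pairs = []
    for tok in sorted(toy_lexicon.vocabulary):
        if len(tok) < 4:
            continue
        for _ in range(30):
            cat = cats[int(rng.integers(0, len(cats)))]
            pairs.append((tok, make_typo(tok, cat, rng)))
    return TokenPairCorpus(pairs, {"seed": 7})


@pytest.fixture(scope="session")
def trained_matrix(training_corpus):
    return build_matrix(training_corpus)


@pytest.fixture(scope="session")
def trained_profile(training_corpus):
    return profile_errors(training_corpus)


@pytest.fixture(scope="session")
def recognizer(toy_lexicon, trained_matrix, trained_profile):
    return Recognizer(toy_lexicon, trained_matrix, profile=trained_profile)
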