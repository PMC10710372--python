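import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tblat.kmers import ErrorCategory, classify_transition, pair_transitions
from tblat.synthetic import (
    AnnotatedDoc,
    TypoSpec,
    band_error_count,
    gen_pair_corpus,
    gen_typo_errors,
    make_typo,
    perturb_corpus,
)


def damerau_levenshtein(a: str, b: str) -> int:
    """Independent restricted Damerau-Levenshtein distance (test oracle)."""
    d = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        d[i][0] = i
    for j in range(len(b) + 1):
        d[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[len(a)][len(b)]


def has_category(canonical, typo, category):
    if len(typo) < 3:
        return False
    return any(
        classify_transition(r.source, r.target) is category
        for r in pair_transitions(canonical, typo)
        if r.target is not None
    )


class TestMakeTypo:
    @pytest.mark.parametrize(
        "category",
        [
            ErrorCategory.SHIFT,
            ErrorCategory.SINGLE_REPLACEMENT,
            ErrorCategory.DOUBLE_REPLACEMENT,
            ErrorCategory.GAP_SHIFT,
            ErrorCategory.INVERSION,
        ],
    )
    def test_requested_category_present(self, category):
        rng = np.random.default_rng(0)
        for token in ("abnormal", "skeletal", "phalanges", "acylglycine"):
            for _ in range(10):
                typo = make_typo(token, category, rng)
                assert typo != token
                assert has_category(token, typo, category)

    def test_inversion_is_adjacent_swap(self):
        rng = np.random.default_rng(1)
        typo = make_typo("abnormal", ErrorCategory.INVERSION, rng)
        assert sorted(typo) == sorted("abnormal")
        assert damerau_levenshtein("abnormal", typo) == 1

    def test_deterministic_under_seed(self):
        a = make_typo("abnormal", ErrorCategory.SHIFT, np.random.default_rng(9))
        b = make_typo("abnormal", ErrorCategory.SHIFT, np.random.default_rng(9))
        assert a == b

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            make_typo("hip", ErrorCategory.SHIFT, np.random.default_rng(0))

    def test_identity_category_rejected(self):
        with pytest.raises(ValueError):
            make_typo("abnormal", ErrorCategory.IDENTITY, np.random.default_rng(0))

    def test_classification_rate_of_single_edit_typos(self):
        # requested category must be confirmed by classification for >= 95%
        rng = np.random.default_rng(3)
        cats = [
            ErrorCategory.SHIFT,
            ErrorCategory.SINGLE_REPLACEMENT,
            ErrorCategory.INVERSION,
        ]
        ok = total = 0
        for token in ("abnormal", "phalanges", "shortening", "dysplasia"):
            for cat in cats:
                for _ in range(20):
                    typo = make_typo(token, cat, rng)
                    total += 1
                    ok += has_category(token, typo, cat)
        assert ok / total >= 0.95


class TestBanding:
    @pytest.mark.parametrize(
        "length,expected", [(4, 1), (9, 1), (10, 3), (17, 3), (18, 4), (25, 4)]
    )
    def test_band_error_count(self, length, expected):
        assert band_error_count(length) == expected

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=4, max_value=25), st.integers(min_value=0, max_value=99))
    def test_variants_carry_banded_edit_count(self, length, seed):
        token = ("abcdefghijklmnopqrstuvwxy" * 2)[:length]
        spec = TypoSpec(seed=seed)
        variants = gen_typo_errors(token, spec, n_variants=3, return_edits=True)
        expected = band_error_count(length)
        for typo, edits in variants.items():
            assert len(edits) == expected
            assert typo != token
            assert 1 <= damerau_levenshtein(token, typo) <= 2 * expected

    def test_length_11_uses_three_errors(self):
        variants = gen_typo_errors("acylglycine", TypoSpec(seed=2), n_variants=4, return_edits=True)
        assert all(len(edits) == 3 for edits in variants.values())

    def test_reproducible(self):
        a = gen_typo_errors("abnormal", TypoSpec(seed=5), n_variants=5)
        b = gen_typo_errors("abnormal", TypoSpec(seed=5), n_variants=5)
        assert a == b

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            gen_typo_errors("hip", TypoSpec(seed=1))

    def test_spec_weights_validated(self):
        with pytest.raises(ValueError):
            TypoSpec(categories={})
        with pytest.raises(ValueError):
            TypoSpec(categories={ErrorCategory.OTHER: 1.0})
        with pytest.raises(ValueError):
            TypoSpec(categories={ErrorCategory.SHIFT: -1.0})

    def test_category_mix_recovered_from_edit_logs(self):
        # generator parameters are the oracle: 50/50 shift/inversion
        spec = TypoSpec(
            categories={ErrorCategory.SHIFT: 0.5, ErrorCategory.INVERSION: 0.5},
            seed=17,
        )
        counts = {ErrorCategory.SHIFT: 0, ErrorCategory.INVERSION: 0}
        total = 0
        for i in range(120):
            variants = gen_typo_errors(
                "shortening", TypoSpec(categories=spec.categories, seed=1000 + i),
                n_variants=3, return_edits=True,
            )
            for edits in variants.values():
                for cat in edits:
                    counts[cat] += 1
                    total += 1
        for cat, n in counts.items():
            assert n / total == pytest.approx(0.5, abs=0.03)


class TestGenPairCorpus:
    ROWS = {"abc": {"abd": 0.7, "abe": 0.3}}

    def test_n_pairs(self):
        corpus = gen_pair_corpus(["abc"], self.ROWS, n=50, seed=0)
        assert len(corpus) == 50
        assert all(c == "abc" for c, _ in corpus)

    def test_single_pair(self):
        corpus = gen_pair_corpus(["abc"], self.ROWS, n=1, seed=0)
        assert len(corpus) == 1

    def test_draws_match_distribution(self):
        corpus = gen_pair_corpus(["abc"], self.ROWS, n=4000, seed=3)
        frac = sum(t == "abd" for _, t in corpus) / len(corpus)
        assert frac == pytest.approx(0.7, abs=0.02)

    def test_deterministic(self):
        a = gen_pair_corpus(["abc"], self.ROWS, n=20, seed=5)
        b = gen_pair_corpus(["abc"], self.ROWS, n=20, seed=5)
        assert a.pairs == b.pairs

    def test_identity_only_distribution_rejected(self):
        with pytest.raises(ValueError):
            gen_pair_corpus(["abc"], {"abc": {"abc": 1.0}}, n=10, seed=0)

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValueError):
            gen_pair_corpus([], self.ROWS, n=10, seed=0)

    def test_non_trigram_vocab_rejected(self):
        with pytest.raises(ValueError):
            gen_pair_corpus(["abcd"], self.ROWS, n=10, seed=0)

    def test_unnormalized_row_rejected(self):
        with pytest.raises(ValueError):
            gen_pair_corpus(["abc"], {"abc": {"abd": 0.5}}, n=10, seed=0)

    def test_parameters_recorded(self):
        corpus = gen_pair_corpus(["abc"], self.ROWS, n=10, seed=5)
        assert corpus.metadata["seed"] == 5
        assert corpus.metadata["transition_probs"]["abc"]["abd"] == 0.7


class TestPerturbCorpus:
    def _doc(self):
        text = "Patient has a cataract and skeletal dysplasia today."
        anns = [
            (text.index("cataract"), text.index("cataract") + len("cataract"), "HP:0000518"),
            (text.index("skeletal"), text.index("dysplasia") + len("dysplasia"), "HP:0002652"),
        ]
        return AnnotatedDoc("d1", text, anns)

    def test_replacements_and_offsets(self):
        doc = self._doc()
        typo_map = {"cataract": "catract", "skeletal": "skeletral", "dysplasia": "dyplasia"}
        (out,) = perturb_corpus([doc], typo_map, seed=0)
        assert "catract" in out.text and "skeletral" in out.text
        s, e, cid = out.annotations[0]
        assert out.text[s:e] == "catract"
        s, e, cid = out.annotations[1]
        assert out.text[s:e] == "skeletral dyplasia"

    def test_empty_map_is_identity(self):
        doc = self._doc()
        (out,) = perturb_corpus([doc], {}, seed=0)
        assert out.text == doc.text
        assert out.annotations == doc.annotations

    def test_tokens_outside_spans_untouched(self):
        doc = self._doc()
        typo_map = {"patient": "pateint", "cataract": "catract"}
        (out,) = perturb_corpus([doc], typo_map, seed=0)
        assert out.text.startswith("Patient has")  # outside any span
        assert "catract" in out.text

    def test_choice_from_sequence_deterministic(self):
        doc = self._doc()
        typo_map = {"cataract": ["catract", "cattaract", "cataroct"]}
        a = perturb_corpus([doc], typo_map, seed=9)[0].text
        b = perturb_corpus([doc], typo_map, seed=9)[0].text
        assert a == b

    def test_replacement_never_crosses_span_boundaries(self):
        doc = self._doc()
        typo_map = {"cataract": "catract"}
        (out,) = perturb_corpus([doc], typo_map, seed=0)
        for (s, e, _), (s2, e2, _) in zip(doc.annotations, out.annotations):
            assert out.text[:s2].count("catract") == 0 or s2 <= s
        assert out.text[out.annotations[1][0] : out.annotations[1][1]] == "skeletal dysplasia"
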