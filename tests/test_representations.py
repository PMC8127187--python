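import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multirep_ner as m
from multirep_ner.representations import NORM_ALPHABET, _deduplicate

# ---------------------------------------------------------------------------
# orthographic


@pytest.mark.parametrize(
    "surface, expected",
    [
        ("HIV-1", [5, 1, 0, 0, 1, 1, 1, 1, 0, 3, 0, 1]),
        ("cat", [3, 0, 1, 0, 0, 0, 0, 0, 3, 0, 0, 0]),
        ("", [0] * 12),
    ],
)
def test_orthographic_hand_computed(surface, expected):
    np.testing.assert_array_equal(m.orthographic_features(surface), expected)


def test_orthographic_greek_detection():
    assert m.orthographic_features("TGF-β")[3] == 1.0
    assert m.orthographic_features("alpha helix")[3] == 1.0
    assert m.orthographic_features("alphabet")[3] == 0.0  # not a whole token


@given(st.text(alphabet=st.characters(codec="ascii", categories=["L", "N", "P", "S"]) | st.just(" "), max_size=30))
@settings(max_examples=200, deadline=None)
def test_orthographic_class_counts_partition_the_string(surface):
    """lower + upper + digits + spaces + symbols = length (no Greek input)."""
    v = m.orthographic_features(surface)
    assert v[8] + v[9] + v[5] + v[10] + v[11] == v[0]


# ---------------------------------------------------------------------------
# normalization and compression


@pytest.mark.parametrize(
    "surface, expected",
    [("HIV-1", "AAA-0"), ("cat", "aaa"), ("AAa0aaa", "AAa0aaa"), ("", "")],
)
def test_normalize_surface(surface, expected):
    assert m.normalize_surface(surface) == expected


@pytest.mark.parametrize(
    "normalized, expected", [("AAa0aaa", "Aa0a"), ("aaaa", "a"), ("", "")]
)
def test_compress(normalized, expected):
    assert m.compress(normalized) == expected


@given(st.text(alphabet=NORM_ALPHABET, max_size=40))
@settings(max_examples=200, deadline=None)
def test_compress_idempotent_and_no_adjacent_repeats(s):
    once = m.compress(s)
    assert m.compress(once) == once
    assert all(a != b for a, b in zip(once, once[1:]))


@given(st.text(max_size=40))
@settings(max_examples=200, deadline=None)
def test_normalize_preserves_length_and_alphabet(s):
    norm = m.normalize_surface(s)
    assert len(norm) == len(s)
    assert set(norm) <= set(NORM_ALPHABET)


# ---------------------------------------------------------------------------
# word shape


def test_word_shape_on_reference_token():
    # classes in 'aA0-' order; per class: total, max run, min run, compressed
    v = m.word_shape_features("AAa0aaa")
    np.testing.assert_array_equal(
        v, [4, 3, 1, 2, 2, 2, 2, 1, 1, 1, 1, 1, 0, 0, 0, 0]
    )


def test_word_shape_simple_and_empty():
    np.testing.assert_array_equal(
        m.word_shape_features("cat"), [3, 3, 3, 1] + [0] * 12
    )
    np.testing.assert_array_equal(m.word_shape_features(""), [0] * 16)


@given(st.text(max_size=30))
@settings(max_examples=200, deadline=None)
def test_word_shape_compressed_count_matches_compress(s):
    v = m.word_shape_features(s)
    comp = m.compress(m.normalize_surface(s))
    for i, symbol in enumerate(NORM_ALPHABET):
        assert v[4 * i + 3] == comp.count(symbol)


# ---------------------------------------------------------------------------
# spectrum


def _brute_substrings(token: str, p: int) -> set:
    return {token[i : i + p] for i in range(len(token) - p + 1)}


def test_spectrum_on_reference_token():
    # compress(normalize("AAa0aaa")) == "Aa0a"
    v2 = m.spectrum_features("AAa0aaa", 2)
    assert v2.sum() == 3  # "Aa", "a0", "0a"
    v1 = m.spectrum_features("AAa0aaa", 1)
    assert v1.sum() == 3  # a, A, 0 present; '-' absent
    assert m.spectrum_features("cat", 3).sum() == 0  # compressed "a" too short


def test_spectrum_bad_arity():
    with pytest.raises(m.ConfigurationError):
        m.spectrum_features("cat", 6)


@pytest.mark.parametrize("p", [1, 2, 3])
def test_spectrum_dot_product_counts_shared_substrings(rng, p):
    """The spectrum inner product equals the brute-force count of distinct
    shared length-p substrings of the compressed normalized surfaces."""
    alphabet = list("aB3-xY 9z")
    for _ in range(100):
        s = "".join(rng.choice(alphabet, size=rng.integers(0, 15)))
        t = "".join(rng.choice(alphabet, size=rng.integers(0, 15)))
        dot = float(m.spectrum_features(s, p) @ m.spectrum_features(t, p))
        cs = m.compress(m.normalize_surface(s))
        ct = m.compress(m.normalize_surface(t))
        assert dot == len(_brute_substrings(cs, p) & _brute_substrings(ct, p))


def test_spectrum_global_dedup_variant():
    assert _deduplicate("AAa0aaa") == "Aa0"
    v = m.spectrum_features("AAa0aaa", 1, dedup="global")
    assert v.sum() == 3


# ---------------------------------------------------------------------------
# affixes


def _resource(counts, name="r"):
    return m.AffixResource(name, counts)


def test_affix_max_count_maps_to_one_and_absent_to_zero():
    res = _resource({("suffix3", "ase"): 10, ("suffix3", "ism"): 5})
    v = m.affix_features("kinase", (res,))
    assert v.shape == (4,)
    assert v[3] == 1.0            # suffix3 "ase" holds the max count
    assert v[0] == v[1] == 0.0    # prefixes absent from the resource
    v2 = m.affix_features("dwarfism", (res,))
    assert v2[3] == 0.5


def test_affix_default_configuration_has_20_features(suffix_fixture):
    v = m.affix_features("kinase", tuple(suffix_fixture.affix_resources))
    assert v.shape == (20,)


def test_affix_short_token_features_are_zero():
    res = _resource({("prefix2", "ca"): 3, ("prefix3", "cat"): 3,
                     ("suffix2", "at"): 3, ("suffix3", "cat"): 3})
    v = m.affix_features("cat", (res,))
    # 3-char token: only the 2-char affixes exist (proper affixes only)
    assert v[0] == 1.0 and v[2] == 1.0
    assert v[1] == 0.0 and v[3] == 0.0
    np.testing.assert_array_equal(m.affix_features("ab", (res,)), [0, 0, 0, 0])


def test_affixes_of_multiword_use_first_and_last_token():
    res = _resource({("prefix2", "De"): 2, ("suffix3", "cid"): 2})
    v = m.affix_features("Deoxyribonucleic acid", (res,))
    assert v[0] == 1.0 and v[3] == 1.0


# ---------------------------------------------------------------------------
# embeddings


def _table():
    return m.EmbeddingTable(
        "t", 3,
        {"deoxyribonucleic": np.array([1.0, 2.0, 3.0]),
         "acid": np.array([3.0, 4.0, 5.0])},
    )


def test_embedding_single_word_identity():
    np.testing.assert_array_equal(
        m.embedding_features("acid", _table()), [3.0, 4.0, 5.0]
    )


def test_embedding_oov_gives_zero_vector():
    np.testing.assert_array_equal(m.embedding_features("zzz qqq", _table()), [0, 0, 0])


def test_embedding_multiword_mean_and_casefold_fallback():
    np.testing.assert_array_equal(
        m.embedding_features("Deoxyribonucleic acid", _table()), [2.0, 3.0, 4.0]
    )


# ---------------------------------------------------------------------------
# the bank


def test_default_bank_has_ten_aligned_entries(suffix_bank):
    bank = suffix_bank
    assert len(bank.names) == 10
    assert sum(1 for n in bank.names if n.startswith("spectrum_")) == 5
    widths = bank.widths()
    assert widths["orthographic"] == 12
    assert widths["affixes"] == 20
    assert widths["word_norm"] == 16
    for p in range(1, 6):
        assert widths[f"spectrum_{p}"] == 4**p
    n = len(bank)
    assert all(bank.matrix(name).shape[0] == n for name in bank.names)
    assert np.isfinite(bank.concatenated()).all()


def test_bank_without_embeddings_has_eight_entries(suffix_fixture, suffix_candidates):
    cands, _ = suffix_candidates
    bank = m.build_representation_bank(
        cands, suffix_fixture.representation_config(include_embeddings=False)
    )
    assert len(bank.names) == 8
    assert len(bank) == len(cands)


def test_bank_requires_configured_resources(suffix_candidates):
    cands, _ = suffix_candidates
    with pytest.raises(m.ConfigurationError, match="affix"):
        m.build_representation_bank(cands, m.RepresentationConfig())
    with pytest.raises(m.ConfigurationError, match="embedding_domain"):
        m.build_representation_bank(
            cands,
            m.RepresentationConfig(
                affix_resources=(m.AffixResource("r", {}),),
                include_embeddings=True,
            ),
        )
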