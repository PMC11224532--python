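"""Lexicon generation, slot encodings and psycholinguistic predictors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triread.errors import (EncodingError, GenerationError,
                            LexiconParseError)
from triread.lexicon import (EncodingSpec, Lexicon, LexiconParams,
                             PhonemeInventory, WordEntry,
                             compute_ons, compute_rime_consistency,
                             encode_orthography, encode_phonology,
                             generate_lexicon, orthography_slots,
                             phonology_slots, read_inventory, read_lexicon,
                             write_inventory, write_lexicon)

INV = PhonemeInventory.default()
SPEC = EncodingSpec.default()


class TestEncoding:
    @pytest.mark.parametrize("spelling,layout", [
        ("yes", {4: "y", 5: "e", 7: "s"}),
        ("great", {3: "g", 4: "r", 5: "e", 6: "a", 7: "t"}),
        ("mint", {4: "m", 5: "i", 7: "n", 8: "t"}),
        ("eat", {5: "e", 6: "a", 7: "t"}),
    ])
    def test_orthographic_slot_layout(self, spelling, layout):
        assert orthography_slots(spelling, SPEC) == layout

    @pytest.mark.parametrize("pron,layout", [
        (("j", "E", "s"), {3: "j", 4: "E", 5: "s"}),
        (("g", "r", "eI", "t"), {2: "g", 3: "r", 4: "eI", 5: "t"}),
        (("eI",), {4: "eI"}),
    ])
    def test_phonological_slot_layout(self, pron, layout):
        assert phonology_slots(pron, INV, SPEC) == layout

    def test_vector_lengths_match_standard_template(self):
        assert SPEC.ortho_len == 14 * 26 == 364
        assert SPEC.phon_len == 8 * 25 == 200
        assert encode_orthography("yes", SPEC).shape == (364,)
        assert encode_phonology(("j", "E", "s"), INV, SPEC).shape == (200,)

    def test_one_hot_per_occupied_slot(self):
        vec = encode_orthography("great", SPEC)
        assert vec.sum() == 5
        by_slot = vec.reshape(14, 26).sum(axis=1)
        assert list(np.flatnonzero(by_slot) + 1) == [3, 4, 5, 6, 7]

    def test_phonology_features_fill_occupied_slots(self):
        vec = encode_phonology(("j", "E", "s"), INV, SPEC).reshape(8, 25)
        assert np.array_equal(vec[2], INV.vector("j"))
        assert np.array_equal(vec[3], INV.vector("E"))
        assert np.array_equal(vec[4], INV.vector("s"))
        assert not vec[[0, 1, 5, 6, 7]].any()

    @pytest.mark.parametrize("bad", [
        "",           # no letters at all
        "xzz",        # no vowel letter
        "Bad",        # not lowercase
        "bcdfgu",     # five onset letters overflow slots 1..4
        "enormousnesses",  # tail overflows slot 14
    ])
    def test_orthography_errors(self, bad):
        with pytest.raises(EncodingError):
            encode_orthography(bad, SPEC)

    def test_phonology_errors(self):
        with pytest.raises(EncodingError):  # unknown label
            encode_phonology(("q", "E"), INV, SPEC)
        with pytest.raises(EncodingError):  # two vowels
            encode_phonology(("E", "E"), INV, SPEC)
        with pytest.raises(EncodingError):  # onset overflow (4 > 3 slots)
            encode_phonology(("s", "t", "r", "w", "E"), INV, SPEC)

    @given(st.lists(
        st.tuples(st.sampled_from([l for l in INV.labels
                                   if not INV.is_vowel(l)]),
                  st.sampled_from([l for l in INV.labels
                                   if INV.is_vowel(l)])),
        min_size=2, max_size=8, unique=True))
    def test_encoding_injective_over_slot_fillings(self, pairs):
        """Distinct (onset, vowel) fillings give distinct vectors."""
        vecs = [tuple(encode_phonology((c, v), INV, SPEC)) for c, v in pairs]
        assert len(set(vecs)) == len(vecs)


class TestInventory:
    def test_default_inventory_shape(self):
        assert INV.n_features == 25
        assert len(INV.labels) == len(set(INV.labels))
        rows = {tuple(r) for r in INV.features.tolist()}
        assert len(rows) == len(INV.labels)

    def test_inventory_roundtrip(self, tmp_path):
        p = tmp_path / "inv.tsv"
        write_inventory(INV, p)
        back = read_inventory(p)
        assert back.labels == INV.labels
        assert np.array_equal(back.features, INV.features)


class TestGenerator:
    def test_deterministic_for_fixed_seed(self):
        a = generate_lexicon(LexiconParams(n_words=100), seed=1)
        b = generate_lexicon(LexiconParams(n_words=100), seed=1)
        assert len(a) == len(b) == 100
        for x, y in zip(a, b):
            assert x.spelling == y.spelling
            assert x.pronunciation == y.pronunciation
            assert x.frequency == y.frequency
            assert np.array_equal(x.semantic_vector, y.semantic_vector)

    def test_all_consistent_when_no_inconsistency(self):
        lex = generate_lexicon(
            LexiconParams(n_words=60, prop_inconsistent=0.0), seed=2)
        assert all(e.features.rc == 1.0 for e in lex)

    def test_zipf_rank_frequency_slope(self):
        lex = generate_lexicon(
            LexiconParams(n_words=200, zipf_exponent=1.0), seed=3)
        f = np.sort([e.frequency for e in lex])[::-1]
        slope = np.polyfit(np.log(np.arange(1, len(f) + 1)),
                           np.log(f), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_consistent_families_have_higher_rc(self):
        lex = generate_lexicon(LexiconParams(), seed=4)
        cons = [e.features.rc for e in lex if e.tags["consistent"]]
        incons = [e.features.rc for e in lex if not e.tags["consistent"]]
        assert incons, "generator produced no inconsistent families"
        assert np.mean(cons) > np.mean(incons)
        assert all(e.features.rc < 1.0 for e in lex
                   if not e.tags["consistent"])

    def test_homophone_families(self):
        lex = generate_lexicon(LexiconParams(), seed=5)
        fams = {}
        for e in lex:
            if "homophone_family" in e.tags:
                fams.setdefault(e.tags["homophone_family"], []).append(e)
        assert len(fams) == 8
        for members in fams.values():
            assert len(members) == 2
            assert len({m.spelling for m in members}) == 1
            assert len({m.pronunciation for m in members}) == 1
            codes = [m.context_code for m in members]
            assert len(set(codes)) == len(codes)
            assert all(1 <= c <= 4 for c in codes)
            sems = {tuple(m.semantic_indices) for m in members}
            assert len(sems) == len(members)

    def test_factorial_cells_tagged(self):
        lex = generate_lexicon(LexiconParams(), seed=6)
        cells = {e.tags["cell"] for e in lex}
        assert cells == {"high_img|consistent", "low_img|consistent",
                         "high_img|inconsistent", "low_img|inconsistent"}

    def test_every_word_fits_slot_template(self):
        lex = generate_lexicon(LexiconParams(), seed=8)
        for e in lex:
            orthography_slots(e.spelling, lex.spec)
            phonology_slots(e.pronunciation, lex.inventory, lex.spec)

    @pytest.mark.parametrize("kwargs", [
        {"family_size_range": (50, 60)},          # beyond the onset pool
        {"homophone_family_size": 5},             # beyond 4 context units
        {"n_active_range": (200, 300)},           # beyond semantic_dim
        {"n_words": 4},                           # too small for homophones
    ])
    def test_infeasible_parameters_raise(self, kwargs):
        with pytest.raises(GenerationError):
            generate_lexicon(LexiconParams(**kwargs), seed=0)


def _brute_ons(entry, lexicon):
    return sum(1 for o in lexicon
               if o is not entry and len(o.spelling) == len(entry.spelling)
               and sum(a != b for a, b in zip(o.spelling, entry.spelling))
               == 1)


def _brute_rc(entry, lexicon):
    def rime_spell(s):
        i = min((s.index(v) for v in "aeiou" if v in s), default=0)
        return s[i:]

    def rime_phon(p, inv):
        for i, x in enumerate(p):
            if inv.is_vowel(x):
                return p[i:]

    friends = enemies = 0.0
    for o in lexicon:
        if rime_spell(o.spelling) != rime_spell(entry.spelling):
            continue
        same = rime_phon(o.pronunciation, lexicon.inventory) == \
            rime_phon(entry.pronunciation, lexicon.inventory)
        (friends, enemies) = (friends + o.frequency, enemies) if same \
            else (friends, enemies + o.frequency)
    return friends / (friends + enemies)


class TestPredictors:
    def test_ons_against_brute_force(self, small_lexicon):
        for e in small_lexicon:
            assert compute_ons(e, small_lexicon) == \
                _brute_ons(e, small_lexicon)

    def test_rc_against_brute_force(self, small_lexicon):
        for e in small_lexicon:
            assert compute_rime_consistency(e, small_lexicon) == \
                pytest.approx(_brute_rc(e, small_lexicon))

    def test_ons_examples(self):
        lex = _fixture_lexicon(
            [("mint", ("m", "I", "n", "t")), ("hint", ("h", "I", "n", "t")),
             ("tint", ("t", "I", "n", "t")), ("mind", ("m", "aI", "n", "d"))])
        assert compute_ons(lex.by_id("mint"), lex) == 3
        single = _fixture_lexicon([("mint", ("m", "I", "n", "t"))])
        assert compute_ons(single.by_id("mint"), single) == 0
        uneven = _fixture_lexicon(
            [("mint", ("m", "I", "n", "t")), ("to", ("t", "u"))])
        assert compute_ons(uneven.by_id("mint"), uneven) == 0

    def test_rc_token_weighted_ratio(self):
        # friends carry frequency mass 8, the enemy carries 2
        lex = _fixture_lexicon(
            [("mint", ("m", "I", "n", "t"), 3.0),
             ("hint", ("h", "I", "n", "t"), 3.0),
             ("tint", ("t", "I", "n", "t"), 2.0),
             ("pint", ("p", "aI", "n", "t"), 2.0),
             ("dog", ("d", "A", "g"), 1.0)])
        assert compute_rime_consistency(lex.by_id("mint"), lex) == \
            pytest.approx(0.8)
        assert compute_rime_consistency(lex.by_id("dog"), lex) == 1.0
        assert compute_rime_consistency(
            lex.by_id("mint"), lex, weighting="type") == pytest.approx(0.75)

    def test_rc_all_friends(self):
        lex = _fixture_lexicon(
            [("mint", ("m", "I", "n", "t")), ("hint", ("h", "I", "n", "t"))])
        assert compute_rime_consistency(lex.by_id("mint"), lex) == 1.0


def _fixture_lexicon(words, semantic_dim=20):
    entries = []
    for i, item in enumerate(words):
        spelling, pron = item[0], item[1]
        freq = item[2] if len(item) > 2 else 1.0
        vec = np.zeros(semantic_dim, dtype=np.int8)
        vec[i] = 1
        entries.append(WordEntry(word_id=spelling, spelling=spelling,
                                 pronunciation=pron, semantic_vector=vec,
                                 frequency=freq))
    return Lexicon(entries=entries, inventory=INV,
                   spec=EncodingSpec(semantic_dim=semantic_dim))


class TestIO:
    def test_roundtrip_json_and_tsv(self, small_lexicon, tmp_path):
        pj, pt = tmp_path / "lex.json", tmp_path / "lex.tsv"
        write_lexicon(small_lexicon, pj)
        write_lexicon(small_lexicon, pt)
        back_j = read_lexicon(pj)
        back_t = read_lexicon(pt, inventory=back_j.inventory,
                              spec=back_j.spec)
        for orig, a, b in zip(small_lexicon, back_j, back_t):
            for e in (a, b):
                assert e.word_id == orig.word_id
                assert e.spelling == orig.spelling
                assert e.pronunciation == orig.pronunciation
                assert np.array_equal(e.semantic_vector,
                                      orig.semantic_vector)
                assert e.frequency == orig.frequency
                assert e.context_code == orig.context_code
                assert e.features.img == pytest.approx(orig.features.img)

    def test_missing_pronunciation_names_row(self, small_lexicon, tmp_path):
        p = tmp_path / "lex.tsv"
        write_lexicon(small_lexicon, p)
        lines = p.read_text().split("\n")
        f = lines[3].split("\t")
        f[2] = ""
        lines[3] = "\t".join(f)
        p.write_text("\n".join(lines))
        with pytest.raises(LexiconParseError, match="row 4"):
            read_lexicon(p, spec=small_lexicon.spec)

    def test_duplicate_id_and_unknown_phoneme_raise(self, small_lexicon,
                                                    tmp_path):
        p = tmp_path / "lex.tsv"
        write_lexicon(small_lexicon, p)
        lines = p.read_text().rstrip("\n").split("\n")
        p.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(LexiconParseError, match="duplicate"):
            read_lexicon(p, spec=small_lexicon.spec)
        f = lines[2].split("\t")
        f[2] = "qq " + f[2].split(" ", 1)[-1]
        lines[2] = "\t".join(f)
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(LexiconParseError, match="unknown phoneme"):
            read_lexicon(p, spec=small_lexicon.spec)


class TestImageability:
    def test_img_proxy_tracks_semantic_richness(self):
        lex = generate_lexicon(LexiconParams(), seed=9)
        k = np.array([e.semantic_vector.sum() for e in lex])
        img = np.array([e.features.img for e in lex])
        assert np.corrcoef(k, img)[0, 1] > 0.99
        assert img.min() == 0.0 and img.max() == 1.0

    def test_external_norms_hook(self):
        from triread.lexicon import set_imageability
        lex = generate_lexicon(LexiconParams(n_words=30), seed=10)
        norms = {e.word_id: float(i) for i, e in enumerate(lex)}
        set_imageability(lex, norms)
        imgs = [e.features.img for e in lex]
        assert imgs[0] == 0.0 and imgs[-1] == 1.0
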