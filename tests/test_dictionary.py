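"""TF-IDF scoring, percentile selection, Jaccard contextualization."""

import math
from collections import Counter
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import policymap as pm
from policymap.dictionary import CorpusStats
from policymap.preprocess import TokenStream

from conftest import RECOVERY_BUILD


def make_streams(docs: dict[str, str]) -> list[TokenStream]:
    return [TokenStream(doc_id=k, lemmas=v.split(), raw_token_count=len(v.split()))
            for k, v in docs.items()]


@pytest.fixture
def toy_streams():
    # 5-document toy area with known counts
    return make_streams({
        "d1": "insulin glucose receptor pathway insulin",
        "d2": "insulin glucose receptor cell",
        "d3": "insulin glucose receptor",
        "d4": "cell pathway membrane protein",
        "d5": "protein membrane cell signal signal",
    })


@pytest.fixture
def toy_stats(toy_streams):
    return CorpusStats.from_streams(toy_streams)


class TestTermFrequency:
    def test_direct_ratio(self):
        s = make_streams({"d": "a b a c d e f g h i"})[0]
        assert pm.term_frequency("a", s) == pytest.approx(0.2)

    def test_absent_term_is_zero(self, toy_streams):
        assert pm.term_frequency("zebra", toy_streams[0]) == 0.0

    def test_single_lemma_stream(self):
        s = make_streams({"d": "obesity"})[0]
        assert pm.term_frequency("obesity", s) == 1.0

    def test_empty_stream_rejected(self):
        s = TokenStream(doc_id="d", lemmas=[], raw_token_count=0)
        with pytest.raises(ValueError):
            pm.term_frequency("a", s)


class TestIDF:
    def test_log_of_df_ratio(self, toy_stats):
        # insulin occurs in 3 of the 5 toy documents
        assert pm.inverse_document_frequency("insulin", toy_stats) == pytest.approx(
            math.log(5 / 3))

    def test_closed_form_quarter(self):
        stats = CorpusStats(N=4, doc_freq={"t": 1}, doc_sets={"t": frozenset("a")})
        assert pm.inverse_document_frequency("t", stats) == pytest.approx(math.log(4))

    def test_unseen_term_rejected(self, toy_stats):
        with pytest.raises(ValueError):
            pm.inverse_document_frequency("zebra", toy_stats)

    def test_configurable_base(self):
        stats = CorpusStats(N=8, doc_freq={"t": 1}, doc_sets={"t": frozenset("a")})
        assert pm.inverse_document_frequency("t", stats, base=2) == pytest.approx(3.0)


class TestTfidf:
    def test_product_closed_form(self):
        streams = make_streams({
            "d1": "x a b c d e f g h x", "d2": "a a", "d3": "b b", "d4": "c c"})
        stats = CorpusStats.from_streams(streams)
        # x: tf 0.2 in d1, df 1 of 4
        assert pm.tfidf("x", streams[0], stats) == pytest.approx(0.2 * math.log(4))

    def test_ubiquitous_term_scores_zero(self, toy_streams):
        streams = make_streams({"a": "t u", "b": "t v", "c": "t w"})
        stats = CorpusStats.from_streams(streams)
        for s in streams:
            assert pm.tfidf("t", s, stats) == 0.0

    def test_all_pairs_match_brute_force(self, toy_streams, toy_stats):
        """Every (term, doc) score equals an independent raw-count recomputation."""
        N = len(toy_streams)
        for stream in toy_streams:
            counts = Counter(stream.lemmas)
            for term in counts:
                df = sum(1 for s in toy_streams if term in s.lemmas)
                expected = (counts[term] / len(stream.lemmas)) * math.log(N / df)
                assert pm.tfidf(term, stream, toy_stats) == pytest.approx(expected)


class TestRankTerms:
    def test_specific_term_outranks_ubiquitous(self):
        streams = make_streams({"d1": "metabolite filler", "d2": "filler junk"})
        ranked = dict(pm.rank_terms(streams))
        assert ranked["metabolite"] > ranked["filler"]

    def test_tie_broken_alphabetically(self):
        streams = make_streams({"d1": "zeta alpha zeta alpha", "d2": "unique"})
        ranked = pm.rank_terms(streams)
        # zeta and alpha have identical occurrence pattern -> adjacent, a-first
        terms = [t for t, _ in ranked]
        assert terms == ["unique", "alpha", "zeta"]

    def test_single_document_area_scores_zero_alphabetical(self):
        streams = make_streams({"d1": "gamma beta alpha"})
        ranked = pm.rank_terms(streams)
        assert [t for t, _ in ranked] == ["alpha", "beta", "gamma"]
        assert all(s == 0.0 for _, s in ranked)

    def test_short_and_numeric_lemmas_excluded(self):
        streams = make_streams({"d1": "ab 2009 word", "d2": "other text"})
        terms = [t for t, _ in pm.rank_terms(streams)]
        assert "ab" not in terms and "2009" not in terms and "word" in terms

    def test_empty_subcorpus_rejected(self):
        with pytest.raises(ValueError):
            pm.rank_terms([])


class TestSelectDwords:
    @pytest.mark.parametrize("n,fraction,expected", [
        (300, 0.01, 3), (1050, 0.01, 11), (5, 1.0, 5), (100, 0.005, 1)])
    def test_ceil_rule(self, n, fraction, expected):
        ranked = [(f"t{i:04d}", 1.0 - i * 1e-4) for i in range(n)]
        out = pm.select_dwords(ranked, fraction)
        assert len(out) == expected
        assert [d.rank for d in out] == list(range(1, expected + 1))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            pm.select_dwords([("a", 1.0)], 0.0)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(5, 400), st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_size_nondecreasing_in_fraction(self, n, f1, f2):
        lo, hi = sorted((f1, f2))
        ranked = [(f"t{i:04d}", float(n - i)) for i in range(n)]
        assert len(pm.select_dwords(ranked, lo)) <= len(pm.select_dwords(ranked, hi))


class TestJaccard:
    def test_identical_sets_give_one(self, toy_stats):
        assert pm.jaccard_terms("insulin", "glucose", toy_stats) == 1.0

    def test_disjoint_sets_give_zero(self, toy_stats):
        assert pm.jaccard_terms("insulin", "signal", toy_stats) == 0.0

    def test_half_overlap(self):
        streams = make_streams({"1": "a", "2": "a b", "3": "a b", "4": "b"})
        stats = CorpusStats.from_streams(streams)
        assert pm.jaccard_terms("a", "b", stats) == 0.5

    def test_all_pairs_equal_brute_force_sets(self, toy_streams, toy_stats):
        """Symmetry, bounds and set arithmetic on every vocabulary pair."""
        vocab = sorted(toy_stats.doc_sets)
        for a, b in combinations(vocab, 2):
            sa = {s.doc_id for s in toy_streams if a in s.lemmas}
            sb = {s.doc_id for s in toy_streams if b in s.lemmas}
            expected = len(sa & sb) / len(sa | sb)
            got = pm.jaccard_terms(a, b, toy_stats)
            assert got == pytest.approx(expected)
            assert got == pm.jaccard_terms(b, a, toy_stats)
            assert 0.0 <= got <= 1.0


class TestContextTerms:
    def test_constant_companions_win(self, toy_stats):
        ctx = pm.context_terms("insulin", toy_stats, k=2)
        assert [t for t, _ in ctx] == ["glucose", "receptor"]
        assert ctx[0][1] == 1.0

    def test_isolated_term_has_no_context(self):
        streams = make_streams({"d1": "loner", "d2": "a b"})
        stats = CorpusStats.from_streams(streams)
        assert pm.context_terms("loner", stats) == []

    def test_k_larger_than_vocabulary(self, toy_stats):
        ctx = pm.context_terms("signal", toy_stats, k=10)
        assert {t for t, _ in ctx} == {"cell", "membrane", "protein"}


class TestBuildTaxonomy:
    def test_planted_pools_recovered(self, study_config, scientific_sim,
                                     study_taxonomy):
        """>=90% of each area's d-words come from that area's generating pool."""
        _, truth = scientific_sim
        for area, adict in study_taxonomy.dictionaries.items():
            terms = adict.terms()
            assert len(terms) >= 4
            in_pool = sum(t in truth.area_pools[area] for t in terms)
            assert in_pool / len(terms) >= 0.9

    def test_shared_frequent_lemma_carries_context_in_both_areas(self):
        recs = [
            {"doc_id": "h1", "source_kind": "scientific", "area_label": "health",
             "text": "diet clinic patient diet exercise"},
            {"doc_id": "h2", "source_kind": "scientific", "area_label": "health",
             "text": "clinic exercise patient nurse"},
            {"doc_id": "s1", "source_kind": "scientific", "area_label": "social",
             "text": "diet culture survey diet norm"},
            {"doc_id": "s2", "source_kind": "scientific", "area_label": "social",
             "text": "culture survey norm media"},
        ]
        corpus = pm.corpus_from_records(recs)
        tax = pm.build_taxonomy(corpus, fraction=1.0, areas=["health", "social"])
        for area in ("health", "social"):
            (dw,) = [d for d in tax.dictionaries[area].dwords if d.term == "diet"]
            assert dw.ambiguous and 1 <= len(dw.context_terms) <= 2

    def test_fraction_one_keeps_all_candidates(self, toy_policy_records):
        recs = [dict(r, source_kind="scientific", area_label="health")
                for r in toy_policy_records[:2]]
        recs += [dict(toy_policy_records[2], source_kind="scientific",
                      area_label="social")]
        tax = pm.build_taxonomy(pm.corpus_from_records(recs), fraction=1.0,
                                areas=["health", "social"])
        for adict in tax.dictionaries.values():
            assert len(adict.dwords) == adict.candidate_count

    def test_empty_area_rejected_by_name(self, toy_policy_records):
        recs = [dict(r, source_kind="scientific", area_label="health")
                for r in toy_policy_records]
        with pytest.raises(ValueError, match="social"):
            pm.build_taxonomy(pm.corpus_from_records(recs),
                              areas=["health", "social"])

    def test_deterministic_byte_identical_tsv(self, tmp_path, study_config,
                                              scientific_sim):
        corpus, _ = scientific_sim
        paths = []
        for name in ("a.tsv", "b.tsv"):
            tax = pm.build_taxonomy(corpus, areas=study_config.areas,
                                    **RECOVERY_BUILD)
            paths.append(pm.write_dictionary(tax, tmp_path / name))
        assert paths[0].read_bytes() == paths[1].read_bytes()
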