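"""Homologue filtering, deduplication, presence reduction and the
local-alignment identity oracle."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetralink.errors import ValidationError
from tetralink.homology_screen import (
    HomologHit,
    ScreenConfig,
    dedupe_hits,
    filter_hits,
    hit_scaffolds,
    presence_by_unit,
    sw_identity,
)


def make_hit(evalue=1e-40, pident=50.0, family="mss", scaffold="scf1",
             protein=1, bitscore=200.0):
    return HomologHit(
        family=family,
        scaffold_id=scaffold,
        protein_index=protein,
        pident=pident,
        evalue=evalue,
        bitscore=bitscore,
    )


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,pident,kept",
        [
            (1e-31, 35.0, True),
            (1e-30, 35.0, False),   # e-value threshold is strictly "<"
            (1e-31, 30.0, True),    # identity threshold is inclusive ">="
            (1e-31, 29.99, False),
        ],
    )
    def test_threshold_operators(self, evalue, pident, kept):
        hits = filter_hits([make_hit(evalue=evalue, pident=pident)])
        assert (len(hits) == 1) == kept

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_order_preserved(self):
        hits = [make_hit(scaffold=f"s{i}") for i in range(5)]
        assert filter_hits(hits) == hits

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1e-60, max_value=1e-10),
                st.floats(min_value=0, max_value=100),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_monotone(self, params):
        hits = [make_hit(evalue=e, pident=p) for e, p in params]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        tighter = ScreenConfig(evalue_max=1e-35, pident_min=50.0)
        assert set(map(id, filter_hits(hits, tighter))) <= set(map(id, once))


class TestDedupeHits:
    def test_keeps_lowest_evalue(self):
        a = make_hit(evalue=1e-40)
        b = make_hit(evalue=1e-35)
        assert dedupe_hits([b, a]) == [a]

    def test_distinct_proteins_both_kept(self):
        a = make_hit(protein=1)
        b = make_hit(protein=2)
        assert dedupe_hits([a, b]) == [a, b]

    def test_evalue_tie_broken_by_bitscore_then_first(self):
        a = make_hit(bitscore=180.0)
        b = make_hit(bitscore=200.0)
        assert dedupe_hits([a, b]) == [b]
        c = make_hit(bitscore=200.0)
        assert dedupe_hits([b, c]) == [b]


class TestPresenceByUnit:
    def test_bin_presence_collapses_scaffolds(self):
        hits = [
            make_hit(scaffold="scf1", protein=1),
            make_hit(scaffold="scf1", protein=2),
            make_hit(scaffold="scf2", protein=1),
        ]
        presence = presence_by_unit(hits, {"scf1": "bin1", "scf2": "bin1"})
        assert presence == {("mss", "bin1"): ["scf1", "scf2"]}

    def test_unbinned_scaffold_is_its_own_unit(self):
        presence = presence_by_unit([make_hit(scaffold="scf7")], {})
        assert presence == {("mss", "unbinned:scf7"): ["scf7"]}

    def test_no_hits(self):
        assert presence_by_unit([], {"scf1": "bin1"}) == {}

    def test_hit_scaffolds_grouping(self):
        hits = [make_hit(scaffold="b"), make_hit(scaffold="a"),
                make_hit(family="ger", scaffold="c")]
        assert hit_scaffolds(hits) == {"mss": ["a", "b"], "ger": ["c"]}


# ---------------------------------------------------------------------------
# Smith-Waterman identity oracle, checked against exhaustive enumeration.


def _all_alignments(sa, sb, match, mismatch, gap, _cache=None):
    """All (score, matches, columns) of global alignments of sa vs sb."""
    if _cache is None:
        _cache = {}
    key = (sa, sb)
    if key in _cache:
        return _cache[key]
    if not sa and not sb:
        return {(0.0, 0, 0)}
    out = set()
    if sa and sb:
        eq = sa[0] == sb[0]
        step = match if eq else mismatch
        for s, m, c in _all_alignments(sa[1:], sb[1:], match, mismatch, gap, _cache):
            out.add((s + step, m + eq, c + 1))
    if sa:
        for s, m, c in _all_alignments(sa[1:], sb, match, mismatch, gap, _cache):
            out.add((s + gap, m, c + 1))
    if sb:
        for s, m, c in _all_alignments(sa, sb[1:], match, mismatch, gap, _cache):
            out.add((s + gap, m, c + 1))
    _cache[key] = out
    return out


def brute_force_local(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Best local-alignment score and the identities of all optimal
    alignments, by enumerating every substring pair and every alignment."""
    best_score = 0.0
    identities = set()
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            for s, m, c in _all_alignments(a[i1:i2], b[j1:j2], match, mismatch, gap):
                if s > best_score:
                    best_score = s
                    identities = set()
                if s == best_score and c > 0 and s > 0:
                    identities.add(100.0 * m / c)
    return best_score, identities


class TestSwIdentity:
    def test_identical_sequences(self):
        assert sw_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0

    def test_disjoint_alphabets_convention(self):
        # no positive-scoring local alignment exists: identity 0 by convention
        assert sw_identity("AAAA", "CCCC") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            sw_identity("", "ACD")

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACDEFG", "ACXEFG"),
            ("ACDEF", "CDE"),
            ("AAC", "ACA"),
            ("GATTA", "GCATG"),
            ("WYWYW", "YWYWY"),
        ],
    )
    def test_against_exhaustive_enumeration(self, a, b):
        best_score, identities = brute_force_local(a, b)
        got = sw_identity(a, b)
        if best_score == 0:
            assert got == 0.0
        else:
            assert any(abs(got - ident) < 1e-9 for ident in identities), (
                got,
                identities,
            )

    def test_local_alignment_ignores_flanks(self):
        # the common core aligns perfectly regardless of unrelated flanks
        assert sw_identity("WWWACDEFGWWW", "YYYACDEFGYYY") == 100.0
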