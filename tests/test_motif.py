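"""Motif scanning, global alignment, consensus building, family calls."""

import math
import re

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from sepiapep.motif import (
    AlignmentResult,
    FamilyCall,
    MotifPattern,
    build_consensus,
    classify_family,
    global_align,
    load_patterns,
    parse_pattern,
    progressive_align,
    scan_motif,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# scan_motif vs a regular-expression oracle


def _regex_oracle(sequence, pattern):
    """Overlap-aware scan via lookahead regex — independent of scan_motif."""
    parts = []
    for el in pattern.elements:
        if len(el) == 1:
            parts.append(re.escape(next(iter(el))))
        else:
            parts.append("[" + "".join(sorted(el)) + "]")
    rx = re.compile("(?=" + "".join(parts) + ")")
    return [m.start() + 1 for m in rx.finditer(sequence)]


class TestScanMotif:
    def test_hexapeptide_on_flga1(self, patterns):
        hits = scan_motif("GAESGEAHVFDSLGGGHVPYY", patterns["flgamide_hexapeptide"])
        assert hits == [11]

    def test_hexapeptide_rejects_thr_variant(self, patterns):
        # the Thr-containing homolog core is NOT a strict hexapeptide match
        assert scan_motif("VFDTLGGGHVPYY", patterns["flgamide_hexapeptide"]) == []

    def test_overlapping_matches_reported(self):
        ggg = parse_pattern("ggg", ["G", "G", "G"])
        assert scan_motif("GGGG", ggg) == [1, 2]

    @given(
        st.text(alphabet=AA, min_size=0, max_size=60),
        st.lists(
            st.one_of(
                st.sampled_from(list(AA)),
                st.sets(st.sampled_from(list(AA)), min_size=2, max_size=3),
            ),
            min_size=1,
            max_size=5,
        ),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_regex_oracle(self, sequence, elements):
        tokens = [
            el if isinstance(el, str) else "(" + "/".join(sorted(el)) + ")"
            for el in elements
        ]
        pattern = parse_pattern("fuzz", tokens)
        assert scan_motif(sequence, pattern) == _regex_oracle(sequence, pattern)


# ---------------------------------------------------------------------------
# global_align vs exhaustive enumeration


def _brute_force_score(a, b, gap_open=-10.0, gap_extend=-1.0):
    """Enumerate every global alignment path; affine gap costs: a gap of
    length L costs open + (L-1)*extend, gap-type switches re-open."""
    best = -math.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + BLOSUM62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "D", score + (gap_extend if prev == "D" else gap_open))
        if j < len(b):
            rec(i, j + 1, "I", score + (gap_extend if prev == "I" else gap_open))

    rec(0, 0, "", 0.0)
    return best


class TestGlobalAlign:
    def test_identical_sequences(self):
        res = global_align("GAESGE", "GAESGE")
        assert "-" not in res.aligned_a and res.identity_fraction == 1.0
        assert res.score == sum(BLOSUM62[c, c] for c in "GAESGE")

    def test_single_substitution(self):
        res = global_align("A", "G")
        assert res.score == BLOSUM62["A", "G"]
        assert res.identity_fraction == 0.0

    def test_degapped_equals_inputs(self):
        res = global_align("GAESGEAHV", "GESGEV")
        assert res.aligned_a.replace("-", "") == "GAESGEAHV"
        assert res.aligned_b.replace("-", "") == "GESGEV"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "A")

    @pytest.mark.parametrize("seed", range(6))
    def test_score_equals_enumeration_oracle(self, seed):
        import random

        rng = random.Random(seed)
        la, lb = rng.randint(1, 6), rng.randint(1, 6)
        a = "".join(rng.choice(AA) for _ in range(la))
        b = "".join(rng.choice(AA) for _ in range(lb))
        assert global_align(a, b).score == pytest.approx(_brute_force_score(a, b))

    def test_oracle_agreement_at_length_eight(self):
        a, b = "GAESGEAH", "GTESGDAH"
        assert global_align(a, b).score == pytest.approx(_brute_force_score(a, b))


# ---------------------------------------------------------------------------
# consensus


class TestConsensus:
    def test_hexapeptide_from_its_two_realizations(self):
        pattern = build_consensus(["DSLGGG", "DSIGGG"])
        assert pattern.to_tokens() == "D S (I/L) G G G"

    def test_single_repeated_sequence_is_itself(self):
        pattern = build_consensus(["DSLGGG", "DSLGGG"])
        assert pattern.to_tokens() == "D S L G G G"

    def test_nonconservative_split_gives_wildcard(self):
        pattern = build_consensus(["AAAA", "CCCC"], majority=0.8)
        assert pattern.to_tokens() == ". . . ."

    def test_all_gap_columns_dropped(self):
        pattern = build_consensus(["DS-G", "DS-G"])
        assert pattern.to_tokens() == "D S G"

    def test_permutation_invariance(self):
        seqs = ["DSLGGG", "DSIGGG", "DTLGGG", "DSLGGG"]
        base = build_consensus(seqs).to_tokens()
        assert build_consensus(seqs[::-1]).to_tokens() == base
        assert build_consensus(seqs[1:] + seqs[:1]).to_tokens() == base

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(["DSL", "DSLG"])


def test_progressive_align_propagates_anchor_gaps():
    rows = progressive_align(["GAESGEAHV", "GAESGEAHV", "GAEGEAHV"])
    assert len(rows) == 3
    assert all(len(r) == len(rows[0]) for r in rows)
    assert rows[2].replace("-", "") == "GAEGEAHV"


# ---------------------------------------------------------------------------
# family classification


class TestClassifyFamily:
    def test_flga1_is_orcokinin_b(self, patterns):
        call = classify_family("GAESGEAHVFDSLGGGHVPYY", patterns)
        assert call.family == "orcokinin_B"
        assert any("@11" in e for e in call.evidence)

    def test_ggg_alone_is_not_orcokinin_b(self, patterns):
        call = classify_family("AAAGGGAAA", patterns)
        assert call.family != "orcokinin_B"

    def test_no_hits_unclassified(self, patterns):
        assert classify_family("PWPWPWPW", patterns).family == "unclassified"

    def test_fcan_requires_consensus_identity_and_no_orcokinin_motif(self, patterns):
        fcan = "SGQWQRNPNAFRM"
        assert classify_family(fcan, patterns).family == "FCAN"
        # same flanks but carrying the orcokinin-B core: cascade prefers B
        assert classify_family("DSLGGG" + fcan, patterns).family == "orcokinin_B"

    def test_orcokinin_c_flanks_without_dsl(self, patterns):
        # satisfies the C-core class pattern but not the B hexapeptide
        seq = "AANFDEIDRSGGGAA"
        call = classify_family(seq, patterns)
        assert call.family == "orcokinin_C"

    def test_all_fixture_peptides_are_orcokinin_b(self, flga_peptides, patterns):
        for pep in flga_peptides:
            assert classify_family(pep.sequence, patterns).family == "orcokinin_B"
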