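"""Disorder/domain context, free-end-gap alignment, conservation, net charge."""

import functools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ptmforge.context import (
    SET2_NTERM15,
    SET2_PHOSPHOSITES,
    AlphabetError,
    DisorderTrack,
    DomainInterval,
    InvalidMutationError,
    align_free_end_gaps,
    conserved_phosphosites,
    disorder_context,
    domain_context,
    net_charge,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Independent alignment oracle: top-down recursion over suffixes with the
# same scoring contract (terminal gap runs free, affine internal gaps).


def oracle_score(a, b, matrix=BLOSUM62, open_=12.0, ext=3.0, memo=True):
    m, n = len(a), len(b)

    def rec(i, j, state):
        if i == m and j == n:
            return 0.0
        best = float("-inf")
        if i < m and j < n:
            best = matrix[a[i], b[j]] + rec(i + 1, j + 1, 0)
        if i < m:  # consume a[i] against a gap in b; run sits at B-offset j
            cost = 0.0 if (j == 0 or j == n) else (ext if state == 1 else open_)
            best = max(best, rec(i + 1, j, 1) - cost)
        if j < n:
            cost = 0.0 if (i == 0 or i == m) else (ext if state == 2 else open_)
            best = max(best, rec(i, j + 1, 2) - cost)
        return best

    if memo:
        rec = functools.cache(rec)
    return rec(0, 0, 0)


class TestAlignment:
    def test_identical_sequences_identity_alignment(self):
        res = align_free_end_gaps("MKTAYIAK", "MKTAYIAK")
        assert res.aligned_a == res.aligned_b == "MKTAYIAK"
        assert res.a_to_b == {i: i for i in range(1, 9)}

    def test_short_query_floats_free_inside_subject(self):
        res = align_free_end_gaps("KSA", "AAKSAA")
        expected = BLOSUM62["K", "K"] + BLOSUM62["S", "S"] + BLOSUM62["A", "A"]
        assert res.score == expected
        assert res.a_to_b == {1: 3, 2: 4, 3: 5}

    def test_degapped_rows_reproduce_inputs(self):
        res = align_free_end_gaps("MKWY", "MAAKWAY")
        assert res.aligned_a.replace("-", "") == "MKWY"
        assert res.aligned_b.replace("-", "") == "MAAKWAY"

    def test_symbol_outside_alphabet(self):
        with pytest.raises(AlphabetError):
            align_free_end_gaps("MK1", "MK")

    def test_matches_enumeration_oracle_small(self):
        """Pure (unmemoized) path enumeration on every random pair <= 5."""
        rng = np.random.default_rng(99)
        aas = np.array(list("ARNDKS"))
        for _ in range(40):
            a = "".join(rng.choice(aas, rng.integers(1, 6)))
            b = "".join(rng.choice(aas, rng.integers(1, 6)))
            assert align_free_end_gaps(a, b).score == oracle_score(a, b, memo=False), (a, b)

    def test_matches_recursive_oracle_length8(self):
        """Optimal score equals the suffix-recursion oracle for pairs <= 8."""
        rng = np.random.default_rng(1234)
        aas = np.array(list("ARNDCQEGHILKMFPSTWYV"))
        for _ in range(150):
            a = "".join(rng.choice(aas, rng.integers(1, 9)))
            b = "".join(rng.choice(aas, rng.integers(1, 9)))
            assert align_free_end_gaps(a, b).score == oracle_score(a, b), (a, b)


class TestConservation:
    def test_self_alignment_all_conserved(self):
        seq = "MKSATYSR"
        res = align_free_end_gaps(seq, seq)
        sites = [3, 5, 7]
        calls = conserved_phosphosites(sites, res, seq, partner_phospho=sites)
        assert set(calls.values()) == {"phosphosite_conserved"}

    def test_site_aligned_to_gap(self):
        res = align_free_end_gaps("KWYS", "KWY")
        calls = conserved_phosphosites([4], res, "KWY")
        assert calls[4] == "not_aligned"

    def test_planted_partner_phosphosites_counted(self):
        """6 of 19 aligned phosphoacceptors planted as partner phosphosites."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), 100))
        positions = sorted(rng.choice(100, 19, replace=False) + 1)
        seq = list(seq)
        for p in positions:
            seq[p - 1] = "S"
        seq = "".join(seq)
        res = align_free_end_gaps(seq, seq)
        planted = positions[:6]
        calls = conserved_phosphosites(positions, res, seq, partner_phospho=planted)
        assert sum(c == "phosphosite_conserved" for c in calls.values()) == 6
        assert sum(c == "residue_conserved" for c in calls.values()) == 13


class TestDisorderDomains:
    def test_fully_disordered(self):
        track = DisorderTrack("P1", np.full(40, 0.9))
        out = disorder_context([3, 10, 20, 35], track)
        assert out["percent_disordered"] == 100.0
        assert out["n_sites_disordered"] == 4

    def test_half_disordered(self):
        track = DisorderTrack("P1", np.r_[np.ones(20), np.zeros(20)])
        out = disorder_context([], track)
        assert out["percent_disordered"] == 50.0

    def test_threshold_inclusive(self):
        track = DisorderTrack("P1", np.array([0.5, 0.49]))
        assert track.is_disordered(1) and not track.is_disordered(2)

    def test_random_tallies_match_bruteforce(self):
        rng = np.random.default_rng(17)
        scores = rng.uniform(0, 1, 300)
        track = DisorderTrack("P1", scores)
        sites = sorted(rng.choice(300, 30, replace=False) + 1)
        out = disorder_context(sites, track)
        assert out["n_sites_disordered"] == sum(scores[p - 1] >= 0.5 for p in sites)
        assert out["percent_disordered"] == pytest.approx(
            100.0 * np.mean(scores >= 0.5)
        )

    def test_site_beyond_track_raises(self):
        with pytest.raises(IndexError):
            disorder_context([5], DisorderTrack("P1", np.zeros(3)))

    def test_domain_boundaries_inclusive(self):
        doms = [DomainInterval("P1", "SET", 10, 20)]
        out = domain_context([10, 20, 9, 21], doms)
        assert out["site_in_domain"] == {10: True, 20: True, 9: False, 21: False}

    def test_planted_fraction_matches_tally(self):
        doms = [DomainInterval("P1", "SET", 1, 15)]
        sites = list(range(1, 16)) + list(range(100, 228))  # 15 in-domain of 143
        out = domain_context(sites, doms)
        assert round(100 * out["fraction_in_domain"], 1) == 10.5

    def test_no_domains_zero_fraction(self):
        assert domain_context([1, 2], [])["fraction_in_domain"] == 0.0


class TestNetCharge:
    WT = SET2_NTERM15
    PH = SET2_PHOSPHOSITES

    @pytest.mark.parametrize(
        "mutations,expected",
        [
            ({}, -7),  # wild type, all three serines phosphorylated
            ({8: "A"}, -5),  # single phosphonull
            ({6: "A", 8: "A", 10: "A"}, -1),  # triple phosphonull
            ({8: "D"}, -6),  # single phosphomimetic
            ({6: "D", 8: "D", 10: "D"}, -4),  # triple phosphomimetic
        ],
    )
    def test_set2_window_charges(self, mutations, expected):
        assert net_charge(self.WT, self.PH, mutations) == expected

    def test_single_mutation_increments(self):
        """Each S->A adds +2 and each S->D adds +1 relative to wild type."""
        wt = net_charge(self.WT, self.PH)
        for pos in self.PH:
            assert net_charge(self.WT, self.PH, {pos: "A"}) == wt + 2
            assert net_charge(self.WT, self.PH, {pos: "D"}) == wt + 1

    def test_mutation_at_non_serine_rejected(self):
        with pytest.raises(InvalidMutationError):
            net_charge(self.WT, self.PH, {3: "A"})

    def test_unphosphorylated_serines_neutral(self):
        assert net_charge(self.WT, ()) == -1  # +1 Nterm +1 K3 +1 K14 -4 acidic
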