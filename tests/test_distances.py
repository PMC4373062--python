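"""Alignment and divergence estimators: brute-force alignment oracle,
closed-form distance checks, and estimator properties."""

from __future__ import annotations

import functools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ervkit import (
    DistanceMatrix,
    PairwiseAlignment,
    SaturationError,
    ScoringScheme,
    SiteCounts,
    count_site_patterns,
    distance_matrix,
    global_align,
    k2p_distance,
    p_distance,
)

SCHEME = ScoringScheme(match=1, mismatch=-1, gap_open=-5, gap_extend=-1)


def brute_force_score(a: str, b: str, s: ScoringScheme = SCHEME) -> float:
    """Exhaustive optimal global alignment score under affine gaps.

    Independent of the production path: plain recursion over
    (i, j, gap-state) where opening a gap costs open+extend and extending
    costs extend.
    """

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:  # state: 0 none, 1 gap-in-b, 2 gap-in-a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(
                (s.match if a[i] == b[j] else s.mismatch) + rec(i + 1, j + 1, 0)
            )
        if i < len(a):  # a[i] against a gap in b
            cost = s.gap_extend if state == 1 else s.gap_open + s.gap_extend
            options.append(cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = s.gap_extend if state == 2 else s.gap_open + s.gap_extend
            options.append(cost + rec(i, j + 1, 2))
        return max(options)

    return rec(0, 0, 0)


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACGT", "ACGT", SCHEME)
        assert aln.score == 4 and "-" not in aln.gapped_a + aln.gapped_b

    def test_length_difference_forces_one_gap(self):
        aln = global_align("AAAA", "AAA", SCHEME)
        assert aln.gapped_b.count("-") == 1 and aln.gapped_a.count("-") == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_gap_removal_recovers_inputs(self):
        aln = global_align("ACGTTACG", "ACGACG", SCHEME)
        assert aln.gapped_a.replace("-", "") == "ACGTTACG"
        assert aln.gapped_b.replace("-", "") == "ACGACG"

    @pytest.mark.parametrize("la", [1, 2, 3, 4])
    @pytest.mark.parametrize("lb", [1, 2, 3, 4])
    def test_exhaustive_score_oracle_small(self, la, lb):
        """Optimal score equals exhaustive enumeration for all {A,C} strings
        of lengths up to 4."""
        from itertools import product

        for a_t in product("AC", repeat=la):
            for b_t in product("AC", repeat=lb):
                a, b = "".join(a_t), "".join(b_t)
                assert global_align(a, b, SCHEME).score == brute_force_score(a, b)

    @given(
        st.text(alphabet="AC", min_size=1, max_size=6),
        st.text(alphabet="AC", min_size=1, max_size=6),
    )
    def test_score_oracle_random(self, a, b):
        assert global_align(a, b, SCHEME).score == brute_force_score(a, b)

    def test_no_gap_gap_column_invariant(self):
        aln = global_align("ACGTACGTA", "TTACGTT", SCHEME)
        assert all(not (x == "-" and y == "-") for x, y in zip(aln.gapped_a, aln.gapped_b))


class TestSiteCounts:
    def test_identical_sequences(self):
        c = count_site_patterns(global_align("A" * 50 + "C" * 50, "A" * 50 + "C" * 50))
        assert (c.n, c.ts, c.tv) == (100, 0, 0)

    def test_hand_tally_with_exclusions(self):
        aln = PairwiseAlignment(
            gapped_a="ACAA", gapped_b="GTC-", score=0.0, scoring_scheme=SCHEME
        )
        c = count_site_patterns(aln)
        assert (c.n, c.ts, c.tv) == (3, 2, 1)

    def test_all_n_yields_zero_sites(self):
        aln = PairwiseAlignment(
            gapped_a="NNNN", gapped_b="ACGT", score=0.0, scoring_scheme=SCHEME
        )
        assert count_site_patterns(aln).n == 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SiteCounts(n=5, ts=4, tv=2)


class TestPDistance:
    def test_zero_differences(self):
        est = p_distance(SiteCounts(n=100, ts=0, tv=0))
        assert est.value == 0.0 and est.se == 0.0

    def test_closed_form_se(self):
        est = p_distance(SiteCounts(n=100, ts=6, tv=4))
        assert est.value == pytest.approx(0.10)
        assert est.se == pytest.approx(math.sqrt(0.1 * 0.9 / 100))

    def test_bootstrap_se_matches_analytic(self):
        est = p_distance(
            SiteCounts(n=100, ts=6, tv=4), se_method="bootstrap", n_bootstrap=10_000, seed=1
        )
        assert est.se == pytest.approx(0.03, rel=0.10)

    def test_no_sites_error(self):
        with pytest.raises(ValueError):
            p_distance(SiteCounts(n=0, ts=0, tv=0))


class TestK2P:
    def test_zero(self):
        assert k2p_distance(SiteCounts(n=100, ts=0, tv=0)).value == 0.0

    def test_closed_form_value(self):
        # D = -0.5 ln(0.75) - 0.25 ln(0.90) at P=0.1, Q=0.05
        est = k2p_distance(SiteCounts(n=1000, ts=100, tv=50))
        assert est.value == pytest.approx(0.17018, abs=1e-5)

    @pytest.mark.parametrize("p", [0.03, 0.12, 0.30, 0.45, 0.60, 0.72])
    def test_reduces_to_jukes_cantor(self, p):
        """With transitions/transversions in the 1:2 ratio the K2P distance
        collapses to the Jukes-Cantor formula."""
        n = 1000
        ts = round(n * p / 3)
        tv = round(n * 2 * p / 3)
        est = k2p_distance(SiteCounts(n=n, ts=ts, tv=tv))
        p_exact = (ts + tv) / n
        jc = -0.75 * math.log(1 - 4 * p_exact / 3)
        assert est.value == pytest.approx(jc, rel=1e-9)

    def test_saturation_is_explicit_error(self):
        with pytest.raises(SaturationError):
            k2p_distance(SiteCounts(n=100, ts=50, tv=10))
        with pytest.raises(SaturationError):
            k2p_distance(SiteCounts(n=100, ts=10, tv=50))

    @given(
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
    )
    def test_exceeds_p_distance_and_monotone(self, ts, tv):
        n = 200
        if 1 - 2 * ts / n - tv / n <= 0 or 1 - 2 * tv / n <= 0:
            return
        k = k2p_distance(SiteCounts(n=n, ts=ts, tv=tv)).value
        p = p_distance(SiteCounts(n=n, ts=ts, tv=tv)).value
        assert k >= p
        if ts + tv == 0:
            assert k == 0.0
        else:
            assert k > p or p == 0.0
        # strictly increasing in each argument on the domain
        if 1 - 2 * (ts + 1) / n - tv / n > 0:
            assert k2p_distance(SiteCounts(n=n, ts=ts + 1, tv=tv)).value > k
        if 1 - 2 * ts / n - (tv + 1) / n > 0 and 1 - 2 * (tv + 1) / n > 0:
            assert k2p_distance(SiteCounts(n=n, ts=ts, tv=tv + 1)).value > k


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = distance_matrix([("a", "ACGT" * 20), ("b", "ACGT" * 20), ("c", "ACGT" * 20)])
        assert np.all(dm.values == 0)

    def test_matches_pairwise_estimate(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACGAACGTACGT"  # one transversion T->A
        dm = distance_matrix([("a", a), ("b", b)], model="p")
        assert dm[("a", "b")] == pytest.approx(1 / 20)

    def test_label_permutation_invariance(self):
        seqs = [("a", "ACGTACGT" * 5), ("b", "ACGAACGT" * 5), ("c", "TCGTACCT" * 5)]
        d1 = distance_matrix(seqs, model="p")
        d2 = distance_matrix(seqs[::-1], model="p")
        for x in "abc":
            for y in "abc":
                if x != y:
                    assert d1[(x, y)] == pytest.approx(d2[(x, y)])

    def test_undefined_pair_reports_ids(self):
        # saturated pair: every site a transversion
        with pytest.raises(SaturationError, match="'x1'.*'x2'"):
            distance_matrix([("x1", "A" * 120), ("x2", "C" * 120)], model="K2P")

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestPDistanceUnbiased:
    def test_mean_over_replicates_near_truth(self):
        """The p-distance estimator is unbiased: the mean over 1000 seeded
        K2P-simulated replicates lands within 3 SE of the expected
        proportion of differing sites."""
        from ervkit import NucSequence, make_ancestral_ltr, mutate_k2p

        d, kappa = 0.1, 2.0
        beta_t = d / (kappa + 2.0)
        e1 = math.exp(-4 * beta_t)
        e2 = math.exp(-2 * d * (kappa + 1) / (kappa + 2))
        expected_p = (0.25 + 0.25 * e1 - 0.5 * e2) + 2 * (0.25 - 0.25 * e1)
        base = make_ancestral_ltr(500, 0.42, seed=8).residues
        vals = []
        for rep in range(1000):
            out = mutate_k2p(NucSequence("x", base), d, kappa, seed=rep).residues
            diff = sum(a != b for a, b in zip(base, out))
            vals.append(diff / len(base))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - expected_p) <= 3 * se
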