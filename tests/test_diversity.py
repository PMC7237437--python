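import itertools

import numpy as np
import pytest
from scipy import stats as sps

from smithrna.diversity import (
    DiversityWindow,
    SequenceAlignment,
    assign_regions,
    dunn_test,
    kruskal_wallis,
    mann_whitney,
    nucleotide_diversity,
    pairwise_p_distance,
    sliding_window_diversity,
)


def brute_force_pi(rows):
    """Independent oracle: mean pairwise p-distance over all row pairs with
    the N/(N-1) correction (sum over unordered pairs / N^2, times N/(N-1))."""
    n = len(rows)
    total = sum(
        pairwise_p_distance(a, b) for a, b in itertools.combinations(rows, 2)
    )
    return total / (n * (n - 1))


class TestPDistance:
    def test_identical(self):
        assert pairwise_p_distance("ACGTACGTAC", "ACGTACGTAC") == 0.0

    def test_one_in_ten(self):
        assert pairwise_p_distance("ACGTACGTAC", "ACGTACGTAT") == pytest.approx(0.1)

    def test_gap_excluded_from_both_sides(self):
        assert pairwise_p_distance("AC-T", "ACGT") == 0.0  # 0 diffs / 3 sites

    def test_ambiguity_excluded(self):
        assert pairwise_p_distance("ACNT", "ACGA") == pytest.approx(1 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_p_distance("ACG", "ACGT")


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self):
        assert nucleotide_diversity(["ACGT"] * 5) == 0.0

    def test_two_distinct_rows(self):
        # pi_12 = 0.1; as-printed estimator: (2/1) * 0.5*0.5*0.1 = 0.05
        assert nucleotide_diversity(["ACGTACGTAC", "ACGTACGTAT"]) == pytest.approx(0.05)

    def test_three_to_one_haplotypes(self):
        # pi_AB = 0.2 on 10 sites; (4/3) * (0.75*0.25*0.2) = 0.05
        rows = ["ACGTACGTAC"] * 3 + ["ACGTACGTGT"]
        assert nucleotide_diversity(rows) == pytest.approx(0.05)
        assert brute_force_pi(rows) == pytest.approx(0.05)

    def test_ordered_pair_convention_doubles(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rows = ["".join(rng.choice(list("ACGT"), size=12))
                    for _ in range(int(rng.integers(2, 8)))]
            assert nucleotide_diversity(rows, ordered_pairs=True) == pytest.approx(
                2 * nucleotide_diversity(rows))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 10))
            L = int(rng.integers(5, 25))
            base = rng.choice(list("ACGT"), size=L)
            rows = []
            for _ in range(n):
                row = base.copy()
                k = rng.random(L) < 0.2
                row[k] = rng.choice(list("ACGT"), size=int(k.sum()))
                rows.append("".join(row))
            assert nucleotide_diversity(rows) == pytest.approx(
                brute_force_pi(rows), abs=1e-12)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACGT"])

    def test_invariant_under_row_permutation(self):
        rows = ["ACGTACGTAC", "ACGTACGTAT", "ACCTACGTAT", "ACGTACGTAC"]
        ref = nucleotide_diversity(rows)
        for p in itertools.permutations(rows):
            assert nucleotide_diversity(list(p)) == pytest.approx(ref, abs=1e-14)


class TestSlidingWindows:
    def test_window_starts(self):
        aln = SequenceAlignment(["a", "b"], ["ACGTACGTACGTACGTACGT"] * 2)
        ws = sliding_window_diversity(aln, 10, 5)
        assert [(w.start, w.end) for w in ws] == [(1, 10), (6, 15), (11, 20)]

    def test_monomorphic_windows_are_zero_and_included(self):
        aln = SequenceAlignment(["a", "b", "c"], ["ACGT" * 10] * 3)
        ws = sliding_window_diversity(aln, 10, 5)
        assert ws and all(w.pi_hat == 0.0 for w in ws)

    def test_doubling_step_halves_window_count(self):
        aln = SequenceAlignment(["a", "b"], ["ACGT" * 25] * 2)
        n1 = len(sliding_window_diversity(aln, 10, 5))
        n2 = len(sliding_window_diversity(aln, 10, 10))
        assert abs(n1 - 2 * n2) <= 1

    def test_short_alignment_yields_nothing(self):
        aln = SequenceAlignment(["a", "b"], ["ACGT", "ACGA"])
        assert sliding_window_diversity(aln, 10, 5) == []

    def test_windows_match_direct_computation_with_gaps(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(6):
            row = rng.choice(list("ACGT-"), size=40, p=[0.23, 0.23, 0.23, 0.23, 0.08])
            rows.append("".join(row))
        aln = SequenceAlignment([f"s{i}" for i in range(6)], rows)
        for w in sliding_window_diversity(aln, 10, 5):
            sub = [r[w.start - 1 : w.end] for r in rows]
            assert w.pi_hat == pytest.approx(nucleotide_diversity(sub), abs=1e-12)


class TestAssignRegions:
    REGIONS = [(1, 50, "PCG"), (51, 70, "tRNA"), (71, 100, "UR"),
               (60, 80, "smithRNA")]

    def test_midpoint_labels(self):
        ws = [DiversityWindow(1, 10, 0.0), DiversityWindow(91, 100, 0.0)]
        assign_regions(ws, self.REGIONS)
        assert [w.region for w in ws] == ["PCG", "UR"]

    def test_overlay_precedence(self):
        w = DiversityWindow(61, 70, 0.0)  # midpoint 65: tRNA and smithRNA
        assign_regions([w], self.REGIONS)
        assert w.region == "smithRNA"

    def test_boundary_straddling_window_uses_midpoint(self):
        w = DiversityWindow(46, 55, 0.0)  # midpoint 50 -> PCG
        assign_regions([w], self.REGIONS)
        assert w.region == "PCG"

    def test_uncovered_midpoint_raises(self):
        with pytest.raises(ValueError):
            assign_regions([DiversityWindow(101, 110, 0.0)], self.REGIONS)


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_degenerate_all_equal(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5], [5]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            groups = [rng.integers(0, 15, size=rng.integers(3, 20)).astype(float)
                      for _ in range(k)]
            mine = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=8) for _ in range(4)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = dunn_test([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res.z.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_adjusted.iloc[0] == 1.0

    def test_hand_computed_no_ties(self):
        # 3 groups of 5, values 1..15, no ties: mean ranks 3, 8, 13;
        # sigma^2 = N(N+1)/12 = 20; se = sqrt(20 * 2/5) = sqrt(8)
        groups = [[1, 2, 3, 4, 5], [6, 7, 8, 9, 10], [11, 12, 13, 14, 15]]
        res = dunn_test(groups, ["a", "b", "c"])
        z_ab = res.loc[(res.group_i == "a") & (res.group_j == "b"), "z"].iloc[0]
        assert z_ab == pytest.approx((3 - 8) / np.sqrt(8))
        z_ac = res.loc[(res.group_i == "a") & (res.group_j == "c"), "z"].iloc[0]
        assert z_ac == pytest.approx((3 - 13) / np.sqrt(8))

    def test_bonferroni_multiplier_for_six_groups(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=10) for _ in range(6)]
        res = dunn_test(groups)
        assert len(res) == 15  # k(k-1)/2
        raw_capped = np.minimum(1.0, 15 * res.p)
        assert np.allclose(res.p_adjusted, raw_capped)

    def test_matches_independent_recomputation(self):
        # independent oracle: recompute z from first principles with pandas
        import pandas as pd

        rng = np.random.default_rng(7)
        for _ in range(30):
            k = int(rng.integers(2, 6))
            groups = [rng.integers(0, 8, size=rng.integers(4, 12)).astype(float)
                      for _ in range(k)]
            res = dunn_test(groups)
            pooled = pd.Series(np.concatenate(groups))
            ranks = pooled.rank()
            sizes = [len(g) for g in groups]
            bounds = np.cumsum([0] + sizes)
            mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
            N = len(pooled)
            ties = pooled.value_counts()
            T = float((ties**3 - ties).sum())
            var = N * (N + 1) / 12 - T / (12 * (N - 1))
            row = 0
            for i in range(k):
                for j in range(i + 1, k):
                    se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
                    z = (mean_ranks[i] - mean_ranks[j]) / se
                    assert res.z.iloc[row] == pytest.approx(z, abs=1e-10)
                    row += 1


class TestMannWhitney:
    def test_exact_tail_example(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], "less")
        assert res.pvalue == pytest.approx(1 / 20)

    def test_identical_samples_two_sided_p_is_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3], "two-sided")
        assert res.pvalue == 1.0

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            x = rng.normal(size=int(rng.integers(2, 12)))
            y = rng.normal(size=int(rng.integers(2, 12)))
            for alt in ("less", "greater", "two-sided"):
                mine = mann_whitney(x, y, alt)
                ref = sps.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert mine.statistic == pytest.approx(ref.statistic)
                assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.integers(0, 10, size=30).astype(float)
            y = rng.integers(0, 10, size=25).astype(float)
            for alt in ("less", "greater", "two-sided"):
                mine = mann_whitney(x, y, alt)
                ref = sps.mannwhitneyu(x, y, alternative=alt, method="asymptotic")
                assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_and_normal_branches_agree_at_moderate_n(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            for alt in ("less", "greater", "two-sided"):
                e = mann_whitney(x, y, alt, method="exact").pvalue
                a = mann_whitney(x, y, alt, method="normal").pvalue
                assert abs(e - a) < 0.01

    def test_exact_with_ties_refused(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 1, 2], [2, 3, 4], method="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
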