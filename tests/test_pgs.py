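"""P+T polygenic scores: harmonization, clumping, scoring, concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arraybench as ab
from test_metrics import pearson_two_pass


def _variants(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def _stats(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "effect_allele", "other_allele", "beta", "p"]
    )


class TestHarmonize:
    def test_exact_match_keeps_beta(self):
        matched, counters = ab.harmonize(
            _stats([("1", 100, "G", "A", 0.3, 0.01)]),
            _variants([("1", 100, "A", "G")]),
        )
        assert counters["matched"] == 1
        assert matched["beta"].item() == 0.3

    def test_swapped_match_negates_beta(self):
        matched, counters = ab.harmonize(
            _stats([("1", 100, "A", "G", 0.2, 0.01)]),
            _variants([("1", 100, "A", "G")]),
        )
        assert counters["swapped"] == 1
        assert matched["beta"].item() == -0.2
        assert matched["effect_allele"].item() == "G"

    def test_ambiguous_swap_dropped(self):
        # A/T site requiring a swap cannot be distinguished from a strand flip
        matched, counters = ab.harmonize(
            _stats([("1", 100, "A", "T", 0.2, 0.01)]),
            _variants([("1", 100, "A", "T")]),
        )
        assert counters["ambiguous"] == 1
        assert len(matched) == 0

    def test_four_case_match_table(self):
        variants = _variants(
            [("1", 100, "A", "G"), ("1", 200, "C", "G"), ("1", 300, "A", "C")]
        )
        stats = _stats(
            [
                ("1", 100, "G", "A", 0.1, 0.5),   # exact
                ("1", 200, "C", "G", 0.2, 0.5),   # swapped but C/G ambiguous
                ("1", 300, "T", "G", 0.3, 0.5),   # alleles do not match
                ("1", 400, "A", "G", 0.4, 0.5),   # position absent
            ]
        )
        matched, counters = ab.harmonize(stats, variants)
        assert counters == {"matched": 1, "swapped": 0, "ambiguous": 1, "unmatched": 2}
        assert matched["pos"].tolist() == [100]

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            ab.harmonize(
                _stats([("1", 100, "G", "A", 0.1, 0.5), ("1", 100, "G", "A", 0.1, 0.5)]),
                _variants([("1", 100, "A", "G")]),
            )


def brute_force_clump(table, geno, spec):
    """Reference clumping that rescans all pairwise r² at every step."""
    remaining = list(range(len(table)))
    retained = []
    chrom = table["chrom"].to_numpy()
    pos = table["pos"].to_numpy()
    p = table["p"].to_numpy()
    while remaining:
        best = min(remaining, key=lambda i: (p[i], chrom[i], pos[i]))
        retained.append(best)
        remaining.remove(best)
        for j in list(remaining):
            if chrom[j] != chrom[best] or abs(pos[j] - pos[best]) > spec.window_bp:
                continue
            r = np.corrcoef(geno[:, best], geno[:, j])[0, 1]
            if not np.isfinite(r):
                continue
            if r * r >= spec.r2_threshold:
                remaining.remove(j)
    return sorted(retained)


def random_clump_instance(rng, n_var=20, n_samp=30):
    table = pd.DataFrame(
        {
            "chrom": rng.choice(["1", "2"], n_var),
            "pos": rng.choice(500_000, n_var, replace=False),
            "beta": rng.normal(0, 0.1, n_var),
            "p": rng.uniform(0, 1, n_var),
        }
    )
    base = rng.integers(0, 3, size=(n_samp, n_var)).astype(float)
    # correlate some neighbouring columns to create LD
    for j in range(1, n_var):
        if rng.random() < 0.5:
            base[:, j] = base[:, j - 1] * 0.9 + rng.normal(0, 0.3, n_samp)
    return table, base


class TestClump:
    SPEC = ab.ClumpSpec(window_bp=250_000, r2_threshold=0.1)

    def test_nearby_correlated_variant_removed(self):
        table = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [100_000, 200_000], "p": [1e-10, 1e-4]}
        )
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 50).astype(float)
        b = 0.8 * a + rng.normal(0, 0.5, 50)  # r2 well above 0.1
        retained = ab.clump(table, np.column_stack([a, b]), self.SPEC)
        assert retained.tolist() == [0]

    def test_outside_window_both_retained(self):
        table = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [100_000, 400_000], "p": [1e-10, 1e-4]}
        )
        geno = np.random.default_rng(0).integers(0, 3, size=(40, 2)).astype(float)
        geno[:, 1] = geno[:, 0]  # perfect LD but 300 kb apart
        retained = ab.clump(table, geno, self.SPEC)
        assert sorted(retained.tolist()) == [0, 1]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            table, geno = random_clump_instance(rng)
            got = sorted(ab.clump(table, geno, self.SPEC).tolist())
            want = brute_force_clump(table, geno, self.SPEC)
            assert got == want

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        table, geno = random_clump_instance(rng)
        keys = set(zip(table["chrom"], table["pos"]))
        perm = rng.permutation(len(table))
        shuffled = table.iloc[perm].reset_index(drop=True)
        a = ab.clump(table, geno, self.SPEC)
        b = ab.clump(shuffled, geno[:, perm], self.SPEC)
        got_a = {(table["chrom"][i], table["pos"][i]) for i in a}
        got_b = {(shuffled["chrom"][i], shuffled["pos"][i]) for i in b}
        assert got_a == got_b


class TestScore:
    GRID = ab.ThresholdGrid()

    def test_no_passing_snps_gives_zero(self):
        effects = pd.DataFrame({"beta": [0.5], "p": [0.9]})
        s = ab.score(np.array([[1.0]]), effects, ab.ThresholdGrid((0.5,)))
        assert s.tolist() == [[0.0]]

    def test_single_snp_hand_sum(self):
        effects = pd.DataFrame({"beta": [0.5], "p": [1e-9]})
        x = np.array([[0.0], [1.0], [2.0]])
        s = ab.score(x, effects, ab.ThresholdGrid((5e-8,)))
        assert s[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_three_snp_inner_product(self):
        effects = pd.DataFrame({"beta": [0.1, -0.2, 0.3], "p": [1e-9, 1e-9, 1e-9]})
        x = np.array([[2.0, 1.0, 0.0]])
        s = ab.score(x, effects, ab.ThresholdGrid((1.0,)))
        assert s[0, 0] == pytest.approx(0.0)

    def test_strict_threshold_inequality(self):
        effects = pd.DataFrame({"beta": [1.0], "p": [0.01]})
        s = ab.score(np.array([[2.0]]), effects, ab.ThresholdGrid((0.01, 0.02)))
        assert s[0].tolist() == [0.0, 2.0]  # P_j < P_T is strict

    def test_linearity_in_beta_and_x(self):
        rng = np.random.default_rng(3)
        effects = pd.DataFrame({"beta": rng.normal(0, 1, 8), "p": rng.uniform(0, 1, 8)})
        x = rng.integers(0, 3, size=(10, 8)).astype(float)
        s1 = ab.score(x, effects, self.GRID)
        doubled = effects.assign(beta=2 * effects["beta"])
        assert np.allclose(ab.score(x, doubled, self.GRID), 2 * s1)
        assert np.allclose(ab.score(2 * x, effects, self.GRID), 2 * s1)
        other = pd.DataFrame({"beta": rng.normal(0, 1, 8), "p": effects["p"]})
        summed = effects.assign(beta=effects["beta"] + other["beta"])
        assert np.allclose(
            ab.score(x, summed, self.GRID),
            s1 + ab.score(x, other, self.GRID),
        )

    def test_threshold_nesting(self):
        rng = np.random.default_rng(4)
        pvals = rng.uniform(0, 1, 30)
        for t1, t2 in zip(self.GRID, list(self.GRID)[1:]):
            set1 = set(np.flatnonzero(pvals < t1))
            set2 = set(np.flatnonzero(pvals < t2))
            assert set1 <= set2


class TestConcordance:
    def test_identical_scores_correlate_perfectly(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, size=(20, 12))
        r, mean, sd = ab.pgs_correlation(s, s)
        assert np.allclose(r, 1.0, atol=1e-12)
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        s = rng.normal(0, 1, size=(15, 3))
        r, _, _ = ab.pgs_correlation(2 * s + 3, s)
        assert np.allclose(r, 1.0, atol=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(0, 1, size=(5, 1))
            w = rng.normal(0, 1, size=(5, 1))
            r, _, _ = ab.pgs_correlation(a, w)
            assert r[0] == pytest.approx(pearson_two_pass(a[:, 0], w[:, 0]), abs=1e-12)

    def test_constant_threshold_flagged_undefined(self):
        a = np.column_stack([np.zeros(10), np.arange(10.0)])
        w = np.column_stack([np.zeros(10), np.arange(10.0)])
        r, mean, sd = ab.pgs_correlation(a, w)
        assert math.isnan(r[0]) and r[1] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)  # undefined threshold omitted

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ab.pgs_correlation(np.zeros((3, 2)), np.zeros((4, 2)))


class TestADPR:
    def test_identical_vectors_give_zero(self):
        s = np.random.default_rng(8).normal(0, 1, 25)
        per_sample, mean = ab.adpr(s, s)
        assert np.allclose(per_sample, 0.0)
        assert mean == 0.0

    def test_adjacent_swap_hand_example(self):
        wgs = np.array([1.0, 2.0, 3.0, 4.0])      # a < b < c < d
        arr = np.array([2.0, 1.0, 3.0, 4.0])      # a and b swapped
        per_sample, mean = ab.adpr(arr, wgs)
        # percentile = 100*(rank-0.5)/4: swap moves a,b by one rank = 25 points
        assert per_sample.tolist() == [25.0, 25.0, 0.0, 0.0]
        assert mean == pytest.approx(12.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_invariant_to_common_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 12)
        w = rng.normal(0, 1, 12)
        base = ab.adpr(a, w)[0]
        transformed = ab.adpr(np.exp(a), np.exp(w))[0]
        assert np.allclose(base, transformed)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            ab.adpr(np.array([1.0]), np.array([2.0]))

    def test_percentiles_bounded(self):
        s = np.random.default_rng(9).normal(0, 1, 50)
        p = ab.percentile_ranks(s)
        assert p.min() >= 0 and p.max() <= 100


class TestThresholdGrid:
    def test_default_grid_values(self):
        assert list(ab.ThresholdGrid()) == [
            5e-08, 1e-07, 1e-06, 1e-05, 0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.5, 1.0
        ]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ab.ThresholdGrid((0.5, 0.1))

    def test_clump_spec_validation(self):
        with pytest.raises(ValueError):
            ab.ClumpSpec(window_bp=0)
        with pytest.raises(ValueError):
            ab.ClumpSpec(r2_threshold=1.5)
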