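"""QC statistics: log-shift regression, fold flags, distances, tests, error rate."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mockqc import (
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    estimate_error_rate,
    fold_deviations,
    log_shift,
    r2_qc,
    wilcoxon_rank_sum,
)

abundance_vectors = st.lists(
    st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=12
)


class TestLogShift:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.0, -3.0),
            (0.999, 0.0),
            (0.018, math.log10(0.019)),
        ],
    )
    def test_known_values(self, x, expected):
        assert log_shift(x) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_shift(-0.1)


class TestR2QC:
    def test_identity_gives_perfect_fit(self):
        prof = {"a": 0.5, "b": 0.3, "c": 0.2}
        res = r2_qc(prof, prof)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.n_points == 3

    def test_four_clone_toy_matches_closed_form_ols(self):
        expected = {"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1}
        observed = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
        # independent closed-form least squares on the 4 log-shifted pairs
        x = np.log10(np.array([0.4, 0.3, 0.2, 0.1]) + 1e-3)
        y = np.log10(np.array([0.1, 0.2, 0.3, 0.4]) + 1e-3)
        beta = (np.mean(x * y) - x.mean() * y.mean()) / (np.mean(x * x) - x.mean() ** 2)
        alpha = y.mean() - beta * x.mean()
        resid = y - alpha - beta * x
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        res = r2_qc(observed, expected)
        assert res.r2 == pytest.approx(r2_oracle, abs=1e-12)
        assert res.slope == pytest.approx(beta, abs=1e-12)

    def test_mismatched_clone_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            r2_qc({"a": 0.5, "b": 0.5, "c": 0.0}, {"a": 0.5, "b": 0.3, "d": 0.2})

    def test_fewer_than_three_clones_rejected(self):
        with pytest.raises(ValueError, match="3 clones"):
            r2_qc({"a": 0.5, "b": 0.5}, {"a": 0.5, "b": 0.5})

    def test_even_design_degenerate(self):
        even = {c: 1 / 4 for c in "abcd"}
        with pytest.raises(ValueError, match="no variation"):
            r2_qc(even, even)

    @given(st.lists(st.floats(min_value=1e-4, max_value=1.0), min_size=4, max_size=20))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_r2_equals_squared_pearson_and_is_base_invariant(self, raw):
        vals = np.asarray(raw)
        expected = dict(zip(map(str, range(len(vals))), vals / vals.sum()))
        rng = np.random.default_rng(0)
        obs_vals = np.asarray(
            [v * math.exp(e) for v, e in zip(vals, rng.normal(0, 0.3, len(vals)))]
        )
        observed = dict(zip(expected, obs_vals / obs_vals.sum()))
        x = np.log10(np.array([expected[c] for c in sorted(expected)]) + 1e-3)
        y = np.log10(np.array([observed[c] for c in sorted(observed)]) + 1e-3)
        if np.var(x) < 1e-20 or np.var(y) < 1e-20:
            return
        res = r2_qc(observed, expected)
        pearson2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        assert res.r2 == pytest.approx(pearson2, abs=1e-12)
        # natural-log axes rescale both coordinates linearly: same R^2
        xe, ye = x * math.log(10), y * math.log(10)
        p2e = float(np.corrcoef(xe, ye)[0, 1] ** 2)
        assert res.r2 == pytest.approx(p2e, abs=1e-12)


class TestFoldDeviations:
    def test_mgii_dropout_is_a_19_fold_deficit(self):
        base = {"MGII": 0.018, "x": 0.5, "y": 0.482}
        obs = {"MGII": 0.0, "x": 0.509, "y": 0.491}
        dev = fold_deviations(obs, base)
        fold, direction = dev.folds["MGII"]
        assert fold == pytest.approx(0.019 / 0.001)
        assert direction == "deficit"
        assert "single_10fold" in dev.flags
        assert dev.offenders["single_10fold"] == ["MGII"]

    def test_observed_equal_baseline_has_no_flags(self):
        base = {"a": 0.6, "b": 0.4}
        dev = fold_deviations(base, base)
        assert dev.flags == frozenset()
        assert all(f == pytest.approx(1.0) for f, _ in dev.folds.values())

    def test_two_clones_beyond_twofold_raise_multi_flag(self):
        base = {"SAR11": 0.10, "Prochlorococcus": 0.10, "z": 0.80}
        obs = {"SAR11": 0.25, "Prochlorococcus": 0.04, "z": 0.71}
        dev = fold_deviations(obs, base)
        assert dev.folds["SAR11"][0] == pytest.approx(0.251 / 0.101)
        assert dev.folds["Prochlorococcus"][0] == pytest.approx(0.101 / 0.041)
        assert "multi_2fold" in dev.flags
        assert "single_10fold" not in dev.flags

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            fold_deviations({"a": 1.0}, {})

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1),
                st.floats(min_value=0, max_value=1),
            ),
            min_size=2,
            max_size=10,
        ),
        st.floats(min_value=0, max_value=30),
        st.floats(min_value=0, max_value=5),
    )
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_flags_monotone_in_thresholds(self, pairs, d_ten, d_two):
        obs = {str(i): o for i, (o, _) in enumerate(pairs)}
        base = {str(i): b for i, (_, b) in enumerate(pairs)}
        lo = fold_deviations(obs, base)
        hi = fold_deviations(obs, base, ten_fold=10 + d_ten, two_fold=2 + d_two)
        assert hi.flags <= lo.flags


class TestBrayCurtis:
    def test_identical_vectors_at_zero(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports_at_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_toy_value(self):
        assert bray_curtis([1, 3], [3, 1]) == pytest.approx(0.5)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @given(abundance_vectors, abundance_vectors)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_metric_properties(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if sum(a) + sum(b) == 0:
            return
        if sum(a) > 0:
            assert bray_curtis(a, a) == 0.0
        d = bray_curtis(a, b)
        assert 0.0 <= d <= 1.0
        assert d == bray_curtis(b, a)

    def test_matrix_is_symmetric_with_zero_diagonal(self):
        profiles = {"s1": [0.5, 0.5], "s2": [0.9, 0.1], "s3": [0.1, 0.9]}
        dm = bray_curtis_matrix(profiles)
        assert dm["s1", "s1"] == 0.0
        assert dm["s1", "s2"] == dm["s2", "s1"] == pytest.approx(0.4)


def _exact_ranksum_oracle(a, b):
    """Two-sided exact p by brute-force enumeration of group labelings."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n_a)]
    p_le = sum(s <= w_obs + 1e-9 for s in sums) / len(sums)
    p_ge = sum(s >= w_obs - 1e-9 for s in sums) / len(sums)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonRankSum:
    def test_extreme_split_of_six(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2], [1, 2])
        assert p == pytest.approx(1.0)

    def test_extreme_split_of_eight(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    @given(
        st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=10),
        st.integers(min_value=1, max_value=9),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_exact_mode_agrees_with_enumeration(self, values, split):
        if split >= len(values):
            return
        a, b = values[:split], values[split:]
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_exact_ranksum_oracle(a, b), abs=1e-12)

    def test_exact_mode_agrees_with_scipy_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(4)
        a = rng.normal(size=5)
        b = rng.normal(1.0, size=6)
        _, p = wilcoxon_rank_sum(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_large_sample_normal_approximation_is_sane(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=30)
        b = rng.normal(2.0, size=30)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6
        _, p_null = wilcoxon_rank_sum(a, list(a))
        assert p_null > 0.5


class TestAnosim:
    def _separated_matrix(self):
        # within-group distances all < between-group distances
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        return d, ["g1", "g1", "g2", "g2"]

    def test_maximal_separation_gives_r_one(self):
        d, groups = self._separated_matrix()
        r, _ = anosim(d, groups, permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_identical_distances_give_r_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        r, _ = anosim(d, ["a", "a", "b", "b"], permutations=99, seed=0)
        assert r == pytest.approx(0.0)

    def test_r_matches_brute_force_over_label_permutations(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(2)
        n = 6
        pts = rng.normal(size=(n, 2))
        pts[3:] += 2.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        iu = np.triu_indices(n, k=1)
        ranks = rankdata(d[iu])

        def r_of(lab):
            within = lab[iu[0]] == lab[iu[1]]
            return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

        r_obs, p_exact = anosim(d, labels, permutations="exact")
        assert r_obs == pytest.approx(r_of(labels), abs=1e-12)
        # brute-force p over all distinct labelings
        perms = {tuple(labels[list(pi)]) for pi in itertools.permutations(range(n))}
        count = sum(r_of(np.array(lab)) >= r_obs - 1e-12 for lab in perms)
        assert p_exact == pytest.approx(count / len(perms), abs=1e-12)

    def test_monte_carlo_p_within_3se_of_exact(self):
        rng = np.random.default_rng(9)
        n = 6
        pts = rng.normal(size=(n, 2))
        pts[3:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a", "a", "a", "b", "b", "b"]
        _, p_exact = anosim(d, labels, permutations="exact")
        _, p_mc = anosim(d, labels, permutations=999, seed=5)
        se = math.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / 999

    def test_agrees_with_skbio_r_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(3)
        n = 8
        pts = rng.normal(size=(n, 3))
        pts[4:] += 1.5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 4 + ["b"] * 4
        r, _ = anosim(d, labels, permutations=99, seed=0)
        ref = skbio_anosim(DistanceMatrix(d, list("01234567")), grouping=labels,
                           permutations=99)
        assert r == pytest.approx(float(ref["test statistic"]), abs=1e-12)

    def test_singleton_group_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match=">= 2 samples"):
            anosim(d, ["a", "a", "b"], permutations=9, seed=0)


class TestErrorRate:
    def test_perfect_read_contributes_zero(self, staggered_def):
        read = staggered_def.references["SAR11"].sequence[50:300]
        res = estimate_error_rate([read], staggered_def)
        assert res.error_rate_percent == 0.0
        assert res.total_query_bases == 250

    def test_five_substitutions_in_250_is_two_percent(self, staggered_def):
        read = list(staggered_def.references["SAR11"].sequence[50:300])
        for pos in (10, 60, 110, 160, 210):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        res = estimate_error_rate(["".join(read)], staggered_def)
        assert res.total_mismatches == 5
        assert res.error_rate_percent == pytest.approx(2.0)

    def test_indels_count_as_mismatches(self, staggered_def):
        ref = staggered_def.references["MGII"].sequence
        # drop 2 bases and insert 1: 3 mismatching columns, 249 query bases
        read = ref[100:200] + ref[202:300] + "A" + ref[300:350]
        assert len(read) == 249
        res = estimate_error_rate([read], staggered_def)
        assert res.total_mismatches == 3
        assert res.total_query_bases == 249

    def test_overlong_read_rejected_with_warning(self, staggered_def):
        good = staggered_def.references["SAR11"].sequence[0:250]
        monster = "A" * (2 * 800 + 1)
        with pytest.warns(UserWarning, match="excluded"):
            res = estimate_error_rate([good, monster], staggered_def)
        assert res.n_reads == 1
        assert res.n_rejected == 1

    def test_no_reads_rejected(self, staggered_def):
        with pytest.raises(ValueError):
            estimate_error_rate([], staggered_def)

    @pytest.mark.parametrize("rate", [2e-4, 3.3e-4, 1e-3])
    def test_recovers_injected_substitution_rate(self, rate, staggered_def):
        """Injected i.i.d. substitution rates are recovered within 3 binomial SE."""
        from mockqc import SimConfig, simulate_mock_sample

        n_reads, read_len = 10_000, 250
        cfg = SimConfig(
            community_id=staggered_def.community_id,
            seed=97,
            depth=1000,
            reads_per_replicate=n_reads,
            read_length=read_len,
            per_base_error=rate,
        )
        sample = simulate_mock_sample(staggered_def, cfg)
        res = estimate_error_rate(sample.reads, staggered_def)
        n_bases = n_reads * read_len
        se = math.sqrt(rate * (1 - rate) / n_bases)
        assert res.error_rate_percent / 100 == pytest.approx(rate, abs=3 * se)
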