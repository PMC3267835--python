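"""Ridge grids, class-separation criteria and the grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srcca import (
    GroupStats,
    compute_covariances,
    make_grid,
    rcca_loo_objective,
    select_parameters,
    solve_rcca,
    tscore,
    wilks_lambda,
    wrst_score,
)

from conftest import make_labels, make_view


class TestGrid:
    def test_study_grid_is_millesimal_steps(self):
        g = make_grid(0.001, 0.2, 200)
        assert np.allclose(g.values, np.arange(1, 201) * 0.001)

    def test_single_point_grid(self):
        g = make_grid(0.05, 0.9, 1)
        assert list(g.values) == [0.05]

    def test_two_point_grid_is_endpoints(self):
        g = make_grid(0.1, 0.7, 2)
        assert list(g.values) == [0.1, 0.7]

    def test_full_pairs_mode_enumerates_v_squared(self):
        g = make_grid(0.0, 1.0, 3, mode="full-pairs")
        assert len(list(g.pairs())) == 9
        assert g.n_points == 9

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            make_grid(0.5, 0.1, 10)


def group_stats(g1, g2):
    values = np.concatenate([g1, g2])
    labels = make_labels([0] * len(g1) + [1] * len(g2))
    return GroupStats.from_embedding(values, labels), values, labels


class TestTScore:
    def test_identical_groups_zero(self):
        g, _, _ = group_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert tscore(g) == 0.0

    def test_hand_computed_value(self):
        # |1-2-3 mean - 4-5-6 mean| / sqrt(1/3 + 1/3)
        g, _, _ = group_stats([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert tscore(g) == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-12)

    def test_shift_invariance(self):
        g1, _, _ = group_stats([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        g2, _, _ = group_stats([11.0, 12.0, 13.0], [14.0, 15.0, 16.0])
        assert tscore(g1) == pytest.approx(tscore(g2), abs=1e-12)

    def test_zero_variance_distinct_means_is_infinite(self):
        g, _, _ = group_stats([2.0, 2.0], [5.0, 5.0])
        assert tscore(g) == np.inf

    @settings(max_examples=50, deadline=None)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(6)
        b = rng.standard_normal(7) + 1
        g0, _, _ = group_stats(a, b)
        g1, _, _ = group_stats(a * scale + shift, b * scale + shift)
        assert tscore(g1) == pytest.approx(tscore(g0), rel=1e-9)


def brute_force_wrst(values, labels_arr):
    """Exhaustive rank-count oracle: midranks counted pair by pair."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(values < values[i])
        equal = np.sum(values == values[i])
        ranks[i] = less + (equal + 1) / 2
    classes = np.unique(labels_arr)
    n2 = np.sum(labels_arr == classes[1])
    n1 = n - n2
    u = ranks[labels_arr == classes[1]].sum() - n2 * (n2 + 1) / 2
    return max(u, n1 * n2 - u)


class TestWrstScore:
    def test_perfect_separation_attains_maximum(self):
        _, values, labels = group_stats([1.0, 2.0, 3.0], [10.0, 11.0])
        assert wrst_score(values, labels) == 3 * 2

    def test_interleaved_balanced_is_null_center(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        labels = make_labels([0, 1, 1, 0])
        assert wrst_score(values, labels) == 2 * 2 / 2

    def test_all_identical_is_null_center(self):
        values = np.ones(5)
        labels = make_labels([0, 0, 0, 1, 1])
        assert wrst_score(values, labels) == 3 * 2 / 2

    def test_example_matches_exhaustive_oracle(self):
        values = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        labels = make_labels([0, 0, 1, 0, 1])  # W2 = samples 3 and 5
        assert wrst_score(values, labels) == brute_force_wrst(values, labels.labels)

    def test_random_inputs_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            values = rng.integers(0, 6, n).astype(float)  # many ties
            lab = np.zeros(n, dtype=int)
            lab[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if len(np.unique(lab)) < 2:
                continue
            labels = make_labels(lab)
            assert wrst_score(values, labels) == brute_force_wrst(values, lab)

    def test_monotone_transform_invariance(self, rng):
        values = rng.standard_normal(11)
        labels = make_labels([0] * 5 + [1] * 6)
        assert wrst_score(np.exp(values), labels) == wrst_score(values, labels)


class TestWilksLambda:
    def test_zero_within_class_variance(self):
        g, _, _ = group_stats([2.0, 2.0], [7.0, 7.0])
        assert wilks_lambda(g) == 0.0

    def test_identical_class_value_sets_give_one(self):
        g, _, _ = group_stats([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        assert wilks_lambda(g) == pytest.approx(1.0, abs=1e-12)

    def test_sum_of_squares_decomposition_oracle(self):
        g1 = np.array([0.0, 1.0])
        g2 = np.array([10.0, 11.0])
        g, values, _ = group_stats(g1, g2)
        ss_total = np.sum((values - values.mean()) ** 2)
        ss_within = np.sum((g1 - g1.mean()) ** 2) + np.sum((g2 - g2.mean()) ** 2)
        assert wilks_lambda(g) == pytest.approx(ss_within / ss_total, abs=1e-12)
        assert wilks_lambda(g) == pytest.approx(1 / 101, abs=1e-12)

    def test_ss_identity_on_random_inputs(self, rng):
        for _ in range(100):
            a = rng.standard_normal(int(rng.integers(2, 9)))
            b = rng.standard_normal(int(rng.integers(2, 9))) + rng.normal()
            g, values, _ = group_stats(a, b)
            lam = wilks_lambda(g)
            assert 0.0 <= lam <= 1.0
            ss_total = np.sum((values - values.mean()) ** 2)
            n1, n2 = len(a), len(b)
            grand = values.mean()
            ss_between = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
            assert (1 - lam) * ss_total == pytest.approx(ss_between, abs=1e-10)

    def test_degenerate_total_variance_rejected(self):
        g, _, _ = group_stats([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="total variance"):
            wilks_lambda(g)


class TestLooObjective:
    def test_self_view_strong_signal_near_one(self, rng):
        base = rng.standard_normal((12, 1))
        x = make_view(np.hstack([base, base * 2 + 0.01 * rng.standard_normal((12, 1))]), "X")
        score = rcca_loo_objective(x, x, 0.01, 0.01)
        assert score > 0.9

    def test_matches_naive_explicit_loop(self, rng):
        from srcca import cca as cca_mod

        x = make_view(rng.standard_normal((12, 3)), "X")
        y = make_view(rng.standard_normal((12, 2)), "Y")
        lam_x, lam_y = 0.05, 0.11

        u = np.empty(12)
        v = np.empty(12)
        for i in range(12):
            keep = [j for j in range(12) if j != i]
            xt = x.values[keep]
            yt = y.values[keep]
            cov = compute_covariances(
                make_view(xt, "X"), make_view(yt, "Y")
            )
            model = solve_rcca(cov, lam_x, lam_y, d=1)
            u[i] = (x.values[i] - xt.mean(axis=0)) @ model.w_x[:, 0]
            v[i] = (y.values[i] - yt.mean(axis=0)) @ model.w_y[:, 0]
        expected = np.corrcoef(u, v)[0, 1]
        assert rcca_loo_objective(x, y, lam_x, lam_y) == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        v = make_view([[1.0], [2.0]])
        with pytest.raises(ValueError, match="n >= 3"):
            rcca_loo_objective(v, v, 0.1, 0.1)


class TestSelectParameters:
    def test_single_point_grid_counts(self, small_dataset):
        ds = small_dataset
        g = make_grid(0.01, 0.01, 1)
        sup = select_parameters(ds.x_view, ds.y_view, ds.labels, g, "tt")
        assert (sup.lambda_x, sup.lambda_y) == (0.01, 0.01)
        assert sup.factorizations == 1
        uns = select_parameters(ds.x_view, ds.y_view, None, g, "rcca-loo")
        assert uns.factorizations == ds.n_samples

    def test_selected_point_attains_surface_extremum(self, small_dataset):
        ds = small_dataset
        g = make_grid(0.001, 0.2, 8)
        for criterion in ("tt", "wrst", "wlt"):
            res = select_parameters(ds.x_view, ds.y_view, ds.labels, g, criterion)
            scores = {(lx, ly): s for lx, ly, s in res.criterion_surface}
            best = scores[(res.lambda_x, res.lambda_y)]
            if criterion == "wlt":
                assert best == min(scores.values())
            else:
                assert best == max(scores.values())

    def test_factorization_counts_scale_with_n_for_rcca(self, small_dataset):
        ds = small_dataset
        g = make_grid(0.001, 0.2, 10)
        sup = select_parameters(ds.x_view, ds.y_view, ds.labels, g, "wlt")
        uns = select_parameters(ds.x_view, ds.y_view, None, g, "rcca-loo")
        assert sup.factorizations == 10
        assert uns.factorizations == 10 * 19

    def test_label_requirements_enforced(self, small_dataset):
        ds = small_dataset
        g = make_grid(0.01, 0.1, 2)
        with pytest.raises(ValueError, match="requires labels"):
            select_parameters(ds.x_view, ds.y_view, None, g, "tt")
        with pytest.raises(ValueError, match="unsupervised"):
            select_parameters(ds.x_view, ds.y_view, ds.labels, g, "rcca-loo")

    def test_surface_is_deterministic(self, small_dataset):
        ds = small_dataset
        g = make_grid(0.001, 0.2, 5)
        r1 = select_parameters(ds.x_view, ds.y_view, ds.labels, g, "wrst")
        r2 = select_parameters(ds.x_view, ds.y_view, ds.labels, g, "wrst")
        assert r1.criterion_surface == r2.criterion_surface
        assert (r1.lambda_x, r1.lambda_y) == (r2.lambda_x, r2.lambda_y)
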