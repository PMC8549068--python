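"""Penalized Laplace-likelihood change detection."""

import numpy as np
import pytest

from mdsegclust import (
    ChangePointSet,
    DetectionParams,
    detect_changes,
    lambda_ladder,
    laplace_loglik,
    objective,
)
from mdsegclust.changepoint import changepoint_table

from oracles import exhaustive_max_objective


class TestLaplaceLoglik:
    def test_symmetric_pair_hand_value(self):
        # μ̂ = 0, v̂ = 1 → −2·ln 2 − 2
        assert laplace_loglik(np.array([-1.0, 1.0])) == pytest.approx(
            -2 * np.log(2) - 2
        )

    def test_constant_segment_hits_floor(self):
        eps = 1e-8
        got = laplace_loglik(np.full(7, 3.25), scale_floor=eps)
        assert got == pytest.approx(-7 * np.log(2 * eps))

    def test_mle_identity_on_random_segments(self, rng):
        # at the ML fit, loglik = −n(ln(2v̂)+1) whenever the floor is inactive
        for _ in range(20):
            x = rng.normal(0, rng.uniform(0.5, 5), rng.integers(2, 40))
            mu = np.median(x)
            v = np.abs(x - mu).mean()
            if v > 1e-8:
                assert laplace_loglik(x) == pytest.approx(-x.size * (np.log(2 * v) + 1))

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            laplace_loglik(np.array([]))


class TestObjective:
    def test_empty_set_has_no_penalty(self, rng):
        x = rng.normal(size=(30, 2))
        params = DetectionParams(lam=5.0, alpha=0.7)
        S = ChangePointSet.empty(2, 30)
        expect = sum(laplace_loglik(x[:, j]) for j in range(2))
        assert objective(x, S, params) == pytest.approx(expect)

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.7, 1.0])
    def test_single_change_pays_lambda_for_any_alpha(self, rng, alpha):
        x = rng.normal(size=(30, 1))
        params = DetectionParams(lam=7.0, alpha=alpha)
        S = ChangePointSet((np.array([15]),), 30)
        base = laplace_loglik(x[:15, 0]) + laplace_loglik(x[15:, 0])
        assert objective(x, S, params) == pytest.approx(base - 7.0)

    def test_simultaneity_discount(self, rng):
        # d dimensions changing at one time cost λ·d^α < λ·d for α < 1
        d, lam, alpha = 3, 4.0, 0.7
        x = rng.normal(size=(20, d))
        S = ChangePointSet(tuple(np.array([10]) for _ in range(d)), 20)
        params = DetectionParams(lam=lam, alpha=alpha)
        base = sum(
            laplace_loglik(x[:10, j]) + laplace_loglik(x[10:, j]) for j in range(d)
        )
        got = objective(x, S, params)
        assert got == pytest.approx(base - lam * d**alpha)
        assert lam * d**alpha < lam * d

    def test_out_of_range_index_rejected(self, rng):
        x = rng.normal(size=(10, 1))
        with pytest.raises(ValueError):
            ChangePointSet((np.array([0]),), 10)


class TestDetect:
    def test_noiseless_step_found_exactly(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        S = detect_changes(x, DetectionParams(lam=10.0, alpha=0.7))
        np.testing.assert_array_equal(S.per_dim[0], [50])

    def test_constant_series_yields_no_changes(self):
        S = detect_changes(np.full(40, 2.0), DetectionParams(lam=0.5))
        assert S.n_changes == 0

    def test_short_series_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            S = detect_changes(np.zeros(3), DetectionParams(min_seg_len=2))
        assert S.n_changes == 0

    @pytest.mark.parametrize("d", [1, 2])
    def test_matches_exhaustive_enumeration(self, rng, d):
        """Returned objective equals the literal enumeration maximum."""
        params = DetectionParams(lam=2.0, alpha=0.6, min_seg_len=2)
        for _ in range(15):
            T = int(rng.integers(6, 17 if d == 1 else 11))
            x = rng.normal(size=(T, d))
            if rng.random() < 0.5:
                x[T // 2 :] += rng.normal(0, 4, size=d)
            S = detect_changes(x, params)
            got = objective(x, S, params)
            best = exhaustive_max_objective(
                x, params.lam, params.alpha, params.min_seg_len, params.scale_floor
            )
            assert got == pytest.approx(best, abs=1e-9)

    def test_change_count_monotone_in_lambda(self, rng):
        x = np.concatenate(
            [rng.normal(m, 1.0, 30) for m in [0, 6, -3, 8, 0]]
        )
        counts = [
            detect_changes(x, DetectionParams(lam=lam)).n_changes
            for lam in lambda_ladder(200.0, 0.5, 8)
        ]
        assert counts == sorted(counts)  # ladder runs high → low

    def test_affine_invariance(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(5, 1, 40)])
        a, b = -3.7, 12.0
        S1 = detect_changes(x, DetectionParams(lam=8.0, scale_floor=1e-8))
        S2 = detect_changes(
            a * x + b, DetectionParams(lam=8.0, scale_floor=abs(a) * 1e-8)
        )
        np.testing.assert_array_equal(S1.per_dim[0], S2.per_dim[0])

    def test_alpha_one_decouples_dimensions(self, rng):
        # T large enough to exercise the coordinate-ascent path
        cols = [
            np.concatenate([rng.normal(0, 1, 60), rng.normal(7, 1, 60)]),
            np.concatenate([rng.normal(2, 1, 80), rng.normal(-5, 1, 40)]),
        ]
        x = np.column_stack(cols)
        params = DetectionParams(lam=10.0, alpha=1.0)
        S = detect_changes(x, params)
        for j in range(2):
            S1 = detect_changes(cols[j], params)
            np.testing.assert_array_equal(S.per_dim[j], S1.per_dim[0])

    def test_simultaneous_change_preferred_when_coupled(self, rng):
        # both dimensions step at 30; α < 1 makes the joint change cheaper
        x = np.column_stack(
            [
                np.concatenate([rng.normal(0, 0.5, 30), rng.normal(6, 0.5, 30)]),
                np.concatenate([rng.normal(0, 0.5, 30), rng.normal(-6, 0.5, 30)]),
            ]
        )
        S = detect_changes(x, DetectionParams(lam=15.0, alpha=0.7))
        np.testing.assert_array_equal(S.per_dim[0], [30])
        np.testing.assert_array_equal(S.per_dim[1], [30])
        np.testing.assert_array_equal(S.multiplicity, [2])


class TestBookkeeping:
    def test_union_and_multiplicity(self):
        S = ChangePointSet((np.array([10, 20]), np.array([20, 30])), 50)
        np.testing.assert_array_equal(S.union_times, [10, 20, 30])
        np.testing.assert_array_equal(S.multiplicity, [1, 2, 1])
        assert S.n_changes == 4

    def test_changepoint_table_layout(self):
        S = ChangePointSet((np.array([10]), np.array([10, 30])), 50)
        df = changepoint_table(S, ["phi", "psi"])
        assert list(df.columns) == ["time_index", "dimensions", "multiplicity"]
        assert df.iloc[0]["dimensions"] == "phi;psi"
        assert df.iloc[1]["multiplicity"] == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(lam=-1.0)
        with pytest.raises(ValueError):
            DetectionParams(alpha=1.5)
        with pytest.raises(ValueError):
            DetectionParams(min_seg_len=1)
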