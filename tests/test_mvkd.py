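"""Background-model estimation and closed-form LR scoring vs. quadrature."""

import math

import numpy as np
import pytest

from phonlr.mvkd import (
    MVKD,
    BackgroundModel,
    fit_background,
    kernel_bandwidth,
    numeric_lr_oracle,
)


def _random_instance(rng, p=1, m=None, between=5.0, within=1.0):
    m = m or int(rng.integers(3, 11))
    groups = {
        f"s{i:02d}": rng.normal(rng.normal(0.0, between, size=p), within,
                                size=(int(rng.integers(2, 21)), p))
        for i in range(m)
    }
    bg = fit_background(groups)
    suspect = rng.normal(rng.normal(0.0, between, size=p), within,
                         size=(int(rng.integers(2, 12)), p))
    questioned = rng.normal(rng.normal(0.0, between, size=p), within,
                            size=(int(rng.integers(2, 12)), p))
    return bg, suspect, questioned


class TestEstimation:
    def test_two_speaker_closed_form_arithmetic(self):
        # per-speaker variance 2 -> pooled U = 2; cov of means {1, 11} = 50,
        # harmonic-mean count 2 -> C = 50 - 2/2 = 49
        model = fit_background({"a": np.array([0.0, 2.0]), "b": np.array([10.0, 12.0])})
        assert model.U[0, 0] == pytest.approx(2.0)
        assert model.C[0, 0] == pytest.approx(49.0)
        assert model.h == pytest.approx((4.0 / (3.0 * 2.0)) ** 0.2)

    def test_single_token_speaker_is_named_in_error(self):
        groups = {"ok": np.array([1.0, 2.0]), "solo": np.array([5.0]), "x": np.array([0.0, 1.0])}
        with pytest.raises(ValueError, match="solo"):
            fit_background(groups)

    def test_degenerate_within_covariance_warns(self):
        groups = {
            "a": np.array([1.0, 1.0]),
            "b": np.array([5.0, 5.0]),
            "c": np.array([9.0, 9.0]),
        }
        with pytest.warns(RuntimeWarning, match="within-speaker covariance"):
            model = fit_background(groups)
        assert model.U[0, 0] > 0

    def test_unbalanced_counts_use_harmonic_mean(self, rng):
        groups = {
            "a": rng.normal(0, 1, size=8),
            "b": rng.normal(5, 1, size=2),
            "c": rng.normal(10, 1, size=4),
        }
        model = fit_background(groups)
        n_tilde = 3.0 / (1 / 8 + 1 / 2 + 1 / 4)
        expected = np.cov(model.speaker_means[:, 0], ddof=1) - model.U[0, 0] / n_tilde
        assert model.C[0, 0] == pytest.approx(expected)


class TestBandwidth:
    def test_reference_value(self):
        assert kernel_bandwidth(4, 1) == pytest.approx((1.0 / 3.0) ** 0.2)

    def test_monotone_decreasing_in_m(self):
        hs = [kernel_bandwidth(m, 1) for m in range(2, 200)]
        assert all(a > b for a, b in zip(hs, hs[1:]))
        assert kernel_bandwidth(10**9, 1) < 0.02


class TestScoring:
    def test_same_source_far_from_background_supports_same(self, rng):
        groups = {f"s{i}": rng.normal(i * 2.0, 1.0, size=10) for i in range(5)}
        model = fit_background(groups)
        tokens = rng.normal(100.0, 1.0, size=8)
        assert model.log_lr(tokens, tokens).log10_lr > 0

    def test_questioned_on_other_speaker_supports_different(self, rng):
        means = [0.0, 20.0, 40.0, 60.0]
        groups = {f"s{i}": rng.normal(mu, 1.0, size=20) for i, mu in enumerate(means)}
        model = fit_background(groups)
        suspect = rng.normal(0.0, 1.0, size=10)
        questioned = rng.normal(40.0, 1.0, size=10)
        assert model.log_lr(suspect, questioned).log10_lr < 0

    def test_background_exchangeability(self, rng):
        bg, s, q = _random_instance(rng)
        base = bg.log_lr(s, q).log10_lr
        order = list(bg.speaker_ids)[::-1]
        permuted = BackgroundModel(
            speaker_ids=tuple(order),
            speaker_means=bg.speaker_means[::-1].copy(),
            U=bg.U, C=bg.C, h=bg.h,
            token_counts=bg.token_counts[::-1],
        )
        assert permuted.log_lr(s, q).log10_lr == pytest.approx(base, abs=1e-12)

    def test_affine_invariance_2d(self, rng):
        groups = {f"s{i}": rng.normal(rng.normal(0, 5, 2), 1.0, size=(15, 2)) for i in range(6)}
        s = rng.normal([2.0, -1.0], 1.0, size=(8, 2))
        q = rng.normal([-3.0, 4.0], 1.0, size=(9, 2))
        base = fit_background(groups).log_lr(s, q).log10_lr
        for _ in range(5):
            A = rng.normal(size=(2, 2))
            while abs(np.linalg.det(A)) < 0.3:
                A = rng.normal(size=(2, 2))
            b = rng.normal(size=2) * 10
            mapped = {k: v @ A.T + b for k, v in groups.items()}
            lr = fit_background(mapped).log_lr(s @ A.T + b, q @ A.T + b).log10_lr
            assert lr == pytest.approx(base, abs=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        bg, s, q = _random_instance(rng, p=1)
        with pytest.raises(ValueError, match="columns"):
            bg.log_lr(np.ones((3, 2)), q)

    def test_roundtrip_serialization(self, rng, tmp_path):
        bg, s, q = _random_instance(rng)
        path = bg.save(tmp_path / "model.json")
        back = BackgroundModel.load(path)
        assert back.log_lr(s, q).log10_lr == pytest.approx(bg.log_lr(s, q).log10_lr)


class TestOracle:
    def test_oracle_is_symmetric(self, rng):
        bg, s, q = _random_instance(rng)
        assert numeric_lr_oracle(bg, s, q) == pytest.approx(
            numeric_lr_oracle(bg, q, s), abs=1e-9
        )

    def test_closed_form_matches_quadrature_1d(self, rng):
        for _ in range(15):
            bg, s, q = _random_instance(rng, p=1)
            closed = bg.log_lr(s, q).ln_lr
            oracle = numeric_lr_oracle(bg, s, q) * math.log(10.0)
            assert abs(closed - oracle) < 1e-6

    def test_closed_form_matches_quadrature_2d(self, rng):
        bg, s, q = _random_instance(rng, p=2, m=4)
        closed = bg.log_lr(s, q).ln_lr
        oracle = numeric_lr_oracle(bg, s, q) * math.log(10.0)
        assert abs(closed - oracle) < 1e-5

    def test_single_kernel_reduces_to_two_level_normal_lr(self, rng):
        # with one kernel the mixture density is a single Gaussian and the
        # LR has the classical two-level normal closed form, written out
        # here independently with plain 1-D normal densities
        from scipy.stats import norm

        U, B, mu0 = 1.3, 4.0, 2.0
        model = BackgroundModel(
            speaker_ids=("only",),
            speaker_means=np.array([[mu0]]),
            U=np.array([[U]]),
            C=np.array([[B]]),
            h=1.0,
            token_counts=(5,),
        )
        s = rng.normal(3.0, 1.0, size=6)
        q = rng.normal(3.5, 1.0, size=4)
        ys, yq = s.mean(), q.mean()
        d1, d2 = U / len(s), U / len(q)
        d12 = 1.0 / (1.0 / d1 + 1.0 / d2)
        c = d12 * (ys / d1 + yq / d2)
        expected = (
            norm.logpdf(ys, yq, math.sqrt(d1 + d2))
            + norm.logpdf(c, mu0, math.sqrt(d12 + B))
            - norm.logpdf(ys, mu0, math.sqrt(d1 + B))
            - norm.logpdf(yq, mu0, math.sqrt(d2 + B))
        ) / math.log(10.0)
        assert model.log_lr(s, q).log10_lr == pytest.approx(expected, abs=1e-10)
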