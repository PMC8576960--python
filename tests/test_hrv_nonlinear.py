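import numpy as np
import pytest

from pafscreen.ecg_io import RRSeries
from pafscreen.hrv_nonlinear import apen, dfa, nonlinear_features, poincare_sd, sampen
from pafscreen.hrv_time import time_domain_features


def _naive_apen(x, m, r):
    """O(n^2) double-loop ApEn, self-matches included (oracle)."""
    n = len(x)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            c = sum(
                1 for b in templates if max(abs(ai - bi) for ai, bi in zip(a, b)) <= r
            )
            total += np.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def _naive_sampen(x, m, r):
    """O(n^2) SampEn, self-matches excluded (oracle)."""
    n = len(x)
    n_t = n - m

    def count(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)][:n_t]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    return float("nan") if a == 0 or b == 0 else -np.log(a / b)


class TestPoincare:
    def test_constant_series(self):
        rr = RRSeries(intervals=np.full(20, 800.0))
        sd1, sd2, ratio = poincare_sd(rr)
        assert sd1 == pytest.approx(0.0, abs=1e-9)
        assert sd2 == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(ratio)

    def test_variance_identity_brute_force(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(700, 1000, size=300)
        sd1, sd2, _ = poincare_sd(RRSeries(intervals=x))
        a, b = x[:-1], x[1:]
        # the 45-degree rotation preserves total variance of the pair cloud:
        # SD1^2 + SD2^2 = Var(RRn) + Var(RRn+1) exactly (cross terms cancel)
        lhs = sd1**2 + sd2**2
        rhs = np.var(a, ddof=1) + np.var(b, ddof=1)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_sd1_proportional_to_rmssd(self):
        # SD1 = RMSSD/sqrt(2) x sqrt((n-1)/(n-2))-style ddof correction factor:
        # verify numerically against the time-domain module
        rng = np.random.default_rng(22)
        x = rng.uniform(700, 1000, size=400)
        rr = RRSeries(intervals=x)
        sd1, _, _ = poincare_sd(rr)
        rmssd = time_domain_features(rr).RMSSD
        d = np.diff(x)
        expected = rmssd / np.sqrt(2.0) * np.sqrt(
            np.var(d, ddof=1) / np.mean(d**2)
        )
        assert sd1 == pytest.approx(expected, rel=1e-9)


class TestEntropies:
    def test_constant_series_zero(self):
        x = np.full(30, 5.0)
        assert apen(x, m=2, r=0.5) == pytest.approx(0.0, abs=1e-12)
        assert sampen(x, m=2, r=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_apen_matches_naive_oracle(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=100)
        r = 0.2 * np.std(x, ddof=1)
        assert apen(x, 2, r) == pytest.approx(_naive_apen(list(x), 2, r), rel=1e-9)

    def test_sampen_matches_naive_oracle(self):
        rng = np.random.default_rng(24)
        x = rng.normal(size=100)
        r = 0.2 * np.std(x, ddof=1)
        assert sampen(x, 2, r) == pytest.approx(_naive_sampen(list(x), 2, r), rel=1e-9)

    def test_shuffling_a_periodic_series_raises_apen(self):
        rng = np.random.default_rng(25)
        periodic = np.tile([0.0, 1.0, 2.0, 1.0], 50)  # n = 200
        shuffled = rng.permutation(periodic)
        r = 0.2 * np.std(periodic, ddof=1)
        assert apen(shuffled, 2, r) > apen(periodic, 2, r)

    def test_sampen_translation_invariance(self):
        rng = np.random.default_rng(26)
        x = rng.normal(size=120)
        assert sampen(x + 100.0, 2, 0.3) == pytest.approx(sampen(x, 2, 0.3), rel=1e-12)

    def test_r_must_be_positive(self):
        with pytest.raises(ValueError):
            apen(np.arange(30.0), 2, 0.0)


class TestDFA:
    def test_white_noise_alpha1(self):
        # alpha1 over 4-16-beat boxes carries a small-box upward bias, so the
        # white-noise check is on the across-seed mean
        a1s = [dfa(np.random.default_rng(s).normal(size=2000))[0] for s in range(10)]
        assert 0.4 <= np.mean(a1s) <= 0.6

    def test_integrated_noise_alpha1(self):
        a1s = [
            dfa(np.cumsum(np.random.default_rng(s).normal(size=2000)))[0]
            for s in range(10)
        ]
        assert 1.3 <= np.mean(a1s) <= 1.7

    def test_scale_invariance(self):
        x = np.random.default_rng(27).normal(size=1500)
        a = dfa(x)
        b = dfa(7.3 * x)
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[1] == pytest.approx(b[1], rel=1e-9)

    def test_fluctuation_growth(self):
        # recompute F(n) directly to check positivity and growth
        x = np.random.default_rng(28).normal(size=1200)
        y = np.cumsum(x - x.mean())
        fl = []
        for n in (4, 8, 16, 32, 64):
            nb = y.size // n
            z = y[: nb * n].reshape(nb, n)
            t = np.arange(n)
            f = []
            for row in z:
                c = np.polyfit(t, row, 1)
                f.append(np.mean((row - np.polyval(c, t)) ** 2))
            fl.append(np.sqrt(np.mean(f)))
        assert all(v > 0 for v in fl)
        assert all(b > a for a, b in zip(fl, fl[1:]))


class TestNonlinearBundle:
    def test_all_fields_populated(self):
        rng = np.random.default_rng(29)
        rr = RRSeries(intervals=rng.uniform(700, 1000, size=400))
        nl = nonlinear_features(rr)
        for v in (nl.SD1, nl.SD2, nl.SD2_SD1, nl.ApEn, nl.SampEn, nl.alpha1, nl.alpha2):
            assert np.isfinite(v)
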