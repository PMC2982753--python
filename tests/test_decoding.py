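import numpy as np
import pytest
from scipy.stats import poisson

from orientpool import (
    SkewedGaussianSpec,
    SkewedUniformSpec,
    build_skewed_gaussian,
    build_skewed_uniform,
    candidate_log_rates,
    distribution_stats,
    encode_stimulus,
    loglik_profile,
    mean_response,
    ml_decode,
    sample_static_texture,
    stimulus_proportions,
    va_decode,
    wta_decode,
)


def brute_force_ml(bank, counts, duration, template=None):
    """Oracle: argmax of the *full* Poisson log-pmf over all candidates."""
    rates = np.exp(candidate_log_rates(bank, duration, template))
    ll = np.array([poisson.logpmf(counts, rates[:, c]).sum() for c in range(rates.shape[1])])
    return int(np.argmax(ll))


class TestLogLikelihood:
    def test_noiseless_point_stimulus_peaks_at_truth(self, bank):
        p = np.zeros(180)
        p[90] = 1.0
        counts = np.round(mean_response(bank, p, 1.0))
        profile = loglik_profile(bank, counts, 1.0)
        assert profile.candidates[np.argmax(profile.loglik)] == 90.0

    def test_profile_symmetric_for_symmetric_counts(self, bank):
        counts = np.zeros(180)
        counts[80] = counts[100] = 5.0
        ll = loglik_profile(bank, counts, 1.0).loglik
        lo, hi = ll[81:90], ll[91:100][::-1]
        np.testing.assert_allclose(lo, hi, rtol=1e-12)

    @pytest.mark.parametrize("template", [None, "exp3"])
    def test_matches_full_poisson_oracle(self, bank, template):
        """Eq-5 weighted-sum argmax equals the full-likelihood argmax."""
        dist = build_skewed_uniform(SkewedUniformSpec(range_ccw=75, range_cw=15), 90.0)
        tmpl = dist if template else None
        rng = np.random.default_rng(42)
        rates = mean_response(bank, stimulus_proportions(dist, bank), 0.5)
        log_rates = candidate_log_rates(bank, 0.5, tmpl)
        for _ in range(200):
            counts = rng.poisson(rates)
            mine = ml_decode(loglik_profile(bank, counts, 0.5, log_rates=log_rates))
            assert int(mine.estimate) == brute_force_ml(bank, counts, 0.5, tmpl)

    def test_rate_term_does_not_change_argmax(self, bank, rng):
        """On the wrapped uniform grid the -R_i term is candidate-independent."""
        counts = rng.poisson(5.0, size=180)
        a = loglik_profile(bank, counts, 1.0, include_rate_term=False).loglik
        b = loglik_profile(bank, counts, 1.0, include_rate_term=True).loglik
        np.testing.assert_allclose(a - a.max(), b - b.max(), atol=1e-8)


class TestMLDecode:
    def test_unique_maximum(self):
        from orientpool import LikelihoodProfile

        ll = np.zeros(180)
        ll[37] = 1.0
        est = ml_decode(LikelihoodProfile(np.arange(180.0), ll))
        assert est.estimate == 37.0 and not est.degenerate

    def test_flat_profile_degenerate(self, bank):
        from orientpool import LikelihoodProfile

        est = ml_decode(LikelihoodProfile(np.arange(180.0), np.zeros(180)))
        assert est.degenerate

    def test_tie_break_uniform(self):
        from orientpool import LikelihoodProfile

        ll = np.zeros(180)
        ll[[40, 140]] = 7.0
        picks = []
        for seed in range(2000):
            est = ml_decode(
                LikelihoodProfile(np.arange(180.0), ll), np.random.default_rng(seed)
            )
            picks.append(est.estimate)
        frac40 = np.mean(np.asarray(picks) == 40.0)
        assert 0.45 < frac40 < 0.55

    def test_consistency_for_point_stimulus(self, bank):
        """Long-duration ML estimates concentrate on the true orientation."""
        p = np.zeros(180)
        p[90] = 1.0
        rates = mean_response(bank, p, 1.3)
        log_rates = candidate_log_rates(bank, 1.3)
        rng = np.random.default_rng(0)
        ests = []
        for _ in range(2000):
            counts = rng.poisson(rates)
            ests.append(ml_decode(loglik_profile(bank, counts, 1.3, log_rates=log_rates), rng).estimate)
        assert abs(np.mean(ests) - 90.0) < 0.5


class TestWTADecode:
    def test_one_hot(self, bank):
        counts = np.zeros(180)
        counts[120] = 3
        assert wta_decode(bank, counts).estimate == 120.0

    def test_all_equal_degenerate(self, bank):
        assert wta_decode(bank, np.full(180, 4.0)).degenerate

    def test_higher_variance_than_ml_at_short_duration(self, bank):
        p = np.zeros(180)
        p[90] = 1.0
        rates = mean_response(bank, p, 0.052)
        log_rates = candidate_log_rates(bank, 0.052)
        rng = np.random.default_rng(1)
        wta_off, ml_off = [], []
        for _ in range(1500):
            counts = rng.poisson(rates)
            w = wta_decode(bank, counts, rng)
            m = ml_decode(loglik_profile(bank, counts, 0.052, log_rates=log_rates), rng)
            if not w.degenerate:
                wta_off.append((w.estimate - 90 + 90) % 180 - 90)
            if not m.degenerate:
                ml_off.append((m.estimate - 90 + 90) % 180 - 90)
        assert abs(np.mean(wta_off)) < 3.0  # centered on the truth
        assert np.std(wta_off) > np.std(ml_off)


class TestVADecode:
    def test_symmetric_counts(self, bank):
        counts = np.zeros(180)
        counts[[80, 100]] = 5.0
        assert np.isclose(va_decode(bank, counts).estimate, 90.0)

    def test_noiseless_exp1_estimate_matches_stimulus_mean(self, bank):
        dist = build_skewed_gaussian(SkewedGaussianSpec(sigma_ccw=30, sigma_cw=0), 90.0)
        rates = mean_response(bank, stimulus_proportions(dist, bank), 1.0)
        est = va_decode(bank, rates)
        expected = 90.0 + distribution_stats(dist).mean
        assert abs(est.estimate - expected) < 0.5

    def test_seam_rotation_equivariance(self, bank):
        counts = np.zeros(180)
        counts[10] = 5.0
        assert va_decode(bank, counts).estimate == pytest.approx(10.0)
        counts = np.zeros(180)
        counts[170] = 5.0
        assert va_decode(bank, counts).estimate == pytest.approx(170.0)

    def test_uniform_counts_degenerate(self, bank):
        assert va_decode(bank, np.full(180, 2.0)).degenerate

    def test_resultant_method_available(self, bank):
        counts = np.zeros(180)
        counts[45] = 1.0
        assert va_decode(bank, counts, method="resultant").estimate == pytest.approx(45.0)


@pytest.mark.parametrize("delta", [10.0, 45.0, 90.0])
def test_decoders_are_rotation_equivariant(bank, delta):
    """Rotating the stimulus by delta shifts every decoder's mean estimate by delta."""
    base = build_skewed_gaussian(SkewedGaussianSpec(sigma_ccw=20, sigma_cw=10), 30.0)
    shifted = base.rotated(delta)
    rng = np.random.default_rng(11)

    def mean_estimate(dist, decoder, n=300):
        log_rates = candidate_log_rates(bank, 0.052, dist) if decoder == "ml" else None
        offs = []
        ref = dist.reference
        while len(offs) < n:
            tex = sample_static_texture(dist, rng=rng)
            resp = encode_stimulus(bank, tex, rng)
            if decoder == "va":
                est = va_decode(bank, resp.spike_counts)
            elif decoder == "wta":
                est = wta_decode(bank, resp.spike_counts, rng)
            else:
                est = ml_decode(
                    loglik_profile(bank, resp.spike_counts, resp.duration, log_rates=log_rates), rng
                )
            if not est.degenerate:
                offs.append((est.estimate - ref + 90.0) % 180.0 - 90.0)
        return np.mean(offs)

    for decoder in ("va", "wta", "ml"):
        a = mean_estimate(base, decoder)
        b = mean_estimate(shifted, decoder)
        assert abs(a - b) < 1.0, decoder
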