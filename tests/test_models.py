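"""Closed-form model evaluation, conversions and their identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyauxic as px

E = math.e


class TestMonoauxicAnchors:
    @pytest.mark.parametrize(
        "func,x,expected",
        [
            (px.eval_boltzmann, 0.0, 1.0 / (1.0 + E**2)),  # value at the lag time
            (px.eval_boltzmann, 0.5, 0.5),                 # inflection = midpoint
            (px.eval_boltzmann, 0.75, 1.0 / (1.0 + math.exp(-1))),  # x0 + gamma
            (px.eval_gompertz, 0.0, math.exp(-E)),
            (px.eval_gompertz, 1.0 / E, 1.0 / E),          # ordinate at inflection
            (px.eval_gompertz, 1e4, 1.0),                  # upper asymptote
        ],
    )
    def test_unit_sigmoid_anchor_points(self, func, x, expected):
        assert func(0.0, 1.0, 1.0, 0.0, x) == pytest.approx(expected, abs=1e-9)

    def test_lag_point_is_12_percent_of_amplitude(self):
        val = px.eval_boltzmann(2.0, 10.0, 3.0, 4.0, 4.0)
        assert (val - 2.0) / 8.0 == pytest.approx(1.0 / (1.0 + E**2), abs=1e-12)

    def test_gamma_marks_27_and_73_percent_points(self):
        cb = px.CanonicalBoltzmann(yi=0.0, yf=1.0, x0=3.0, gamma=0.7)
        assert round(100 * cb(cb.x0 - cb.gamma)) == 27
        assert round(100 * cb(cb.x0 + cb.gamma)) == 73

    def test_overflow_saturates_to_asymptotes(self):
        assert px.eval_boltzmann(0, 1, 1000.0, 5.0, -1e6) == pytest.approx(0.0)
        assert px.eval_boltzmann(0, 1, 1000.0, 5.0, 1e6) == pytest.approx(1.0)
        assert px.eval_gompertz(0, 1, 1000.0, 5.0, -1e6) == pytest.approx(0.0)

    def test_degenerate_amplitude_rejected(self):
        with pytest.raises(ValueError):
            px.eval_boltzmann(1.0, 1.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            px.eval_gompertz(0.0, 1.0, -1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            px.eval_gompertz(0.0, math.nan, 1.0, 0.0, 0.0)


params = st.tuples(
    st.floats(-5, 5),          # yi
    st.floats(0.1, 50),        # amplitude
    st.floats(-10, 10),        # x0 (Boltzmann) / lam-ish
    st.floats(0.05, 5),        # gamma or c
)


class TestCanonicalEquivalence:
    @settings(max_examples=50, derandomize=True)
    @given(params, st.integers(0, 2**31 - 1))
    def test_boltzmann_canonical_matches_reparam(self, ps, seed):
        yi, amp, x0, gamma = ps
        cb = px.CanonicalBoltzmann(yi, yi + amp, x0, gamma)
        rmax, lam = px.boltzmann_canonical_to_reparam(cb)
        x = np.random.default_rng(seed).uniform(x0 - 10 * gamma, x0 + 10 * gamma, 100)
        np.testing.assert_allclose(
            px.eval_boltzmann(yi, yi + amp, rmax, lam, x), cb(x), atol=1e-10
        )

    @settings(max_examples=50, derandomize=True)
    @given(params, st.integers(0, 2**31 - 1))
    def test_gompertz_canonical_matches_reparam(self, ps, seed):
        yi, amp, lnb, c = ps
        cg = px.CanonicalGompertz(yi, yi + amp, math.exp(lnb), c)
        rmax, lam = px.gompertz_canonical_to_reparam(cg)
        x = np.random.default_rng(seed).uniform(lnb / c - 10 / c, lnb / c + 10 / c, 100)
        np.testing.assert_allclose(
            px.eval_gompertz(yi, yi + amp, rmax, lam, x), cg(x), atol=1e-10
        )

    @settings(max_examples=50, derandomize=True)
    @given(params)
    def test_boltzmann_round_trip(self, ps):
        yi, amp, x0, gamma = ps
        cb = px.CanonicalBoltzmann(yi, yi + amp, x0, gamma)
        rmax, lam = px.boltzmann_canonical_to_reparam(cb)
        back = px.boltzmann_reparam_to_canonical(yi, yi + amp, rmax, lam)
        assert back.x0 == pytest.approx(x0, abs=1e-12, rel=1e-12)
        assert back.gamma == pytest.approx(gamma, abs=1e-12, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(params)
    def test_gompertz_round_trip(self, ps):
        yi, amp, lnb, c = ps
        cg = px.CanonicalGompertz(yi, yi + amp, math.exp(lnb), c)
        rmax, lam = px.gompertz_canonical_to_reparam(cg)
        back = px.gompertz_reparam_to_canonical(yi, yi + amp, rmax, lam)
        assert math.log(back.b) == pytest.approx(lnb, abs=1e-10)
        assert back.c == pytest.approx(c, rel=1e-12)

    def test_conversion_worked_examples(self):
        rmax, lam = px.boltzmann_canonical_to_reparam(
            px.CanonicalBoltzmann(0, 1, 0.5, 0.25)
        )
        assert (rmax, lam) == pytest.approx((1.0, 0.0))
        rmax, lam = px.boltzmann_canonical_to_reparam(
            px.CanonicalBoltzmann(0, 2, 10.0, 1.0)
        )
        assert (rmax, lam) == pytest.approx((0.5, 8.0))
        rmax, lam = px.gompertz_canonical_to_reparam(
            px.CanonicalGompertz(0, 1, math.e, 1.0)
        )
        assert rmax == pytest.approx(1 / E)
        assert lam == pytest.approx(0.0, abs=1e-12)
        # inflection abscissa x0 = ln b / c
        cg = px.CanonicalGompertz(0, 1, math.e**2, 1.0)
        rmax, lam = px.gompertz_canonical_to_reparam(cg)
        assert px.inflection_time("gompertz", 0, 1, rmax, lam) == pytest.approx(2.0)


class TestPolyauxic:
    def test_single_phase_reduces_to_monoauxic(self):
        x = np.linspace(-5, 30, 101)
        for family, mono in (
            ("boltzmann", px.eval_boltzmann),
            ("gompertz", px.eval_gompertz),
        ):
            m = px.KineticModel(family, 1.0, 4.0, [px.PhaseParams(1.0, 2.0, 0.7)])
            np.testing.assert_allclose(
                px.eval_polyauxic(m, x), mono(1.0, 4.0, 0.7, 2.0, x), rtol=1e-12
            )

    def test_interphase_plateau_of_well_separated_diauxic(self):
        m = px.KineticModel(
            "boltzmann", 0, 1, [px.PhaseParams(0.5, 0.0, 1.0), px.PhaseParams(0.5, 50.0, 1.0)]
        )
        # brute-force sum of the two phase terms
        a1 = px.eval_boltzmann(0, 0.5, 1.0, 0.0, 25.0)
        a2 = px.eval_boltzmann(0, 0.5, 1.0, 50.0, 25.0)
        assert px.eval_polyauxic(m, 25.0) == pytest.approx(a1 + a2, abs=1e-12)
        assert px.eval_polyauxic(m, 25.0) == pytest.approx(0.5, abs=1e-6)

    def test_asymptotic_normalization(self, diauxic_truth):
        assert px.eval_polyauxic(diauxic_truth, 1e6) == pytest.approx(1.0, abs=1e-9)
        assert px.eval_polyauxic(diauxic_truth, -1e6) == pytest.approx(0.0, abs=1e-9)

    def test_composite_rate_nonnegative_and_matches_finite_difference(self):
        rng = np.random.default_rng(42)
        for family in ("boltzmann", "gompertz"):
            for _ in range(10):
                n = rng.integers(1, 4)
                p = rng.dirichlet(np.ones(n))
                lams = np.sort(rng.uniform(0, 50, n))
                lams += np.arange(n) * 1e-3
                model = px.KineticModel(
                    family,
                    0.0,
                    float(rng.uniform(0.5, 10)),
                    [
                        px.PhaseParams(float(p[j]), float(lams[j]), float(rng.uniform(0.01, 2)))
                        for j in range(n)
                    ],
                )
                x = rng.uniform(-10, 80, 50)
                h = 1e-5
                fd = (px.eval_polyauxic(model, x + h) - px.eval_polyauxic(model, x - h)) / (2 * h)
                an = px.rate_polyauxic(model, x)
                np.testing.assert_allclose(an, fd, atol=1e-6)
                assert np.all(an >= -1e-12)

    def test_rate_peaks_at_rmax_at_inflection(self):
        assert px.rate_polyauxic(
            px.KineticModel("boltzmann", 0, 1, [px.PhaseParams(1.0, 0.0, 1.0)]), 0.5
        ) == pytest.approx(1.0)
        assert px.rate_polyauxic(
            px.KineticModel("gompertz", 0, 1, [px.PhaseParams(1.0, 0.0, 1.0)]), 1 / E
        ) == pytest.approx(1.0)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            px.KineticModel("boltzmann", 0, 1, [])
        with pytest.raises(ValueError):
            px.KineticModel(
                "boltzmann", 0, 1,
                [px.PhaseParams(0.5, 0.0, 1.0), px.PhaseParams(0.6, 5.0, 1.0)],
            )
        with pytest.raises(ValueError):  # lag ordering
            px.KineticModel(
                "boltzmann", 0, 1,
                [px.PhaseParams(0.5, 5.0, 1.0), px.PhaseParams(0.5, 2.0, 1.0)],
            )


class TestFirstOrder:
    def test_values_and_asymptote(self):
        assert px.eval_first_order(100.0, 0.1, 0.0) == 0.0
        assert px.eval_first_order(100.0, 0.1, 10.0) == pytest.approx(100 * (1 - math.exp(-1)))
        assert px.eval_first_order(100.0, 0.1, 1e6) == pytest.approx(100.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            px.eval_first_order(100.0, 0.1, -1.0)


class TestSpecificGrowthRateConversion:
    def test_boltzmann_and_gompertz_conversions(self):
        assert px.mu_max_to_rmax("boltzmann", 0.2, 0.0, 2.0) == pytest.approx(0.2)
        assert px.mu_max_to_rmax("gompertz", 0.2, 0.0, 2.0) == pytest.approx(0.4 / E)

    def test_inverse_round_trip(self):
        for family in ("boltzmann", "gompertz"):
            r = px.mu_max_to_rmax(family, 0.37, 0.5, 3.1)
            assert px.rmax_to_mu_max(family, r, 0.5, 3.1) == pytest.approx(0.37)

    def test_degenerate_amplitude_flagged(self):
        with pytest.raises(ValueError):
            px.mu_max_to_rmax("boltzmann", 0.2, 2.0, 2.0)


class TestMonodSaturation:
    def test_exact_recovery_from_noiseless_design(self):
        s = np.array([1.0, 2.0, 10.0, 50.0])
        r = 10.0 * s / (2.0 + s)
        fit = px.fit_monod_saturation(s, r)
        assert fit.rstar == pytest.approx(10.0, abs=1e-6)
        assert fit.km == pytest.approx(2.0, abs=1e-6)

    def test_half_saturation_identity(self):
        mp = px.MonodParams(rstar=8.0, km=3.0)
        assert mp.rate(3.0) == pytest.approx(4.0)

    def test_noisy_recovery_within_ten_percent(self):
        s = np.array([1.0, 2.0, 10.0, 50.0])
        truth = 10.0 * s / (2.0 + s)
        rstars, kms = [], []
        for seed in range(100):
            noisy = truth + np.random.default_rng(seed).normal(0, 0.1, s.size)
            fit = px.fit_monod_saturation(s, np.clip(noisy, 1e-6, None))
            rstars.append(fit.rstar)
            kms.append(fit.km)
        assert abs(np.median(rstars) / 10.0 - 1) < 0.10
        assert abs(np.median(kms) / 2.0 - 1) < 0.10

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            px.fit_monod_saturation([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
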