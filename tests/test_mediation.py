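"""Saturated standardized mediation model: closed forms, oracles, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from blinkpath import (
    CorrelationInput,
    MediationModel,
    TraitSampleSpec,
    bootstrap_indirect,
    classify_effect,
    corr_from_data,
    fit_mediation,
    fit_mediation_from_data,
    generate_trait_sample,
)

r_st = st.floats(-0.95, 0.95)


def psd_triple(r_xm, r_xy, r_my):
    m = np.array([[1, r_xm, r_xy], [r_xm, 1, r_my], [r_xy, r_my, 1]])
    return np.min(np.linalg.eigvalsh(m)) > 1e-6


class TestCorrelationInput:
    def test_range_validation(self):
        with pytest.raises(ValueError):
            CorrelationInput(1.2, 0.0, 0.0, 50)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError, match="semi-definite"):
            CorrelationInput(0.9, -0.9, 0.9, 50)

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            CorrelationInput(0.1, 0.1, 0.1, 3)


class TestCorrFromData:
    def test_identical_vectors_all_unit(self, rng):
        x = rng.standard_normal(20)
        c = corr_from_data(x, x.copy(), x.copy())
        assert c.r_xm == pytest.approx(1.0)
        assert c.r_xy == pytest.approx(1.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_mediation(c)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            corr_from_data(np.ones(10), rng.standard_normal(10), rng.standard_normal(10))

    def test_independent_vectors_near_zero(self, rng):
        x, m, y = rng.standard_normal((3, 10_000))
        c = corr_from_data(x, m, y)
        assert max(abs(c.r_xm), abs(c.r_xy), abs(c.r_my)) < 0.05

    def test_cholesky_roundtrip_to_targets(self):
        spec = TraitSampleSpec(n=100_000, seed=11)
        df = generate_trait_sample(spec)
        c = corr_from_data(
            df["negative_emotionality"], df["stress"], df["objective_blink"]
        )
        assert c.r_xm == pytest.approx(0.35, abs=0.01)
        assert c.r_xy == pytest.approx(-0.17, abs=0.01)
        assert c.r_my == pytest.approx(0.27, abs=0.01)


class TestFitMediation:
    def test_suppression_triangle(self):
        """Neuroticism -> stress -> blink rate: the direct path strengthens
        and flips sign once the mediator enters (suppression)."""
        m = fit_mediation(CorrelationInput(0.35, -0.17, 0.27, 86))
        assert round(m.a, 2) == 0.35
        assert round(m.c_prime, 2) == -0.30
        assert round(m.b, 2) == 0.38
        assert round(m.r2_m, 2) == 0.12
        assert round(m.r2_y, 2) == 0.15
        assert m.classification == "suppression"
        # finite-sample t statistics track the published asymptotic ones
        assert m.t_a == pytest.approx(3.43, abs=0.1)
        assert m.t_b == pytest.approx(3.53, abs=0.1)
        assert m.t_cprime == pytest.approx(-2.81, abs=0.1)

    def test_indirect_only_triangle(self):
        m = fit_mediation(CorrelationInput(-0.26, 0.001, 0.27, 86))
        assert round(m.c_prime, 2) == 0.08
        assert round(m.b, 2) == 0.29
        assert m.r2_m == pytest.approx(0.07, abs=0.005)
        assert m.r2_y == pytest.approx(0.08, abs=0.005)
        assert m.classification == "indirect-only"
        assert m.t_a == pytest.approx(-2.45, abs=0.1)
        assert m.t_b == pytest.approx(2.71, abs=0.1)
        assert m.t_cprime == pytest.approx(0.71, abs=0.1)

    def test_no_mediator_association(self):
        m = fit_mediation(CorrelationInput(0.0, 0.3, 0.2, 100))
        assert m.a == 0 and m.indirect == 0
        assert m.c_prime == pytest.approx(0.3)
        assert m.b == pytest.approx(0.2)

    @settings(derandomize=True, deadline=None, max_examples=300)
    @given(r_xm=r_st, r_xy=r_st, r_my=r_st, n=st.integers(10, 500))
    def test_exact_effect_decomposition(self, r_xm, r_xy, r_my, n):
        """c = c' + a*b holds to 1e-12 for every admissible correlation triple."""
        assume(psd_triple(r_xm, r_xy, r_my))
        m = fit_mediation(CorrelationInput(r_xm, r_xy, r_my, n))
        assert abs(m.c_total - (m.c_prime + m.indirect)) < 1e-12

    def test_fit_from_raw_equals_fit_from_correlations(self, rng):
        df = generate_trait_sample(TraitSampleSpec(n=500, seed=3))
        x, m_, y = (df[c].to_numpy() for c in ("negative_emotionality", "stress", "objective_blink"))
        direct = fit_mediation_from_data(x, m_, y)
        via_corr = fit_mediation(corr_from_data(x, m_, y))
        for f in ("a", "b", "c_prime", "indirect", "r2_y"):
            assert getattr(direct, f) == pytest.approx(getattr(via_corr, f), abs=1e-12)

    def test_normal_equation_oracle(self, rng):
        """b and c' must solve the standardized two-predictor regression;
        cross-checked against an explicit 2x2 inversion and statsmodels."""
        import statsmodels.api as sm

        df = generate_trait_sample(TraitSampleSpec(n=400, seed=8))
        x, m_, y = (df[c].to_numpy() for c in ("negative_emotionality", "stress", "objective_blink"))
        x = (x - x.mean()) / x.std(ddof=1)
        m_ = (m_ - m_.mean()) / m_.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        fit = fit_mediation_from_data(x, m_, y)

        r_xm = np.corrcoef(x, m_)[0, 1]
        rhs = np.array([np.corrcoef(x, y)[0, 1], np.corrcoef(m_, y)[0, 1]])
        gram = np.array([[1.0, r_xm], [r_xm, 1.0]])
        det = gram[0, 0] * gram[1, 1] - gram[0, 1] * gram[1, 0]
        inv = np.array([[gram[1, 1], -gram[0, 1]], [-gram[1, 0], gram[0, 0]]]) / det
        beta = inv @ rhs
        assert fit.c_prime == pytest.approx(beta[0], abs=1e-10)
        assert fit.b == pytest.approx(beta[1], abs=1e-10)

        ols = sm.OLS(y, np.column_stack([x, m_])).fit()
        assert fit.c_prime == pytest.approx(ols.params[0], abs=1e-8)
        assert fit.b == pytest.approx(ols.params[1], abs=1e-8)


class TestClassification:
    def _model(self, indirect, c_prime, p_a=0.01, p_b=0.01, p_c=0.01):
        a = 0.5 if indirect >= 0 else -0.5
        b = indirect / a
        return MediationModel(
            a=a, b=b, c_prime=c_prime, c_total=c_prime + indirect,
            indirect=indirect, r2_m=a * a, r2_y=0.2,
            t_a=0, t_b=0, t_cprime=0, p_a=p_a, p_b=p_b, p_cprime=p_c,
            n=100, classification="",
        )

    def test_consistent_mediation_same_signs(self):
        assert classify_effect(self._model(0.25, 0.3)) == "consistent-mediation"

    def test_suppression_opposite_signs(self):
        assert classify_effect(self._model(0.25, -0.3)) == "suppression"

    def test_indirect_only_when_direct_ns(self):
        assert classify_effect(self._model(0.25, 0.05, p_c=0.5)) == "indirect-only"

    def test_no_effect_when_indirect_ns(self):
        assert classify_effect(self._model(0.02, 0.3, p_a=0.6)) == "no-effect"


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        x, m, y = rng.standard_normal((3, 100))
        ci1 = bootstrap_indirect(x, m, y, replicates=1000, seed=7)
        ci2 = bootstrap_indirect(x, m, y, replicates=1000, seed=7)
        assert ci1 == ci2

    def test_power_case_excludes_zero(self, rng):
        n = 500
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n) * math.sqrt(0.75)
        y = 0.5 * m + rng.standard_normal(n) * math.sqrt(0.75)
        ci = bootstrap_indirect(x, m, y, replicates=2000, seed=1)
        assert ci.lower > 0
        assert ci.lower <= ci.estimate <= ci.upper

    def test_null_interval_is_never_anticonservative(self, rng):
        """Percentile intervals for a product of coefficients are known to be
        conservative at the complete null: coverage of zero should be at
        least nominal."""
        cover = 0
        for _ in range(100):
            x, m, y = rng.standard_normal((3, 200))
            ci = bootstrap_indirect(x, m, y, replicates=1000,
                                    seed=int(rng.integers(2**31)))
            cover += ci.lower <= 0 <= ci.upper
        assert cover >= 95

    def test_guards(self, rng):
        x, m, y = rng.standard_normal((3, 100))
        with pytest.raises(ValueError):
            bootstrap_indirect(x, m, y, replicates=10)
        with pytest.raises(ValueError):
            bootstrap_indirect(x[:5], m[:5], y[:5])
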