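"""Operational allosteric model: reductions, EC50 oracles, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allofit.curves import LogisticParams, NonIdentifiableWarning, logistic3_predict
from allofit.operational import (
    NoEC50Error,
    OperationalModel,
    OperationalParams,
    fit_operational,
    gain_in_potency,
    observed_ec50,
    operational_effect,
    predicted_affinity_shift,
    round_up_emax,
)
from allofit.synthetic import SimConfig, simulate_assay
from .conftest import WT_SURFACE_TRUTH


def closed_form_ec50_taub0(p: OperationalParams, b: float) -> float:
    """Independent algebra for n=1, tau_B=0: EC50 = KA(KB+b)/(KB+ab+tauA(KB+abb))."""
    ka, kb, a, bb, tau = p.ka, p.kb, p.alpha, p.alpha * p.beta, p.tau_a
    return ka * (kb + b) / (kb + a * b + tau * (kb + bb * b))


class TestForwardModel:
    def test_zero_zero_is_zero(self, wt_params):
        assert operational_effect(wt_params, 0.0, 0.0) == 0.0

    def test_reduces_to_logistic_at_b_zero(self, wt_params):
        p = wt_params
        top = p.emax * p.tau_a / (1 + p.tau_a)
        ec50 = p.ka / (1 + p.tau_a)
        lp = LogisticParams(0.0, top, np.log10(ec50))
        a = np.logspace(-12, -7, 20)
        dev = np.abs(operational_effect(p, a, np.zeros_like(a)) - logistic3_predict(lp, a))
        assert dev.max() <= 1e-12

    def test_neutral_cooperativity_makes_effect_b_independent(self):
        p = OperationalParams(emax=100, log_ka=-8, log_kb=-6, tau_a=4, tau_b=0.0,
                              log_alpha=0.0, log_beta=0.0)
        a = np.logspace(-11, -6, 12)
        grid_b = [0.0, 1e-8, 1e-7, 1e-6, 1e-5]
        ref = operational_effect(p, a, np.zeros_like(a))
        for b in grid_b[1:]:
            dev = np.abs(operational_effect(p, a, np.full_like(a, b)) - ref)
            assert dev.max() <= 1e-12

    def test_bounded_and_monotone(self, wt_params, rng):
        a = np.sort(rng.uniform(0, 1e-6, 200))
        for b in (0.0, 1e-7, 1e-5):
            e = operational_effect(wt_params, a, np.full_like(a, b))
            assert np.all(e >= 0) and np.all(e < wt_params.emax)
            assert np.all(np.diff(e) >= -1e-12)

    def test_swap_invariance_when_efficacies_equal(self, rng):
        # the alpha*beta numerator term carries tau_A, so the A<->B swap is an
        # exact invariance only when tau_A == tau_B
        for _ in range(20):
            tau = rng.uniform(0.2, 10)
            p = OperationalParams(
                emax=100, log_ka=rng.uniform(-10, -6), log_kb=rng.uniform(-8, -5),
                tau_a=tau, tau_b=tau,
                log_alpha=rng.uniform(-1, 2), log_beta=rng.uniform(-1, 1),
            )
            q = OperationalParams(
                emax=100, log_ka=p.log_kb, log_kb=p.log_ka, tau_a=p.tau_b,
                tau_b=p.tau_a, log_alpha=p.log_alpha, log_beta=p.log_beta,
            )
            a, b = rng.uniform(0, 1e-5, 2)
            assert operational_effect(p, a, b) == pytest.approx(
                operational_effect(q, b, a), rel=1e-10, abs=1e-12
            )


class TestObservedEc50:
    def test_closed_form_at_b_zero(self):
        p = OperationalParams(emax=100, log_ka=-8, log_kb=-6, tau_a=5.0, tau_b=0,
                              log_alpha=0.5, log_beta=0.2)
        assert observed_ec50(p, 0.0) == pytest.approx(1e-8 / 6.0, rel=1e-9)

    def test_matches_independent_algebra_taub_zero(self, rng):
        for _ in range(100):
            p = OperationalParams(
                emax=100.0,
                log_ka=rng.uniform(-10, -7),
                log_kb=rng.uniform(-8, -5),
                tau_a=rng.uniform(0.5, 20),
                tau_b=0.0,
                log_alpha=rng.uniform(-1, 2),
                log_beta=rng.uniform(-1, 1),
            )
            b = 10.0 ** rng.uniform(-8, -5)
            assert observed_ec50(p, b) == pytest.approx(
                closed_form_ec50_taub0(p, b), rel=1e-9
            )

    def test_pam_monotonicity(self, wt_params):
        bs = np.logspace(-9, -5, 15)
        ec = [observed_ec50(wt_params, b) for b in bs]
        assert np.all(np.diff(ec) <= 1e-18)

    def test_flat_profile_raises(self):
        p = OperationalParams(emax=100, log_ka=-8, log_kb=-6, tau_a=0.0, tau_b=0.5,
                              log_alpha=0.0, log_beta=0.0)
        with pytest.raises(NoEC50Error):
            observed_ec50(p, 0.0)


class TestGainInPotency:
    def test_zero_without_modulation(self):
        p = OperationalParams(emax=100, log_ka=-8, log_kb=-6, tau_a=5, tau_b=0,
                              log_alpha=0.0, log_beta=0.0)
        assert gain_in_potency(p) == pytest.approx(0.0, abs=1e-10)

    def test_equals_log_ratio_of_bruteforce_ec50s(self, wt_params):
        g = gain_in_potency(wt_params, b_ref=1e-6)
        expect = np.log10(observed_ec50(wt_params, 0.0) / observed_ec50(wt_params, 1e-6))
        assert g == pytest.approx(expect, abs=1e-8)

    def test_recoverable_by_refitting_simulated_surfaces(self):
        # wild-type-scale inputs; beta and tau are generator choices
        p = OperationalParams(emax=110, log_ka=-8.83, log_kb=-6.16, tau_a=5.0,
                              tau_b=0.3, log_alpha=1.62, log_beta=0.3)
        truth_gain = gain_in_potency(p)
        gains = []
        for s in range(1, 16):
            surf, _ = simulate_assay(
                SimConfig(model="operational",
                          truth=dict(emax=110, log_ka=-8.83, log_kb=-6.16, tau_a=5.0,
                                     tau_b=0.3, log_alpha=1.62, log_beta=0.3),
                          noise_sd=5.0, seed=s)
            )
            gains.append(fit_operational(surf, {"emax": 110.0}, seed=s).gain_in_potency)
        assert np.mean(gains) == pytest.approx(truth_gain, abs=0.15)


class TestAffinityShift:
    def test_neutral_alpha_gives_zero(self):
        for b in (0.0, 1e-9, 1e-5):
            assert predicted_affinity_shift(-6.0, 0.0, b) == 0.0

    def test_saturates_at_log_alpha(self):
        kb = 10 ** -6.16
        assert predicted_affinity_shift(-6.16, 1.62, kb * 1e9) == pytest.approx(
            1.62, abs=1e-6
        )

    def test_wildtype_scale_value(self):
        # closed form with logKB=-6.16, logalpha=1.62, b=1 uM:
        # log10[(1 + 41.687*1.4454)/(1 + 1.4454)] = 1.399
        assert predicted_affinity_shift(-6.16, 1.62, 1e-6) == pytest.approx(
            1.399, abs=1e-3
        )


class TestFit:
    def test_noiseless_recovery(self, noiseless_surface):
        surf, truth = noiseless_surface
        fit = fit_operational(surf, {"emax": truth["params"]["emax"]})
        for name in ("log_ka", "log_kb", "log_alpha", "log_beta"):
            assert getattr(fit.params, name) == pytest.approx(
                truth["params"][name], abs=1e-4
            )
        assert np.log10(fit.params.tau_a) == pytest.approx(
            np.log10(truth["params"]["tau_a"]), abs=1e-4
        )
        assert fit.fixed == {"emax": 110.0, "n": 1.0}

    def test_boundary_taub_zero_recovered(self):
        truth = dict(WT_SURFACE_TRUTH, tau_b=0.0)
        surf, _ = simulate_assay(
            SimConfig(model="operational", truth=truth, noise_sd=0.0, seed=4)
        )
        fit = fit_operational(surf, {"emax": 110.0})
        assert fit.params.tau_b <= 1e-3

    def test_emax_below_observed_mean_rejected(self, noiseless_surface):
        surf, _ = noiseless_surface
        with pytest.raises(ValueError, match="emax"):
            fit_operational(surf, {"emax": 10.0})

    def test_single_modulator_level_flags_alpha_beta(self):
        surf, _ = simulate_assay(
            SimConfig(model="operational", truth=WT_SURFACE_TRUTH,
                      design={"b_grid": [0.0, 1e-6]}, noise_sd=0.0, seed=9)
        )
        with pytest.warns(NonIdentifiableWarning):
            fit = fit_operational(surf, {"emax": 110.0})
        assert any("alpha" in w or "beta" in w for w in fit.warnings)

    def test_auto_emax_rounds_up_to_multiple_of_ten(self, noiseless_surface):
        surf, _ = noiseless_surface
        fit = fit_operational(surf, {"emax": "auto"})
        peak = max(
            surf.signal[(surf.conc_a == a) & (surf.conc_b == b)].mean()
            for a in surf.ortho_concentrations for b in surf.allo_concentrations
        )
        assert fit.fixed["emax"] == round_up_emax(peak)
        assert fit.fixed["emax"] % 10 == 0


class TestRoundUpEmax:
    @pytest.mark.parametrize("x,expected", [(91.3, 100.0), (100.0, 100.0), (101.0, 110.0)])
    def test_multiple_of_ten(self, x, expected):
        assert round_up_emax(x) == expected

    def test_plain_ceiling_option(self):
        assert round_up_emax(91.3, multiple=None) == 92.0


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = OperationalModel(emax=110.0, n_starts=4, seed=2)
        est2 = OperationalModel().set_params(**est.get_params())
        assert est2.emax == 110.0 and est2.n_starts == 4

    def test_predict_reproduces_surface(self, noiseless_surface):
        surf, _ = noiseless_surface
        X = np.column_stack([surf.conc_a, surf.conc_b])
        est = OperationalModel(emax=110.0).fit(X, surf.signal)
        np.testing.assert_allclose(est.predict(X), surf.signal, atol=1e-6)


@given(
    log_ka=st.floats(-10, -6),
    log_kb=st.floats(-8, -5),
    tau_a=st.floats(0.2, 20),
    tau_b=st.floats(0.0, 2),
    log_alpha=st.floats(-1, 2),
    log_beta=st.floats(-1, 1),
)
@settings(max_examples=40, deadline=None)
def test_effect_bounded_for_random_params(log_ka, log_kb, tau_a, tau_b,
                                          log_alpha, log_beta):
    """E stays within [0, Emax) over a concentration grid for any valid params."""
    p = OperationalParams(emax=100.0, log_ka=log_ka, log_kb=log_kb, tau_a=tau_a,
                          tau_b=tau_b, log_alpha=log_alpha, log_beta=log_beta)
    a = np.logspace(-12, -4, 9)
    b = np.logspace(-10, -4, 7)
    aa, bb = np.meshgrid(a, b)
    e = operational_effect(p, aa.ravel(), bb.ravel())
    assert np.all(e >= 0.0) and np.all(e < p.emax)
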