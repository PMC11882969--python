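"""NCA against closed forms, LLOQ rules, dialysis/stability/permeability."""

import numpy as np
import pytest

from cb1triage.pk import (
    DialysisAreas,
    PKError,
    PKProfile,
    apply_lloq,
    decay_kinetics,
    nca,
    papp_efflux,
    protein_binding,
    recovery,
    stability,
)


def mono_exp_profile(c0=100.0, ke=0.00693, times=None, lloq=0.0):
    t = np.asarray(times if times is not None else np.arange(1.0, 1500.0, 2.0))
    return PKProfile("plasma", t, c0 * np.exp(-ke * t), lloq=lloq, route="bolus")


class TestNCA:
    def test_dense_mono_exponential_closed_form(self):
        """AUC_inf ~ C0/ke = 14430 and T1/2 ~ 100 min for ke = ln2/100."""
        res = nca(mono_exp_profile())
        assert res.auc_inf == pytest.approx(100.0 / 0.00693, rel=0.05)
        assert res.t_half == pytest.approx(100.0, rel=0.05)
        assert res.auc_inf >= res.auc_last

    def test_two_point_profile_auc_only(self):
        prof = PKProfile("plasma", [10.0, 60.0], [80.0, 40.0])
        res = nca(prof)
        assert res.auc_last == pytest.approx(0.5 * (80 + 40) * 50)
        assert res.lambda_z is None and res.t_half is None and res.auc_inf is None
        assert "unestimable" in res.status

    def test_rising_tail_unestimable(self):
        prof = PKProfile("plasma", [10, 20, 30, 40.0], [50, 40, 45, 60.0])
        res = nca(prof)
        assert res.lambda_z is None
        assert "non-negative terminal slope" in res.status

    def test_trapezoid_error_shrinks_under_refinement(self):
        """Chords sit above a convex decay, so the linear trapezoid
        overestimates the integral over the sampled window; the error
        shrinks monotonically as sampling densifies and the extrapolated
        AUC converges to the closed form."""
        ke, truth = 0.00693, 100.0 / 0.00693
        exact_window = (100.0 - 100.0 * np.exp(-ke * 1200.0)) / ke
        errors = []
        for n in (8, 16, 32, 64):
            t = np.linspace(1e-6, 1200.0, n)
            trap = nca(mono_exp_profile(times=t)).auc_last
            assert trap >= exact_window
            errors.append(trap - exact_window)
        assert all(b < a for a, b in zip(errors, errors[1:]))
        res = nca(mono_exp_profile(times=np.linspace(1e-6, 1200.0, 512)))
        assert res.auc_inf == pytest.approx(truth, rel=0.01)

    def test_unit_consistency(self):
        prof = mono_exp_profile()
        res1 = nca(prof)
        scaled = PKProfile("plasma", prof.times, prof.concentrations * 7.5,
                           route="bolus")
        res2 = nca(scaled)
        assert res2.auc_last == pytest.approx(res1.auc_last * 7.5)
        assert res2.auc_inf == pytest.approx(res1.auc_inf * 7.5)
        assert res2.t_half == pytest.approx(res1.t_half)

    def test_best_r2_lambda_selection(self):
        res = nca(mono_exp_profile(), lambda_mode="best-r2")
        assert res.t_half == pytest.approx(100.0, rel=0.05)
        assert res.n_lambda_points >= 3


class TestLLOQ:
    def test_identity_when_all_quantifiable(self):
        prof = mono_exp_profile(lloq=1e-9)
        out = apply_lloq(prof, "auc")
        np.testing.assert_array_equal(out.concentrations, prof.concentrations)

    def test_auc_purpose_zeroes(self):
        prof = PKProfile("plasma", [10, 20.0], [5.0, 1.9], lloq=2.0)
        out = apply_lloq(prof, "auc")
        assert out.concentrations[1] == 0.0

    def test_t_half_purpose_excludes(self):
        t = np.array([100, 200, 300, 400, 500.0])
        c = np.array([80, 40, 20, 10, 1.9])
        prof = PKProfile("plasma", t, c, lloq=2.0)
        res = nca(prof)
        # regression must use (200,300,400), not the censored 500 point
        assert res.n_lambda_points == 3
        assert res.t_half == pytest.approx(100.0, rel=0.02)


class TestDialysisEquations:
    def test_protein_binding(self):
        assert protein_binding(DialysisAreas(0.2, 1.0)) == pytest.approx(80.0)
        assert protein_binding(DialysisAreas(0.0, 1.0)) == 100.0

    def test_binding_plus_free_is_hundred(self):
        d = DialysisAreas(0.37, 0.91)
        assert protein_binding(d) + 100.0 * d.buffer / d.plasma == \
            pytest.approx(100.0)

    def test_recovery(self):
        d = DialysisAreas(0.2, 0.75, stability_sample=1.0)
        assert recovery(d) == pytest.approx(95.0)

    def test_stability(self):
        d = DialysisAreas(0.2, 0.75, stability_sample=1.0, recovery_sample=0.9)
        assert stability(d) == pytest.approx(90.0)

    def test_zero_denominators_rejected(self):
        with pytest.raises(PKError):
            protein_binding(DialysisAreas(0.2, 0.0))
        with pytest.raises(PKError):
            recovery(DialysisAreas(0.2, 0.75, stability_sample=0.0))


class TestDecayKinetics:
    def test_printed_arithmetic(self):
        """Slope -0.0173/min gives T1/2 = 40.1 min, Clint = 41.2 uL/min/mg."""
        t = np.array([0, 10, 20, 30, 40.0])
        res = decay_kinetics(t, -0.0173 * t)
        assert res.kel == pytest.approx(0.0173)
        assert res.t_half == pytest.approx(40.07, abs=0.05)
        assert res.clint == pytest.approx(41.19, abs=0.05)

    def test_half_life_recovered_from_decay_series(self):
        """A series generated with a 41-minute half-life returns 41 min."""
        kel = np.log(2) / 41.0
        t = np.linspace(0, 120, 5)
        res = decay_kinetics(t, np.log(100.0) - kel * t)
        assert res.t_half == pytest.approx(41.0, rel=1e-9)

    def test_flat_series_reports_no_decay(self):
        res = decay_kinetics([0, 10, 20.0], [4.6, 4.6, 4.6])
        assert res.status == "no measurable decay"
        assert res.t_half is None and res.clint is None

    def test_too_few_points(self):
        with pytest.raises(PKError):
            decay_kinetics([0, 10.0], [1.0, 0.5])


class TestPermeability:
    def test_linear_accumulation_closed_form(self):
        t = np.linspace(0, 5400, 7)
        k = 2.5e-4  # amount / s
        res = papp_efflux(t, k * t, 2 * k * t, area_cm2=0.7, donor_conc0=10.0)
        assert res.papp_ab == pytest.approx(k / (0.7 * 10.0), rel=1e-9)
        assert res.efflux_ratio == pytest.approx(2.0)

    def test_equal_bidirectional_ratio_one(self):
        t = np.linspace(0, 3600, 5)
        res = papp_efflux(t, 3e-4 * t, 3e-4 * t, 1.0, 5.0)
        assert res.efflux_ratio == pytest.approx(1.0)

    def test_zero_ab_gives_explicit_status(self):
        t = np.linspace(0, 3600, 5)
        res = papp_efflux(t, np.zeros_like(t), 1e-4 * t, 1.0, 5.0)
        assert res.efflux_ratio is None
        assert "zero A->B" in res.status
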