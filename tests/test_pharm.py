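"""Curve fitting, hit calling, affinity metrics, MPO, bias arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cb1triage.pharm import (
    BRETCalibration,
    ConcResponse,
    MPODescriptors,
    PathwayEfficacy,
    PharmError,
    PlateReadout,
    call_hits,
    cns_mpo,
    combined_sem,
    delta_log_emax_ec50,
    fit_4pl,
    fold_change_and_ddg,
    ki_cheng_prusoff,
    lle,
    percent_activity,
    relative_efficacy,
    sem_of_log_ratio,
    ubret,
)
from cb1triage.synthetic import CurveSpec, gen_conc_response


class TestFit4PL:
    def test_noiseless_exact_recovery(self):
        spec = CurveSpec(true_ec50=2e-8, true_emax=85.0, true_hill=1.3,
                         baseline=5.0, noise_sd=0.0)
        fit = fit_4pl(gen_conc_response(spec).data)
        assert fit.converged
        assert fit.ec50 == pytest.approx(2e-8, rel=1e-6)
        assert fit.emax == pytest.approx(85.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.3, rel=1e-5)
        assert fit.baseline == pytest.approx(5.0, abs=1e-4)

    def test_inhibition_mode(self):
        conc = np.logspace(-11, -5, 8)
        resp = 100.0 - 90.0 / (1 + (1e-8 / conc) ** 1.0)
        fit = fit_4pl(ConcResponse("c", "p", conc, resp), mode="inhibition")
        assert fit.converged
        assert fit.ec50 == pytest.approx(1e-8, rel=1e-4)
        assert fit.emax == pytest.approx(10.0, abs=1e-2)

    def test_constant_responses_flagged_unconverged(self):
        conc = np.logspace(-10, -6, 6)
        fit = fit_4pl(ConcResponse("c", "p", conc, np.full(6, 42.0)))
        assert not fit.converged
        assert fit.ec50 is None
        assert "unidentifiable" in fit.message

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(PharmError, match=">= 4"):
            fit_4pl(ConcResponse("c", "p", [1e-9, 1e-8, 1e-7], [1, 50, 99.0]))

    def test_concentration_unit_rescaling(self):
        spec = CurveSpec(true_ec50=5e-9, noise_sd=2.0, seed=3)
        data = gen_conc_response(spec).data
        fit_m = fit_4pl(data)
        scaled = ConcResponse("c", "p", data.concentrations * 1e9,
                              data.responses)
        fit_nm = fit_4pl(scaled)
        assert fit_nm.ec50 == pytest.approx(fit_m.ec50 * 1e9, rel=1e-3)
        assert fit_nm.emax == pytest.approx(fit_m.emax, rel=1e-6)
        assert fit_nm.hill == pytest.approx(fit_m.hill, rel=1e-4)

    def test_recovery_distribution_200_seeds(self):
        """EC50 recovery at 5 % noise, 3 replicates: median |log10 ratio|
        below 0.15, and the 95 % CI covers the truth in >= 90 % of runs."""
        true = 1e-8
        errors, covered = [], 0
        for seed in range(200):
            spec = CurveSpec(true_ec50=true, noise_sd=5.0, n_replicates=3,
                             seed=seed)
            fit = fit_4pl(gen_conc_response(spec).data)
            assert fit.converged
            errors.append(abs(np.log10(fit.ec50 / true)))
            lo, hi = fit.ec50_ci95()
            covered += lo <= true <= hi
        assert np.median(errors) < 0.15
        assert covered >= 0.90 * 200


class TestCallHits:
    def test_strictly_above_threshold(self):
        out = call_hits({"a": 55.0, "b": 50.0, "c": 49.0})
        assert out.hits == ["a"]

    def test_printed_hit_rate_arithmetic(self):
        vals = {f"c{i}": (80.0 if i < 9 else 20.0) for i in range(46)}
        out = call_hits(vals)
        assert len(out.hits) == 9
        assert out.rate_percent == pytest.approx(19.565, abs=1e-3)
        assert round(out.rate_percent) == 20

    def test_empty_input_is_explicit(self):
        out = call_hits({})
        assert out.rate_percent is None and out.status == "empty input"

    def test_suspect_values_still_classified(self):
        out = call_hits({"weird": 160.0, "neg": -60.0})
        assert set(out.suspect) == {"weird", "neg"}
        assert out.hits == ["weird"]


class TestAffinityMetrics:
    @pytest.mark.parametrize(
        "ic50,L,kd,expected",
        [(10e-9, 0.0, 1e-9, 10e-9),
         (10e-9, 1e-9, 1e-9, 5e-9),
         (10e-9, 0.75e-9, 0.25e-9, 2.5e-9)],
    )
    def test_cheng_prusoff(self, ic50, L, kd, expected):
        assert ki_cheng_prusoff(ic50, L, kd) == pytest.approx(expected)

    def test_cheng_prusoff_zero_kd_rejected(self):
        with pytest.raises(PharmError):
            ki_cheng_prusoff(1e-8, 1e-9, 0.0)

    def test_lle(self):
        assert lle(8.0, 3.0) == 5.0
        assert lle(4.2, 4.2) == 0.0

    def test_fold_change_and_ddg_sar_anchor(self):
        fold, ddg = fold_change_and_ddg(731e-9, 44e-9)
        assert round(fold) == 17
        assert ddg == pytest.approx(-1.66, abs=0.01)

    def test_fold_change_identity(self):
        fold, ddg = fold_change_and_ddg(5e-9, 5e-9)
        assert fold == 1.0 and ddg == 0.0

    def test_fold_loss_one_sig_fig(self):
        fold, _ = fold_change_and_ddg(5e-6, 0.95e-9)
        assert fold == pytest.approx(5263, rel=1e-3)
        assert float(f"{fold:.1g}") == 5000


class TestCnsMpo:
    IDEAL = dict(clogp=2.0, clogd=1.0, mw=300.0, tpsa=60.0, hbd=0.0, pka=7.0)
    WORST = dict(clogp=6.0, clogd=5.0, mw=600.0, tpsa=150.0, hbd=4.0, pka=11.0)

    def test_ideal_scores_six(self):
        assert cns_mpo(MPODescriptors(**self.IDEAL)) == pytest.approx(6.0)

    def test_beyond_worst_knots_scores_zero(self):
        assert cns_mpo(MPODescriptors(**self.WORST)) == pytest.approx(0.0)

    def test_midpoint_transforms(self):
        d = MPODescriptors(clogp=4.0, clogd=3.0, mw=430.0, tpsa=60.0,
                           hbd=2.0, pka=9.0)
        assert cns_mpo(d) == pytest.approx(0.5 * 4 + 1.0 + 0.5, abs=1e-9)

    @pytest.mark.parametrize("field,lo,hi", [
        ("clogp", 3.0, 5.0), ("clogd", 2.0, 4.0), ("mw", 360.0, 500.0),
        ("hbd", 0.5, 3.5), ("pka", 8.0, 10.0),
    ])
    def test_monotone_in_penalized_descriptor(self, field, lo, hi):
        grid = np.linspace(max(lo - 1, 0.0), hi + 1, 15)
        scores = [
            cns_mpo(MPODescriptors(**{**self.IDEAL, field: v})) for v in grid
        ]
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 6.0 for s in scores)

    def test_missing_descriptor_rejected(self):
        with pytest.raises(PharmError, match="clogd"):
            MPODescriptors(clogp=3.0, clogd=float("nan"), mw=400.0,
                           tpsa=60.0, hbd=1.0, pka=8.0)


class TestPlateReadouts:
    def test_percent_activity_examples(self):
        assert percent_activity(PlateReadout(20, 20, 300, 100)) == 0.0
        assert percent_activity(PlateReadout(220, 20, 300, 100)) == 100.0
        assert percent_activity(PlateReadout(120, 20, 300, 100)) == 50.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(PharmError, match="denominator"):
            percent_activity(PlateReadout(120, 20, 100, 100))

    def test_alternate_denominator_selectable(self):
        p = PlateReadout(120, 20, 300, 100)
        assert percent_activity(p, "max-minus-vehicle") == pytest.approx(
            100 * 100 / 280
        )

    def test_ubret_endpoints(self):
        cal = BRETCalibration(A=0.1, B=0.9)
        assert ubret(0.1, cal) == 0.0
        assert ubret(0.9, cal) == 10_000.0
        assert ubret(0.5, cal) == 5_000.0

    @given(
        raw=st.floats(-2, 2), a=st.floats(-1, 1), b=st.floats(-1, 1),
        scale=st.floats(0.1, 10), shift=st.floats(-5, 5),
    )
    def test_ubret_affine_equivariance(self, raw, a, b, scale, shift):
        if abs(b - a) < 1e-6:
            return
        cal = BRETCalibration(A=a, B=b)
        mapped = BRETCalibration(A=a * scale + shift, B=b * scale + shift)
        assert ubret(raw, cal) == pytest.approx(
            ubret(raw * scale + shift, mapped), rel=1e-6, abs=1e-6
        )

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(PharmError):
            BRETCalibration(A=0.5, B=0.5)


class TestBiasArithmetic:
    def _eff(self, emax, ec50, pathway="Gi"):
        return PathwayEfficacy(pathway=pathway, emax=emax, ec50=ec50, n=4,
                               sd_log_ratio=0.2)

    def test_self_comparison_is_zero(self):
        e = self._eff(90.0, 1e-8)
        assert delta_log_emax_ec50(e, e) == 0.0
        assert relative_efficacy(0.0) == 1.0

    def test_half_ec50_gives_log2(self):
        t, r = self._eff(80.0, 5e-9), self._eff(80.0, 1e-8)
        assert delta_log_emax_ec50(t, r) == pytest.approx(np.log10(2), abs=1e-4)

    def test_double_emax_gives_log2(self):
        t, r = self._eff(100.0, 1e-8), self._eff(50.0, 1e-8)
        assert delta_log_emax_ec50(t, r) == pytest.approx(0.3010, abs=1e-4)

    def test_pathway_mismatch_rejected(self):
        with pytest.raises(PharmError, match="mismatch"):
            delta_log_emax_ec50(self._eff(80, 1e-8, "Gi"),
                                self._eff(80, 1e-8, "arrestin"))

    def test_sem_arithmetic(self):
        assert sem_of_log_ratio(0.2, 4) == pytest.approx(0.1)
        assert combined_sem(0.1, 0.1) == pytest.approx(0.14142, abs=1e-5)
        assert combined_sem(0.37, 0.0) == 0.37
        with pytest.raises(PharmError):
            sem_of_log_ratio(0.2, 0)

    @pytest.mark.parametrize("dl,re", [(0.0, 1.0), (0.3010, 2.0), (-1.0, 0.1)])
    def test_relative_efficacy(self, dl, re):
        assert relative_efficacy(dl) == pytest.approx(re, abs=2e-3)
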