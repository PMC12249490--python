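import math

import numpy as np
import pytest

from turnoverkit.chemistry import PeptideRecord
from turnoverkit.enrichment import EnrichmentSeries, TimeCourse, extract_enrichment
from turnoverkit.kinetics import (
    FitStatus,
    KineticFit,
    LabelingParameters,
    adjusted_model_enrichment,
    asymptote_classical,
    fit_adjusted,
    fit_classical_px,
    fit_classical_ra,
    fractional_synthesis,
    half_life_ratio_adjusted,
    half_life_ratio_classical,
    taylor_limit_enrichment,
)

TIMES = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 21.0])


def make_peptide(n_eh=20.0, i0=0.4):
    return PeptideRecord(sequence="X" * 5, protein_id="P", n_eh=n_eh, i0_natural=i0)


def classical_timecourse(k, n_eh, params, i0_0=0.4, times=TIMES):
    """Noiseless series following the single-exponential RA decay."""
    peptide = make_peptide(n_eh, i0_0)
    asymp = asymptote_classical(i0_0, params, n_eh)
    i0 = asymp + (i0_0 - asymp) * np.exp(-k * times)
    return TimeCourse(peptide=peptide, times=times, i0_values=i0, i0_reference=i0_0)


class TestAsymptote:
    def test_pw_equals_ph_limit(self):
        # p_h must be < p_w, so approach the limit
        params = LabelingParameters(p_w=0.0101, p_h=0.01)
        assert asymptote_classical(0.4, params, 20) == pytest.approx(0.4, rel=3e-3)

    def test_matches_loop_oracle(self):
        params = LabelingParameters(p_w=0.04, p_h=0.0)
        expected = 1.0
        for _ in range(15):
            expected *= 0.96
        assert asymptote_classical(1.0, params, 15) == pytest.approx(expected, rel=1e-14)

    def test_decreasing_in_neh(self, params):
        assert asymptote_classical(0.4, params, 25) < asymptote_classical(0.4, params, 15)
        assert asymptote_classical(0.4, params, 15) < 0.4


class TestClassicalFits:
    def test_recovers_rate_from_noiseless_decay(self, params):
        tc = classical_timecourse(0.1, 20, params)
        fit = fit_classical_ra(tc, params)
        assert fit.converged
        assert fit.k == pytest.approx(0.1, rel=1e-6)
        assert fit.residual_sse == pytest.approx(0.0, abs=1e-18)

    def test_ra_and_px_fits_agree(self, params):
        tc = classical_timecourse(0.1, 20, params)
        px = extract_enrichment(
            tc.i0_values, tc.i0_reference, 20, params.p_h, mode="exact"
        )
        es = EnrichmentSeries(peptide=tc.peptide, times=tc.times, px_values=px)
        k_ra = fit_classical_ra(tc, params).k
        k_px = fit_classical_px(es, params).k
        assert k_px == pytest.approx(k_ra, rel=1e-6)

    def test_px_fit_recovers_low_rate(self, params):
        tc = classical_timecourse(0.05, 30, params)
        px = extract_enrichment(
            tc.i0_values, tc.i0_reference, 30, params.p_h, mode="exact"
        )
        es = EnrichmentSeries(peptide=tc.peptide, times=tc.times, px_values=px)
        fit = fit_classical_px(es, params)
        assert fit.k == pytest.approx(0.05, rel=1e-6)

    def test_constant_series_at_plateau_flagged(self, params):
        # series stuck at the plateau from t=0: apparent instantaneous decay,
        # k runs to the upper bound and the fit is flagged unusable
        peptide = make_peptide(20, 0.4)
        asymp = asymptote_classical(0.4, params, 20)
        tc = TimeCourse(
            peptide=peptide, times=TIMES,
            i0_values=np.full_like(TIMES, asymp), i0_reference=0.4,
        )
        fit = fit_classical_ra(tc, params)
        assert not fit.converged
        assert "bound" in fit.message

    def test_too_few_points_not_fittable(self, params):
        peptide = make_peptide()
        tc = TimeCourse(peptide=peptide, times=[0.0], i0_values=[0.4], i0_reference=0.4)
        fit = fit_classical_ra(tc, params)
        assert fit.status is FitStatus.NOT_FITTABLE
        assert math.isnan(fit.k)

    def test_rescaling_invariance(self, params):
        tc = classical_timecourse(0.13, 25, params, i0_0=0.4)
        scaled = TimeCourse(
            peptide=tc.peptide, times=tc.times,
            i0_values=2.0 * tc.i0_values, i0_reference=2.0 * tc.i0_reference,
        )
        assert fit_classical_ra(scaled, params).k == pytest.approx(
            fit_classical_ra(tc, params).k, rel=1e-9
        )


class TestAdjustedFit:
    def test_recovers_rate_from_model_generated_data(self, params):
        n_eh = 33.0
        es = EnrichmentSeries(
            peptide=make_peptide(n_eh),
            times=TIMES,
            px_values=adjusted_model_enrichment(0.2, TIMES, n_eh, params),
        )
        fit = fit_adjusted(es, params)
        assert fit.converged
        assert fit.k == pytest.approx(0.2, rel=1e-6)

    def test_rate_nearly_independent_of_neh_on_taylor_truth(self, params_ph0):
        """When the true enrichment ignores N_EH, the rescaled fit recovers
        nearly the same rate for all N_EH while the classical fit drifts."""
        ks_adj, ks_classical = [], []
        for n_eh in (10, 30, 60):
            px = taylor_limit_enrichment(0.04, 0.1, TIMES)
            es = EnrichmentSeries(
                peptide=make_peptide(n_eh), times=TIMES,
                px_values=np.asarray(px),
            )
            ks_adj.append(fit_adjusted(es, params_ph0).k)
            i0 = 0.4 * (1 - np.asarray(px)) ** n_eh
            tc = TimeCourse(
                peptide=make_peptide(n_eh), times=TIMES, i0_values=i0,
                i0_reference=0.4,
            )
            ks_classical.append(fit_classical_ra(tc, params_ph0).k)
        spread_adj = max(ks_adj) - min(ks_adj)
        spread_classical = max(ks_classical) - min(ks_classical)
        assert spread_adj < 1e-3
        assert spread_adj < spread_classical / 50
        for k in ks_adj:
            assert k == pytest.approx(0.1, rel=0.05)

    def test_empty_series_not_fittable(self, params):
        es = EnrichmentSeries(peptide=make_peptide(), times=[], px_values=[])
        fit = fit_adjusted(es, params)
        assert fit.status is FitStatus.NOT_FITTABLE


class TestHalfLifeRatios:
    """The printed diagnostic values; evaluated with p_h = 0, the convention
    under which the reference evaluations reproduce."""

    @pytest.mark.parametrize(
        "n_eh,p_w,expected",
        [(15, 0.04, 0.43), (25, 0.04, 0.38), (15, 0.01, 0.48), (25, 0.01, 0.47)],
    )
    def test_classical_printed_values(self, n_eh, p_w, expected):
        params = LabelingParameters(p_w=p_w, p_h=0.0)
        assert round(half_life_ratio_classical(n_eh, params), 2) == expected

    @pytest.mark.parametrize("n_eh,expected", [(15, 0.4953), (25, 0.4952)])
    def test_adjusted_printed_values(self, n_eh, expected, params_ph0):
        assert round(half_life_ratio_adjusted(n_eh, params_ph0), 4) == expected

    def test_neh_one_reduces_to_half(self):
        params = LabelingParameters(p_w=0.04, p_h=0.0)
        assert half_life_ratio_classical(1, params) == pytest.approx(0.5, rel=1e-12)
        assert half_life_ratio_adjusted(1, params) == pytest.approx(0.5, rel=1e-12)

    def test_classical_strictly_decreasing_in_neh(self, params_ph0):
        vals = [half_life_ratio_classical(n, params_ph0) for n in range(1, 101)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_adjusted_nearly_flat_in_neh(self, params_ph0):
        vals = [half_life_ratio_adjusted(n, params_ph0) for n in range(5, 101)]
        assert max(vals) - min(vals) < 1e-3

    def test_pw_equal_ph_rejected_by_parameters(self):
        with pytest.raises(ValueError):
            LabelingParameters(p_w=0.02, p_h=0.02)


class TestFractionalSynthesis:
    def test_no_labeling(self):
        assert fractional_synthesis(0.4, 0.4, 0.1) == 0.0

    def test_plateau(self):
        assert fractional_synthesis(0.1, 0.4, 0.1) == 1.0

    def test_midpoint(self):
        assert fractional_synthesis(0.25, 0.4, 0.1) == pytest.approx(0.5)

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fractional_synthesis(0.3, 0.2, 0.2)


class TestTaylorLimit:
    def test_zero_time(self):
        assert taylor_limit_enrichment(0.04, 0.1, 0.0) == 0.0

    def test_asymptote(self):
        assert taylor_limit_enrichment(0.04, 0.1, 1e6) == pytest.approx(0.04)

    def test_agrees_with_rescaled_model_to_first_order(self, params_ph0):
        """The exact rescaled-model enrichment matches p_W(1 - e^{-kt}) to
        O(p_W^2) whenever N_EH * p_W^2 << 1, up to N_EH = 400."""
        t = np.linspace(0.0, 30.0, 61)
        for n_eh in (5, 25, 60, 150, 400):
            for k in (0.02, 0.1, 0.5):
                exact = adjusted_model_enrichment(k, t, n_eh, params_ph0)
                approx = taylor_limit_enrichment(0.04, k, t)
                assert np.max(np.abs(exact - approx)) < 0.04**2 / 2


class TestKineticFit:
    def test_half_life_identity(self):
        fit = KineticFit(k=0.2, model="classical_ra", converged=True)
        assert fit.half_life * fit.k == pytest.approx(math.log(2), rel=1e-15)

    def test_stderr_covers_truth_on_noisy_data(self, params, rng):
        """Jacobian-based stderr is on the right scale: the fitted k of a
        mildly noisy series lies within ~4 stderr of the truth."""
        tc = classical_timecourse(0.1, 20, params)
        noisy = TimeCourse(
            peptide=tc.peptide, times=tc.times,
            i0_values=tc.i0_values + rng.normal(0, 5e-4, tc.times.size),
            i0_reference=tc.i0_reference,
        )
        fit = fit_classical_ra(noisy, params)
        assert fit.converged and fit.k_stderr > 0
        assert abs(fit.k - 0.1) < 4 * fit.k_stderr + 1e-3


class TestLabelingParameters:
    @pytest.mark.parametrize("pw,ph", [(0.0, 0.0), (0.2, 0.0), (0.04, 0.05), (0.04, -0.1)])
    def test_invalid_rejected(self, pw, ph):
        with pytest.raises(ValueError):
            LabelingParameters(p_w=pw, p_h=ph)
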