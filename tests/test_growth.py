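"""Growth-kinetics enumeration: carbon accounting, onset detection,
anchored exponential fit, and the rate -> abundance arithmetic."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporeflux import growth, synthetic
from sporeflux.growth import (
    GrowthFit,
    NoGrowthError,
    OnsetNotDetectedError,
    SlurrySpec,
    TimeCourse,
    abundance_from_rate,
    cell_specific_rate,
    detect_onset,
    dilution_consistency,
    fit_exponential,
    vfa_carbon,
)


class TestVFACarbon:
    @pytest.mark.parametrize(
        "vfa_map, expected",
        [
            ({"acetate": 1.0}, 2.0),
            ({}, 0.0),
            ({"acetate": 0.5, "propionate": 0.2, "formate": 0.1}, 1.7),
            ({"butyrate": 0.25, "isovalerate": 0.2}, 2.0),
        ],
    )
    def test_carbon_weighting(self, vfa_map, expected):
        assert vfa_carbon(vfa_map) == pytest.approx(expected, abs=1e-12)

    def test_unknown_species_named(self):
        with pytest.raises(ValueError, match="caproate"):
            vfa_carbon({"caproate": 1.0})

    @given(
        a=st.dictionaries(st.sampled_from(["acetate", "formate"]),
                          st.floats(0, 10)),
        b=st.dictionaries(st.sampled_from(["butyrate", "valerate"]),
                          st.floats(0, 10)),
    )
    @settings(max_examples=50, derandomize=True)
    def test_additive_over_disjoint_maps(self, a, b):
        assert vfa_carbon({**a, **b}) == pytest.approx(
            vfa_carbon(a) + vfa_carbon(b), abs=1e-9
        )


def _constant_timecourse(value=0.3, n=13):
    t = np.arange(n) * 0.5
    return TimeCourse(
        data=pd.DataFrame({"time_h": t, "acetate_mM": np.full(n, value)})
    )


class TestOnsetDetection:
    def test_noiseless_generator_round_trip(self, noiseless_timecourse):
        """A 3.5 h lag sampled every 15 min is located exactly."""
        assert detect_onset(noiseless_timecourse) == pytest.approx(3.5)

    def test_constant_series_has_no_onset(self):
        with pytest.raises(OnsetNotDetectedError, match="no onset"):
            detect_onset(_constant_timecourse())

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_onset_within_one_sampling_interval(self, seed):
        s = synthetic.SlurryScenario(noise_cv=0.05, seed=seed)
        tc = synthetic.simulate_slurry_timecourse(s, np.arange(0, 6.01, 0.5))
        assert abs(detect_onset(tc) - 3.5) <= 0.5

    def test_requires_three_baseline_points(self, noiseless_timecourse):
        with pytest.raises(ValueError, match=">= 3"):
            detect_onset(noiseless_timecourse, baseline_window=(0.0, 0.3))


class TestExponentialFit:
    def test_exact_log_linear_data(self):
        """C = C0 e^{2(t-4)} is recovered to machine precision, and the
        implied doubling time is 60 ln2 / 2 = 20.79 min."""
        t = np.arange(0.0, 6.01, 0.5)
        c0, k = 0.4, 2.0
        conc = np.where(t >= 4.0, c0 * np.exp(k * (t - 4.0)), c0)
        tc = TimeCourse(
            data=pd.DataFrame({"time_h": t, "acetate_mM": conc / 2.0})
        )
        fit = fit_exponential(tc, fit_window=(4.0, 6.0), baseline_window=(0.0, 4.0))
        assert fit.k == pytest.approx(2.0, rel=1e-12)
        assert fit.c0 == pytest.approx(0.4, rel=1e-12)
        assert fit.doubling_time_min == pytest.approx(20.79, abs=0.005)
        assert fit.rmse_log == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_growth_rate(self, noiseless_scenario,
                                             noiseless_timecourse):
        """Noiseless generator output with the consistent baseline gives
        back mu exactly (well within the 5% the growth-dominated regime
        guarantees)."""
        fit = fit_exponential(noiseless_timecourse)
        assert fit.k == pytest.approx(noiseless_scenario.mu, rel=1e-9)

    def test_initial_rate_identity(self):
        """r_on = k*C0: with k for a 22-min doubling and C0 = 0.688 mM C
        the initial rate is 1.30 mM C/h."""
        k = math.log(2) / (22 / 60)
        fit = GrowthFit(c0=0.688, k=k, t_on=3.5, window=(3.5, 5.0), rmse_log=0.0)
        assert fit.r_on == pytest.approx(1.30, abs=0.005)
        assert fit.doubling_time_min == pytest.approx(22.0, rel=1e-12)

    def test_internal_identities_hold(self, noiseless_timecourse):
        fit = fit_exponential(noiseless_timecourse)
        assert fit.r_on == pytest.approx(fit.k * fit.c0, rel=1e-12)
        assert fit.doubling_time_min == pytest.approx(
            60 * math.log(2) / fit.k, rel=1e-12
        )

    def test_free_intercept_variant(self, noiseless_scenario,
                                    noiseless_timecourse):
        fit = fit_exponential(noiseless_timecourse, free_intercept=True)
        assert fit.k == pytest.approx(noiseless_scenario.mu, rel=1e-9)
        assert fit.c0 == pytest.approx(noiseless_scenario.c_bg_mM, rel=1e-9)

    def test_flat_data_reports_no_growth(self):
        with pytest.raises(NoGrowthError, match="no exponential growth"):
            fit_exponential(_constant_timecourse(),
                            fit_window=(3.5, 5.0), baseline_window=(0.0, 3.5))

    def test_acetate_proxy_matches_total_when_single_species(self):
        t = np.arange(0.0, 6.01, 0.5)
        conc = np.where(t >= 3.5, 0.3 * np.exp(1.5 * (t - 3.5)), 0.3)
        tc = TimeCourse(data=pd.DataFrame({"time_h": t, "acetate_mM": conc}))
        full = fit_exponential(tc)
        proxy = fit_exponential(tc, use_acetate_proxy=True)
        assert proxy.k == pytest.approx(full.k, rel=1e-12)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            TimeCourse(
                data=pd.DataFrame(
                    {"time_h": [0.0, 1.0, 1.0], "acetate_mM": [0.1, 0.1, 0.1]}
                )
            )


class TestCellSpecificRate:
    def test_fish_calibration(self):
        """1.3 mM C/h across 2.03e6 FISH-positive cells/mL is 640 fmol
        C per cell per h."""
        q = cell_specific_rate(1.3, 2.03125e6)
        assert q == pytest.approx(6.4e-13, rel=1e-6)

    def test_zero_rate(self):
        assert cell_specific_rate(0.0, 1e6) == 0.0

    def test_homogeneity(self):
        assert cell_specific_rate(2.6, 4e6) == pytest.approx(
            cell_specific_rate(1.3, 2e6), rel=1e-12
        )

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            cell_specific_rate(1.3, 0.0)


class TestAbundance:
    def test_printed_slurry_and_sediment_densities(self):
        """1.3 mmol C/L/h over 640 fmol C/cell/h gives ~2e6 cells per mL
        slurry; the 1:2 slurry triples that to ~6e6 per mL sediment."""
        est = abundance_from_rate(1.3, 6.4e-13, SlurrySpec(1, 2))
        assert est.n_slurry == pytest.approx(2e6, rel=0.02)
        assert est.n_sediment == pytest.approx(6e6, rel=0.02)
        assert est.n_sediment == pytest.approx(3 * est.n_slurry, rel=1e-12)

    def test_zero_rate_zero_abundance(self):
        est = abundance_from_rate(0.0, 6.4e-13, SlurrySpec(1, 2))
        assert est.n_slurry == 0.0 and est.n_sediment == 0.0

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            abundance_from_rate(1.3, 0.0, SlurrySpec(1, 2))

    @given(
        r=st.floats(1e-3, 10), q=st.floats(1e-14, 1e-11), f=st.floats(1.5, 20)
    )
    @settings(max_examples=100, derandomize=True)
    def test_linearity_in_rate_and_inverse_in_q(self, r, q, f):
        spec = SlurrySpec(1, 2)
        base = abundance_from_rate(r, q, spec).n_slurry
        assert abundance_from_rate(r * f, q, spec).n_slurry == pytest.approx(
            base * f, rel=1e-9
        )
        assert abundance_from_rate(r, q * f, spec).n_slurry == pytest.approx(
            base / f, rel=1e-9
        )

    def test_round_trip_recovers_generating_population(self, noiseless_scenario,
                                                       noiseless_timecourse):
        """Fit + rate arithmetic on noiseless generator output returns the
        generating N0; with the baseline perturbed +/-10% from the
        consistent value the residual bias stays within 10%."""
        fit = fit_exponential(noiseless_timecourse)
        est = abundance_from_rate(fit.r_on, noiseless_scenario.q,
                                  noiseless_timecourse.slurry)
        assert est.n_slurry == pytest.approx(noiseless_scenario.n0, rel=1e-9)

        for factor in (0.9, 1.1):
            s = synthetic.SlurryScenario(
                c_bg=noiseless_scenario.c_bg_mM * factor, noise_cv=0.0
            )
            tc = synthetic.simulate_slurry_timecourse(s, np.arange(0, 6.01, 0.25))
            fit = fit_exponential(tc, fit_window=(3.5, 5.5))
            est = abundance_from_rate(fit.r_on, s.q, tc.slurry)
            assert est.n_slurry == pytest.approx(s.n0, rel=0.10)


class TestDilutionConsistency:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2), (1, 9), 10 / 3),
            ((1, 2), (1, 2), 1.0),
            ((1, 0), (1, 1), 2.0),
        ],
    )
    def test_fold_ratios(self, a, b, expected):
        fold = dilution_consistency(SlurrySpec(*a), SlurrySpec(*b))
        assert fold == pytest.approx(expected, rel=1e-12)

    def test_zero_sediment_rejected(self):
        with pytest.raises(ValueError):
            dilution_consistency(SlurrySpec(0, 2), SlurrySpec(1, 2))
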