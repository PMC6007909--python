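"""Unit and property tests for the proximate/ultimate impact equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpaimpact.core import (
    HandlingSpec,
    HabitatParams,
    ImpactClampWarning,
    MethodProfile,
    ModelInputError,
    SamplingFootprint,
    FootprintProvenance,
    TargetSpec,
    VulnerabilityParams,
    max_allowable_proximate_impact,
    proximate_assemblage_impact,
    proximate_habitat_impact,
    proximate_population_impact,
    sampled_area_from_plots,
    sampled_area_from_target,
    ultimate_assemblage_impact,
    ultimate_habitat_impact,
    ultimate_population_impact,
)


def _method(m=0.0, suscep=None, p_alt=None):
    return MethodProfile(
        method_id="m",
        mortality_by_group={"fishes": m, "mobile_invertebrates": m},
        susceptibility_by_assemblage=(
            {a: suscep for a in ("fishes", "mobile_invertebrates",
                                 "sessile_invertebrates", "macrophytes")}
            if suscep is not None else {}
        ),
        habitat_alteration_by_class=(
            {"rocky intertidal": p_alt} if p_alt is not None else {}
        ),
    )


def _habitat(area=1e6, rt=10.0, cls="rocky intertidal"):
    return HabitatParams(cls, area, rt)


def _target(n, dens, cls="rocky intertidal", sid="sp"):
    return TargetSpec(sid, n, dens, cls)


class TestProximatePopulation:
    @pytest.mark.parametrize(
        "m, m_hand, eff, n, dens, area, expected",
        [
            (0.0, 0.0, 1.0, 50.0, 0.1, 1e4, 0.0),  # observational method
            (1.0, 0.0, 1.0, 10.0, 1.0, 1000.0, 0.01),  # full mortality: N/pop
            (0.5, 0.2, 0.8, 20.0, 0.05, 1e4, 0.03),  # 0.6 * 1.25 * 0.04
        ],
    )
    def test_worked_values(self, m, m_hand, eff, n, dens, area, expected):
        pi = proximate_population_impact(
            _method(m=m),
            "fishes",
            HandlingSpec(mortality_target=m_hand, efficacy=eff),
            _target(n, dens),
            _habitat(area=area),
        )
        assert pi == pytest.approx(expected, abs=1e-12)

    def test_zero_efficacy_rejected_at_construction(self):
        with pytest.raises(ModelInputError):
            HandlingSpec(efficacy=0.0)

    def test_absent_population_is_an_error(self):
        with pytest.raises(ModelInputError):
            _target(10.0, 0.0)

    def test_take_exceeding_population_clamps_with_warning(self):
        with pytest.warns(ImpactClampWarning):
            pi = proximate_population_impact(
                _method(m=1.0), "fishes", HandlingSpec(),
                _target(5000.0, 0.001), _habitat(area=1000.0),
            )
        assert pi == 1.0

    def test_habitat_mismatch_is_an_error(self):
        with pytest.raises(ModelInputError):
            proximate_population_impact(
                _method(m=1.0), "fishes", HandlingSpec(),
                _target(1.0, 1.0, cls="rocky intertidal"),
                _habitat(cls="deep pelagic"),
            )


class TestUltimateImpacts:
    @pytest.mark.parametrize(
        "pi, rt, i, expected",
        [
            (0.00118, 22.0, 3.0, 0.03894),  # prints as ~0.039
            (0.00216, 4.0, 3.0, 0.01296),  # prints as ~0.013
        ],
    )
    def test_reference_case_values(self, pi, rt, i, expected):
        ui = ultimate_population_impact(pi, VulnerabilityParams(rt, i))
        assert ui == pytest.approx(expected, abs=1e-10)
        assert round(ui, 3) in (0.039, 0.013)

    @given(pi=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_neutral_scaling_identity(self, pi):
        # RT = 2 y with interaction 1 leaves the impact unchanged
        vuln = VulnerabilityParams(2.0, 1.0)
        assert ultimate_population_impact(pi, vuln) == pi
        assert ultimate_assemblage_impact(pi, vuln) == pi
        assert ultimate_habitat_impact(pi, _habitat(rt=2.0)) == pi

    def test_out_of_range_pi_is_an_error(self):
        with pytest.raises(ModelInputError):
            ultimate_population_impact(-0.1, VulnerabilityParams(2.0))
        with pytest.raises(ModelInputError):
            ultimate_population_impact(1.1, VulnerabilityParams(2.0))

    def test_habitat_ui_uses_no_interaction_index(self):
        assert ultimate_habitat_impact(0.0033, _habitat(rt=20.0)) == pytest.approx(
            0.033
        )

    def test_habitat_rt_capped_at_20_years(self):
        hab = HabitatParams("rocky intertidal", 1e6, 50.0)
        assert hab.recovery_time_y == 20.0
        assert ultimate_habitat_impact(0.001, hab) == pytest.approx(0.01)


class TestSampledArea:
    def test_inferred_from_target_with_inefficiency_scalar(self):
        fp = sampled_area_from_target(_target(75.0, 0.1))
        assert fp.occupied_area_m2 == pytest.approx(750.0)
        assert fp.area_sampled_m2 == pytest.approx(3750.0)
        assert fp.provenance is FootprintProvenance.INFERRED_FROM_TARGET

    @pytest.mark.parametrize(
        "n, dens, scalar, expected",
        [(0.0, 0.1, 5.0, 0.0), (10.0, 0.5, 5.0, 100.0)],
    )
    def test_inferred_area_values(self, n, dens, scalar, expected):
        fp = sampled_area_from_target(_target(n, dens), scalar=scalar)
        assert fp.area_sampled_m2 == pytest.approx(expected)

    @pytest.mark.parametrize(
        "new_plots, n_events, expected",
        [(True, 4, 40.0), (False, 4, 10.0), (True, 0, 0.0)],
    )
    def test_plot_schedule_areas(self, new_plots, n_events, expected):
        fp = sampled_area_from_plots(1.0, 10, n_events, new_plots)
        assert fp.area_sampled_m2 == expected
        assert fp.provenance is FootprintProvenance.DECLARED_PLOTS


class TestProximateAssemblageAndHabitat:
    def test_zero_susceptibility_means_zero_impact(self):
        pi = proximate_assemblage_impact(
            _method(m=0.9, suscep=0.0), "fishes",
            HandlingSpec(mortality_nontarget=0.5),
            SamplingFootprint(500.0, FootprintProvenance.DECLARED_PLOTS, 1.0),
            _habitat(),
        )
        assert pi == 0.0

    def test_total_removal_over_whole_mpa(self):
        pi = proximate_assemblage_impact(
            _method(m=1.0, suscep=1.0), "fishes", HandlingSpec(),
            SamplingFootprint(1e6, FootprintProvenance.DECLARED_PLOTS, 1.0),
            _habitat(area=1e6),
        )
        assert pi == 1.0

    def test_hand_worked_assemblage_value(self):
        pi = proximate_assemblage_impact(
            _method(m=0.66, suscep=0.25), "fishes",
            HandlingSpec(mortality_nontarget=0.05),
            SamplingFootprint(3750.0, FootprintProvenance.INFERRED_FROM_TARGET),
            _habitat(area=1e6),
        )
        assert pi == pytest.approx(0.677 * 0.25 * 0.00375, rel=1e-12)

    def test_missing_susceptibility_is_an_error(self):
        with pytest.raises(ModelInputError):
            proximate_assemblage_impact(
                _method(m=0.5), "fishes", HandlingSpec(),
                SamplingFootprint(10.0, FootprintProvenance.DECLARED_PLOTS, 1.0),
                _habitat(),
            )

    @pytest.mark.parametrize(
        "p_alt, a_samp, a_mpa, expected",
        [(0.0, 100.0, 1e4, 0.0), (1.0, 5e3, 5e3, 1.0), (0.33, 50.0, 5000.0, 0.0033)],
    )
    def test_habitat_impact_values(self, p_alt, a_samp, a_mpa, expected):
        pi = proximate_habitat_impact(
            _method(p_alt=p_alt), "rocky intertidal",
            SamplingFootprint(a_samp, FootprintProvenance.DECLARED_PLOTS, 1.0),
            _habitat(area=a_mpa),
        )
        assert pi == pytest.approx(expected, rel=1e-12)

    def test_area_ratio_above_one_clamps_with_warning(self):
        with pytest.warns(ImpactClampWarning):
            pi = proximate_habitat_impact(
                _method(p_alt=0.5), "rocky intertidal",
                SamplingFootprint(2e6, FootprintProvenance.DECLARED_PLOTS, 1.0),
                _habitat(area=1e6),
            )
        assert pi == 0.5


class TestMaxAllowableImpact:
    @pytest.mark.parametrize(
        "threshold, rt, i, expected",
        [(0.1, 2.0, 1.0, 0.10), (0.1, 20.0, 5.0, 0.002)],
    )
    def test_inversion_values(self, threshold, rt, i, expected):
        assert max_allowable_proximate_impact(
            threshold, VulnerabilityParams(rt, i)
        ) == pytest.approx(expected, rel=1e-12)

    def test_clamped_to_one_when_threshold_is_huge(self):
        assert max_allowable_proximate_impact(10.0, VulnerabilityParams(4.0, 5.0)) == 1.0

    @given(
        threshold=st.floats(1e-4, 0.5),
        rt=st.floats(2.0, 40.0),
        i=st.floats(1.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_inverse_of_ultimate_scaling(self, threshold, rt, i):
        vuln = VulnerabilityParams(rt, i)
        pi = max_allowable_proximate_impact(threshold, vuln)
        if pi < 1.0:  # no clamp fired
            assert ultimate_population_impact(pi, vuln) == pytest.approx(
                threshold, rel=1e-12
            )


class TestOracleEquivalence:
    """All six impact equations agree with a literal transcription
    evaluated in a different order, to 1e-12 over 1000 random draws."""

    def test_equations_match_brute_force_oracle(self):
        rng = np.random.default_rng(20260925)
        for _ in range(1000):
            m = rng.uniform(0, 1)
            mh = rng.uniform(0, 1)
            mh_nt = rng.uniform(0, 1)
            eff = rng.uniform(0.05, 1)
            n = rng.uniform(0, 100)
            dens = rng.uniform(0.01, 2)
            a_mpa = rng.uniform(1e4, 1e7)
            a_samp = rng.uniform(0, 1e4)
            suscep = rng.uniform(0, 1)
            p_alt = rng.uniform(0, 1)
            rt = rng.uniform(0.5, 40)
            inter = rng.uniform(1, 5)
            hab_rt = rng.uniform(0.5, 19)

            method = MethodProfile(
                "m",
                mortality_by_group={"fishes": m},
                susceptibility_by_assemblage={"fishes": suscep},
                habitat_alteration_by_class={"rocky intertidal": p_alt},
            )
            handling = HandlingSpec(mh, mh_nt, eff)
            hab = _habitat(area=a_mpa, rt=hab_rt)
            fp = SamplingFootprint(a_samp, FootprintProvenance.DECLARED_PLOTS, 1.0)

            # oracle: literal right-to-left transcription of each formula
            pop_oracle = (n / (dens * a_mpa)) * (1.0 / eff) * (mh * (1.0 - m) + m)
            asm_oracle = (a_samp / a_mpa) * suscep * (mh_nt * (1.0 - m) + m)
            hab_oracle = (a_samp / a_mpa) * p_alt

            pi_pop = proximate_population_impact(
                method, "fishes", handling, _target(n, dens), hab
            )
            pi_asm = proximate_assemblage_impact(method, "fishes", handling, fp, hab)
            pi_hab = proximate_habitat_impact(method, "rocky intertidal", fp, hab)

            assert pi_pop == pytest.approx(min(pop_oracle, 1.0), abs=1e-12)
            assert pi_asm == pytest.approx(asm_oracle, abs=1e-12)
            assert pi_hab == pytest.approx(hab_oracle, abs=1e-12)

            vuln = VulnerabilityParams(rt, inter)
            pi_small = min(pi_pop, 1.0) * 0.5
            assert ultimate_population_impact(pi_small, vuln) == pytest.approx(
                inter * rt / 2.0 * pi_small, abs=1e-12
            )
            assert ultimate_assemblage_impact(pi_asm, vuln) == pytest.approx(
                inter * rt / 2.0 * pi_asm, abs=1e-12
            )
            assert ultimate_habitat_impact(pi_hab, hab) == pytest.approx(
                hab_rt / 2.0 * pi_hab, abs=1e-12
            )


class TestMonotonicity:
    """Impacts are monotone non-decreasing in mortality, susceptibility,
    alteration probability, take, recovery time, and interaction index,
    and non-increasing in efficacy, density, and MPA area."""

    def _pi_pop(self, m, mh, eff, n, dens, a):
        return proximate_population_impact(
            _method(m=m), "fishes", HandlingSpec(mh, 0.0, eff),
            _target(n, dens), _habitat(area=a),
        )

    def test_population_model_orderings(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m, mh = rng.uniform(0, 0.9, 2)
            eff = rng.uniform(0.2, 0.9)
            n = rng.uniform(1, 50)
            dens, a = rng.uniform(0.5, 2), rng.uniform(1e5, 1e6)
            base = self._pi_pop(m, mh, eff, n, dens, a)
            eps = 0.05
            assert self._pi_pop(m + eps, mh, eff, n, dens, a) >= base
            assert self._pi_pop(m, mh + eps, eff, n, dens, a) >= base
            assert self._pi_pop(m, mh, eff, n + 1, dens, a) >= base
            assert self._pi_pop(m, mh, eff + eps, n, dens, a) <= base
            assert self._pi_pop(m, mh, eff, n, dens + eps, a) <= base
            assert self._pi_pop(m, mh, eff, n, dens, a * 1.1) <= base

    def test_ultimate_orderings(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pi = rng.uniform(0, 1)
            rt = rng.uniform(1, 30)
            i = rng.uniform(1, 4)
            base = ultimate_population_impact(pi, VulnerabilityParams(rt, i))
            assert ultimate_population_impact(
                pi, VulnerabilityParams(rt + 1, i)
            ) >= base
            assert ultimate_population_impact(
                pi, VulnerabilityParams(rt, i + 0.5)
            ) >= base

    def test_population_pi_is_affine_in_mortalities_and_inverse_in_efficacy(self):
        # affine in M_meth: equal second differences vanish
        f = lambda m: self._pi_pop(m, 0.2, 0.8, 10, 0.5, 1e5)
        second_diff = f(0.0) - 2 * f(0.3) + f(0.6)
        assert second_diff == pytest.approx(0.0, abs=1e-15)
        # proportional to 1/Eff: f(eff) * eff is constant
        g = lambda eff: self._pi_pop(0.4, 0.2, eff, 10, 0.5, 1e5) * eff
        assert g(0.25) == pytest.approx(g(1.0), rel=1e-12)
        # curvature: halving efficacy doubles the impact (not linear shift)
        h = lambda eff: self._pi_pop(0.4, 0.2, eff, 10, 0.5, 1e5)
        assert h(0.25) == pytest.approx(2 * h(0.5), rel=1e-12)
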