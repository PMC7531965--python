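import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eetkinetics as ek
from eetkinetics.model_core import rhs_for
from eetkinetics.presets import WT_DE1, WT_DE2, DOMCS_VARIANT

from conftest import integrate_to_steady

BV_FITTED = ek.ButlerVolmerParameters(k0=0.0131, alpha=0.897, e0=-0.193)


class TestButlerVolmerRate:
    def test_published_triple_predicts_post_step_rate(self):
        """The fitted (k0, alpha, E0) evaluated at +499 mV reproduces the
        fitted interfacial constant of the first step profile to a few %."""
        rate = ek.butler_volmer_rate(BV_FITTED, 0.499)
        assert rate == pytest.approx(0.206, rel=0.05)

    def test_rate_at_formal_potential_is_k0(self):
        assert ek.butler_volmer_rate(BV_FITTED, BV_FITTED.e0) == BV_FITTED.k0

    @pytest.mark.parametrize("e", [-0.5, -0.193, 0.0, 0.7])
    def test_alpha_one_gives_k0_everywhere(self, e):
        bv = ek.ButlerVolmerParameters(k0=0.02, alpha=1.0, e0=-0.2)
        assert ek.butler_volmer_rate(bv, e) == pytest.approx(0.02)

    def test_strictly_increasing_in_potential(self):
        rates = [ek.butler_volmer_rate(BV_FITTED, e) for e in np.linspace(-0.4, 0.8, 30)]
        assert np.all(np.diff(rates) > 0)

    def test_log_rate_affine_with_tafel_slope(self):
        """ln k_i is affine in E with slope (1-alpha)nF/RT."""
        e = np.linspace(-0.3, 0.7, 11)
        logk = np.log([ek.butler_volmer_rate(BV_FITTED, x) for x in e])
        slopes = np.diff(logk) / np.diff(e)
        assert np.allclose(slopes, BV_FITTED.exponential_slope, rtol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ek.butler_volmer_rate(BV_FITTED, np.nan)
        with pytest.raises(ValueError):
            ek.butler_volmer_rate(BV_FITTED, 1e6)  # overflow
        with pytest.raises(ValueError):
            ek.ButlerVolmerParameters(k0=-1.0, alpha=0.5, e0=0.0)
        with pytest.raises(ValueError):
            ek.ButlerVolmerParameters(k0=1.0, alpha=1.5, e0=0.0)


class TestWtRhs:
    def test_hand_computed_derivatives(self):
        """Mid-trajectory state under the first-profile constants."""
        d_im, d_omc = ek.wt_rhs((1000.0, 400.0), WT_DE1, k_i=0.206)
        # 0.0133*1555 - 4.99e-5*1000*414 and 4.99e-5*1000*414 - 0.206*400
        assert d_im == pytest.approx(0.02290, abs=1e-8)
        assert d_omc == pytest.approx(-61.7414, abs=1e-8)

    def test_steady_state_is_fixed_point(self):
        state = ek.steady_state(WT_DE1, WT_DE1.k_i_after)
        d = ek.wt_rhs(state, WT_DE1, WT_DE1.k_i_after)
        assert np.abs(d).max() < 1e-7

    def test_fully_reduced_pools(self):
        d_im, d_omc = ek.wt_rhs((WT_DE1.im_total, WT_DE1.omc_total), WT_DE1, 0.206)
        assert d_im == 0.0
        assert d_omc == pytest.approx(-0.206 * WT_DE1.omc_total)

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError):
            ek.wt_rhs((-1.0, 10.0), WT_DE1, 0.1)


class TestOmcsRhs:
    def test_logistic_midpoint_half_flux(self):
        phi = ek.logistic_transfer_flux(DOMCS_VARIANT.theta, DOMCS_VARIANT)
        assert phi == pytest.approx(DOMCS_VARIANT.k_omc / 2)

    def test_logistic_saturation_and_tail(self):
        assert ek.logistic_transfer_flux(
            DOMCS_VARIANT.theta + 50, DOMCS_VARIANT
        ) == pytest.approx(DOMCS_VARIANT.k_omc)
        assert ek.logistic_transfer_flux(0.0, DOMCS_VARIANT) < 1e-100

    def test_extreme_arguments_do_not_overflow(self):
        p = DOMCS_VARIANT.with_(theta=1e6, s=1e-3)
        assert np.isfinite(ek.logistic_transfer_flux(0.0, p))
        assert np.isfinite(ek.logistic_transfer_flux(1e9, p))

    def test_electron_conservation_between_pools(self):
        """The flux leaving IM_red equals the flux entering Omc_red."""
        d_im, d_omc = ek.omcs_rhs((2000.0, 100.0), DOMCS_VARIANT, k_i=0.316)
        supply = DOMCS_VARIANT.k_ac * (DOMCS_VARIANT.im_total - 2000.0)
        discharge = 0.316 * 100.0
        assert (supply - d_im) == pytest.approx(d_omc + discharge)

    def test_fully_reduced_omc_accepts_no_flux(self):
        _, d_omc = ek.omcs_rhs(
            (2000.0, DOMCS_VARIANT.omc_total), DOMCS_VARIANT, k_i=0.316
        )
        assert d_omc == pytest.approx(-0.316 * DOMCS_VARIANT.omc_total)


class TestCurrentDensity:
    def test_zero_omc_red_zero_current(self):
        assert ek.current_density((100.0, 0.0), 0.2, WT_DE1) == 0.0

    def test_doubling_omc_red_doubles_current(self):
        i1 = ek.current_density((0.0, 300.0), 0.2, WT_DE1)
        i2 = ek.current_density((0.0, 600.0), 0.2, WT_DE1)
        assert i2 == pytest.approx(2 * i1)

    def test_zero_area_rejected_at_construction(self):
        with pytest.raises(ValueError):
            WT_DE1.with_(electrode_area=0.0)

    def test_post_step_steady_current_near_reported(self):
        """First-profile constants give ~0.7 A/m2 at the published area."""
        state = ek.steady_state(WT_DE1, WT_DE1.k_i_after)
        i = ek.current_density(state, WT_DE1.k_i_after, WT_DE1)
        assert i == pytest.approx(0.7, rel=0.1)


class TestSteadyState:
    def test_second_profile_prestep_pool_nearly_fully_reduced(self):
        """At k_i = 2.26e-4 s^-1 essentially all cytochromes stay reduced."""
        state = ek.steady_state(WT_DE2, WT_DE2.k_i_before)
        assert state.omc_red == pytest.approx(721.39, rel=1e-3)
        assert state.omc_red / WT_DE2.omc_total > 0.99

    def test_first_profile_poststep_electron_flux(self):
        state = ek.steady_state(WT_DE1, WT_DE1.k_i_after)
        assert WT_DE1.k_i_after * state.omc_red == pytest.approx(24.56, rel=1e-3)

    def test_no_acetate_fully_oxidized(self):
        state = ek.steady_state(WT_DE1.with_(k_ac=0.0), 0.2)
        assert state.im_red == 0.0 and state.omc_red == 0.0

    @pytest.mark.parametrize(
        "p,variant",
        [(WT_DE1, "wt"), (WT_DE2, "wt"), (DOMCS_VARIANT, "omcs")],
        ids=["wt_de1", "wt_de2", "domcs"],
    )
    @pytest.mark.parametrize("phase", ["k_i_before", "k_i_after"])
    def test_matches_long_time_integration(self, p, variant, phase):
        """Algebraic fixed point vs >=20 relaxation times of integration,
        componentwise within 0.1%."""
        k_i = getattr(p, phase)
        state = ek.steady_state(p, k_i, variant)
        ref = integrate_to_steady(p, k_i, variant)
        assert np.allclose(state.as_array(), ref, rtol=1e-3)

    def test_conservation_bounds(self):
        for k_i in (1e-4, 1e-2, 0.5):
            s = ek.steady_state(WT_DE1, k_i)
            assert 0 <= s.im_red <= WT_DE1.im_total
            assert 0 <= s.omc_red <= WT_DE1.omc_total

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale_ki=st.floats(0.5, 2.0),
        scale_kac=st.floats(0.5, 2.0),
    )
    def test_steady_current_monotone_in_k_i_and_k_ac(self, scale_ki, scale_kac):
        """Steady current density never decreases when k_i or k_Ac grows."""
        p = WT_DE1.with_(k_ac=WT_DE1.k_ac * scale_kac)
        k_i = WT_DE1.k_i_after * scale_ki
        base = ek.current_density(ek.steady_state(p, k_i), k_i, p)
        up_ki = ek.current_density(ek.steady_state(p, 1.3 * k_i), 1.3 * k_i, p)
        p_up = p.with_(k_ac=1.3 * p.k_ac)
        up_kac = ek.current_density(ek.steady_state(p_up, k_i), k_i, p_up)
        assert up_ki >= base - 1e-12
        assert up_kac >= base - 1e-12


class TestDerivedRates:
    def test_nadh_equals_acetate_supply_at_steady_state(self):
        state = ek.steady_state(WT_DE1, WT_DE1.k_i_after)
        d = ek.wt_rhs(state, WT_DE1, WT_DE1.k_i_after)
        rates = ek.derived_rates(state, d, WT_DE1, WT_DE1.k_i_after)
        assert rates["nadh"] == pytest.approx(rates["acetate_e"], rel=1e-6)

    def test_peak_discharge_rate_second_profile(self):
        """Stepping the pre-equilibrated second profile reaches the
        published maximum cytochrome oxidation rate ~268 nmol/s."""
        state = ek.steady_state(WT_DE2, WT_DE2.k_i_before)
        d = ek.wt_rhs(state, WT_DE2, WT_DE2.k_i_after)
        rates = ek.derived_rates(state, d, WT_DE2, WT_DE2.k_i_after)
        assert rates["omc_oxidation"] == pytest.approx(268.0, rel=0.05)

    def test_fully_oxidized_acetate_consumption(self):
        d = ek.wt_rhs((0.0, 0.0), WT_DE1, 0.2)
        rates = ek.derived_rates((0.0, 0.0), d, WT_DE1, 0.2)
        assert rates["acetate_mol"] == pytest.approx(
            WT_DE1.k_ac * WT_DE1.im_total / 8.0
        )

    def test_wt_nadh_identity_along_trajectory(self, de1_trace):
        """For the wild type, NADH turnover == IM->Omc transfer flux
        (k_Omc*IM_red*Omc_ox) at every sampled instant."""
        p = WT_DE1
        k_i = np.where(
            de1_trace.time < de1_trace.meta["t_switch"], p.k_i_before, p.k_i_after
        )
        for idx in range(0, len(de1_trace), 250):
            state = (de1_trace.im_red[idx], de1_trace.omc_red[idx])
            d = ek.wt_rhs(state, p, float(k_i[idx]))
            rates = ek.derived_rates(state, d, p, float(k_i[idx]))
            transfer = p.k_omc * state[0] * (p.omc_total - state[1])
            assert rates["nadh"] == pytest.approx(transfer, rel=1e-9, abs=1e-12)
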