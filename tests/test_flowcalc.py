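"""Hydrodynamics calculators: worked values, scaling laws, and the
symbolic Poiseuille oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silkscale import flowcalc as fc

ML_PER_MIN = 1e-6 / 60.0


class TestMeanVelocityAndResidence:
    def test_needle_velocity(self, needle, q_feed):
        v = fc.mean_velocity(q_feed, needle.cross_section_area)
        assert v == pytest.approx(0.195, rel=2e-3)

    def test_zero_flow(self, needle):
        assert fc.mean_velocity(0.0, needle.cross_section_area) == 0.0

    def test_rectangular_velocity(self, herringbone_channel, q_feed):
        v = fc.mean_velocity(q_feed, herringbone_channel.cross_section_area)
        assert v == pytest.approx(1.055, rel=1e-3)

    def test_zero_area_rejected(self, q_feed):
        with pytest.raises(ValueError):
            fc.mean_velocity(q_feed, 0.0)

    def test_needle_residence_33ms(self, needle, q_feed):
        v = fc.mean_velocity(q_feed, needle.cross_section_area)
        assert fc.residence_time(needle.length, v) == pytest.approx(33e-3, rel=0.015)

    def test_zero_length(self):
        assert fc.residence_time(0.0, 1.0) == 0.0

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError):
            fc.residence_time(1.0, 0.0)

    def test_volumetric_residence(self, q_feed):
        # 2 μL fluidic volume at 1 mL/min -> 120 ms
        assert fc.residence_time_volumetric(2e-9, q_feed) == pytest.approx(0.120)

    def test_volumetric_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            fc.residence_time_volumetric(1e-9, 0.0)


class TestPipeReynolds:
    def test_needle_reynolds(self, silk_fluid, needle, q_feed):
        assert fc.pipe_reynolds(silk_fluid, needle, q_feed) == pytest.approx(
            2.4, rel=0.015
        )

    def test_zero_flow(self, silk_fluid, needle):
        assert fc.pipe_reynolds(silk_fluid, needle, 0.0) == 0.0

    def test_viscosity_halves_re(self, silk_fluid, needle, q_feed):
        thick = fc.FluidProperties(silk_fluid.density,
                                   2 * silk_fluid.dynamic_viscosity)
        assert fc.pipe_reynolds(thick, needle, q_feed) == pytest.approx(
            fc.pipe_reynolds(silk_fluid, needle, q_feed) / 2
        )

    def test_regime_labels(self):
        assert fc.flow_regime(2.4) == "laminar"
        assert fc.flow_regime(5000.0) == "turbulent"


class TestWallShearRates:
    def test_needle_wall_shear_4724(self, needle, q_feed):
        assert fc.pipe_wall_shear_rate(needle, q_feed) == pytest.approx(
            4724.0, rel=0.015
        )

    def test_diameter_cubed_scaling(self, needle, q_feed):
        halved = fc.CylindricalConduit(needle.internal_diameter / 2)
        assert fc.pipe_wall_shear_rate(halved, q_feed) == pytest.approx(
            8 * fc.pipe_wall_shear_rate(needle, q_feed)
        )

    def test_sympy_poiseuille_oracle(self, q_feed):
        """4Q/(πR³) equals the symbolic wall derivative of the Poiseuille
        profile u(r) = 2Q/(πR²)(1 − r²/R²) on random geometries."""
        import sympy as sp

        r, R, Q = sp.symbols("r R Q", positive=True)
        u = 2 * Q / (sp.pi * R**2) * (1 - r**2 / R**2)
        gamma_sym = sp.lambdify((Q, R), sp.Abs(sp.diff(u, r)).subs(r, R))
        rng = np.random.default_rng(42)
        for _ in range(100):
            d = float(rng.uniform(1e-5, 1e-2))
            q = float(rng.uniform(1e-10, 1e-5))
            expected = float(gamma_sym(q, d / 2))
            got = fc.pipe_wall_shear_rate(fc.CylindricalConduit(d), q)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_micromixer_wall_shear_80114(self, herringbone_channel, q_feed):
        assert fc.rect_wall_shear_rate(herringbone_channel, q_feed) == pytest.approx(
            80114.0, rel=0.015
        )

    def test_square_slot_hand_value(self, q_feed):
        chan = fc.RectangularChannel(width=100e-6, height=100e-6)
        assert fc.rect_wall_shear_rate(chan, q_feed) == pytest.approx(1e5, rel=1e-3)

    def test_exact_option_below_wide_slot(self, herringbone_channel, q_feed):
        approx = fc.rect_wall_shear_rate(herringbone_channel, q_feed)
        exact = fc.rect_wall_shear_rate(herringbone_channel, q_feed, exact=True)
        assert 0 < exact != approx


class TestHydraulicDiameterAndChannelRe:
    def test_grooved_142um(self, herringbone_channel):
        assert fc.hydraulic_diameter(herringbone_channel) == pytest.approx(
            142e-6, rel=0.015
        )

    def test_ungrooved_113um(self, herringbone_channel):
        d = fc.hydraulic_diameter(herringbone_channel, include_groove=False)
        assert d == pytest.approx(113e-6, rel=3e-3)

    def test_square_identity(self):
        a = 50e-6
        assert fc.hydraulic_diameter(
            fc.RectangularChannel(a, a)
        ) == pytest.approx(a)

    def test_channel_reynolds_40(self, ipa_water_fluid, herringbone_channel, q_feed):
        assert fc.channel_reynolds(
            ipa_water_fluid, herringbone_channel, q_feed
        ) == pytest.approx(40.0, rel=0.015)

    def test_linear_in_flow(self, ipa_water_fluid, herringbone_channel, q_feed):
        re1 = fc.channel_reynolds(ipa_water_fluid, herringbone_channel, q_feed)
        re3 = fc.channel_reynolds(
            ipa_water_fluid, herringbone_channel, 3 * ML_PER_MIN
        )
        assert re3 == pytest.approx(3 * re1)


class TestPecletAndMixing:
    def test_micromixer_peclet(self, ipa_water_fluid, herringbone_channel, q_feed):
        v = fc.mean_velocity(q_feed, herringbone_channel.cross_section_area)
        pe = fc.peclet_number(
            v, fc.hydraulic_diameter(herringbone_channel),
            ipa_water_fluid.diffusion_coefficient,
        )
        assert pe == pytest.approx(4.28e5, rel=0.01)

    def test_zero_velocity(self):
        assert fc.peclet_number(0.0, 1e-4, 1e-9) == 0.0

    def test_length_doubling(self):
        assert fc.peclet_number(1.0, 2e-4, 1e-9) == pytest.approx(
            2 * fc.peclet_number(1.0, 1e-4, 1e-9)
        )

    def test_calibrated_mixing_time_21ms(
        self, ipa_water_fluid, herringbone_channel, q_feed
    ):
        t = fc.shm_mixing_time(herringbone_channel, ipa_water_fluid, q_feed)
        assert t == pytest.approx(21e-3, rel=0.01)

    def test_diffusive_limit_zero(self, herringbone_channel):
        slow = fc.FluidProperties(837.0, 3.14e-3, diffusion_coefficient=1.0)
        # Pe clamps to 1 -> ln(Pe) = 0
        assert fc.shm_mixing_time(
            herringbone_channel, slow, fc.FlowConditions(ML_PER_MIN)
        ) == 0.0

    def test_log_growth_with_flow(self, ipa_water_fluid, herringbone_channel):
        t1 = fc.shm_mixing_time(
            herringbone_channel, ipa_water_fluid, fc.FlowConditions(ML_PER_MIN))
        t2 = fc.shm_mixing_time(
            herringbone_channel, ipa_water_fluid, fc.FlowConditions(2 * ML_PER_MIN))
        # mixing LENGTH grows ~ ln(Pe): doubling Q raises length by ln 2
        assert t2 * 2 / t1 == pytest.approx(
            1 + math.log(2) / math.log(427774), rel=1e-3
        )

    def test_unknown_model_rejected(
        self, ipa_water_fluid, herringbone_channel, q_feed
    ):
        with pytest.raises(ValueError):
            fc.shm_mixing_time(
                herringbone_channel, ipa_water_fluid, q_feed, model="nope"
            )


class TestStirredVessel:
    def test_reynolds_2514(self, stir_bar_vessel, ipa_water_fluid):
        assert fc.stirred_reynolds(
            stir_bar_vessel, ipa_water_fluid
        ) == pytest.approx(2514.0, rel=0.015)

    def test_reynolds_isopropanol_3070(self, stir_bar_vessel):
        ipa = fc.FluidProperties(density=786.0, dynamic_viscosity=2.4e-3)
        assert fc.stirred_reynolds(stir_bar_vessel, ipa) == pytest.approx(
            3.07e3, rel=0.01
        )

    def test_zero_speed(self, stir_bar_vessel, ipa_water_fluid):
        still = fc.StirredVessel(
            15e-3, 6e-3, 1, 25e-3, 6e-6, rotational_speed=0.0)
        assert fc.stirred_reynolds(still, ipa_water_fluid) == 0.0

    def test_power_number_hand_value(self, stir_bar_vessel):
        assert fc.power_number(stir_bar_vessel) == pytest.approx(3.04, rel=2e-3)

    def test_power_number_unit_ratio(self):
        v = fc.StirredVessel(15e-3, 15e-3, 1, 25e-3, 6e-6, 400.0)
        assert fc.power_number(v) == pytest.approx(10.0)

    def test_power_number_monotone_in_blade_height(self):
        heights = [3e-3, 6e-3, 9e-3, 12e-3]
        nps = [
            fc.power_number(fc.StirredVessel(15e-3, h, 1, 25e-3, 6e-6, 400.0))
            for h in heights
        ]
        assert all(a < b for a, b in zip(nps, nps[1:]))

    def test_power_draw_hand_value(self, stir_bar_vessel, ipa_water_fluid):
        assert fc.power_draw(stir_bar_vessel, ipa_water_fluid) == pytest.approx(
            5.7e-4, rel=0.01
        )

    def test_power_cubic_in_speed(self, stir_bar_vessel, ipa_water_fluid):
        double = fc.StirredVessel(15e-3, 6e-3, 1, 25e-3, 6e-6, 800.0)
        assert fc.power_draw(double, ipa_water_fluid) == pytest.approx(
            8 * fc.power_draw(stir_bar_vessel, ipa_water_fluid)
        )

    def test_tip_speed_197(self, stir_bar_vessel):
        assert fc.tip_speed(stir_bar_vessel) == pytest.approx(1.97, rel=0.015)

    def test_tip_speed_rev_convention(self, stir_bar_vessel):
        assert fc.tip_speed(stir_bar_vessel, convention="rev") == pytest.approx(
            0.314, rel=0.01
        )

    def test_tip_speed_linear_in_diameter(self, stir_bar_vessel):
        bigger = fc.StirredVessel(30e-3, 6e-3, 1, 50e-3, 6e-6, 400.0)
        assert fc.tip_speed(bigger) == pytest.approx(
            2 * fc.tip_speed(stir_bar_vessel)
        )

    def test_isf_hand_value(self, stir_bar_vessel):
        assert fc.integrated_shear_factor(stir_bar_vessel) == pytest.approx(
            62.8, rel=2e-3
        )

    def test_isf_diverges_on_gap_closure(self):
        near = fc.StirredVessel(15e-3, 6e-3, 1, 15.001e-3, 6e-6, 400.0)
        far = fc.StirredVessel(15e-3, 6e-3, 1, 25e-3, 6e-6, 400.0)
        assert fc.integrated_shear_factor(near) > 100 * fc.integrated_shear_factor(far)

    def test_impeller_must_fit(self):
        with pytest.raises(ValueError):
            fc.StirredVessel(25e-3, 6e-3, 1, 15e-3, 6e-6, 400.0)


class TestShearAndDissipation:
    def test_average_shear_hand_value(self, ipa_water_fluid):
        assert fc.average_shear_rate(0.1, ipa_water_fluid, 6e-6) == pytest.approx(
            2.30e3, rel=0.01
        )

    def test_average_shear_sqrt_scaling(self, ipa_water_fluid):
        one = fc.average_shear_rate(0.1, ipa_water_fluid, 6e-6)
        four = fc.average_shear_rate(0.4, ipa_water_fluid, 6e-6)
        assert four == pytest.approx(2 * one)

    def test_energy_dissipation_hand_value(self, ipa_water_fluid):
        assert fc.energy_dissipation(0.1, ipa_water_fluid, 6e-6) == pytest.approx(
            19.9, rel=0.01
        )

    def test_energy_dissipation_volume_halving(self, ipa_water_fluid):
        assert fc.energy_dissipation(0.1, ipa_water_fluid, 12e-6) == pytest.approx(
            fc.energy_dissipation(0.1, ipa_water_fluid, 6e-6) / 2
        )

    def test_zero_power(self, ipa_water_fluid):
        assert fc.average_shear_rate(0.0, ipa_water_fluid, 6e-6) == 0.0
        assert fc.energy_dissipation(0.0, ipa_water_fluid, 6e-6) == 0.0

    def test_nonpositive_volume_rejected(self, ipa_water_fluid):
        with pytest.raises(ValueError):
            fc.average_shear_rate(0.1, ipa_water_fluid, 0.0)


class TestFickianScales:
    def test_time_from_length(self):
        assert fc.fickian_time(1e-3, 1e-9) == pytest.approx(250.0)

    def test_zero_time_zero_length(self):
        assert fc.fickian_length(0.0, 1e-9) == 0.0

    def test_length_sqrt_in_time(self):
        assert fc.fickian_length(4.0, 1e-9) == pytest.approx(
            2 * fc.fickian_length(1.0, 1e-9)
        )

    def test_roundtrip_with_custom_factor(self):
        for factor in (2.0, 4.0, 6.0):
            t = fc.fickian_time(5e-4, 2e-10, factor)
            assert fc.fickian_length(t, 2e-10, factor) == pytest.approx(5e-4)

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            fc.fickian_time(1e-3, 0.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    q1=st.floats(1e-10, 1e-5),
    factor=st.floats(1.01, 100.0),
)
def test_monotone_in_flow(q1, factor):
    """Re, wall shear, and Pe all strictly increase with Q at fixed
    geometry and fluid."""
    fluid = fc.FluidProperties(1000.0, 1e-3, 1e-9)
    pipe = fc.CylindricalConduit(1e-3)
    chan = fc.RectangularChannel(2e-4, 1e-4)
    q2 = q1 * factor
    assert fc.pipe_reynolds(fluid, pipe, q2) > fc.pipe_reynolds(fluid, pipe, q1)
    assert fc.pipe_wall_shear_rate(pipe, q2) > fc.pipe_wall_shear_rate(pipe, q1)
    v1 = fc.mean_velocity(q1, chan.cross_section_area)
    v2 = fc.mean_velocity(q2, chan.cross_section_area)
    d_h = fc.hydraulic_diameter(chan)
    assert fc.peclet_number(v2, d_h, 1e-9) > fc.peclet_number(v1, d_h, 1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    d=st.floats(1e-5, 1e-2),
    q=st.floats(1e-12, 1e-5),
)
def test_si_roundtrip_consistency(d, q):
    """Outputs are plain SI and consistent under unit-preserving
    reformulations: Re from v·d equals Re from 4ρQ/(πdμ)."""
    fluid = fc.FluidProperties(997.0, 0.89e-3)
    pipe = fc.CylindricalConduit(d)
    re = fc.pipe_reynolds(fluid, pipe, q)
    re_alt = 4 * fluid.density * q / (math.pi * d * fluid.dynamic_viscosity)
    assert re == pytest.approx(re_alt, rel=1e-12)
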