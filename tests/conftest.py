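"""Shared fixtures: the reference process geometry and fluids.

The semi-batch feed train is a 0.33 mm × 6.35 mm blunt needle fed at
1 mL min⁻¹ with 3% w/v aqueous silk (ρ = 1.02 g mL⁻¹, μ = 27 mPa·s);
the micromixer is a 79 × 200 μm herringbone channel (31 μm grooves)
carrying the 5:1 isopropanol/water mixture (ρ = 0.837 g mL⁻¹,
μ = 3.14 mPa·s, D = 3.5 × 10⁻¹⁰ m² s⁻¹); the stirred vessel holds a
15 × 6 mm egg-shaped stir bar at 400 rpm.
"""

import pytest

from silkscale import flowcalc as fc

ML_PER_MIN = 1e-6 / 60.0


@pytest.fixture
def silk_fluid() -> fc.FluidProperties:
    return fc.FluidProperties(density=1020.0, dynamic_viscosity=27e-3)


@pytest.fixture
def ipa_water_fluid() -> fc.FluidProperties:
    return fc.FluidProperties(
        density=837.0, dynamic_viscosity=3.14e-3, diffusion_coefficient=3.5e-10
    )


@pytest.fixture
def needle() -> fc.CylindricalConduit:
    return fc.CylindricalConduit(internal_diameter=0.33e-3, length=6.35e-3)


@pytest.fixture
def herringbone_channel() -> fc.RectangularChannel:
    return fc.RectangularChannel(width=200e-6, height=79e-6, groove_depth=31e-6)


@pytest.fixture
def stir_bar_vessel() -> fc.StirredVessel:
    return fc.StirredVessel(
        impeller_diameter=15e-3,
        blade_height=6e-3,
        n_blades=1,
        reactor_diameter=25e-3,
        fill_volume=6e-6,
        rotational_speed=400.0,
    )


@pytest.fixture
def q_feed() -> fc.FlowConditions:
    """1 mL min⁻¹ in SI."""
    return fc.FlowConditions(ML_PER_MIN)
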