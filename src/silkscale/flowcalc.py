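"""Hydrodynamic characterization of nanoprecipitation hardware.

Covers the semi-batch feed train (syringe, blunt needle, stirred
round-bottom flask) and the staggered-herringbone micromixer (SHM):
Reynolds numbers, laminar wall shear rates, residence times, Peclet
number, chaotic-advection mixing-time estimate, impeller power draw,
tip speed, integrated shear factor, average shear rate, energy
dissipation, and Fickian diffusion scales.

All inputs and outputs are SI floats.  Angular-speed conventions differ
between correlations and are documented per function: ``stirred_reynolds``
and ``tip_speed`` interpret rotational speed in rad s⁻¹, while
``power_draw`` (power-number convention) and ``integrated_shear_factor``
use rev s⁻¹.  Each exposes a ``convention`` override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FluidProperties",
    "CylindricalConduit",
    "RectangularChannel",
    "StirredVessel",
    "FlowConditions",
    "mean_velocity",
    "pipe_reynolds",
    "flow_regime",
    "pipe_wall_shear_rate",
    "rect_wall_shear_rate",
    "hydraulic_diameter",
    "channel_reynolds",
    "residence_time",
    "residence_time_volumetric",
    "peclet_number",
    "shm_mixing_time",
    "stirred_reynolds",
    "power_number",
    "power_draw",
    "tip_speed",
    "integrated_shear_factor",
    "average_shear_rate",
    "energy_dissipation",
    "fickian_time",
    "fickian_length",
    "PIPE_LAMINAR_THRESHOLD",
    "DEFAULT_SHM_MIXING_LENGTH",
]

#: Laminar/turbulent transition for pipe flow.
PIPE_LAMINAR_THRESHOLD = 2100.0

#: c·λ (m) in the chaotic-advection mixing-length law Δy = c·λ·ln(Pe),
#: calibrated so the reference SHM cartridge (79×200 μm channel, grooves
#: 31 μm, 5:1 isopropanol/water at 1 mL min⁻¹ total) returns the
#: manufacturer-quoted 21 ms micro-mixing time.  A calibration, not a
#: prediction.
DEFAULT_SHM_MIXING_LENGTH = 1.7084e-3


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density ρ (kg m⁻³), dynamic viscosity μ (Pa·s),
    optional diffusion coefficient D (m² s⁻¹)."""

    density: float
    dynamic_viscosity: float
    diffusion_coefficient: float | None = None

    def __post_init__(self) -> None:
        _require_positive("density", self.density)
        _require_positive("dynamic_viscosity", self.dynamic_viscosity)
        if self.diffusion_coefficient is not None:
            _require_positive("diffusion_coefficient", self.diffusion_coefficient)


@dataclass(frozen=True)
class CylindricalConduit:
    """Straight cylinder approximation of a needle or syringe barrel (m)."""

    internal_diameter: float
    length: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("internal_diameter", self.internal_diameter)
        if self.length < 0:
            raise ValueError("length must be >= 0")

    @property
    def cross_section_area(self) -> float:
        return math.pi * (self.internal_diameter / 2.0) ** 2


@dataclass(frozen=True)
class RectangularChannel:
    """Rectangular microchannel w×h (m) with optional herringbone groove
    depth; ``length`` is the mixing-path length."""

    width: float
    height: float
    groove_depth: float = 0.0
    length: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("width", self.width)
        _require_positive("height", self.height)
        if self.groove_depth < 0:
            raise ValueError("groove_depth must be >= 0")
        if self.length < 0:
            raise ValueError("length must be >= 0")

    @property
    def cross_section_area(self) -> float:
        """Ungrooved cross-section w·h."""
        return self.width * self.height


@dataclass(frozen=True)
class StirredVessel:
    """Stirred vessel with a paddle-approximated stir bar.

    ``rotational_speed`` is in rev min⁻¹ (rpm), the unit stirrer plates
    display; conversions happen inside each correlation.
    """

    impeller_diameter: float
    blade_height: float
    n_blades: int
    reactor_diameter: float
    fill_volume: float
    rotational_speed: float

    def __post_init__(self) -> None:
        _require_positive("impeller_diameter", self.impeller_diameter)
        _require_positive("blade_height", self.blade_height)
        _require_positive("reactor_diameter", self.reactor_diameter)
        _require_positive("fill_volume", self.fill_volume)
        if self.n_blades < 1:
            raise ValueError("n_blades must be >= 1")
        if self.rotational_speed < 0:
            raise ValueError("rotational_speed must be >= 0")
        if not self.impeller_diameter < self.reactor_diameter:
            raise ValueError("impeller_diameter must be < reactor_diameter")

    @property
    def rev_per_s(self) -> float:
        return self.rotational_speed / 60.0

    @property
    def rad_per_s(self) -> float:
        return self.rotational_speed * 2.0 * math.pi / 60.0


@dataclass(frozen=True)
class FlowConditions:
    """Volumetric flow rate Q (m³ s⁻¹)."""

    volumetric_flow_rate: float

    def __post_init__(self) -> None:
        if self.volumetric_flow_rate < 0:
            raise ValueError("volumetric_flow_rate must be >= 0")


def _q(flow: FlowConditions | float) -> float:
    return (
        flow.volumetric_flow_rate if isinstance(flow, FlowConditions) else float(flow)
    )


def mean_velocity(flow: FlowConditions | float, cross_section_area: float) -> float:
    """Mean (superficial) velocity v = Q/A in m s⁻¹."""
    _require_positive("cross_section_area", cross_section_area)
    return _q(flow) / cross_section_area


def pipe_reynolds(
    fluid: FluidProperties,
    conduit: CylindricalConduit,
    flow: FlowConditions | float,
) -> float:
    """Pipe Reynolds number Re = ρ·v·d/μ."""
    v = mean_velocity(flow, conduit.cross_section_area)
    return fluid.density * v * conduit.internal_diameter / fluid.dynamic_viscosity


def flow_regime(reynolds: float, threshold: float = PIPE_LAMINAR_THRESHOLD) -> str:
    """Classify pipe flow as ``"laminar"`` or ``"turbulent"``."""
    return "laminar" if reynolds < threshold else "turbulent"


def pipe_wall_shear_rate(
    conduit: CylindricalConduit, flow: FlowConditions | float
) -> float:
    """Laminar Newtonian wall shear rate γ_w = 4Q/(πR³) in s⁻¹."""
    r = conduit.internal_diameter / 2.0
    return 4.0 * _q(flow) / (math.pi * r**3)


def rect_wall_shear_rate(
    channel: RectangularChannel,
    flow: FlowConditions | float,
    exact: bool = False,
) -> float:
    """Wall shear rate of laminar flow in a rectangular channel, s⁻¹.

    The groove depth is excluded: shear is evaluated for the plain
    rectangular section.  The default is the wide-slot approximation
    γ_w = 6Q/(w·h²); ``exact=True`` applies the aspect-ratio correction
    γ_w = (6Q/(w·h²))·(1 + h/w)·f*(h/w) with Shah & London's shape factor
    f*(α) ≈ 1 − 0.351·α evaluated for the short-side midpoint.
    """
    w, h = channel.width, channel.height
    gamma = 6.0 * _q(flow) / (w * h * h)
    if exact:
        alpha = min(h / w, w / h)
        gamma *= (1.0 + alpha) * (1.0 - 0.351 * alpha)
    return gamma


def hydraulic_diameter(
    channel: RectangularChannel, include_groove: bool = True
) -> float:
    """Hydraulic diameter D_h = 4A/P of the rectangular section, m.

    ``include_groove=True`` adds the herringbone groove depth to the
    channel height (the effective section the flow samples on average).
    """
    h = channel.height + (channel.groove_depth if include_groove else 0.0)
    return 4.0 * channel.width * h / (2.0 * (channel.width + h))


def channel_reynolds(
    fluid: FluidProperties,
    channel: RectangularChannel,
    flow: FlowConditions | float,
    strict: bool = False,
) -> float:
    """Micromixer Reynolds number Re = ρ·v·D_h/μ.

    Default convention: mean velocity from the ungrooved w×h section
    (where the superficial velocity is set) and D_h from the grooved
    section (the length scale the flow samples).  ``strict=True`` uses
    the ungrooved section for both.
    """
    v = mean_velocity(flow, channel.cross_section_area)
    d_h = hydraulic_diameter(channel, include_groove=not strict)
    return fluid.density * v * d_h / fluid.dynamic_viscosity


def residence_time(path_length: float, velocity: float) -> float:
    """Plug-flow residence time t = L/v, s."""
    _require_positive("velocity", velocity)
    if path_length < 0:
        raise ValueError("path_length must be >= 0")
    return path_length / velocity


def residence_time_volumetric(volume: float, flow: FlowConditions | float) -> float:
    """Residence time t = V/Q from the fluidic volume, s."""
    q = _q(flow)
    _require_positive("flow rate", q)
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return volume / q


def peclet_number(
    velocity: float, characteristic_length: float, diffusivity: float
) -> float:
    """Peclet number Pe = v·L/D (convective vs diffusive transport)."""
    _require_positive("diffusivity", diffusivity)
    return velocity * characteristic_length / diffusivity


def shm_mixing_time(
    channel: RectangularChannel,
    fluid: FluidProperties,
    flow: FlowConditions | float,
    model: str = "herringbone-log",
    mixing_length_scale: float = DEFAULT_SHM_MIXING_LENGTH,
) -> float:
    """Micro-mixing time of a staggered-herringbone mixer, s.

    The ``"herringbone-log"`` model uses the chaotic-advection mixing
    length Δy = c·λ·ln(Pe) (λ = half mixing-cycle length, c an order-one
    constant; supplied jointly as ``mixing_length_scale``) converted to
    time through the mean velocity.  The constant is calibrated, not
    predicted — see :data:`DEFAULT_SHM_MIXING_LENGTH`.
    """
    if model != "herringbone-log":
        raise ValueError(f"unknown mixing-time model {model!r}")
    if fluid.diffusion_coefficient is None:
        raise ValueError("fluid.diffusion_coefficient is required for Pe")
    v = mean_velocity(flow, channel.cross_section_area)
    if v == 0.0:
        raise ValueError("zero flow: mixing time undefined")
    pe = peclet_number(v, hydraulic_diameter(channel), fluid.diffusion_coefficient)
    if pe < 1.0:
        pe = 1.0  # fully diffusive limit: zero advective mixing length
    return mixing_length_scale * math.log(pe) / v


def stirred_reynolds(
    vessel: StirredVessel, fluid: FluidProperties, convention: str = "rad"
) -> float:
    """Impeller Reynolds number Re = ρ·ω·d²/μ.

    ``convention="rad"`` (default) takes ω in rad s⁻¹, which reproduces
    the stirred-vessel values quoted for this system; ``"rev"`` uses the
    textbook rev s⁻¹ form.
    """
    omega = {"rad": vessel.rad_per_s, "rev": vessel.rev_per_s}[convention]
    return (
        fluid.density * omega * vessel.impeller_diameter**2 / fluid.dynamic_viscosity
    )


def power_number(vessel: StirredVessel) -> float:
    """Maximum power number of a flat-paddle impeller, fully baffled:
    Np = 10·(n_b^0.7·(h_b/d))^1.3 (Kamei–Hiraoka correlation)."""
    ratio = vessel.blade_height / vessel.impeller_diameter
    return 10.0 * (vessel.n_blades**0.7 * ratio) ** 1.3


def power_draw(
    vessel: StirredVessel, fluid: FluidProperties, convention: str = "rev"
) -> float:
    """Impeller power draw P = Np·ρ·N³·d⁵, W.

    Standard power-number convention: N in rev s⁻¹ (override with
    ``convention="rad"``).
    """
    n = {"rev": vessel.rev_per_s, "rad": vessel.rad_per_s}[convention]
    return power_number(vessel) * fluid.density * n**3 * vessel.impeller_diameter**5


def power_per_volume(
    vessel: StirredVessel, fluid: FluidProperties, convention: str = "rev"
) -> float:
    """P/V in W m⁻³ at the vessel fill volume."""
    return power_draw(vessel, fluid, convention) / vessel.fill_volume


def tip_speed(vessel: StirredVessel, convention: str = "rad") -> float:
    """Impeller tip speed = rotational speed × π × impeller diameter, m s⁻¹.

    Default reads rotational speed in rad s⁻¹ (the convention that
    reproduces the quoted 1.97 m s⁻¹ at 400 rpm, d = 15 mm); the rev s⁻¹
    reading (``convention="rev"``, the usual πNd) gives 0.314 m s⁻¹.
    """
    n = {"rad": vessel.rad_per_s, "rev": vessel.rev_per_s}[convention]
    return n * math.pi * vessel.impeller_diameter


def integrated_shear_factor(vessel: StirredVessel, convention: str = "rev") -> float:
    """Integrated shear factor ISF = 2πN·d/(D − d), s⁻¹, with N in
    rev s⁻¹ (standard ISF convention)."""
    gap = vessel.reactor_diameter - vessel.impeller_diameter
    if gap <= 0:
        raise ValueError("reactor_diameter must exceed impeller_diameter")
    n = {"rev": vessel.rev_per_s, "rad": vessel.rad_per_s}[convention]
    return 2.0 * math.pi * n * vessel.impeller_diameter / gap


def average_shear_rate(power: float, fluid: FluidProperties, volume: float) -> float:
    """Average shear rate γ̄ = √(P/(μ·V)), s⁻¹."""
    _require_positive("volume", volume)
    if power < 0:
        raise ValueError("power must be >= 0")
    return math.sqrt(power / (fluid.dynamic_viscosity * volume))


def energy_dissipation(power: float, fluid: FluidProperties, volume: float) -> float:
    """Energy dissipation per unit mass ε = P/(ρ·V), W kg⁻¹."""
    _require_positive("volume", volume)
    if power < 0:
        raise ValueError("power must be >= 0")
    return power / (fluid.density * volume)


def fickian_time(length: float, diffusivity: float, factor: float = 4.0) -> float:
    """Fickian diffusion time t = L²/(factor·D); factor 4 is the 1-D
    convention (2 and 6 are the half-space and 3-D choices)."""
    _require_positive("diffusivity", diffusivity)
    _require_positive("factor", factor)
    return length**2 / (factor * diffusivity)


def fickian_length(time: float, diffusivity: float, factor: float = 4.0) -> float:
    """Fickian diffusion length L = √(factor·D·t)."""
    _require_positive("diffusivity", diffusivity)
    _require_positive("factor", factor)
    if time < 0:
        raise ValueError("time must be >= 0")
    return math.sqrt(factor * diffusivity * time)
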