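"""Seeded synthetic-data generators for every analysis stage.

Each generator emits data with the statistical structure its stage
assumes plus the ground truth used to assess recovery, so the whole
pipeline is testable without measured inputs.  All draws are fixed by
the seed (bit-reproducible); defaults mirror the reference process where
printed values exist (240 fps video, 4 cm⁻¹-resolution FTIR spectra,
four-participant round robin with grand mean 109 nm, thermograms over
20–350 °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dismt import FrameSequence, MaskRegion
from .ftir import Spectrum
from .interlab import RoundRobinTable
from .thermal import DEFAULT_SCAN_RATE, Thermogram

__all__ = [
    "MixingVideoConfig",
    "FTIRBand",
    "FTIRSpectrumConfig",
    "RoundRobinConfig",
    "ThermogramConfig",
    "gen_mixing_video",
    "gen_ftir_spectrum",
    "gen_round_robin",
    "gen_thermogram",
]


# --------------------------------------------------------------------------
# mixing videos


@dataclass(frozen=True)
class MixingVideoConfig:
    """Synthetic red→yellow homogenization video.

    The masked spatial SD of the normalized green channel follows
    σ(t) = σ∞ + (σ₀−σ∞)·e^(−t/τ) exactly: per-frame pixel noise is
    standardized over the mask (exact zero mean, unit SD) before scaling,
    so the prescribed relaxation is not blurred by estimator noise.
    ``duration`` defaults to 14τ, long enough that the 10-frame baseline
    window's tail bias moves the t₉₅% crossing by less than one frame.
    """

    tau: float = 2.0
    sigma0: float = 0.12
    sigma_inf: float = 0.02
    frame_rate: float = 240.0
    duration: float | None = None
    frame_shape: tuple[int, int] = (90, 80)
    mask: MaskRegion | None = None
    mean_green: float = 0.5
    total_intensity: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0 <= self.sigma_inf < self.sigma0:
            raise ValueError("need 0 <= sigma_inf < sigma0")


def gen_mixing_video(
    cfg: MixingVideoConfig | None = None, **overrides
) -> tuple[FrameSequence, dict]:
    """Build a lazily-evaluated frame sequence plus ground truth.

    Returns ``(sequence, truth)`` with truth keys ``t95`` (= τ·ln 20),
    ``tau``, ``sigma0``, ``sigma_inf`` and ``mask``.
    """
    if cfg is None:
        cfg = MixingVideoConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    h, w = cfg.frame_shape
    mask = cfg.mask
    if mask is None:
        rows, cols = max(h * 2 // 3, 2), max(w * 5 // 8, 2)
        r0, c0 = (h - rows) // 2, (w - cols) // 2
        mask = MaskRegion(r0, r0 + rows, c0, c0 + cols)
    mask.validate_for((h, w))
    duration = cfg.duration if cfg.duration is not None else 14.0 * cfg.tau
    n_frames = max(int(round(duration * cfg.frame_rate)) + 1, 12)
    rs, cs = mask.slice()
    area = mask.area

    def build(i: int) -> np.ndarray:
        t = i / cfg.frame_rate
        s = cfg.sigma_inf + (cfg.sigma0 - cfg.sigma_inf) * math.exp(-t / cfg.tau)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6D6978, i]))
        g = np.full((h, w), cfg.mean_green)
        # clip before standardizing: keeps every pixel intensity positive
        # for any sigma0 <= 0.13 while the masked SD stays exactly s
        z = np.clip(rng.standard_normal(area), -3.5, 3.5)
        z = (z - z.mean()) / z.std()  # exact sample moments
        g[rs, cs] = cfg.mean_green + s * z.reshape(mask.row1 - mask.row0, -1)
        frame = np.empty((h, w, 3), dtype=np.float64)
        green = g * cfg.total_intensity
        frame[:, :, 1] = green
        frame[:, :, 0] = frame[:, :, 2] = (cfg.total_intensity - green) / 2.0
        return frame

    seq = FrameSequence.from_callable(build, n_frames, cfg.frame_rate)
    truth = {
        "t95": cfg.tau * math.log(20.0),
        "tau": cfg.tau,
        "sigma0": cfg.sigma0,
        "sigma_inf": cfg.sigma_inf,
        "mask": mask,
    }
    return seq, truth


# --------------------------------------------------------------------------
# FTIR spectra


@dataclass(frozen=True)
class FTIRBand:
    center: float
    fraction: float  # % of total band area
    width: float = 3.5  # Gaussian SD, cm⁻¹ (FWHM ≈ 8.2)


#: Default amide-I mixture: 56% total β-sheet (intermolecular 36% +
#: anti-parallel 20%), random coil 17%, α-helix 9%, β-turn 14%,
#: side-chain 4% — a silk-nanoparticle-like composition.  All widths
#: equal, so absorbance-area fractions equal the second-derivative-area
#: fractions the deconvolution pipeline estimates.
DEFAULT_FTIR_BANDS = (
    FTIRBand(1609.0, 4.0),
    FTIRBand(1624.0, 36.0),
    FTIRBand(1645.0, 17.0),
    FTIRBand(1659.0, 9.0),
    FTIRBand(1680.0, 14.0),
    FTIRBand(1699.0, 20.0),
)


@dataclass(frozen=True)
class FTIRSpectrumConfig:
    """Amide-I spectrum: sum of Gaussians at 4 cm⁻¹ optical resolution
    plus Gaussian noise at the stated SNR (peak absorbance over noise
    SD; ``None`` or ``inf`` = noiseless).

    The storage grid is 2 cm⁻¹ — vendor FTIR software stores roughly
    two interpolated points per resolution element — and the noise is
    drawn white on the 4 cm⁻¹ resolution elements and interpolated to
    the storage grid, since instrument noise is band-limited by the
    lineshape just as the signal is.
    """

    bands: tuple[FTIRBand, ...] = DEFAULT_FTIR_BANDS
    grid: tuple[float, float, float] = (1500.0, 1800.0, 2.0)
    resolution: float = 4.0
    snr: float | None = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(b.fraction for b in self.bands)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"band fractions must sum to 100, got {total}")
        for b in self.bands:
            if not 1600.0 <= b.center <= 1700.0:
                raise ValueError(f"band center {b.center} outside 1600-1700 cm⁻¹")


def gen_ftir_spectrum(
    cfg: FTIRSpectrumConfig | None = None, **overrides
) -> tuple[Spectrum, dict]:
    """Synthetic amide-I spectrum plus true class fractions.

    Truth keys: ``fractions`` (center → % area) and ``total_beta``
    computed with the default class assignment.
    """
    from .ftir import DEFAULT_ASSIGNMENT, BETA_SHEET_CLASSES

    if cfg is None:
        cfg = FTIRSpectrumConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    lo, hi, step = cfg.grid
    nu = np.arange(lo, hi + step / 2, step)
    absorbance = np.zeros_like(nu)
    for b in cfg.bands:
        z = (nu - b.center) / b.width
        absorbance += b.fraction * np.exp(-0.5 * z * z) / (b.width * np.sqrt(2 * np.pi))
    if cfg.snr is not None and np.isfinite(cfg.snr):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x66746972]))
        nu_res = np.arange(lo, hi + cfg.resolution / 2, cfg.resolution)
        noise = rng.normal(0.0, absorbance.max() / cfg.snr, nu_res.shape)
        absorbance = absorbance + np.interp(nu, nu_res, noise)
    class_fracs: dict[str, float] = {}
    for b in cfg.bands:
        label = DEFAULT_ASSIGNMENT.classify(b.center)
        class_fracs[label] = class_fracs.get(label, 0.0) + b.fraction
    truth = {
        "fractions": class_fracs,
        "total_beta": sum(class_fracs.get(c, 0.0) for c in BETA_SHEET_CLASSES),
        "bands": cfg.bands,
    }
    return Spectrum(nu, absorbance), truth


# --------------------------------------------------------------------------
# round-robin tables


@dataclass(frozen=True)
class RoundRobinConfig:
    """Participant×replicate table: value = grand mean + participant
    effect N(0, s_L²) + replicate noise N(0, s_r²).

    Defaults mirror the four-participant microfluidic size study:
    grand mean 109 nm, n = (3, 4, 3, 4) replicates, s_r = 13/2.8 ≈ 4.64
    and s_L = √((17/2.8)² − s_r²) ≈ 3.91 back-computed from the 95%
    repeatability/reproducibility limits of 13 and 17 nm.
    """

    n_per_cell: tuple[int, ...] = (3, 4, 3, 4)
    grand_mean: float = 109.0
    s_r: float = 13.0 / 2.8
    s_L: float = 3.91
    property_name: str = "size"
    units: str = "nm"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cell) < 2 or any(n < 2 for n in self.n_per_cell):
            raise ValueError("need >= 2 participants with >= 2 replicates each")
        if self.s_r < 0 or self.s_L < 0:
            raise ValueError("variance components must be >= 0")


def gen_round_robin(
    cfg: RoundRobinConfig | None = None, **overrides
) -> tuple[RoundRobinTable, dict]:
    if cfg is None:
        cfg = RoundRobinConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x726F626E]))
    cells: dict[str, np.ndarray] = {}
    for i, n in enumerate(cfg.n_per_cell, start=1):
        effect = rng.normal(0.0, cfg.s_L) if cfg.s_L > 0 else 0.0
        noise = rng.normal(0.0, cfg.s_r, n) if cfg.s_r > 0 else np.zeros(n)
        cells[f"participant_{i}"] = cfg.grand_mean + effect + noise
    table = RoundRobinTable(cells, cfg.property_name, cfg.units)
    truth = {
        "grand_mean": cfg.grand_mean,
        "s_r": cfg.s_r,
        "s_L": cfg.s_L,
        "s_R": math.hypot(cfg.s_r, cfg.s_L),
    }
    return table, truth


# --------------------------------------------------------------------------
# thermograms


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ThermogramConfig:
    """Paired TGA/DSC curves over 20–350 °C.

    TGA: 100% minus a logistic water-loss step (midpoint ``water_mid``)
    minus a logistic decomposition step whose midpoint is the true
    decomposition peak T_dec and whose extrapolated onset is
    T_o = T_dec − 2·``dec_width``.  DSC: Gaussian desorption endotherm
    (center = T_d, time-domain area = ``endo_area`` J g⁻¹, negative)
    plus a logistic exotherm shoulder at decomposition.
    """

    water_step: float = 13.0       # % w/w
    water_mid: float = 80.0        # °C
    water_width: float = 8.0       # logistic scale, °C
    dec_mid: float = 290.0         # °C (TGA T_dec)
    dec_width: float = 6.0         # °C; T_o = dec_mid − 2·dec_width
    dec_drop: float = 40.0         # % mass lost in decomposition step
    endo_center: float = 60.0      # °C (DSC T_d)
    endo_sd: float = 10.0          # °C
    endo_area: float = -150.0      # J g⁻¹, endothermic
    exo_height: float = 0.3        # W g⁻¹ shoulder amplitude
    t_range: tuple[float, float] = (20.0, 350.0)
    grid_step: float = 0.1         # °C
    tga_noise: float = 0.01        # mass-% SD
    dsc_noise: float = 0.002       # W g⁻¹ SD
    scan_rate: float = DEFAULT_SCAN_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.t_range
        for name, val in (
            ("water_mid", self.water_mid),
            ("dec_mid", self.dec_mid),
            ("endo_center", self.endo_center),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside the {lo}-{hi} °C range")
        if self.water_step < 0 or self.dec_drop < 0:
            raise ValueError("step amplitudes must be >= 0")


def gen_thermogram(
    cfg: ThermogramConfig | None = None, **overrides
) -> tuple[Thermogram, Thermogram, dict]:
    """Return ``(tga, dsc, truth)``.

    Truth holds the analytic features of the noiseless curves:
    ``water_content`` (mass lost across 20–140 °C), ``t_o`` (tangent
    intersection of the decomposition logistic, = dec_mid − 2·dec_width),
    ``t_dec``, ``t_d`` and ``dh_d`` (endotherm area inside 20–140 °C).
    """
    if cfg is None:
        cfg = ThermogramConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    lo, hi = cfg.t_range
    t = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7468726D]))

    water = cfg.water_step * _logistic((t - cfg.water_mid) / cfg.water_width)
    dec = cfg.dec_drop * _logistic((t - cfg.dec_mid) / cfg.dec_width)
    mass = 100.0 - water - dec
    if cfg.tga_noise > 0:
        mass = mass + rng.normal(0.0, cfg.tga_noise, t.shape)
    mass = np.clip(mass, 1e-6, 100.0)

    rate_c_per_s = cfg.scan_rate / 60.0
    # Gaussian endotherm: time-domain area = endo_area J/g
    amp = cfg.endo_area * rate_c_per_s / (cfg.endo_sd * np.sqrt(2 * np.pi))
    z = (t - cfg.endo_center) / cfg.endo_sd
    heat = amp * np.exp(-0.5 * z * z)
    heat = heat + cfg.exo_height * _logistic((t - cfg.dec_mid) / cfg.dec_width)
    if cfg.dsc_noise > 0:
        heat = heat + rng.normal(0.0, cfg.dsc_noise, t.shape)

    def logi(x: float, mid: float, k: float) -> float:
        return 1.0 / (1.0 + math.exp(-(x - mid) / k))

    water_truth = cfg.water_step * (
        logi(140.0, cfg.water_mid, cfg.water_width)
        - logi(20.0, cfg.water_mid, cfg.water_width)
    )
    # endotherm mass fraction captured inside the 20-140 °C window
    from math import erf, sqrt

    def phi(x: float) -> float:
        return 0.5 * (1.0 + erf(x / sqrt(2.0)))

    captured = phi((140.0 - cfg.endo_center) / cfg.endo_sd) - phi(
        (20.0 - cfg.endo_center) / cfg.endo_sd
    )
    truth = {
        "water_content": water_truth,
        "t_o": cfg.dec_mid - 2.0 * cfg.dec_width,
        "t_dec": cfg.dec_mid,
        "t_d": cfg.endo_center,
        "dh_d": cfg.endo_area * captured,
    }
    return (
        Thermogram(t, mass, "tga"),
        Thermogram(t, heat, "dsc"),
        truth,
    )
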