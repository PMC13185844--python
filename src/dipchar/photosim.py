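"""Virtual material and virtual printer.

Every closed-loop component in this package is exercised against simulation
rather than hardware.  This module supplies the three fixtures that make that
possible:

* a photopolymerization-kinetics material model giving the radical initiation
  rate R_i and polymerization rate R_p as functions of optical intensity,
* a grayscale -> measured-modulus response (the "unknown material response"
  the stiffness-seeking loop probes), built as a saturating Hill-type
  function of R_p with multiplicative measurement noise, and
* synthetic uniaxial compression traces (hydrostatic background + linear
  elastic structural term + noise) and TPMS lattice voxel geometries.

The kinetics follow the classical steady-state free-radical scheme:
``R_i = 2 f0 phi alpha [PI] I0 exp(-alpha [PI] L / 2)`` evaluated mid-depth,
and ``R_p = k_p [M] sqrt(R_i / (2 k_t))``, so R_p scales with the square root
of intensity.  The Hill link from R_p to modulus is an explicit stand-in for
the real (unknown) opto-mechanical response, not a claim about chemistry; its
parameters are configuration-exposed and chosen to reproduce both the
near-linear and the sigmoidal response regimes seen in graded prints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .mechtest import G_STANDARD, ForceTrace, HydrostaticModel

__all__ = [
    "MaterialModel",
    "ResponseModel",
    "VirtualSpecimen",
    "initiation_rate",
    "polymerization_rate",
    "grayscale_to_intensity",
    "modulus_response",
    "simulate_compression",
    "simulate_density_sweep",
    "tpms_geometry",
    "TPMS_FAMILIES",
]


@dataclass(frozen=True)
class MaterialModel:
    """Photopolymerization constants for the kinetics equations.

    Defaults describe a dilute acrylate formulation; only ratios matter for
    the response shape, since the seek loop never sees absolute rates.
    """

    kp: float = 500.0  # propagation rate constant, L mol^-1 s^-1
    M_conc: float = 1.0  # monomer concentration, mol L^-1
    kt: float = 5e7  # termination rate constant, L mol^-1 s^-1
    f0: float = 0.5  # initiator efficiency
    phi: float = 0.6  # quantum yield
    alpha_abs: float = 150.0  # initiator absorption, L mol^-1 cm^-1
    PI_conc: float = 0.01  # photoinitiator concentration, mol L^-1
    I0_max: float = 1e-5  # peak incident intensity, einstein L^-1 s^-1
    depth_L: float = 0.005  # optical path length, cm

    def __post_init__(self):
        for name in (
            "kp",
            "M_conc",
            "kt",
            "f0",
            "phi",
            "alpha_abs",
            "PI_conc",
            "I0_max",
            "depth_L",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"material parameter {name} must be non-negative")
        if self.kt <= 0:
            raise DomainError("termination rate kt must be positive")


def initiation_rate(material: MaterialModel, I0: float | None = None) -> float:
    """Local radical initiation rate R_i at mid-depth.

    R_i = 2 f0 phi alpha [PI] I0 exp(-alpha [PI] L / 2); ``I0`` defaults to
    the material's peak intensity.
    """
    if I0 is None:
        I0 = material.I0_max
    m = material
    attenuation = np.exp(-m.alpha_abs * m.PI_conc * m.depth_L / 2.0)
    return 2.0 * m.f0 * m.phi * m.alpha_abs * m.PI_conc * I0 * attenuation


def polymerization_rate(material: MaterialModel, I0: float | None = None) -> float:
    """Steady-state polymerization rate R_p = k_p [M] sqrt(R_i / (2 k_t))."""
    if material.kt <= 0:
        raise DomainError("termination rate kt must be positive")
    ri = initiation_rate(material, I0)
    return material.kp * material.M_conc * np.sqrt(ri / (2.0 * material.kt))


def grayscale_to_intensity(g, I0_max: float):
    """Linear dose map I0 = (g/255) * I0_max for 8-bit grayscale g."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g > 255):
        raise DomainError("grayscale values must lie in [0, 255]")
    out = (g / 255.0) * I0_max
    return float(out) if out.ndim == 0 else out


@dataclass
class ResponseModel:
    """Synthetic grayscale -> measured modulus oracle.

    Mean response: E(g) = E_sat * R_p(g)^n / (half_rate^n + R_p(g)^n), a
    monotone saturating (Hill) function of the polymerization rate.  Because
    R_p scales with sqrt(g), a Hill exponent n produces a response that is
    sigmoidal in g for n > 2 and near-linear for small n.  A measurement
    adds Gaussian noise with standard deviation noise_sd_frac * E(g),
    mimicking the modulus-measurement repeatability of in-situ compression.

    A single seeded generator drives the noise, so repeated calls with the
    same seed *and call order* reproduce bit-identically.
    """

    material: MaterialModel = field(default_factory=MaterialModel)
    E_sat: float = 40e3  # saturation modulus, Pa
    half_rate: float | None = None  # R_p at half saturation; default: R_p(g=128)
    hill_n: float = 4.0
    noise_sd_frac: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if self.half_rate is None:
            self.half_rate = polymerization_rate(
                self.material, grayscale_to_intensity(128.0, self.material.I0_max)
            )
        self._rng = np.random.default_rng(self.seed)

    def mean(self, g: float) -> float:
        """Noise-free mean modulus at grayscale g (Pa)."""
        rp = polymerization_rate(
            self.material, grayscale_to_intensity(g, self.material.I0_max)
        )
        if rp == 0.0:
            return 0.0
        return float(
            self.E_sat * rp**self.hill_n / (self.half_rate**self.hill_n + rp**self.hill_n)
        )

    def __call__(self, g: float, rng: np.random.Generator | None = None) -> float:
        return modulus_response(g, self, rng)


def modulus_response(
    g: float, model: ResponseModel, rng: np.random.Generator | None = None
) -> float:
    """One noisy modulus measurement at grayscale g (Pa)."""
    if rng is None:
        rng = model._rng
    mean = model.mean(g)
    return mean + rng.normal(0.0, model.noise_sd_frac * mean)


@dataclass(frozen=True)
class VirtualSpecimen:
    """Geometry, stiffness and bath conditions of a simulated construct."""

    E_true: float  # Pa
    diameter_D: float = 0.010  # m
    height_H0: float = 0.005  # m
    hydro: HydrostaticModel = field(
        default_factory=lambda: HydrostaticModel(
            beta0=0.05, beta1=1000.0 * G_STANDARD * 1e-4, wetted_area_Ap=1e-4
        )
    )
    buckling_strain: float | None = None  # stress plateau onset, optional

    def __post_init__(self):
        if self.diameter_D <= 0 or self.height_H0 <= 0:
            raise DomainError("specimen dimensions must be positive")


def simulate_density_sweep(
    spec: VirtualSpecimen,
    z_range: tuple[float, float],
    n_samples: int = 100,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_dt: float = 0.01,
) -> ForceTrace:
    """No-contact vertical sweep: pure hydrostatic force + noise.

    Emulates the pre-print density calibration pass through ``z_range``
    (typically 25 % of the container height).
    """
    rng = np.random.default_rng() if rng is None else rng
    z = np.linspace(z_range[0], z_range[1], n_samples)
    f = spec.hydro.predict(z) + rng.normal(0.0, noise_sd, n_samples)
    return ForceTrace(time=np.arange(n_samples) * sample_dt, z=z, force=f)


def simulate_compression(
    spec: VirtualSpecimen,
    strain_schedule,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    n_approach: int = 50,
    approach_span: float | None = None,
    z_contact: float = 0.02,
    sample_dt: float = 0.01,
) -> ForceTrace:
    """Raw (uncorrected) compression trace for a linear-elastic specimen.

    The trace begins with ``n_approach`` no-contact samples descending over
    ``approach_span`` (default 0.5 * H0) to the contact height, then follows
    the strain schedule with z = z_contact - strain * H0.  Measured force is
    hydrostatic background + A0 * E_true * strain (optionally capped past the
    buckling strain) + Gaussian noise.
    """
    eps = np.asarray(strain_schedule, dtype=float)
    if np.any(eps < 0) or np.any(eps >= 1):
        raise DomainError("strain schedule must lie in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    if approach_span is None:
        approach_span = 0.5 * spec.height_H0

    z_app = np.linspace(z_contact + approach_span, z_contact, n_approach, endpoint=False)
    z_cmp = z_contact - eps * spec.height_H0
    z = np.concatenate([z_app, z_cmp])

    a0 = np.pi * (spec.diameter_D / 2.0) ** 2
    sigma = spec.E_true * eps
    if spec.buckling_strain is not None:
        sigma = np.minimum(sigma, spec.E_true * spec.buckling_strain)
    f_struct = np.concatenate([np.zeros(n_approach), a0 * sigma])

    f = spec.hydro.predict(z) + f_struct + rng.normal(0.0, noise_sd, z.size)
    return ForceTrace(time=np.arange(z.size) * sample_dt, z=z, force=f)


# ---------------------------------------------------------------------------
# TPMS voxel fixtures
# ---------------------------------------------------------------------------


def _gyroid(x, y, z):
    return np.sin(x) * np.cos(y) + np.sin(y) * np.cos(z) + np.sin(z) * np.cos(x)


def _diamond(x, y, z):
    return (
        np.sin(x) * np.sin(y) * np.sin(z)
        + np.sin(x) * np.cos(y) * np.cos(z)
        + np.cos(x) * np.sin(y) * np.cos(z)
        + np.cos(x) * np.cos(y) * np.sin(z)
    )


def _split_p(x, y, z):
    return (
        1.1
        * (
            np.sin(2 * x) * np.cos(y) * np.sin(z)
            + np.sin(2 * y) * np.cos(z) * np.sin(x)
            + np.sin(2 * z) * np.cos(x) * np.sin(y)
        )
        - 0.2
        * (
            np.cos(2 * x) * np.cos(2 * y)
            + np.cos(2 * y) * np.cos(2 * z)
            + np.cos(2 * z) * np.cos(2 * x)
        )
        - 0.4 * (np.cos(2 * x) + np.cos(2 * y) + np.cos(2 * z))
    )


def _fluorite(x, y, z):
    # Schoen F-RD level set, the standard "fluorite" lattice surface
    return 4.0 * np.cos(x) * np.cos(y) * np.cos(z) - (
        np.cos(2 * x) * np.cos(2 * y)
        + np.cos(2 * y) * np.cos(2 * z)
        + np.cos(2 * z) * np.cos(2 * x)
    )


TPMS_FAMILIES = {
    "gyroid": _gyroid,
    "diamond": _diamond,
    "split_p": _split_p,
    "fluorite": _fluorite,
}

#: unit-cell sizes (mm) used throughout the lattice sweep fixtures
UNIT_CELL_PRESETS_MM = (2.0, 4.0, 6.0)


def tpms_geometry(
    family: str,
    unit_cell_mm: float = 4.0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_mm: float = 0.1,
    threshold: float = 0.0,
) -> np.ndarray:
    """Binary occupancy grid of a TPMS lattice (solid where F(x) <= threshold).

    Coordinates are voxel-centred; the implicit equations are evaluated with
    period ``unit_cell_mm``, so the occupancy is periodic with the requested
    cell size whenever the cell spans an integer number of voxels.
    """
    if family not in TPMS_FAMILIES:
        raise DomainError(
            f"unknown TPMS family {family!r}; choose from {sorted(TPMS_FAMILIES)}"
        )
    if unit_cell_mm <= 0 or voxel_mm <= 0 or any(s <= 0 for s in grid_shape):
        raise DomainError("unit cell, voxel pitch and grid shape must be positive")
    # when the cell spans an integer number of voxels, reduce indices modulo
    # the cell so voxels one cell apart evaluate bit-identical arguments
    # (exact periodicity of the thresholded grid even on the iso-surface)
    per = unit_cell_mm / voxel_mm
    if abs(per - round(per)) < 1e-9:
        p = round(per)
        axes = [2.0 * np.pi * (np.arange(n) % p + 0.5) / p for n in grid_shape]
    else:
        axes = [
            2.0 * np.pi * (np.arange(n) + 0.5) * voxel_mm / unit_cell_mm
            for n in grid_shape
        ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return (TPMS_FAMILIES[family](x, y, z) <= threshold).astype(np.uint8)
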