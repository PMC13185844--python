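"""Load-cell metrology and effective-modulus estimation for in-fluid testing.

Printed constructs are compressed *in situ*, inside the unpolymerized resin
bath, immediately after fabrication.  The measured load therefore contains a
buoyancy/hydrostatic component that varies linearly with print-head depth and
can rival the structural force for soft gels.  This module provides the full
metrology chain:

1. load-cell calibration from traceable test masses (ADC counts -> newtons),
2. hydrostatic regression over a pre-print vertical sweep and its subtraction
   from compression traces,
3. contact-point detection on the corrected trace,
4. engineering stress/strain conversion using the construct's apparent
   footprint area, and
5. the effective structural modulus E_eff as the least-squares slope of the
   stress-strain curve over a fixed strain window (default 5-10 % strain).

All quantities are SI internally (N, m, Pa); grams and raw counts appear only
inside the calibration step.  Compression is sign-positive: decreasing stage
height z past the contact point gives positive strain, and force pushing on
the print head is positive stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateFitError,
    DomainError,
    DoubleCorrectionError,
    InsufficientDataError,
    NoContactError,
)

G_STANDARD = 9.81  # m s^-2

__all__ = [
    "CalibrationCurve",
    "HydrostaticModel",
    "ForceTrace",
    "StressStrainCurve",
    "ModulusEstimate",
    "calibrate_load_cell",
    "fit_hydrostatic",
    "subtract_hydrostatic",
    "detect_contact",
    "stress_strain",
    "effective_modulus",
    "run_characterisation",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine ADC-counts -> force map fitted from traceable test masses.

    The fitted model is ``mass_g = scale_alpha * (counts - offset_beta)`` so
    that predicted force is ``F = g_const * scale_alpha * (D - offset_beta)``
    in newtons (alpha in grams/count, beta in counts: the zero-load bias).
    """

    scale_alpha: float  # grams per count
    offset_beta: float  # counts at zero load
    g_const: float = G_STANDARD
    full_scale: float = 0.0  # newtons; largest calibrated force
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))  # N

    def counts_to_force(self, counts) -> np.ndarray:
        """Predicted force (N) for raw ADC counts."""
        counts = np.asarray(counts, dtype=float)
        return self.g_const * self.scale_alpha * (counts - self.offset_beta) * 1e-3

    def validate(self, mass_g: float, counts: float, tol_frac: float = 5e-4) -> bool:
        """Check a held-out mass against the fit.

        Returns True when the force residual is within ``tol_frac`` of full
        scale (default 0.05 % FS, the load-cell linearity spec).
        """
        predicted = float(self.counts_to_force(counts))
        truth = self.g_const * mass_g * 1e-3
        return abs(predicted - truth) <= tol_frac * self.full_scale


@dataclass(frozen=True)
class HydrostaticModel:
    """Depth-linear hydrostatic force model ``F(z) = beta0 + beta1 * z``.

    ``beta1`` is the hydrostatic gradient rho * g * A_p, from which the resin
    density is inferred given the wetted print-head cross-section A_p.
    """

    beta0: float  # N at z = 0
    beta1: float  # N / m
    wetted_area_Ap: float  # m^2
    g_const: float = G_STANDARD
    fit_window: tuple[float, float] = (0.0, 0.0)  # [z_bottom, z_top] m

    @property
    def density_rho(self) -> float:
        """Inferred fluid density (kg m^-3)."""
        return self.beta1 / (self.g_const * self.wetted_area_Ap)

    def predict(self, z) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(z, dtype=float)


@dataclass(frozen=True)
class ForceTrace:
    """Time-ordered (t, z, F) samples; the unit of all metrology.

    ``corrected`` records whether the hydrostatic component has already been
    subtracted, guarding against double correction.
    """

    time: np.ndarray  # s
    z: np.ndarray  # m, stage height
    force: np.ndarray  # N
    corrected: bool = False

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        z = np.asarray(self.z, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (t.shape == z.shape == f.shape and t.ndim == 1):
            raise DomainError("trace arrays must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise DomainError("trace time must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise DomainError("trace forces must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress-strain pairs for a cylindrical construct."""

    strain: np.ndarray  # dimensionless, non-negative, non-decreasing
    stress: np.ndarray  # Pa
    footprint_area_A0: float  # m^2
    diameter_D: float  # m
    initial_height_H0: float  # m


@dataclass(frozen=True)
class ModulusEstimate:
    """Windowed least-squares slope of stress vs strain."""

    E_eff: float  # Pa
    strain_window_L: tuple[float, float]
    n_points_in_window: int
    fit_r2: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y ~ a*x + b; returns (slope, intercept, r2)."""
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 1.0
    return float(res.slope), float(res.intercept), r2


def calibrate_load_cell(
    points: Sequence[tuple[float, float]], g_const: float = G_STANDARD
) -> CalibrationCurve:
    """Fit the affine counts->force calibration from (mass_g, counts) pairs.

    Ordinary least squares of mass on counts; the slope is the scale factor
    alpha (g/count) and the zero crossing is the count offset beta.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("calibration needs >= 2 (mass, counts) points")
    mass_g, counts = pts[:, 0], pts[:, 1]
    if np.any(mass_g < 0):
        raise DomainError("calibration masses must be non-negative")
    if np.ptp(counts) == 0:
        raise DegenerateFitError("all calibration counts identical")
    slope, intercept, _ = _ols(counts, mass_g)
    if slope == 0 or not np.isfinite(slope):
        raise DegenerateFitError("calibration slope is zero or non-finite")
    alpha = slope
    beta = -intercept / slope
    full_scale = g_const * float(np.max(mass_g)) * 1e-3
    curve = CalibrationCurve(
        scale_alpha=alpha, offset_beta=beta, g_const=g_const, full_scale=full_scale
    )
    residuals = curve.counts_to_force(counts) - g_const * mass_g * 1e-3
    return replace(curve, residuals=residuals)


def apply_calibration(trace_counts: ForceTrace, curve: CalibrationCurve) -> ForceTrace:
    """Convert a raw-counts trace to newtons through a calibration curve."""
    return ForceTrace(
        time=trace_counts.time,
        z=trace_counts.z,
        force=curve.counts_to_force(trace_counts.force),
        corrected=False,
    )


def fit_hydrostatic(
    trace: ForceTrace, wetted_area_Ap: float, g_const: float = G_STANDARD
) -> HydrostaticModel:
    """Regress force on stage height over a no-contact vertical sweep.

    The slope beta1 ~= rho * g * A_p yields the formulation density before
    printing.  The sweep typically covers 25 % of the container height.
    """
    if wetted_area_Ap <= 0:
        raise DomainError("wetted area A_p must be positive")
    if len(trace) < 2:
        raise InsufficientDataError("hydrostatic fit needs >= 2 samples")
    if np.ptp(trace.z) == 0:
        raise DegenerateFitError("hydrostatic fit needs >= 2 distinct z values")
    slope, intercept, _ = _ols(trace.z, trace.force)
    return HydrostaticModel(
        beta0=intercept,
        beta1=slope,
        wetted_area_Ap=wetted_area_Ap,
        g_const=g_const,
        fit_window=(float(np.min(trace.z)), float(np.max(trace.z))),
    )


def subtract_hydrostatic(trace: ForceTrace, model: HydrostaticModel) -> ForceTrace:
    """Deconvolve the structural force: F_struct,j = F_meas,j - (b0 + b1 z_j)."""
    if trace.corrected:
        raise DoubleCorrectionError("trace already hydrostatically corrected")
    return ForceTrace(
        time=trace.time,
        z=trace.z,
        force=trace.force - model.predict(trace.z),
        corrected=True,
    )


def detect_contact(
    trace: ForceTrace,
    noise_sd: float | None = None,
    k_sigma: float = 5.0,
    m_sustain: int = 5,
) -> tuple[int, float]:
    """First index where |F| exceeds k_sigma * noise_sd for m_sustain samples.

    A sustained-threshold rule rejects single-sample spikes.  When ``noise_sd``
    is None it is estimated from the leading 10 % of samples, which are assumed
    to precede contact.  Returns ``(index, z_contact)``.
    """
    if not trace.corrected:
        raise DomainError("contact detection requires a corrected trace")
    f = trace.force
    if noise_sd is None:
        n_head = max(2, len(trace) // 10)
        noise_sd = float(np.std(f[:n_head]))
        if noise_sd == 0.0:
            noise_sd = 1e-12  # noiseless trace: any nonzero force triggers
    above = np.abs(f) > k_sigma * noise_sd
    run = 0
    for i, hit in enumerate(above):
        run = run + 1 if hit else 0
        if run >= m_sustain:
            idx = i - m_sustain + 1
            return idx, float(trace.z[idx])
    raise NoContactError(
        f"|force| never exceeded {k_sigma} x {noise_sd:.3g} N "
        f"for {m_sustain} consecutive samples"
    )


def stress_strain(
    trace: ForceTrace,
    diameter_D: float,
    initial_height_H0: float,
    z_contact: float,
) -> StressStrainCurve:
    """Engineering stress/strain after contact for a cylindrical footprint.

    A0 = pi (D/2)^2, strain = (z_contact - z)/H0 (compression positive),
    stress = F_struct / A0.  Samples above the contact height are dropped.
    """
    if diameter_D <= 0 or initial_height_H0 <= 0:
        raise DomainError("diameter and initial height must be positive")
    if not trace.corrected:
        raise DomainError("stress-strain requires a corrected trace")
    a0 = np.pi * (diameter_D / 2.0) ** 2
    eps = (z_contact - trace.z) / initial_height_H0
    keep = eps >= 0
    eps, sigma = eps[keep], trace.force[keep] / a0
    order = np.argsort(eps, kind="stable")
    return StressStrainCurve(
        strain=eps[order],
        stress=sigma[order],
        footprint_area_A0=a0,
        diameter_D=diameter_D,
        initial_height_H0=initial_height_H0,
    )


def effective_modulus(
    curve: StressStrainCurve, window: tuple[float, float] = (0.05, 0.10)
) -> ModulusEstimate:
    """E_eff = d(sigma)/d(epsilon) over the closed strain window.

    The default 5-10 % window avoids contact nonlinearity at small strain and
    geometry-driven effects (buckling, snap-through) at large strain.  Plain
    OLS on every point in the window; no smoothing.
    """
    lo, hi = window
    if not lo < hi:
        raise DomainError("strain window must satisfy lo < hi")
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    n = int(np.count_nonzero(mask))
    if n < 2 or np.ptp(curve.strain[mask]) == 0:
        raise InsufficientDataError(
            f"need >= 2 distinct-strain points in window [{lo}, {hi}], got {n}"
        )
    slope, _, r2 = _ols(curve.strain[mask], curve.stress[mask])
    return ModulusEstimate(
        E_eff=slope, strain_window_L=(lo, hi), n_points_in_window=n, fit_r2=r2
    )


def run_characterisation(
    sweep: ForceTrace,
    compression: ForceTrace,
    wetted_area_Ap: float,
    diameter_D: float,
    initial_height_H0: float,
    window: tuple[float, float] = (0.05, 0.10),
    g_const: float = G_STANDARD,
    k_sigma: float = 5.0,
    m_sustain: int = 5,
) -> tuple[ModulusEstimate, HydrostaticModel, StressStrainCurve]:
    """Full chain: density sweep -> correction -> contact -> window modulus."""
    hydro = fit_hydrostatic(sweep, wetted_area_Ap, g_const)
    corrected = subtract_hydrostatic(compression, hydro)
    _, z_contact = detect_contact(corrected, k_sigma=k_sigma, m_sustain=m_sustain)
    curve = stress_strain(corrected, diameter_D, initial_height_H0, z_contact)
    return effective_modulus(curve, window), hydro, curve
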