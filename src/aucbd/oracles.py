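"""Closed-form reference solutions for sedimentation in a sector cell.

These are the exact limits against which the stochastic engine is tested,
and the quick estimators used to seed the global fit:

* the diffusion-free sedimentation-velocity profile (sharp boundary at
  r_m exp(s w^2 t), plateau diluted by the square law exp(-2 s w^2 t));
* the sedimentation-equilibrium profile c(r) = A exp(sigma (r^2 - r_m^2)/2)
  with sigma = M_b w^2 / (R T), the zero-net-flux fixed point;
* boundary-midpoint tracking and the classical ln r(t) vs t regression for
  the sedimentation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bd_engine import ScanSet
from .errors import AnalysisError, ConfigurationError, DomainError
from .physics import R_GAS, SVEDBERG, CellGeometry, SoluteComponent

__all__ = [
    "BoundaryTrack",
    "no_diffusion_profile",
    "no_diffusion_boundary_radius",
    "equilibrium_sigma",
    "equilibrium_profile",
    "equilibrium_bin_probabilities",
    "sample_equilibrium_positions",
    "estimate_s_from_boundary",
    "locate_boundary",
]


@dataclass
class BoundaryTrack:
    """Radial position of the sedimenting boundary at successive scan times."""

    times: np.ndarray
    boundary_radii: np.ndarray
    estimated_s: float | None = None   # Svedberg
    s_stderr: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.boundary_radii = np.asarray(self.boundary_radii, dtype=float)
        if self.times.shape != self.boundary_radii.shape:
            raise DomainError("times and boundary_radii must have equal shapes")


def no_diffusion_boundary_radius(component: SoluteComponent,
                                 geometry: CellGeometry, omega: float,
                                 t: float) -> float:
    """Boundary position r_m exp(s w^2 t) of the diffusion-free profile."""
    return geometry.r_m * math.exp(component.s * SVEDBERG * omega ** 2 * t)


def no_diffusion_profile(component: SoluteComponent, geometry: CellGeometry,
                         omega: float, t: float, radii=None):
    """Piecewise diffusion-free profile z/z0 vs r at time t.

    Zero below the boundary, plateau exp(-2 s w^2 t) above it (radial
    dilution in the sector cell), truncated at the bottom.  If the boundary
    has passed the bottom the whole column is solvent (the solute sits in
    the bottom pellet, outside the reported column).
    """
    if t < 0:
        raise DomainError(f"t must be non-negative, got {t}")
    if radii is None:
        radii = np.linspace(geometry.r_m, geometry.r_b, 1001)
    radii = np.asarray(radii, dtype=float)
    r_bnd = no_diffusion_boundary_radius(component, geometry, omega, t)
    plateau = math.exp(-2.0 * component.s * SVEDBERG * omega ** 2 * t)
    z = np.where(radii < r_bnd, 0.0, plateau)
    if r_bnd >= geometry.r_b:
        z = np.zeros_like(radii)
    return radii, z


def equilibrium_sigma(buoyant_mw: float, omega: float,
                      temperature_K: float) -> float:
    """Reduced buoyant weight sigma = M_b w^2 / (R T), in cm^-2."""
    if buoyant_mw <= 0 or omega <= 0 or temperature_K <= 0:
        raise DomainError("buoyant_mw, omega and temperature must be positive")
    # (kg/mol) (rad/s)^2 / (J/mol) = m^-2; 1 m^-2 = 1e-4 cm^-2
    return buoyant_mw * 1e-3 * omega ** 2 / (R_GAS * temperature_K) * 1e-4


def equilibrium_profile(component: SoluteComponent, geometry: CellGeometry,
                        omega: float, temperature_K: float, radii=None):
    """Sedimentation-equilibrium concentration profile, loading-normalised.

    c(r) = A exp(sigma (r^2 - r_m^2) / 2) with A fixed so that the
    sector-weighted integral of c over the column equals that of the uniform
    loading profile (c = 1): integral of c(r) r dr = (r_b^2 - r_m^2) / 2.
    """
    if radii is None:
        radii = np.linspace(geometry.r_m, geometry.r_b, 1001)
    radii = np.asarray(radii, dtype=float)
    sigma = equilibrium_sigma(component.buoyant_mw, omega, temperature_K)
    span = geometry.r_b ** 2 - geometry.r_m ** 2
    x = sigma * span / 2.0
    # A = (sigma span / 2) / (exp(sigma span / 2) - 1); -> 1 as omega -> 0
    amplitude = x / math.expm1(x) if x > 1e-12 else 1.0
    c = amplitude * np.exp(sigma * (radii ** 2 - geometry.r_m ** 2) / 2.0)
    return radii, c


def equilibrium_bin_probabilities(component: SoluteComponent,
                                  geometry: CellGeometry, omega: float,
                                  temperature_K: float,
                                  n_bins: int) -> np.ndarray:
    """Probability for an equilibrated particle to fall in each radial bin.

    The particle (count) density is proportional to c(r) r, so the bin mass
    is the increment of exp(sigma r^2 / 2) across the bin.
    """
    sigma = equilibrium_sigma(component.buoyant_mw, omega, temperature_K)
    edges = geometry.bin_edges(n_bins)
    # stabilised: exp(sigma (r^2 - r_b^2)/2) increments, then normalised
    w = np.exp(sigma * (edges ** 2 - geometry.r_b ** 2) / 2.0)
    p = np.diff(w)
    return p / p.sum()


def sample_equilibrium_positions(n: int, component: SoluteComponent,
                                 geometry: CellGeometry, omega: float,
                                 temperature_K: float, rng) -> np.ndarray:
    """Draw n radii from the equilibrium particle density ~ c(r) r (inverse CDF)."""
    sigma = equilibrium_sigma(component.buoyant_mw, omega, temperature_K)
    span = geometry.r_b ** 2 - geometry.r_m ** 2
    u = rng.random(n)
    x = sigma * span / 2.0
    if x < 1e-12:
        return np.sqrt(geometry.r_m ** 2 + u * span)
    return np.sqrt(geometry.r_m ** 2 +
                   2.0 / sigma * np.log1p(u * math.expm1(x)))


def estimate_s_from_boundary(track: BoundaryTrack, omega: float):
    """Sedimentation coefficient from ln r(t) vs t.

    The boundary of a sedimenting species obeys ln[r(t)/r(t0)] = s w^2 (t-t0);
    the least-squares slope of ln r against t, divided by w^2, is s.  Returns
    (s in Svedberg, standard error in Svedberg; the standard error is NaN for
    a two-point track).
    """
    if track.times.size < 2:
        raise ConfigurationError("need at least 2 boundary points")
    if np.any(track.boundary_radii <= 0):
        raise DomainError("boundary radii must be positive")
    res = stats.linregress(track.times, np.log(track.boundary_radii))
    s = res.slope / omega ** 2 / SVEDBERG
    stderr = res.stderr / omega ** 2 / SVEDBERG if res.stderr is not None else math.nan
    return s, stderr


def locate_boundary(scan_set: ScanSet, geometry: CellGeometry = None,
                    plateau_window_cm: float = 0.5,
                    bottom_margin_cm: float = 0.2, meniscus_bins: int = 2,
                    min_plateau: float = 0.05,
                    flatness_tol: float = 0.15) -> BoundaryTrack:
    """Track the sedimentation boundary as the half-plateau crossing radius.

    For every scan the plateau is estimated as the median of z/z0 over a
    window of width ``plateau_window_cm`` just inside the bottom margin; a
    scan contributes a boundary point when that window is flat (interquartile
    range below ``flatness_tol`` of the plateau, so rising equilibrium-like
    profiles are rejected) and the profile crosses half the plateau somewhere
    inside the cell.  The crossing radius is linearly interpolated between
    bins.  Raises :class:`AnalysisError` when no scan yields a boundary.
    """
    if geometry is None:
        geometry = scan_set.meta.get("geometry") or scan_set.inferred_geometry()
    radii = scan_set.radii
    hi = geometry.r_b - bottom_margin_cm
    lo = hi - plateau_window_cm
    window = (radii >= lo) & (radii <= hi)
    if window.sum() < 3:
        raise AnalysisError(
            "plateau window too narrow: fewer than 3 bins between "
            f"r={lo:.3f} and r={hi:.3f} cm"
        )
    times, positions, reasons = [], [], []
    first = meniscus_bins
    for j, t in enumerate(scan_set.times):
        z = scan_set.z[:, j] / scan_set.z0
        zw = z[window]
        plateau = float(np.median(zw))
        if plateau < min_plateau:
            reasons.append(f"t={t:g}: plateau below {min_plateau}")
            continue
        q25, q75 = np.percentile(zw, [25, 75])
        if (q75 - q25) > flatness_tol * plateau:
            reasons.append(f"t={t:g}: plateau window not flat")
            continue
        half = plateau / 2.0
        zi = z[first:]
        ri = radii[first:]
        if zi[0] >= half:
            reasons.append(f"t={t:g}: boundary at or behind the meniscus")
            continue
        above = np.nonzero(zi >= half)[0]
        if above.size == 0:
            reasons.append(f"t={t:g}: no half-plateau crossing")
            continue
        i = above[0]
        r_half = ri[i - 1] + (half - zi[i - 1]) / (zi[i] - zi[i - 1]) * (
            ri[i] - ri[i - 1])
        times.append(float(t))
        positions.append(float(r_half))
    if not times:
        raise AnalysisError(
            "no scan with a resolvable boundary: " + "; ".join(reasons[:5])
        )
    return BoundaryTrack(times=np.array(times),
                         boundary_radii=np.array(positions))
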