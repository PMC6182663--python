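"""Physical constants, unit conversions and the algebraic relations of
analytical ultracentrifugation (AUC).

A dilute, non-interacting species in a centrifugal field is characterised by
its sedimentation coefficient ``s`` (in Svedberg, 1 S = 1e-13 s) and its
buoyant molecular weight ``M_b = M (1 - vbar * rho)`` in Da.  The Svedberg
relation ties the diffusion coefficient to the same pair,

    D = R T s / M_b ,

so ``(s, M_b)`` fully determines the transport of the species.  For mixtures,
each component additionally carries the fraction ``y`` of the loading signal
it contributes; ``y`` reduces to the weight fraction for mass-proportional
detection (absorbance/interference, alpha = 0) and to the number fraction for
molar-proportional detection (e.g. end-labelled fluorescence, alpha = 1) when
the specific signal constants ``q`` are equal.

Canonical internal units: cm for radius, s for time, rad/s for the rotor
angular velocity, Svedberg for user-facing sedimentation coefficients, Da for
masses and cm^2/s for diffusion coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, FlotationError

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314
#: Boltzmann constant, J K^-1.
BOLTZMANN = 1.380649e-23
#: One Svedberg, in seconds.
SVEDBERG = 1e-13


def rpm_to_omega(rpm):
    """Convert rotor speed in revolutions/min to angular velocity in rad/s."""
    rpm = np.asarray(rpm, dtype=float)
    if np.any(rpm <= 0):
        raise DomainError(f"rotor speed must be positive, got {rpm}")
    out = 2.0 * math.pi * rpm / 60.0
    return float(out) if out.ndim == 0 else out


def omega_to_rpm(omega):
    """Inverse of :func:`rpm_to_omega`."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise DomainError(f"angular velocity must be positive, got {omega}")
    out = omega * 60.0 / (2.0 * math.pi)
    return float(out) if out.ndim == 0 else out


def diffusion_coefficient(s, buoyant_mw, temperature_K):
    """Diffusion coefficient from the Svedberg relation, in cm^2/s.

    Parameters
    ----------
    s : float or array
        Sedimentation coefficient in Svedberg.
    buoyant_mw : float or array
        Buoyant molecular weight in Da (g/mol).
    temperature_K : float
        Absolute temperature.
    """
    s = np.asarray(s, dtype=float)
    mw = np.asarray(buoyant_mw, dtype=float)
    if np.any(s <= 0) or np.any(mw <= 0) or temperature_K <= 0:
        raise DomainError("s, buoyant_mw and temperature must all be positive")
    # D [m^2/s] = R T (s * 1e-13 s) / (M_b * 1e-3 kg/mol); 1 m^2 = 1e4 cm^2.
    d = R_GAS * temperature_K * (s * SVEDBERG) / (mw * 1e-3) * 1e4
    return float(d) if d.ndim == 0 else d


def sedimentation_coefficient(diffusion_cm2_s, buoyant_mw, temperature_K):
    """Inverse Svedberg relation: s (in Svedberg) from D (cm^2/s) and M_b (Da)."""
    d = np.asarray(diffusion_cm2_s, dtype=float)
    mw = np.asarray(buoyant_mw, dtype=float)
    if np.any(d <= 0) or np.any(mw <= 0) or temperature_K <= 0:
        raise DomainError("D, buoyant_mw and temperature must all be positive")
    s = (d * 1e-4) * (mw * 1e-3) / (R_GAS * temperature_K) / SVEDBERG
    return float(s) if s.ndim == 0 else s


def buoyant_mass(mw, vbar, rho):
    """Buoyant molecular weight M (1 - vbar * rho), in Da.

    Parameters
    ----------
    mw : float
        Molecular weight in Da.
    vbar : float
        Partial specific volume, cm^3/g.
    rho : float
        Solvent density, g/cm^3.
    """
    if mw <= 0:
        raise DomainError(f"molecular weight must be positive, got {mw}")
    if vbar < 0 or rho < 0:
        raise DomainError("vbar and rho must be non-negative")
    if vbar * rho >= 1.0:
        raise FlotationError(
            f"vbar*rho = {vbar * rho:.4f} >= 1: the species would float; "
            "only outward sedimentation is supported"
        )
    return mw * (1.0 - vbar * rho)


def signal_fractions(q, c0, mw, alpha):
    """Per-component signal fractions y_k from loading composition.

    Each component contributes ``z_0k = q_k c_0k / M_k^alpha_k`` to the
    initially uniform signal; ``y_k`` is that contribution normalised over the
    sample, so ``sum(y) == 1``.  ``alpha_k = 0`` for detection proportional to
    mass concentration, ``alpha_k = 1`` for molar concentration.
    """
    q = np.asarray(q, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    mw = np.asarray(mw, dtype=float)
    alpha = np.asarray(alpha)
    if not (q.shape == c0.shape == mw.shape == alpha.shape):
        raise DomainError("q, c0, mw and alpha must have equal lengths")
    if np.any(q <= 0) or np.any(c0 <= 0) or np.any(mw <= 0):
        raise DomainError("q, c0 and mw must be positive")
    if not np.all(np.isin(alpha, (0, 1))):
        raise DomainError(f"alpha values must be 0 or 1, got {alpha}")
    z0k = q * c0 / mw ** alpha.astype(float)
    total = z0k.sum()
    if not total > 0:
        raise DomainError("degenerate sample: total loading signal is zero")
    return z0k / total


@dataclass(frozen=True)
class SoluteComponent:
    """One non-interacting solute species.

    Parameters
    ----------
    s : float
        Sedimentation coefficient, Svedberg.
    buoyant_mw : float
        Buoyant molecular weight, Da.
    signal_fraction : float
        Fraction y of the loading signal contributed by this species.
    q, alpha, c0, mw, vbar, rho : optional
        Specific signal constant, signal exponent (0 or 1), loading mass
        concentration, molecular weight (Da), partial specific volume
        (cm^3/g) and solvent density (g/cm^3).  When ``mw``, ``vbar`` and
        ``rho`` are all given they must be consistent with ``buoyant_mw``.
    """

    s: float
    buoyant_mw: float
    signal_fraction: float = 1.0
    q: float | None = None
    alpha: int | None = None
    c0: float | None = None
    mw: float | None = None
    vbar: float | None = None
    rho: float | None = None

    def __post_init__(self):
        if self.s <= 0:
            raise DomainError(f"s must be positive, got {self.s}")
        if self.buoyant_mw <= 0:
            raise DomainError(f"buoyant_mw must be positive, got {self.buoyant_mw}")
        if not 0 < self.signal_fraction <= 1:
            raise DomainError(
                f"signal_fraction must be in (0, 1], got {self.signal_fraction}"
            )
        if self.alpha is not None and self.alpha not in (0, 1):
            raise DomainError(f"alpha must be 0 or 1, got {self.alpha}")
        if self.mw is not None and self.vbar is not None and self.rho is not None:
            implied = buoyant_mass(self.mw, self.vbar, self.rho)
            if abs(implied - self.buoyant_mw) > 1e-9 * abs(implied):
                raise DomainError(
                    f"buoyant_mw={self.buoyant_mw} inconsistent with "
                    f"mw*(1-vbar*rho)={implied}"
                )

    def diffusion_coefficient(self, temperature_K: float) -> float:
        """D in cm^2/s at the given temperature (Svedberg relation)."""
        return diffusion_coefficient(self.s, self.buoyant_mw, temperature_K)


@dataclass(frozen=True)
class CellGeometry:
    """Sector-shaped cell bounds: meniscus and bottom radii in cm."""

    r_m: float
    r_b: float

    def __post_init__(self):
        if not 0 < self.r_m < self.r_b:
            raise DomainError(
                f"need 0 < r_m < r_b, got r_m={self.r_m}, r_b={self.r_b}"
            )

    @property
    def width(self) -> float:
        return self.r_b - self.r_m

    def bin_width(self, n_bins: int) -> float:
        return self.width / n_bins

    def bin_edges(self, n_bins: int) -> np.ndarray:
        return np.linspace(self.r_m, self.r_b, n_bins + 1)

    def bin_midpoints(self, n_bins: int) -> np.ndarray:
        chi = self.bin_width(n_bins)
        return self.r_m + (np.arange(n_bins) + 0.5) * chi


@dataclass(frozen=True)
class RunConditions:
    """Instrumental conditions of one sedimentation run.

    ``scan_times`` are the times (s, strictly increasing, all within
    [0, t_run]) at which concentration profiles are reported.
    """

    rpm: float
    temperature_K: float
    t_run: float
    scan_times: tuple = field(default=None)

    def __post_init__(self):
        if self.rpm <= 0:
            raise DomainError(f"rpm must be positive, got {self.rpm}")
        if self.temperature_K <= 0:
            raise DomainError(
                f"temperature_K must be positive, got {self.temperature_K}"
            )
        if self.t_run < 0:
            raise DomainError(f"t_run must be non-negative, got {self.t_run}")
        times = self.scan_times
        if times is None:
            times = (self.t_run,)
        times = tuple(float(t) for t in np.atleast_1d(times))
        if any(t < 0 for t in times):
            raise DomainError("scan times must be non-negative")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DomainError(f"scan times must be strictly increasing: {times}")
        if times[-1] > self.t_run * (1 + 1e-12) + 1e-12:
            raise DomainError(
                f"scan times must not exceed t_run={self.t_run}: {times}"
            )
        object.__setattr__(self, "scan_times", times)

    @property
    def omega(self) -> float:
        """Rotor angular velocity, rad/s."""
        return rpm_to_omega(self.rpm)

    @classmethod
    def uniform_scans(cls, rpm, temperature_K, t_run, n_scans, include_t0=True):
        """Run with ``n_scans`` equally spaced scans from t=0 (or the first
        interval) to ``t_run``."""
        times = np.linspace(0.0, t_run, n_scans if include_t0 else n_scans + 1)
        if not include_t0:
            times = times[1:]
        return cls(rpm=rpm, temperature_K=temperature_K, t_run=t_run,
                   scan_times=tuple(times))
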