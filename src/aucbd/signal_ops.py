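"""Smoothing and derivatives of sedimentation profiles.

Simulated (and experimental) scans carry point-to-point noise; Savitzky-Golay
least-squares polynomial smoothing reduces it without displacing boundary
features, and its derivative variant yields dz/dr directly.  The time
derivative dz/dt, taken as pairwise differences of consecutive scans, is the
quantity used in "dcdt"-style analyses (time-invariant baselines cancel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .bd_engine import ScanSet
from .errors import ConfigurationError

__all__ = [
    "DerivativeSet",
    "savitzky_golay_smooth",
    "smooth_scan_set",
    "radial_derivative",
    "time_derivative",
]

#: Default Savitzky-Golay window (points) and polynomial order.
DEFAULT_WINDOW = 11
DEFAULT_ORDER = 2


@dataclass
class DerivativeSet:
    """A derivative matrix on the scan grid.

    ``kind`` is "dz_dr" (signal/cm, on the scan times) or "dz_dt" (signal/s,
    on the midpoints of consecutive scan intervals).
    """

    radii: np.ndarray
    times: np.ndarray
    values: np.ndarray
    kind: str
    window: int | None = None
    order: int | None = None


def _check_window(window: int, order: int, length: int):
    if window % 2 != 1:
        raise ConfigurationError(f"window must be odd, got {window}")
    if order < 0 or order >= window:
        raise ConfigurationError(
            f"need window > order >= 0, got window={window}, order={order}"
        )
    if length < window:
        raise ConfigurationError(
            f"series of length {length} is shorter than window {window}"
        )


def savitzky_golay_smooth(series, window: int = DEFAULT_WINDOW,
                          order: int = DEFAULT_ORDER):
    """Least-squares local-polynomial smoothing on a uniform grid.

    Endpoints are handled by fitting the edge polynomial on a one-sided
    window, so polynomials of degree <= order pass through unchanged.
    """
    series = np.asarray(series, dtype=float)
    _check_window(window, order, series.shape[-1])
    return savgol_filter(series, window, order, mode="interp")


def smooth_scan_set(scan_set: ScanSet, window: int = DEFAULT_WINDOW,
                    order: int = DEFAULT_ORDER) -> ScanSet:
    """Savitzky-Golay smooth every scan along the radius."""
    _check_window(window, order, scan_set.n_bins)
    z = savgol_filter(scan_set.z, window, order, axis=0, mode="interp")
    # smoothing ringing may produce tiny negative excursions near sharp steps
    z = np.clip(z, 0.0, None)
    meta = dict(scan_set.meta)
    meta["smoothing"] = {"window": window, "order": order}
    return ScanSet(scan_set.radii, scan_set.times, z, scan_set.z0, meta)


def radial_derivative(scan_set: ScanSet, window: int = DEFAULT_WINDOW,
                      order: int = DEFAULT_ORDER) -> DerivativeSet:
    """dz/dr per scan via the Savitzky-Golay first-derivative filter."""
    _check_window(window, order, scan_set.n_bins)
    chi = float(np.median(np.diff(scan_set.radii)))
    dz = savgol_filter(scan_set.z, window, order, deriv=1, delta=chi, axis=0,
                       mode="interp")
    return DerivativeSet(scan_set.radii, scan_set.times, dz, "dz_dr",
                         window, order)


def time_derivative(scan_set: ScanSet, presmooth_window: int | None = None,
                    presmooth_order: int = DEFAULT_ORDER) -> DerivativeSet:
    """dz/dt as pairwise scan differences, reported at interval midpoints.

    By default the raw scans are differenced (differencing across scans
    already averages over many particles); pass ``presmooth_window`` to
    smooth each scan along the radius first.
    """
    if scan_set.n_scans < 2:
        raise ConfigurationError("time derivative needs at least 2 scans")
    z = scan_set.z
    if presmooth_window is not None:
        z = smooth_scan_set(scan_set, presmooth_window, presmooth_order).z
    dt = np.diff(scan_set.times)
    dz = np.diff(z, axis=1) / dt[None, :]
    midpoints = 0.5 * (scan_set.times[:-1] + scan_set.times[1:])
    return DerivativeSet(scan_set.radii, midpoints, dz, "dz_dt",
                         presmooth_window, presmooth_order
                         if presmooth_window is not None else None)
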