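"""Reference sample and run conditions used in tests and examples.

The benchmark mixture pairs a small and a large protein of very different
transport properties: a lysozyme-like species (s = 1.91 S, M_b = 4250 Da)
and a fibrinogen-like species (s = 7.90 S, M_b = 97,350 Da).  Two standard
runs probe it: a sedimentation-velocity (SV) run, 8 h at 40,000 rpm, and an
approach-to-equilibrium (SE) run, 100 h at 10,000 rpm, both reported as 11
scans from t = 0 in a 6.0-7.2 cm solution column at 20 deg C.
"""

from __future__ import annotations

from .physics import CellGeometry, RunConditions, SoluteComponent

DEFAULT_GEOMETRY = CellGeometry(r_m=6.0, r_b=7.2)
DEFAULT_TEMPERATURE_K = 293.15


def lysozyme_like(signal_fraction: float = 1.0) -> SoluteComponent:
    return SoluteComponent(s=1.91, buoyant_mw=4250.0,
                           signal_fraction=signal_fraction)


def fibrinogen_like(signal_fraction: float = 1.0) -> SoluteComponent:
    return SoluteComponent(s=7.90, buoyant_mw=97_350.0,
                           signal_fraction=signal_fraction)


def two_component_sample(y=(0.60, 0.40)):
    """The benchmark mixture with the given signal fractions."""
    return [lysozyme_like(y[0]), fibrinogen_like(y[1])]


def sv_conditions(n_scans: int = 11, rpm: float = 40_000.0,
                  t_run: float = 8 * 3600.0,
                  temperature_K: float = DEFAULT_TEMPERATURE_K) -> RunConditions:
    """Sedimentation-velocity run: 8 h at 40,000 rpm, scans from t=0."""
    return RunConditions.uniform_scans(rpm, temperature_K, t_run, n_scans)


def se_conditions(n_scans: int = 11, rpm: float = 10_000.0,
                  t_run: float = 100 * 3600.0,
                  temperature_K: float = DEFAULT_TEMPERATURE_K) -> RunConditions:
    """Approach-to-equilibrium run: 100 h at 10,000 rpm."""
    return RunConditions.uniform_scans(rpm, temperature_K, t_run, n_scans)
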