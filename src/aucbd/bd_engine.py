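"""Brownian-dynamics engine for sedimentation in a sector-shaped cell.

Each solute molecule is represented by a particle whose radial position is
advanced in discrete time steps.  Per step of duration dt the position is
updated as

    r  ->  r * exp(s w^2 dt)  +  (D dt / r)  +  N(0, 2 D dt) ,

i.e. the exact exponential solution of the centrifugal drift, a geometric
drift term that accounts for the cylindrical divergence of diffusion in the
sector cell (without it the stationary state is not the Boltzmann
exponential demanded by the zero-net-flux condition at meniscus and bottom),
and a Gaussian Brownian displacement of variance 2 D dt.  Positions leaving
the solution column are folded back by specular reflection, which conserves
particles and enforces zero net flux in the small-step limit.

Because the drift is integrated exactly and Brownian increments are
self-similar, the step length is almost arbitrary: 50-100 steps per run
suffice, with residual discretisation artifacts confined to the extremes of
the cell (mostly ~0.2 cm at the bottom, a region conventionally disregarded
in data analysis).

Profiles are obtained by binning particles on ``n_bins`` radial intervals of
width chi and converting counts to sector-cell concentrations,

    z(r_i, t_j) / z0 = (r_b^2 - r_m^2) / (2 chi r_i) * n(i, j) / N_part ,

so that the initially uniform loading corresponds to z/z0 = 1 everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ConsistencyError, DomainError, NumericalError
from .physics import (
    SVEDBERG,
    CellGeometry,
    RunConditions,
    SoluteComponent,
)

__all__ = [
    "SimulationSettings",
    "ScanSet",
    "NoiseEstimate",
    "sample_initial_positions",
    "drift_displacement",
    "brownian_displacement",
    "apply_boundaries",
    "allocate_particles",
    "counts_to_signal",
    "simulate_component",
    "simulate_sample",
    "estimate_noise",
    "interior_mask",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Discretisation controls of the BD simulation.

    Parameters
    ----------
    n_part : int
        Total number of particles (split between components for mixtures).
    n_steps : int
        Number of uniform time steps the run duration is divided into.
    n_bins : int
        Number of radial bins between meniscus and bottom.
    seed : int
        Root RNG seed; per-component child streams are derived from it.
    substeps_per_scan : int
        Extra subdivision of every integration interval (>= 1); useful to
        suppress end effects near meniscus/bottom at small ``n_steps``.
    include_diffusion : bool
        If False the Brownian term (and the geometric drift that belongs to
        it) is disabled; particles follow the pure drift r(t) = r0 exp(s w^2 t).
    geometric_drift : bool
        Include the cylindrical-geometry drift D dt / r (default True).
    """

    n_part: int
    n_steps: int
    n_bins: int
    seed: int = 0
    substeps_per_scan: int = 1
    include_diffusion: bool = True
    geometric_drift: bool = True

    def __post_init__(self):
        if self.n_part < 1:
            raise ConfigurationError(f"n_part must be >= 1, got {self.n_part}")
        if self.n_steps < 1:
            raise ConfigurationError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.n_bins < 2:
            raise ConfigurationError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.substeps_per_scan < 1:
            raise ConfigurationError(
                f"substeps_per_scan must be >= 1, got {self.substeps_per_scan}"
            )


@dataclass
class ScanSet:
    """A set of concentration/signal profiles z(r_i, t_j).

    ``radii`` are the bin midpoints (cm), ``times`` the scan times (s) and
    ``z`` the signal matrix of shape (len(radii), len(times)).  ``z0`` is the
    loading signal the profiles are relative to (default 1, i.e. profiles are
    reported as z/z0).
    """

    radii: np.ndarray
    times: np.ndarray
    z: np.ndarray
    z0: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.radii.ndim != 1 or self.times.ndim != 1:
            raise DomainError("radii and times must be one-dimensional")
        if np.any(np.diff(self.radii) <= 0):
            raise DomainError("radii must be strictly increasing")
        if self.z.shape != (self.radii.size, self.times.size):
            raise DomainError(
                f"z has shape {self.z.shape}, expected "
                f"{(self.radii.size, self.times.size)}"
            )
        if not np.all(np.isfinite(self.z)):
            raise DomainError("z must be finite")
        if np.any(self.z < -1e-12):
            raise DomainError("z must be non-negative")
        if self.z0 <= 0:
            raise DomainError(f"z0 must be positive, got {self.z0}")

    @property
    def n_bins(self) -> int:
        return self.radii.size

    @property
    def n_scans(self) -> int:
        return self.times.size

    def inferred_geometry(self) -> CellGeometry:
        """Cell bounds reconstructed from the (uniform) midpoint grid."""
        chi = float(np.median(np.diff(self.radii)))
        return CellGeometry(self.radii[0] - chi / 2.0, self.radii[-1] + chi / 2.0)

    def interior_mask(self, bottom_margin_cm: float = 0.2,
                      meniscus_bins: int = 2) -> np.ndarray:
        geometry = self.meta.get("geometry") or self.inferred_geometry()
        return interior_mask(self.radii, geometry, bottom_margin_cm, meniscus_bins)

    def copy(self) -> "ScanSet":
        return ScanSet(self.radii.copy(), self.times.copy(), self.z.copy(),
                       self.z0, dict(self.meta))


def interior_mask(radii, geometry: CellGeometry, bottom_margin_cm: float = 0.2,
                  meniscus_bins: int = 2) -> np.ndarray:
    """Boolean mask of the bins used for statistics and comparisons.

    Excludes ``bottom_margin_cm`` adjacent to the cell bottom (where
    discretisation end effects concentrate and experimental data are
    conventionally discarded) and ``meniscus_bins`` bins at the meniscus.
    """
    radii = np.asarray(radii, dtype=float)
    mask = radii <= geometry.r_b - bottom_margin_cm
    mask &= np.arange(radii.size) >= meniscus_bins
    return mask


def sample_initial_positions(n: int, geometry: CellGeometry, rng) -> np.ndarray:
    """Draw n starting radii corresponding to uniform loading concentration.

    In a sector cell the volume of a shell at radius r is proportional to r,
    so uniform concentration means position density proportional to r:
    r0 = sqrt(u (r_b^2 - r_m^2) + r_m^2) with u uniform on (0, 1).
    """
    if n < 1:
        raise ConfigurationError(f"need n >= 1, got {n}")
    u = rng.random(n)
    return np.sqrt(u * (geometry.r_b ** 2 - geometry.r_m ** 2) + geometry.r_m ** 2)


def drift_displacement(r, s_seconds, omega, dt):
    """Centrifugal drift r [exp(s w^2 dt) - 1] over one step (s in seconds)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("radius must be positive")
    if dt < 0:
        raise DomainError(f"dt must be non-negative, got {dt}")
    out = r * math.expm1(s_seconds * omega ** 2 * dt)
    return float(out) if out.ndim == 0 else out


def brownian_displacement(n: int, diffusion_cm2_s: float, dt: float, rng):
    """n independent Gaussian displacements of mean 0 and variance 2 D dt."""
    if diffusion_cm2_s < 0 or dt < 0:
        raise DomainError("D and dt must be non-negative")
    if diffusion_cm2_s == 0.0 or dt == 0.0:
        return np.zeros(n)
    return rng.standard_normal(n) * math.sqrt(2.0 * diffusion_cm2_s * dt)


def apply_boundaries(r, geometry: CellGeometry):
    """Fold positions into [r_m, r_b] by (repeated) specular reflection."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise NumericalError("non-finite particle position")
    width = geometry.width
    y = np.mod(r - geometry.r_m, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    out = geometry.r_m + y
    return float(out) if out.ndim == 0 else out


def allocate_particles(y, n_part: int) -> np.ndarray:
    """Split ``n_part`` particles between components.

    The per-component share is phi_k = y_k^(2/3) / sum_j y_j^(2/3), the
    allocation that balances the counting noise each component contributes to
    the combined signal.  Counts are rounded with the largest component
    absorbing the residual so they sum exactly to ``n_part``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise DomainError(f"signal fractions must be positive, got {y}")
    if abs(y.sum() - 1.0) > 1e-6:
        raise DomainError(f"signal fractions must sum to 1, got sum={y.sum()}")
    phi = y ** (2.0 / 3.0)
    phi /= phi.sum()
    counts = np.round(phi * n_part).astype(np.int64)
    counts[np.argmax(counts)] += n_part - counts.sum()
    if np.any(counts < 1):
        raise ConfigurationError(
            f"n_part={n_part} too small to give every component >= 1 particle "
            f"(fractions {phi})"
        )
    return counts


def counts_to_signal(counts, geometry: CellGeometry, n_bins: int,
                     n_part: int) -> np.ndarray:
    """Convert bin occupancies n(i, j) to relative concentration z/z0."""
    counts = np.asarray(counts)
    if counts.shape[0] != n_bins:
        raise ConsistencyError(
            f"counts has {counts.shape[0]} rows, expected n_bins={n_bins}"
        )
    sums = counts.sum(axis=0)
    if np.any(sums != n_part):
        raise ConsistencyError(
            f"particle count not conserved: column sums {sums} != {n_part}"
        )
    chi = geometry.bin_width(n_bins)
    r_i = geometry.bin_midpoints(n_bins)
    factor = (geometry.r_b ** 2 - geometry.r_m ** 2) / (2.0 * chi * r_i)
    return factor[:, None] * counts / n_part


def _time_grid(run: RunConditions, settings: SimulationSettings):
    """Integration times (uniform steps merged with scan times) and, for each
    scan, the index of its grid point."""
    n_fine = settings.n_steps * settings.substeps_per_scan
    grid = np.linspace(0.0, run.t_run, n_fine + 1) if run.t_run > 0 else np.array([0.0])
    scan_times = np.asarray(run.scan_times, dtype=float)
    grid = np.union1d(grid, scan_times)
    # merge near-duplicate points produced by floating-point differences
    if grid.size > 1:
        tol = 1e-9 * max(run.t_run, 1.0)
        keep = np.concatenate(([True], np.diff(grid) > tol))
        grid = grid[keep]
    scan_idx = np.array([int(np.argmin(np.abs(grid - t))) for t in scan_times])
    return grid, scan_idx


def _bin_positions(r, geometry: CellGeometry, n_bins: int) -> np.ndarray:
    chi = geometry.bin_width(n_bins)
    idx = ((r - geometry.r_m) / chi).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def simulate_component(component: SoluteComponent, geometry: CellGeometry,
                       run: RunConditions, settings: SimulationSettings,
                       rng, r0=None) -> np.ndarray:
    """Simulate one species and return its bin-count matrix n_k(i, j).

    The returned matrix has shape (n_bins, n_scans); every column sums to the
    particle count of this component (``settings.n_part``).  ``r0`` may supply
    explicit starting positions (e.g. to start from a non-uniform state);
    otherwise positions are sampled for uniform loading concentration.
    """
    omega = run.omega
    s_sec = component.s * SVEDBERG
    diffusion = (component.diffusion_coefficient(run.temperature_K)
                 if settings.include_diffusion else 0.0)

    if r0 is None:
        r = sample_initial_positions(settings.n_part, geometry, rng)
    else:
        r = np.array(r0, dtype=float)
        if r.size != settings.n_part:
            raise ConfigurationError(
                f"r0 has {r.size} positions, expected n_part={settings.n_part}"
            )

    grid, scan_idx = _time_grid(run, settings)
    record_at = {gi: [] for gi in scan_idx}
    for j, gi in enumerate(scan_idx):
        record_at[gi].append(j)

    counts = np.zeros((settings.n_bins, len(run.scan_times)), dtype=np.int64)
    width = geometry.width
    two_width = 2.0 * width
    for gi in range(grid.size):
        if gi > 0:
            dt = grid[gi] - grid[gi - 1]
            # the cap keeps exp() finite for absurdly fast trial species (a
            # fitter may probe them); they pellet immediately either way
            growth = math.exp(min(s_sec * omega ** 2 * dt, 50.0))
            if diffusion > 0.0:
                step = rng.standard_normal(r.size)
                step *= math.sqrt(2.0 * diffusion * dt)
                if settings.geometric_drift:
                    step += (diffusion * dt) / r
                r *= growth
                r += step
            else:
                r *= growth
            if not np.all(np.isfinite(r)):
                raise NumericalError("non-finite particle position during run")
            # specular reflection at meniscus and bottom (vectorised fold)
            np.mod(r - geometry.r_m, two_width, out=r)
            np.subtract(two_width, r, out=r, where=r > width)
            r += geometry.r_m
        if gi in record_at:
            binned = _bin_positions(r, geometry, settings.n_bins)
            for j in record_at[gi]:
                counts[:, j] = binned
    return counts


def simulate_sample(components, y=None, geometry: CellGeometry = None,
                    run: RunConditions = None,
                    settings: SimulationSettings = None,
                    seed: int | None = None, z0: float = 1.0,
                    particles_per_component: int | None = None) -> ScanSet:
    """Simulate a (possibly heterogeneous) sample and assemble its ScanSet.

    Particles are distributed between components with the noise-balancing
    y^(2/3) rule, each component is simulated on an independent RNG stream
    derived deterministically from the root seed (stream index = component
    index, so results do not depend on execution order), and the signal is the
    y-weighted sum of the per-component relative concentrations:

        z(r_i, t_j) = z0 * (r_b^2-r_m^2)/(2 chi r_i)
                      * sum_k y_k n_k(i, j) / N_part_k .

    ``particles_per_component`` overrides the y^(2/3) allocation with a fixed
    count per component.  This keeps the random-number stream consumed by
    each component independent of y, which is what makes a fixed-seed
    objective vary smoothly with the model parameters during fitting.
    """
    components = list(components)
    if not components:
        raise ConfigurationError("need at least one component")
    if y is None:
        y = np.array([c.signal_fraction for c in components], dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    if y.size != len(components):
        raise ConfigurationError("y must have one entry per component")
    if abs(y.sum() - 1.0) > 1e-6:
        raise DomainError(f"signal fractions must sum to 1, got {y.sum()}")
    y = y / y.sum()

    root_seed = settings.seed if seed is None else int(seed)
    if particles_per_component is not None:
        counts_per_comp = np.full(len(components), int(particles_per_component),
                                  dtype=np.int64)
    else:
        counts_per_comp = allocate_particles(y, settings.n_part)

    weighted = np.zeros((settings.n_bins, len(run.scan_times)))
    for k, (comp, n_k) in enumerate(zip(components, counts_per_comp)):
        rng = np.random.default_rng([root_seed, k])
        comp_settings = replace(settings, n_part=int(n_k))
        n_kij = simulate_component(comp, geometry, run, comp_settings, rng)
        weighted += y[k] * n_kij / n_k

    chi = geometry.bin_width(settings.n_bins)
    r_i = geometry.bin_midpoints(settings.n_bins)
    factor = (geometry.r_b ** 2 - geometry.r_m ** 2) / (2.0 * chi * r_i)
    z = z0 * factor[:, None] * weighted
    meta = {
        "geometry": geometry,
        "run": run,
        "settings": settings,
        "seed": root_seed,
        "components": tuple(components),
        "y": tuple(float(v) for v in y),
        "particles_per_component": tuple(int(n) for n in counts_per_comp),
        "rpm": run.rpm,
        "temperature_K": run.temperature_K,
    }
    return ScanSet(radii=r_i, times=np.asarray(run.scan_times), z=z, z0=z0,
                   meta=meta)


@dataclass
class NoiseEstimate:
    """Replicate-to-replicate standard deviation of simulated profiles."""

    std: np.ndarray            # pointwise std of z/z0, shape (n_bins, n_scans)
    interior_mean: float       # mean of std over the interior mask
    mask: np.ndarray
    n_replicates: int


def estimate_noise(components, y, geometry, run, settings, n_replicates: int,
                   base_seed: int, bottom_margin_cm: float = 0.2,
                   meniscus_bins: int = 2) -> NoiseEstimate:
    """Statistical noise of the simulated signal, from repeated runs.

    Runs ``n_replicates`` simulations that differ only in the RNG seed
    (base_seed, base_seed+1, ...) and returns the pointwise standard deviation
    of z/z0 together with its mean over the interior of the cell.
    """
    if n_replicates < 2:
        raise ConfigurationError(
            f"need at least 2 replicates, got {n_replicates}"
        )
    stack = []
    for i in range(n_replicates):
        scan_set = simulate_sample(components, y, geometry, run, settings,
                                   seed=base_seed + i)
        stack.append(scan_set.z / scan_set.z0)
    std = np.std(np.stack(stack), axis=0, ddof=1)
    mask = interior_mask(scan_set.radii, geometry, bottom_margin_cm,
                         meniscus_bins)
    return NoiseEstimate(std=std, interior_mean=float(std[mask, :].mean()),
                         mask=mask, n_replicates=n_replicates)
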