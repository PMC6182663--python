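# Methods

## Model and scope

`aucbd` treats sedimentation–diffusion transport in the sector-shaped cell
of an analytical ultracentrifuge at the particle level.  Each of the n_c
non-interacting solute species is described by the trio (s, M_b, y): the
sedimentation coefficient, the buoyant molecular weight, and the fraction
of the loading signal the species contributes.  The diffusion coefficient
is not an independent parameter; it follows from the Svedberg relation
D = R T s / M_b with R = 8.314 J mol⁻¹ K⁻¹.  Detection is assumed
proportional to concentration; y_k reduces to weight fractions for
mass-proportional detection (α = 0) and number fractions for
molar-proportional detection (α = 1) when the specific signal constants are
equal.  Concentration dependence of s or D, flotation (v̄ρ ≥ 1), solvent
compressibility, rotor acceleration ramps and radially varying instrument
baselines are out of scope; flotation is rejected at validation.

Canonical units: cm (radius), s (time), rad/s (rotor speed internally; rpm
at interfaces), Svedberg for user-facing s, Da for masses, cm²/s for D.

## The stochastic propagator

Per step Δt the radial position is updated as

    r ← r·exp(s ω² Δt) + (D Δt)/r + ξ,     ξ ~ N(0, 2 D Δt),

followed by specular reflection at the meniscus and bottom (repeated
folding, so any finite overshoot maps into [r_m, r_b] and particle number
is conserved exactly).

Three choices deserve comment.

**Exact drift.**  The centrifugal term integrates dr/dt = s ω² r exactly
over the step rather than linearising it; steps can therefore be as long as
the interval between scans without degrading the drift.

**Geometric (cylindrical) drift D Δt / r.**  A one-dimensional walk with
drift s ω² r and Gaussian steps has stationary density ∝ exp(σ r²/2) in r,
which corresponds to a *binned concentration* ∝ exp(σ r²/2)/r once counts
are divided by the sector weight r.  The zero-net-flux (Lamm) equilibrium
in a sector cell is c(r) ∝ exp(σ r²/2) with σ = M_b ω²/(R T).  The missing
factor r is the usual metric term of radial diffusion; restoring it at the
particle level requires the Bessel-type drift D/r.  With the term included
the simulator's stationary state matches the Boltzmann exponential
(chi-square test against the closed form passes at α = 0.01 with 2×10⁵
particles); without it the same test fails decisively.  For sedimentation
velocity conditions the term is negligible (D/(s ω² r²) ≈ 0.8% for the
benchmark small protein at 40,000 rpm).  It is on by default and can be
switched off (`SimulationSettings.geometric_drift`) to study the
uncorrected propagator.

**Reflection.**  Specular reflection after the combined step enforces zero
net flux only in the small-step limit; with long steps a boundary layer of
thickness ~√(2DΔt) at the cell bottom is distorted.  This is the familiar
end-effect region (~0.2 cm at the bottom) that is disregarded in data
analysis; all interior statistics and fit comparisons exclude it by
default (plus two bins at the meniscus for noise statistics).

## Discretisation and binning

The run duration is divided into `n_steps` uniform steps, merged with the
scan times into one integration grid (`substeps_per_scan` further
subdivides it).  Because the drift is exact and Brownian increments are
self-similar, 50–100 steps suffice for SV work; approach-to-equilibrium
runs are more sensitive at the column ends and default to more steps in the
benchmarks (100 for the 100 h SE run; the equilibrium chi-square check uses
1000 steps so that the bottom boundary layer stays inside the excluded
margin).

Profiles are reported on `n_bins` uniform radial bins as

    z(r_i, t_j)/z₀ = (r_b² − r_m²)/(2 χ r_i) · n(i,j)/N_part,

so uniform loading gives z/z₀ = 1.  Initial positions are drawn with
density ∝ r (uniform concentration in a sector cell),
r₀ = sqrt(u(r_b² − r_m²) + r_m²).  For mixtures, particles are allocated
to components as φ_k ∝ y_k^(2/3), which balances the per-component counting
noise of the combined signal; rounding residuals go to the largest
component so the counts sum exactly.

Statistical noise scales as N_part^(−1/2) (verified over 10⁴–10⁷ particles,
regression slope −0.50) and grows with the bin count at fixed N_part.  At
the SV benchmark conditions (N_r = 100, two components) the replicate
standard deviation of z/z₀ per interior point is ≈ 6×10⁻³ at N_part = 10⁶
and ≈ 1.8×10⁻³ at 10⁷.  This is a counting-statistics floor: a bin holding
a unit signal contains N_part/N_r·(2r/(r_b+r_m)) ≈ 10⁵ particles at
N_part = 10⁷, giving z/√n ≈ 3×10⁻³ pointwise before the cell-average over
partly cleared scans.  Savitzky–Golay smoothing reduces it further at the
cost of correlating neighbouring bins; noise statistics here are always
quoted for raw profiles.

## Reproducibility

One root seed; component k runs on the RNG stream seeded by (root, k), so
results are bit-for-bit reproducible and independent of execution order.
`estimate_noise` varies only the root seed across replicates.

## The global fit

The objective is Δ² = Σ_e W_e Δ_e², with Δ_e² the mean squared deviation
between calculated and observed profiles over the compared points, relative
to the loading signal; weights default to uniform.  The comparison excludes
the bottom 0.2 cm.  Minimisation is Nelder–Mead over (log s_k, log M_b_k)
and a softmax parameterisation of y (positivity and Σy = 1 for free).

Because the forward model is stochastic, three measures make the objective
well behaved:

1. **Common random numbers.**  The simulation seed inside the objective is
   fixed, so the objective is a deterministic function of the parameters.
2. **Fixed per-component particle counts during the search.**  With the
   y^(2/3) allocation, the number of particles per component — and hence
   the alignment of the random-number stream — changes with y, which makes
   the fixed-seed objective discontinuous in y at the 10⁻⁵ scale and stalls
   the simplex.  The search therefore simulates every component with
   `search_n_part` particles of its own and lets y act as a pure weight.
3. **A wide initial simplex** (edge 0.5 in log-parameter space): the model
   expansion starts a factor of two away from the eventual optimum, and the
   default few-percent simplex cannot cross between basins before
   contracting.

The search runs at reduced fidelity (10⁵ particles per component),
followed by a short polish at four times that fidelity with a fresh seed
and a small initial simplex: the fixed-seed noise texture of the coarse
search biases weakly determined parameters (in the benchmark, the buoyant
weight of the fast species, whose information sits in a narrow boundary
and in the masked bottom region), and the polish removes most of that
bias at a fraction of the search cost.  The
*reported* Δ² comes from a separate final evaluation at `final_n_part`
total particles with the standard allocation.  Note that this evaluation
has a noise floor of its own: at equal obs/calc fidelity the expected Δ²
of a perfect model is the *sum* of both noise variances.  When the misfit
of the fit itself is the quantity of interest (as in the benchmark
reproduction), the final evaluation should use an order of magnitude more
particles than the data so that Δ² measures the fit-versus-data deviation;
the benchmark uses 10⁷ against 10⁶-particle data, where the exact truth
model scores Δ² = 6.9×10⁻⁵ and the fitted model the same within 1%.

Stopping: the simplex halts when the spread of objective values across its
vertices falls below `tol` relative to the best value (implemented by
restarting scipy's Nelder–Mead with its absolute tolerance rescaled), or at
`maxiter` iterations (flagged non-converged).  The fit-level default
tol = 10⁻³ reflects that polishing below the objective's own texture only
burns evaluations; `simplex_minimize` itself defaults to 10⁻⁶ for generic
deterministic use.

**Model expansion.**  Fit one component first (initial guess: s from the
ln r(t) slope of the fastest trackable boundary; M_b from the Svedberg
relation with a D estimated from the 25–75% boundary width; generic
2 S / 20 kDa fallback).  Then try n_c+1 components — from one component,
seeded at (half, twice) the optimum with equal fractions; from n ≥ 2, the
fitted trios plus a new component at twice the largest (s, M_b) — and
accept while Δ² improves at least `improvement_factor` (default 2×).  The
two-fold threshold is this package's rule; it cleanly separates the
order-of-magnitude improvement of a genuinely missing component from the
percent-level improvement of overfitting.

## Benchmark study conditions

Two species resembling lysozyme (1.91 S, 4250 Da buoyant) and fibrinogen
(7.90 S, 97,350 Da buoyant) in a 6.0–7.2 cm column at 20 °C — cell bounds
chosen as typical XL-I double-sector values.  SV: 8 h at 40,000 rpm,
11 scans from t = 0, 20 steps, 100 bins.  SE: 100 h at 10,000 rpm,
11 scans, 100 steps.  The fit benchmark uses y = (0.65, 0.35) and data at
N_part = 10⁶; the noise benchmark uses y = (0.60, 0.40).  These sizes keep
the full fit benchmark at minutes on one CPU; they are the package's
standard test conditions, stated here so results can be reproduced exactly.

## What the synthetic data do and do not emulate

Synthetic scan sets carry the counting noise of the particle scheme
(optionally plus Gaussian measurement noise via
`io_formats.add_measurement_noise`, clipped at zero signal).  They do not
contain time-invariant or radially structured instrument baselines,
meniscus optical artifacts, buffer-signal gradients, or concentration-
dependent non-ideality.  Passing fits on synthetic data therefore
demonstrate the estimator's statistical behaviour under the stated model,
not robustness to systematic instrument error.

## Known limitations

- Long time steps distort a ~√(2DΔt) layer at the cell bottom; the layer is
  excluded from analysis rather than corrected.
- The boundary tracker assumes a resolvable plateau; it raises a diagnostic
  error on equilibrium-shaped profiles and skips scans whose boundary sits
  at the meniscus.
- Nelder–Mead with the expansion heuristic is a local strategy; strongly
  overlapping components (s ratios near 1) may need user-supplied initial
  models.
- Δ² values below the combined obs+calc noise floor are not meaningful;
  compare against the floors quoted above.
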