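"""Global nonlinear least-squares analysis of sedimentation experiments.

One or more experiments (scan sets with their instrumental conditions) are
fitted simultaneously by repeated Brownian-dynamics simulation.  The model is
a set of n_c trios (s_k, M_b_k, y_k); since sum_k y_k = 1, a model has
3 n_c - 1 free parameters.  The objective is the weighted global square
deviation

    Delta^2 = sum_e W_e Delta_e^2 ,
    Delta_e^2 = mean over compared (r_i, t_j) of
                [z_calc(r_i, t_j) - z_obs(r_i, t_j)]^2 / z0^2 ,

minimised with the Nelder-Mead simplex on transformed parameters (log s,
log M_b, softmax-parameterised y).  The simulation seed inside the objective
is held fixed (common random numbers) so the stochastic simulator presents a
smooth, deterministic objective to the simplex.

Model selection follows a heuristic expansion: fit one component first, then
try two components seeded at (half, twice) the single-component optimum with
equal fractions, and keep expanding while the global Delta^2 improves by at
least a factor of two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .bd_engine import ScanSet, SimulationSettings, interior_mask, simulate_sample
from .errors import (
    AlignmentError,
    AnalysisError,
    ConfigurationError,
)
from .oracles import estimate_s_from_boundary, locate_boundary
from .physics import R_GAS, SVEDBERG, CellGeometry, RunConditions, SoluteComponent

__all__ = [
    "Experiment",
    "FitSettings",
    "FitResult",
    "SimplexResult",
    "delta2_single",
    "delta2_global",
    "simplex_minimize",
    "fit_n_components",
    "fit_auto",
    "default_initial_guess",
]


@dataclass
class Experiment:
    """One observed experiment and the conditions needed to re-simulate it."""

    scan_set: ScanSet
    geometry: CellGeometry
    run: RunConditions
    weight: float = 1.0
    n_steps: int = 100     # BD steps used when simulating this experiment

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigurationError(f"weight must be >= 0, got {self.weight}")

    @classmethod
    def from_scan_set(cls, scan_set: ScanSet, weight: float = 1.0,
                      n_steps: int = 100, rpm: float | None = None,
                      temperature_K: float | None = None) -> "Experiment":
        """Build an Experiment from a ScanSet, taking geometry from the radius
        grid and rotor speed/temperature from the metadata unless given."""
        geometry = scan_set.meta.get("geometry") or scan_set.inferred_geometry()
        rpm = rpm if rpm is not None else scan_set.meta.get("rpm")
        temperature_K = (temperature_K if temperature_K is not None
                         else scan_set.meta.get("temperature_K"))
        if rpm is None or temperature_K is None:
            raise ConfigurationError(
                "rotor speed and temperature are needed (metadata or argument)"
            )
        run = RunConditions(rpm=float(rpm), temperature_K=float(temperature_K),
                            t_run=float(scan_set.times[-1]),
                            scan_times=tuple(scan_set.times))
        return cls(scan_set=scan_set, geometry=geometry, run=run,
                   weight=weight, n_steps=n_steps)


@dataclass
class FitSettings:
    """Controls of the global fit.

    The simplex search runs at a reduced fidelity (``search_n_part``
    particles *per component*, equal allocation, fixed seed) for speed and
    objective smoothness; the reported Delta^2 values come from a final
    evaluation with ``final_n_part`` total particles distributed by the
    standard y^(2/3) rule.
    """

    search_n_part: int = 100_000
    final_n_part: int = 1_000_000
    seed: int = 20_18            # common-random-numbers seed of the objective
    tol: float = 1e-3            # relative Delta^2 spread of the simplex
    maxiter: int = 500           # per model size; a capped run is flagged
    xatol: float = 1e-4          # absolute spread of the (log-scale) simplex
    initial_step: float = 0.5    # starting simplex edge in log-parameter space
    n_restarts: int = 1          # tolerance-rescaling simplex restarts
    # short refinement at higher fidelity: the fixed-seed noise texture of
    # the coarse search biases weakly determined parameters; re-minimising
    # briefly with more particles (and a fresh seed) removes most of it.
    # None means 4 * search_n_part; 0 disables the stage.
    polish_n_part: int | None = None
    polish_maxiter: int = 60
    polish_step: float = 0.1

    @property
    def resolved_polish_n_part(self) -> int:
        if self.polish_n_part is None:
            return 4 * self.search_n_part
        return int(self.polish_n_part)
    bottom_margin_cm: float = 0.2
    meniscus_bins: int = 0       # the comparison mask excludes the bottom only


@dataclass
class FitResult:
    """Optimised model with fit statistics."""

    components: list
    y: np.ndarray
    delta2: float
    delta2_per_experiment: np.ndarray
    delta2_search: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    history: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.components)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "components": [
                {"s_svedberg": c.s, "buoyant_mw_da": c.buoyant_mw,
                 "y": float(f)}
                for c, f in zip(self.components, self.y)
            ],
            "delta2": self.delta2,
            "delta2_per_experiment": [float(d) for d in
                                      self.delta2_per_experiment],
            "rms_percent_of_loading": 100.0 * math.sqrt(self.delta2),
            "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations,
            "converged": bool(self.converged),
        }

    def report(self) -> str:
        lines = [f"Fitted model: {self.n_components} component(s)",
                 f"{'k':>3} {'s (S)':>10} {'M_b (Da)':>12} {'y':>8}"]
        for k, (c, f) in enumerate(zip(self.components, self.y), start=1):
            lines.append(f"{k:>3} {c.s:>10.3f} {c.buoyant_mw:>12.0f} "
                         f"{f:>8.4f}")
        lines.append(f"global Delta^2 = {self.delta2:.4g}  "
                     f"(rms {100 * math.sqrt(self.delta2):.3f}% of loading signal)")
        per = ", ".join(f"{d:.4g}" for d in self.delta2_per_experiment)
        lines.append(f"per-experiment Delta_e^2 = {per}")
        lines.append(f"iterations = {self.n_iterations}, "
                     f"evaluations = {self.n_evaluations}, "
                     f"converged = {self.converged}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Objective


def delta2_single(calc: ScanSet, obs: ScanSet, mask=None) -> float:
    """Mean squared deviation between two scan sets, relative to z0.

    ``mask`` optionally restricts the radial bins compared (e.g. to the cell
    interior, excluding the bottom margin).
    """
    if calc.radii.size != obs.radii.size or not np.allclose(
            calc.radii, obs.radii, rtol=0, atol=1e-8):
        raise AlignmentError("radius grids differ between calc and obs")
    if calc.times.size != obs.times.size or not np.allclose(
            calc.times, obs.times, rtol=0, atol=1e-6):
        raise AlignmentError("scan times differ between calc and obs")
    diff = calc.z - obs.z
    if mask is not None:
        diff = diff[np.asarray(mask, dtype=bool), :]
    return float(np.mean(diff ** 2) / obs.z0 ** 2)


def _normalised_weights(experiments) -> np.ndarray:
    w = np.array([e.weight for e in experiments], dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("experiment weights sum to zero")
    return w / w.sum()


def _simulate_experiment(experiment: Experiment, components, y, n_part: int,
                         seed: int,
                         particles_per_component: int | None = None) -> ScanSet:
    settings = SimulationSettings(
        n_part=n_part, n_steps=experiment.n_steps,
        n_bins=experiment.scan_set.n_bins, seed=seed)
    calc = simulate_sample(components, y, experiment.geometry, experiment.run,
                           settings, z0=experiment.scan_set.z0,
                           particles_per_component=particles_per_component)
    return calc


def delta2_global(experiments, components, y, n_part: int, seed: int,
                  bottom_margin_cm: float = 0.2,
                  meniscus_bins: int = 0, equal_allocation: bool = False):
    """Weighted global Delta^2 of a candidate model over all experiments.

    Every experiment is re-simulated with the candidate model using the fixed
    ``seed``, so repeated evaluation at the same parameters returns the
    identical value.  With ``equal_allocation`` each component is simulated
    with ``n_part`` particles of its own (rather than sharing ``n_part``
    through the y^(2/3) rule), which keeps the fixed-seed objective smooth in
    the signal fractions.  Returns (Delta^2, per-experiment array).
    """
    if not experiments:
        raise ConfigurationError("need at least one experiment")
    weights = _normalised_weights(experiments)
    per = np.empty(len(experiments))
    ppc = n_part if equal_allocation else None
    for i, e in enumerate(experiments):
        calc = _simulate_experiment(e, components, y, n_part, seed,
                                    particles_per_component=ppc)
        mask = interior_mask(e.scan_set.radii, e.geometry, bottom_margin_cm,
                             meniscus_bins)
        per[i] = delta2_single(calc, e.scan_set, mask=mask)
    return float(np.dot(weights, per)), per


# ---------------------------------------------------------------------------
# Parameter transform: x = (log s_1..n, log M_1..n, w_1..n-1), y = softmax(w, 0)


def _pack(components, y) -> np.ndarray:
    n = len(components)
    y = np.asarray(y, dtype=float)
    x = [math.log(c.s) for c in components]
    x += [math.log(c.buoyant_mw) for c in components]
    x += [math.log(y[k] / y[-1]) for k in range(n - 1)]
    return np.array(x)


def _unpack(x, n_c: int):
    x = np.asarray(x, dtype=float)
    s = np.exp(x[:n_c])
    mw = np.exp(x[n_c:2 * n_c])
    w = np.concatenate([x[2 * n_c:], [0.0]])
    w -= w.max()
    y = np.exp(w)
    y /= y.sum()
    components = [SoluteComponent(s=float(sk), buoyant_mw=float(mk),
                                  signal_fraction=float(yk))
                  for sk, mk, yk in zip(s, mw, y)]
    return components, y


# ---------------------------------------------------------------------------
# Simplex


@dataclass
class SimplexResult:
    x: np.ndarray
    fun: float
    n_iterations: int
    n_evaluations: int
    converged: bool
    history: np.ndarray


def simplex_minimize(objective, initial_params, tol: float = 1e-6,
                     maxiter: int = 2000, xatol: float = 1e-6,
                     n_restarts: int = 2,
                     initial_step: float | None = None) -> SimplexResult:
    """Nelder-Mead minimisation with a relative function-spread stop.

    The simplex stops when the spread of objective values across its vertices
    falls below ``tol`` relative to the current best value, or when the
    iteration budget ``maxiter`` is exhausted (the result is then flagged
    non-converged).  Because the underlying scipy implementation uses an
    absolute function tolerance, the target is approached by restarting the
    simplex with the tolerance rescaled to the best value found so far.

    ``initial_step`` sets the edge length of the starting simplex (per
    coordinate); a generous value lets the search cross between basins before
    contracting, which matters when the starting model is only known to a
    factor of two.
    """
    x0 = np.asarray(initial_params, dtype=float)
    history = []

    def wrapped(x):
        f = float(objective(x))
        history.append(f if not history else min(f, history[-1]))
        return f

    f0 = float(objective(x0))
    if not math.isfinite(f0):
        raise ConfigurationError(
            f"objective is not finite at the initial point: {f0}"
        )
    x, fbest = x0, f0
    remaining = maxiter
    total_iter = 0
    converged = False
    step = initial_step
    for _ in range(max(1, n_restarts)):
        fatol = tol * max(abs(fbest), 1e-300)
        options = {"maxiter": remaining, "fatol": fatol, "xatol": xatol,
                   "adaptive": True}
        if step is not None:
            simplex = np.tile(x, (x.size + 1, 1))
            simplex[1:] += np.eye(x.size) * step
            options["initial_simplex"] = simplex
        res = minimize(wrapped, x, method="Nelder-Mead", options=options)
        total_iter += res.nit
        remaining -= res.nit
        improved = res.fun < fbest
        x, fbest = res.x, float(res.fun)
        converged = bool(res.success)
        if remaining <= 0:
            converged = False
            break
        if not improved:
            break
        step = None   # restarts only re-tighten the tolerance locally
    return SimplexResult(x=np.asarray(x), fun=fbest, n_iterations=total_iter,
                         n_evaluations=len(history), converged=converged,
                         history=np.array(history))


# ---------------------------------------------------------------------------
# Fitting


def fit_n_components(experiments, n_c: int, initial_components,
                     initial_y=None,
                     settings: FitSettings | None = None) -> FitResult:
    """Fit a fixed number of components to the experiments.

    ``initial_components`` supplies the starting trios; ``initial_y``
    overrides their signal fractions.  Returns the optimised model with
    Delta^2 evaluated at the final (high) particle count.
    """
    settings = settings or FitSettings()
    initial_components = list(initial_components)
    if len(initial_components) != n_c:
        raise ConfigurationError(
            f"initial model has {len(initial_components)} components, "
            f"expected n_c={n_c}")
    if initial_y is None:
        initial_y = np.array([c.signal_fraction for c in initial_components])
        initial_y = initial_y / initial_y.sum()

    def make_objective(n_part, seed):
        def objective(x):
            components, y = _unpack(x, n_c)
            total, _ = delta2_global(
                experiments, components, y, n_part=n_part, seed=seed,
                bottom_margin_cm=settings.bottom_margin_cm,
                meniscus_bins=settings.meniscus_bins, equal_allocation=True)
            return total
        return objective

    res = simplex_minimize(make_objective(settings.search_n_part,
                                          settings.seed),
                           _pack(initial_components, initial_y),
                           tol=settings.tol, maxiter=settings.maxiter,
                           xatol=settings.xatol,
                           initial_step=settings.initial_step,
                           n_restarts=settings.n_restarts)
    history = [res.history]
    if settings.resolved_polish_n_part > 0:
        polish = simplex_minimize(
            make_objective(settings.resolved_polish_n_part,
                           settings.seed + 7),
            res.x, tol=settings.tol, maxiter=settings.polish_maxiter,
            xatol=settings.xatol, initial_step=settings.polish_step,
            n_restarts=1)
        history.append(polish.history)
        res = SimplexResult(
            x=polish.x, fun=polish.fun,
            n_iterations=res.n_iterations + polish.n_iterations,
            n_evaluations=res.n_evaluations + polish.n_evaluations,
            # convergence is judged on the search; the polish is a
            # deliberately budget-capped refinement
            converged=res.converged,
            history=np.concatenate(history))
    components, y = _unpack(res.x, n_c)
    delta2, per = delta2_global(
        experiments, components, y, n_part=settings.final_n_part,
        seed=settings.seed + 1, bottom_margin_cm=settings.bottom_margin_cm,
        meniscus_bins=settings.meniscus_bins)
    return FitResult(components=components, y=y, delta2=delta2,
                     delta2_per_experiment=per, delta2_search=res.fun,
                     n_iterations=res.n_iterations,
                     n_evaluations=res.n_evaluations,
                     converged=res.converged, history=res.history)


def _boundary_spread_diffusion(scan_set: ScanSet, track, geometry):
    """Crude D estimate from the width of the last tracked boundary.

    For a diffusion-broadened boundary the 25-75% rise width is about
    1.349 sqrt(2 D t); inverting gives an order-of-magnitude D for seeding
    the fit.  Returns None when the width cannot be measured.
    """
    t = track.times[-1]
    if t <= 0:
        return None
    j = int(np.argmin(np.abs(scan_set.times - t)))
    z = scan_set.z[:, j] / scan_set.z0
    hi = geometry.r_b - 0.2
    window = (scan_set.radii >= hi - 0.5) & (scan_set.radii <= hi)
    plateau = float(np.median(z[window]))
    if plateau <= 0:
        return None
    radii = scan_set.radii
    crossings = {}
    for frac in (0.25, 0.75):
        level = frac * plateau
        above = np.nonzero(z >= level)[0]
        if above.size == 0 or above[0] == 0:
            return None
        i = above[0]
        crossings[frac] = radii[i - 1] + (level - z[i - 1]) / (
            z[i] - z[i - 1]) * (radii[i] - radii[i - 1])
    width = crossings[0.75] - crossings[0.25]
    if width <= 0:
        return None
    sigma_b = width / 1.349
    return sigma_b ** 2 / (2.0 * t)


def default_initial_guess(experiments) -> SoluteComponent:
    """Single-component starting trio from simple boundary analysis.

    The sedimentation coefficient comes from the ln r(t) slope of the
    fastest-moving resolvable boundary; the buoyant weight from the Svedberg
    relation with a diffusion coefficient estimated from the boundary spread.
    Falls back to a generic small-protein guess (2 S, 20 kDa) when no
    boundary can be tracked.
    """
    best = None
    for e in experiments:
        try:
            track = locate_boundary(e.scan_set, geometry=e.geometry)
        except AnalysisError:
            continue
        if track.times.size < 2:
            continue
        s, _ = estimate_s_from_boundary(track, e.run.omega)
        if not (s > 0):
            continue
        travel = float(track.boundary_radii[-1] - track.boundary_radii[0])
        if best is None or travel > best[0]:
            best = (travel, s, e, track)
    if best is None:
        return SoluteComponent(s=2.0, buoyant_mw=20_000.0)
    _, s, e, track = best
    diffusion = _boundary_spread_diffusion(e.scan_set, track, e.geometry)
    if diffusion is not None and diffusion > 0:
        buoyant_mw = (R_GAS * e.run.temperature_K * (s * SVEDBERG)
                      / (diffusion * 1e-4) * 1e3)
        buoyant_mw = float(np.clip(buoyant_mw, 100.0, 1e9))
    else:
        buoyant_mw = 20_000.0
    return SoluteComponent(s=float(s), buoyant_mw=buoyant_mw)


def _expand_model(result: FitResult):
    """Initial model with one more component than ``result``.

    From one component, seed two components at (half, twice) the optimum with
    equal fractions.  From n >= 2, keep the fitted trios and add a new
    component at twice the largest (s, M_b), with equal fraction share.
    """
    comps = result.components
    if len(comps) == 1:
        c = comps[0]
        new = [SoluteComponent(c.s / 2.0, c.buoyant_mw / 2.0),
               SoluteComponent(c.s * 2.0, c.buoyant_mw * 2.0)]
        y = np.array([0.5, 0.5])
        return new, y
    k_max = int(np.argmax([c.s for c in comps]))
    new = [SoluteComponent(c.s, c.buoyant_mw) for c in comps]
    new.append(SoluteComponent(comps[k_max].s * 2.0,
                               comps[k_max].buoyant_mw * 2.0))
    n = len(new)
    y = np.concatenate([result.y * (n - 1) / n, [1.0 / n]])
    y = y / y.sum()
    return new, y


def fit_auto(experiments, settings: FitSettings | None = None,
             max_components: int = 3, initial_components=None,
             initial_y=None, improvement_factor: float = 2.0) -> FitResult:
    """Heuristic model-expansion fit.

    Starts from a single component (boundary-derived guess unless an initial
    model is given) and adds components while the global Delta^2 improves by
    at least ``improvement_factor``; the best accepted model is returned.

    The exploratory stages run without the polish refinement and evaluate
    their Delta^2 at moderate fidelity (model selection compares
    order-of-magnitude differences); only the accepted model receives the
    polish and the full-fidelity final evaluation.
    """
    from dataclasses import replace as _replace

    if max_components < 1:
        raise ConfigurationError(
            f"max_components must be >= 1, got {max_components}")
    settings = settings or FitSettings()
    stage_settings = _replace(
        settings, polish_n_part=0,
        final_n_part=min(settings.final_n_part, 10 * settings.search_n_part))
    if initial_components is None:
        initial_components = [default_initial_guess(experiments)]
        initial_y = np.array([1.0])
    best = fit_n_components(experiments, len(initial_components),
                            initial_components, initial_y, stage_settings)
    while best.n_components < max_components:
        comps0, y0 = _expand_model(best)
        trial = fit_n_components(experiments, len(comps0), comps0, y0,
                                 stage_settings)
        if best.delta2 / max(trial.delta2, 1e-300) >= improvement_factor:
            best = trial
        else:
            break
    return _refine_result(experiments, best, settings)


def _refine_result(experiments, result: FitResult,
                   settings: FitSettings) -> FitResult:
    """Polish an accepted model at higher fidelity and re-evaluate Delta^2."""
    n_c = result.n_components
    x = _pack(result.components, result.y)
    n_iter, n_eval = result.n_iterations, result.n_evaluations
    history = [result.history]
    converged = result.converged
    if settings.resolved_polish_n_part > 0:
        def objective(x):
            components, y = _unpack(x, n_c)
            total, _ = delta2_global(
                experiments, components, y,
                n_part=settings.resolved_polish_n_part,
                seed=settings.seed + 7,
                bottom_margin_cm=settings.bottom_margin_cm,
                meniscus_bins=settings.meniscus_bins, equal_allocation=True)
            return total

        polish = simplex_minimize(objective, x, tol=settings.tol,
                                  maxiter=settings.polish_maxiter,
                                  xatol=settings.xatol,
                                  initial_step=settings.polish_step,
                                  n_restarts=1)
        x = polish.x
        n_iter += polish.n_iterations
        n_eval += polish.n_evaluations
        history.append(polish.history)
    components, y = _unpack(x, n_c)
    delta2, per = delta2_global(
        experiments, components, y, n_part=settings.final_n_part,
        seed=settings.seed + 1, bottom_margin_cm=settings.bottom_margin_cm,
        meniscus_bins=settings.meniscus_bins)
    return FitResult(components=components, y=y, delta2=delta2,
                     delta2_per_experiment=per,
                     delta2_search=result.delta2_search,
                     n_iterations=n_iter, n_evaluations=n_eval,
                     converged=converged, history=np.concatenate(history))
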