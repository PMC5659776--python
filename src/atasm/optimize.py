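"""Genetic-algorithm shape search and derivative-free pose refinement.

Shape parameters ``b`` are optimized by a real-coded genetic algorithm:
fitness-proportional (roulette-wheel) selection on min-shifted fitness,
single-point crossover with probability 0.5, per-chromosome mutation with
probability 0.01 (one random gene replaced by a fresh uniform in-bounds
value), and elitism.  Evolution stops when the elite fitness has not changed
(absolute tolerance 1e-9) for 10 generations, or after ``max_generations``.

Pose (translation, scale, rotation) is refined separately with Powell's
direction-set method; the segmentation pipeline alternates pose refinement
and GA shape search until the joint energy stabilizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sp_optimize

from .energy import EnergyEvaluator, EnergyWeights
from .shape_model import PointDistributionModel, ShapeParams

log = logging.getLogger(__name__)


@dataclass
class GAConfig:
    population_size: int = 50
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    convergence_patience: int = 10
    max_generations: int = 200
    rng_seed: int | None = None
    elite_tol: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.convergence_patience < 1:
            raise ValueError("convergence_patience must be >= 1")


@dataclass
class Chromosome:
    """A candidate mode-weight vector and its fitness (Eq-6-style energy)."""

    b: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(-1)


def _roulette_probs(fitness: np.ndarray) -> np.ndarray:
    """Selection probabilities: min-shifted fitness, uniform on a flat field."""
    shifted = fitness - fitness.min()
    total = shifted.sum()
    if total <= 0:
        return np.full(len(fitness), 1.0 / len(fitness))
    return shifted / total


def ga_maximize(fitness_fn, bounds: np.ndarray, config: GAConfig | None = None,
                fitness_batch=None):
    """Maximize ``fitness_fn(b)`` over the clamp box ``|b_i| <= bounds[i]``.

    Parameters
    ----------
    fitness_fn : callable
        Scalar fitness of one gene vector.
    bounds : (m,) array
        Per-gene half-widths of the (symmetric) search box.
    fitness_batch : callable, optional
        Vectorized fitness of an (n, m) gene matrix; used when provided.

    Returns
    -------
    best : Chromosome
    history : (n_generations,) ndarray of per-generation elite fitness.
    """
    config = config or GAConfig()
    bounds = np.asarray(bounds, dtype=float).reshape(-1)
    m = len(bounds)
    rng = np.random.default_rng(config.rng_seed)
    if m == 0:
        b = np.zeros(0)
        return Chromosome(b, float(fitness_fn(b))), np.zeros(1)

    def evaluate(pop: np.ndarray) -> np.ndarray:
        if fitness_batch is not None:
            return np.asarray(fitness_batch(pop), dtype=float)
        return np.array([fitness_fn(b) for b in pop], dtype=float)

    def sample(n: int) -> np.ndarray:
        return rng.uniform(-bounds, bounds, size=(n, m))

    pop = sample(config.population_size)
    fit = evaluate(pop)
    for _ in range(20):  # resample non-finite chromosomes
        bad = ~np.isfinite(fit)
        if not bad.any():
            break
        pop[bad] = sample(int(bad.sum()))
        fit[bad] = evaluate(pop[bad])
    fit = np.where(np.isfinite(fit), fit, -np.inf)

    history = []
    best_idx = int(np.argmax(fit))
    best = Chromosome(pop[best_idx].copy(), float(fit[best_idx]))
    stall = 0
    for _gen in range(config.max_generations):
        history.append(best.fitness)
        probs = _roulette_probs(fit)
        n_children = config.population_size - 1
        pa = rng.choice(config.population_size, size=n_children, p=probs)
        pb = rng.choice(config.population_size, size=n_children, p=probs)
        children = pop[pa].copy()
        if m >= 2:
            do_cross = rng.random(n_children) < config.crossover_prob
            cuts = rng.integers(1, m, size=n_children)
            for j in np.flatnonzero(do_cross):
                children[j, cuts[j]:] = pop[pb[j], cuts[j]:]
        do_mut = rng.random(n_children) < config.mutation_prob
        for j in np.flatnonzero(do_mut):
            g = rng.integers(m)
            children[j, g] = rng.uniform(-bounds[g], bounds[g])

        cfit = evaluate(children)
        for _ in range(20):
            bad = ~np.isfinite(cfit)
            if not bad.any():
                break
            children[bad] = sample(int(bad.sum()))
            cfit[bad] = evaluate(children[bad])
        cfit = np.where(np.isfinite(cfit), cfit, -np.inf)

        pop = np.vstack([best.b[None, :], children])
        fit = np.concatenate([[best.fitness], cfit])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best.fitness + config.elite_tol:
            best = Chromosome(pop[gen_best].copy(), float(fit[gen_best]))
            stall = 0
        else:
            stall += 1
            if stall >= config.convergence_patience:
                history.append(best.fitness)
                break
    return best, np.asarray(history)


# ---------------------------------------------------------------------------
# Powell local optimization
# ---------------------------------------------------------------------------

def powell_minimize(objective, x0, ftol: float = 1e-4, max_iter: int = 100) -> np.ndarray:
    """Direction-set minimization (Powell); returns the best point found."""
    res = sp_optimize.minimize(objective, np.asarray(x0, dtype=float),
                               method="Powell",
                               options={"ftol": ftol, "maxiter": max_iter})
    if not res.success and res.status != 0:
        log.info("Powell stopped early (%s); returning best point found", res.message)
    return np.asarray(res.x, dtype=float)


# ---------------------------------------------------------------------------
# pose refinement and alternation with the GA
# ---------------------------------------------------------------------------

def refine_pose(evaluator: EnergyEvaluator, model: PointDistributionModel,
                weights: EnergyWeights, params: ShapeParams,
                scale_guard: tuple[float, float] = (0.5, 2.0)) -> ShapeParams:
    """Maximize total energy over (tx, ty, scale, rotation) with ``b`` fixed.

    Diverged solutions (scale outside ``scale_guard`` times the initial
    scale) are reverted to the input pose.
    """
    b = params.b.copy()
    s0 = params.pose[2]

    def negative_energy(pose_vec):
        pts = model.synthesize_batch(b[None, :], tuple(pose_vec))
        return -float(evaluator.batch_total(pts, weights)[0])

    x = powell_minimize(negative_energy, np.asarray(params.pose, dtype=float))
    new_pose = (float(x[0]), float(x[1]), float(x[2]), float(x[3]))
    if not (scale_guard[0] * s0 <= new_pose[2] <= scale_guard[1] * s0):
        log.warning("pose refinement diverged (scale %.3f from %.3f); reverted",
                    new_pose[2], s0)
        return params.copy()
    if negative_energy(np.asarray(new_pose)) > negative_energy(np.asarray(params.pose)):
        return params.copy()
    return ShapeParams(b, new_pose)


def alternate_optimize(evaluator: EnergyEvaluator, model: PointDistributionModel,
                       weights: EnergyWeights, init_params: ShapeParams,
                       ga_config: GAConfig | None = None,
                       max_rounds: int = 5, rel_tol: float = 1e-4):
    """Alternate Powell pose refinement and GA shape search.

    Runs up to ``max_rounds`` rounds of (pose refinement, GA over ``b``) and
    stops early once the relative change of the joint energy drops below
    ``rel_tol``.

    Returns
    -------
    params : ShapeParams
    diagnostics : dict with per-round energies and GA histories.
    """
    ga_config = ga_config or GAConfig()
    bounds = model.clamp_bounds()
    params = model.clamp_params(init_params)
    diagnostics = {"round_energy": [], "ga_history": []}

    def energy_of(p: ShapeParams) -> float:
        pts = model.synthesize_batch(p.b[None, :], p.pose)
        return float(evaluator.batch_total(pts, weights)[0])

    prev = energy_of(params)
    for rnd in range(max_rounds):
        params = refine_pose(evaluator, model, weights, params)
        pose = params.pose

        def batch_fitness(bmat):
            pts = model.synthesize_batch(np.clip(bmat, -bounds, bounds), pose)
            return evaluator.batch_total(pts, weights)

        cfg = GAConfig(**{**ga_config.__dict__})
        if ga_config.rng_seed is not None:
            cfg.rng_seed = ga_config.rng_seed + rnd
        best, hist = ga_maximize(lambda b: batch_fitness(b[None, :])[0],
                                 bounds, cfg, fitness_batch=batch_fitness)
        cand = ShapeParams(best.b, pose)
        if energy_of(cand) >= energy_of(params):
            params = cand
        cur = energy_of(params)
        diagnostics["round_energy"].append(cur)
        diagnostics["ga_history"].append(hist)
        if abs(cur - prev) <= rel_tol * max(1.0, abs(prev)):
            break
        prev = cur
    return model.clamp_params(params), diagnostics
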