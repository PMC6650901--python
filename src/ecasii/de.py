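"""Differential evolution (rand/1/bin) of transition-rule tables.

The genome is the flattened M x 6 rule table (D = 6M, default 180).  Each
generation, every individual is challenged by a trial vector built from three
distinct others (``mutate`` then ``crossover``) and the lower-cost of the two
survives (``select``).  Cost of a genome = run the automaton for K iterations
on a labeled training scene and score the output with the intra/inter-class
segmentation cost.

Because each evaluation may use a different random training scene, the cost
is noisy.  Two evaluation modes are provided:

* ``fresh`` (default) — every target/trial duel draws one fresh scene and
  scores *both* genomes on it with the same fitness sampling stream: a fair
  paired comparison under noise, at twice the evaluation cost.
* ``fixed`` — a single scene and fitness stream for the entire run: the cost
  function is deterministic, parents keep their cached cost, and the best
  cost is monotonically non-increasing (used for tests and quick runs).

The generic engine (``de_core``) is independent of the automaton and can
minimize any vector objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitness import FitnessConfig, derive_ground_truth, total_cost
from .mgca import UpdateConfig, run_mgca
from .rules import PARAMS_PER_RULE, RuleSet
from .synthgen import SceneBundle, SceneSpec, generate_scene

__all__ = [
    "DEConfig",
    "EvolutionTrace",
    "SyntheticSceneSource",
    "FixedSceneSource",
    "init_population",
    "mutate",
    "crossover",
    "select",
    "evaluate_genome",
    "de_core",
    "evolve",
]


@dataclass
class DEConfig:
    """Differential-evolution settings (defaults follow the standard recipe:
    NP=100, CR=0.7, F=0.8, 30 rules -> 180 parameters, stop at the generation
    cap or when the best cost drops below 1e-6)."""

    NP: int = 100
    F: float = 0.8
    CR: float = 0.7
    n_rules: int = 30
    max_generations: int = 500
    min_cost: float = 1e-6
    mode: str = "fresh"  # 'fresh' (paired duels on fresh scenes) | 'fixed'
    seed: int = 0
    update: UpdateConfig = field(default_factory=UpdateConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)

    def __post_init__(self) -> None:
        if self.NP < 4:
            raise ValueError("NP must be >= 4 (rand/1 needs three distinct donors)")
        if not 0.0 < self.F <= 2.0:
            raise ValueError("F must lie in (0, 2]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must lie in [0, 1]")
        if self.mode not in ("fresh", "fixed"):
            raise ValueError("mode must be 'fresh' or 'fixed'")

    @property
    def genome_length(self) -> int:
        return PARAMS_PER_RULE * self.n_rules


@dataclass
class EvolutionTrace:
    """Per-generation record of an evolution run."""

    generations: list = field(default_factory=list)
    best_genome: np.ndarray | None = None
    best_cost: float = np.inf

    def append(self, generation: int, best: float, mean: float) -> None:
        self.generations.append(
            {"generation": generation, "best_cost": best, "mean_cost": mean}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.generations)

    @property
    def best_costs(self) -> np.ndarray:
        return np.array([g["best_cost"] for g in self.generations])


# ---------------------------------------------------------------------------
# scene sources
# ---------------------------------------------------------------------------

class SyntheticSceneSource:
    """Draws a fresh synthetic scene per request from a spec template."""

    def __init__(self, template: SceneSpec):
        self.template = template

    def draw(self, seed: int) -> SceneBundle:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return generate_scene(self.template.replace(seed=int(seed)))


class FixedSceneSource:
    """Cycles deterministically through a pre-built collection of scenes."""

    def __init__(self, bundles: list[SceneBundle]):
        if not bundles:
            raise ValueError("scene source must contain at least one scene")
        self.bundles = list(bundles)

    def draw(self, seed: int) -> SceneBundle:
        return self.bundles[int(seed) % len(self.bundles)]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def init_population(cfg: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """NP genomes uniform over the parameter bounds."""
    lo = RuleSet.lower_bounds(cfg.n_rules)
    hi = RuleSet.upper_bounds(cfg.n_rules)
    return rng.uniform(lo, hi, size=(cfg.NP, cfg.genome_length))


def mutate(
    x_r1: np.ndarray, x_r2: np.ndarray, x_r3: np.ndarray, F: float
) -> np.ndarray:
    """rand/1 donor: ``x_r1 + F (x_r2 - x_r3)``, then bounds repair
    (moduli clipped, angles wrapped)."""
    return RuleSet.repair_genome(x_r1 + F * (x_r2 - x_r3))


def crossover(
    target: np.ndarray, mutant: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover with one forced mutant gene."""
    if target.shape != mutant.shape:
        raise ValueError("target and mutant must have the same length")
    d = target.size
    take = rng.random(d) <= CR
    take[rng.integers(0, d)] = True  # rnbr(i): at least one mutant gene
    return np.where(take, mutant, target)


def _pick_donors(i: int, np_size: int, rng: np.random.Generator) -> tuple[int, int, int]:
    choices = np.delete(np.arange(np_size), i)
    r1, r2, r3 = rng.choice(choices, size=3, replace=False)
    return int(r1), int(r2), int(r3)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_genome(
    genome: np.ndarray,
    bundle: SceneBundle,
    cfg: DEConfig,
    fitness_seed: int,
    gt=None,
) -> float:
    """Cost of one genome on one scene: segment for K iterations, then score."""
    rules = RuleSet.from_genome(genome)
    if gt is None:
        gt = derive_ground_truth(bundle.labels)
    out = run_mgca(bundle.image, rules, cfg.update)
    fit_cfg = FitnessConfig(V=cfg.fitness.V, U=cfg.fitness.U, seed=fitness_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return total_cost(out, gt, fit_cfg).e


def select(
    target: np.ndarray,
    trial: np.ndarray,
    bundle: SceneBundle,
    cfg: DEConfig,
    fitness_seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Score both genomes on one shared scene; lower cost survives, ties keep
    the target.  Returns (survivor, target_cost, trial_cost)."""
    gt = derive_ground_truth(bundle.labels)
    c_t = evaluate_genome(target, bundle, cfg, fitness_seed, gt=gt)
    c_u = evaluate_genome(trial, bundle, cfg, fitness_seed, gt=gt)
    return (trial, c_t, c_u) if c_u < c_t else (target, c_t, c_u)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def de_core(
    objective,
    lower: np.ndarray,
    upper: np.ndarray,
    NP: int = 50,
    F: float = 0.8,
    CR: float = 0.7,
    max_generations: int = 200,
    min_cost: float = 1e-6,
    seed: int = 0,
    repair=None,
) -> tuple[np.ndarray, float, EvolutionTrace]:
    """Generic rand/1/bin DE with cached parent costs (deterministic
    objectives).  Used directly for sanity checks and by the fixed-image
    evolution mode."""
    lower = np.asarray(lower, dtype=np.float64)
    upper = np.asarray(upper, dtype=np.float64)
    d = lower.size
    repair = repair or (lambda g: np.clip(g, lower, upper))
    rng0 = np.random.default_rng([seed, 0])
    pop = rng0.uniform(lower, upper, size=(NP, d))
    costs = np.array([objective(g) for g in pop])
    trace = EvolutionTrace()
    trace.append(0, float(costs.min()), float(costs.mean()))
    for gen in range(1, max_generations + 1):
        if costs.min() <= min_cost:
            break
        for i in range(NP):
            rng = np.random.default_rng([seed, gen, i])
            r1, r2, r3 = _pick_donors(i, NP, rng)
            mutant = repair(pop[r1] + F * (pop[r2] - pop[r3]))
            trial = crossover(pop[i], mutant, CR, rng)
            c_u = objective(trial)
            if c_u < costs[i]:
                pop[i] = trial
                costs[i] = c_u
        trace.append(gen, float(costs.min()), float(costs.mean()))
    best = int(np.argmin(costs))
    trace.best_genome = pop[best].copy()
    trace.best_cost = float(costs[best])
    return pop[best].copy(), float(costs[best]), trace


def evolve(
    cfg: DEConfig,
    scene_source,
    progress=None,
) -> tuple[RuleSet, EvolutionTrace]:
    """Evolve a rule table against a scene source.

    ``scene_source`` must expose ``draw(seed) -> SceneBundle``.  All
    randomness is keyed off ``cfg.seed`` through per-(generation, individual)
    counter streams, so a run is a pure function of its configuration.

    Returns the best rule set and the evolution trace.  In ``fixed`` mode
    "best" is the exact minimizer of the (deterministic) cost; in ``fresh``
    mode the final population is re-scored on one common held-out scene and
    the minimizer returned.
    """
    if scene_source is None:
        raise ValueError("scene_source is required")
    seed = int(cfg.seed)

    if cfg.mode == "fixed":
        bundle = scene_source.draw(seed)
        gt = derive_ground_truth(bundle.labels)
        fit_seed = seed + 1

        def objective(genome: np.ndarray) -> float:
            return evaluate_genome(genome, bundle, cfg, fit_seed, gt=gt)

        best, best_cost, trace = de_core(
            objective,
            RuleSet.lower_bounds(cfg.n_rules),
            RuleSet.upper_bounds(cfg.n_rules),
            NP=cfg.NP,
            F=cfg.F,
            CR=cfg.CR,
            max_generations=cfg.max_generations,
            min_cost=cfg.min_cost,
            seed=seed,
            repair=RuleSet.repair_genome,
        )
        return RuleSet.from_genome(best), trace

    # fresh-per-comparison mode
    rng0 = np.random.default_rng([seed, 0])
    pop = init_population(cfg, rng0)
    trace = EvolutionTrace()
    stop = False
    for gen in range(1, cfg.max_generations + 1):
        gen_costs = np.empty(cfg.NP)
        for i in range(cfg.NP):
            rng = np.random.default_rng([seed, gen, i])
            r1, r2, r3 = _pick_donors(i, cfg.NP, rng)
            mutant = mutate(pop[r1], pop[r2], pop[r3], cfg.F)
            trial = crossover(pop[i], mutant, cfg.CR, rng)
            scene_seed = int(rng.integers(0, 2**31))
            fit_seed = int(rng.integers(0, 2**31))
            bundle = scene_source.draw(scene_seed)
            gt = derive_ground_truth(bundle.labels)
            c_t = evaluate_genome(pop[i], bundle, cfg, fit_seed, gt=gt)
            c_u = evaluate_genome(trial, bundle, cfg, fit_seed, gt=gt)
            if c_u < c_t:
                pop[i] = trial
                gen_costs[i] = c_u
            else:
                gen_costs[i] = c_t
        trace.append(gen, float(gen_costs.min()), float(gen_costs.mean()))
        if progress is not None:
            progress(gen, float(gen_costs.min()), float(gen_costs.mean()))
        if gen_costs.min() <= cfg.min_cost:
            stop = True
        if stop:
            break

    # final paired scoring of the population on one held-out scene
    holdout = scene_source.draw(seed + 977)
    gt = derive_ground_truth(holdout.labels)
    final = np.array(
        [evaluate_genome(g, holdout, cfg, seed + 977, gt=gt) for g in pop]
    )
    best = int(np.argmin(final))
    trace.best_genome = pop[best].copy()
    trace.best_cost = float(final[best])
    return RuleSet.from_genome(pop[best]), trace
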