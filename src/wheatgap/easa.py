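"""Evolutionary search algorithm with self-adaptation (EASA).

An elitist (1+16) evolution strategy run from 8 independent parents
(one seeded with the reference cultivar, the others scattered uniformly
in the trait box).  Mutation uses standard log-normal step-size
self-adaptation; offspring are clipped to the observed genetic-variation
bounds.  Candidates are scored by mean simulated yield over a fixed
multi-year weather realisation (common random numbers) and removed from
selection when the inter-annual yield CV exceeds 10% or the mean
harvest index exceeds 0.64.

The search itself is generic: any callable mapping a trait vector to a
:class:`FitnessRecord` can stand in for the simulator, which is how the
optimizer is validated against analytic fitness surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .crop import Management, ModelConstants, DEFAULT_CONSTANTS, SeasonError, simulate_years
from .cultivar import CLAIRE, TRAIT_BOUNDS, TRAIT_NAMES, CultivarParams
from .sites import SiteClimate
from .soil import SoilProfile
from .weather import WeatherSeries, generate_weather

__all__ = [
    "CandidateGenome",
    "FitnessRecord",
    "EASAConfig",
    "OptimizationResult",
    "init_parents",
    "mutate",
    "fitness_from_yields",
    "make_simulation_fitness",
    "select_next_parent",
    "run_easa",
    "design_ideotype",
    "active_trait_names",
]

#: LUE uplift applied when designing ideotypes (not to the reference)
IDEOTYPE_LUE = 1.10


def active_trait_names(mode: str) -> tuple[str, ...]:
    """Optimizable traits per mode; W_ss is meaningless without water stress."""
    if mode == "potential":
        return tuple(n for n in TRAIT_NAMES if n != "W_ss")
    return TRAIT_NAMES


@dataclass
class CandidateGenome:
    traits: np.ndarray          # active trait values
    step_sizes: np.ndarray      # per-trait mutation scales (same units)
    trait_names: tuple
    lineage_id: int = 0
    generation: int = 0

    def as_cultivar(self, reference: CultivarParams = CLAIRE,
                    name: str = "candidate") -> CultivarParams:
        kw = {n: float(v) for n, v in zip(self.trait_names, self.traits)}
        return reference.replace(name=name, **kw)

    def key(self) -> tuple:
        return tuple(np.round(self.traits, 10))


@dataclass(frozen=True)
class FitnessRecord:
    mean_yield: float  # t/ha
    cv_yield: float
    mean_HI: float
    feasible: bool
    n_years: int
    reason: str = ""


@dataclass(frozen=True)
class EASAConfig:
    n_parents: int = 8
    n_offspring: int = 16
    n_years: int = 100
    cv_threshold: float = 0.10
    hi_threshold: float = 0.64
    max_generations: int = 200
    stall_generations: int = 15
    rel_tol: float = 1e-3
    seed: int = 0
    include_reference_parent: bool = True
    mode: str = "water_limited"

    def __post_init__(self):
        if not (0.0 < self.cv_threshold < 1.0 and 0.0 < self.hi_threshold < 1.0):
            raise ValueError("feasibility thresholds must lie in (0, 1)")
        if self.n_offspring < 1 or self.n_parents < 1:
            raise ValueError("need at least one parent and one offspring")

    @property
    def trait_names(self) -> tuple:
        return active_trait_names(self.mode)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([TRAIT_BOUNDS[n][0] for n in self.trait_names])
        hi = np.array([TRAIT_BOUNDS[n][1] for n in self.trait_names])
        return lo, hi


@dataclass
class LineageTrace:
    lineage_id: int
    best_yield: list  # best feasible mean yield per generation (nan before any)
    generations: int = 0
    stalled: bool = False


@dataclass
class OptimizationResult:
    best_genome: CandidateGenome
    best_fitness: FitnessRecord
    traces: list
    generations_run: int
    n_evaluations: int
    converged: bool
    config: EASAConfig


def init_parents(config: EASAConfig, reference: CultivarParams | None = CLAIRE,
                 rng: np.random.Generator | None = None) -> list[CandidateGenome]:
    """Seeded initial parents: parent 0 = reference (clipped into bounds),
    the rest uniform within the trait box."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.bounds
    sigma0 = (hi - lo) / 8.0
    parents = []
    start = 0
    if config.include_reference_parent:
        if reference is None:
            raise ValueError("include_reference_parent requires a reference cultivar")
        ref = np.array([getattr(reference, n) for n in config.trait_names])
        clipped = np.clip(ref, lo, hi)
        parents.append(CandidateGenome(clipped, sigma0.copy(),
                                       config.trait_names, lineage_id=0))
        start = 1
    for j in range(start, config.n_parents):
        x = rng.uniform(lo, hi)
        parents.append(CandidateGenome(x, sigma0.copy(),
                                       config.trait_names, lineage_id=j))
    return parents


def mutate(parent: CandidateGenome, rng: np.random.Generator,
           config: EASAConfig) -> list[CandidateGenome]:
    """16 offspring by log-normal step-size self-adaptation, clipped to bounds."""
    lo, hi = config.bounds
    n = len(parent.traits)
    tau_global = 1.0 / math.sqrt(2.0 * n)
    tau_coord = 1.0 / math.sqrt(2.0 * math.sqrt(n))
    span = hi - lo
    offspring = []
    for _ in range(config.n_offspring):
        g = rng.standard_normal()
        sig = parent.step_sizes * np.exp(
            tau_global * g + tau_coord * rng.standard_normal(n)
        )
        sig = np.clip(sig, 1e-8 * span, span)
        x = parent.traits + sig * rng.standard_normal(n)
        x = np.clip(x, lo, hi)
        offspring.append(
            CandidateGenome(x, sig, parent.trait_names,
                            lineage_id=parent.lineage_id,
                            generation=parent.generation + 1)
        )
    return offspring


def fitness_from_yields(mean_yield: float, cv_yield: float, mean_hi: float,
                        n_years: int, config: EASAConfig) -> FitnessRecord:
    """Apply the CV/HI feasibility filter (thresholds inclusive)."""
    reasons = []
    if cv_yield > config.cv_threshold:
        reasons.append(f"CV {cv_yield:.3f} > {config.cv_threshold}")
    if mean_hi > config.hi_threshold:
        reasons.append(f"HI {mean_hi:.3f} > {config.hi_threshold}")
    return FitnessRecord(mean_yield, cv_yield, mean_hi,
                         feasible=not reasons, n_years=n_years,
                         reason="; ".join(reasons))


def make_simulation_fitness(
    series: WeatherSeries,
    config: EASAConfig,
    soil: SoilProfile | None = None,
    reference: CultivarParams = CLAIRE,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    lue_multiplier: float = IDEOTYPE_LUE,
):
    """Fitness callable scoring genomes by simulated multi-year yield.

    All candidates in a run see the same weather realisation (common
    random numbers), mirroring optimisation against a fixed
    baseline-climate series.  Evaluations are memoized per genome.
    """
    management = Management(mode=config.mode, lue_multiplier=lue_multiplier)
    cache: dict = {}

    def fitness(genome: CandidateGenome) -> FitnessRecord:
        key = genome.key()
        if key in cache:
            return cache[key]
        cv = genome.as_cultivar(reference)
        try:
            ys = simulate_years(cv, series, soil, management, constants)
            rec = fitness_from_yields(ys.mean_yield, ys.cv_yield, ys.mean_HI,
                                      len(ys.results), config)
        except SeasonError as exc:
            rec = FitnessRecord(0.0, np.inf, 0.0, feasible=False,
                                n_years=series.n_years - 1,
                                reason=f"simulation failed: {exc}")
        cache[key] = rec
        return rec

    return fitness


def _rank_key(genome: CandidateGenome, rec: FitnessRecord):
    # feasible first, then yield; deterministic tie-break on the traits
    return (rec.feasible, rec.mean_yield, tuple(-genome.traits))


def select_next_parent(candidates: list) -> tuple[CandidateGenome, FitnessRecord]:
    """Elitist selection: argmax mean yield over feasible members of
    {parent} U offspring; the parent (listed first) wins ties."""
    if not candidates:
        raise ValueError("nothing to select from")
    best = candidates[0]
    for c in candidates[1:]:
        if _rank_key(c[0], c[1]) > _rank_key(best[0], best[1]):
            best = c
    return best


def run_easa(config: EASAConfig, fitness, reference: CultivarParams | None = CLAIRE,
             ) -> OptimizationResult:
    """Run the multi-start elitist search until convergence.

    ``fitness`` maps a :class:`CandidateGenome` to a
    :class:`FitnessRecord`.  Per lineage the search stops after
    ``stall_generations`` without a relative improvement above
    ``rel_tol`` (or at ``max_generations``); the best feasible candidate
    across all lineages is returned.
    """
    root = np.random.SeedSequence(config.seed)
    parent_rng = np.random.default_rng(root.spawn(1)[0])
    lineage_seeds = root.spawn(config.n_parents)
    parents = init_parents(config, reference, parent_rng)

    best_genome = None
    best_rec = None
    traces = []
    n_eval = 0
    total_gens = 0
    all_converged = True

    for li, parent in enumerate(parents):
        rng = np.random.default_rng(lineage_seeds[li])
        prec = fitness(parent)
        n_eval += 1
        trace = LineageTrace(li, [prec.mean_yield if prec.feasible else np.nan])
        stall = 0
        converged = False
        for gen in range(1, config.max_generations + 1):
            offspring = mutate(parent, rng, config)
            scored = [(parent, prec)] + [(o, fitness(o)) for o in offspring]
            n_eval += len(offspring)
            new_parent, new_rec = select_next_parent(scored)
            improved = False
            if new_rec.feasible:
                if not prec.feasible:
                    improved = True
                else:
                    improved = (new_rec.mean_yield
                                > prec.mean_yield * (1.0 + config.rel_tol))
            parent, prec = new_parent, new_rec
            trace.best_yield.append(prec.mean_yield if prec.feasible else np.nan)
            trace.generations = gen
            stall = 0 if improved else stall + 1
            if stall >= config.stall_generations:
                converged = True
                break
        trace.stalled = not prec.feasible
        all_converged = all_converged and converged
        total_gens += trace.generations
        traces.append(trace)
        if prec.feasible and (best_rec is None
                              or prec.mean_yield > best_rec.mean_yield):
            best_genome, best_rec = parent, prec

    if best_genome is None:
        raise RuntimeError("EASA found no feasible candidate in any lineage")
    return OptimizationResult(
        best_genome=best_genome,
        best_fitness=best_rec,
        traces=traces,
        generations_run=total_gens,
        n_evaluations=n_eval,
        converged=all_converged,
        config=config,
    )


def design_ideotype(
    site: SiteClimate,
    mode: str = "water_limited",
    config: EASAConfig | None = None,
    weather: WeatherSeries | None = None,
    weather_seed: int | None = None,
    soil: SoilProfile | None = None,
    reference: CultivarParams = CLAIRE,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> OptimizationResult:
    """Design an ideotype for ``site``/``mode`` over seeded baseline weather.

    Candidates are evaluated with the 10% light-use-efficiency uplift;
    the weather realisation is shared by all candidates.
    """
    config = config or EASAConfig(mode=mode)
    if config.mode != mode:
        config = replace(config, mode=mode)
    if weather is None:
        seed = weather_seed if weather_seed is not None else config.seed
        # +1 year: a sowing-year season matures in the following calendar year
        weather = generate_weather(site, config.n_years + 1, seed)
    fitness = make_simulation_fitness(weather, config, soil, reference, constants)
    return run_easa(config, fitness, reference)
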