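"""Evolution-strategy optimizer: initialisation, mutation, selection,
feasibility filtering, and recovery of known analytic optima."""

import numpy as np
import pytest
from scipy import stats

import wheatgap as wg
from wheatgap.easa import (CandidateGenome, EASAConfig, FitnessRecord,
                           fitness_from_yields, init_parents,
                           make_simulation_fitness, mutate, run_easa,
                           select_next_parent)


def analytic_fitness(optimum, weights, cfg, recorder=None):
    """Concave quadratic surrogate fitness over the trait box."""
    lo, hi = cfg.bounds
    span = hi - lo

    def fitness(genome):
        if recorder is not None:
            recorder.append(genome)
        u = (genome.traits - optimum) / span
        val = 10.0 - float(np.sum(weights * u * u))
        return FitnessRecord(val, 0.02, 0.5, feasible=True, n_years=1)

    return fitness


class TestInitParents:
    def test_reference_seeded_parent_and_count(self):
        cfg = EASAConfig(seed=3)
        parents = init_parents(cfg, wg.CLAIRE)
        assert len(parents) == 8
        ref = np.array([getattr(wg.CLAIRE, n) for n in cfg.trait_names])
        np.testing.assert_allclose(parents[0].traits, ref)

    def test_seeded_reproducibility(self):
        cfg = EASAConfig(seed=5)
        a = init_parents(cfg, wg.CLAIRE)
        b = init_parents(cfg, wg.CLAIRE)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.traits, y.traits)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            init_parents(EASAConfig(), None)

    def test_random_parents_uniform_within_bounds(self):
        cfg = EASAConfig(seed=11, n_parents=10001)
        parents = init_parents(cfg, wg.CLAIRE)
        samples = np.array([p.traits for p in parents[1:]])
        lo, hi = cfg.bounds
        assert np.all(samples >= lo) and np.all(samples <= hi)
        for j, name in enumerate(cfg.trait_names):
            u = (samples[:, j] - lo[j]) / (hi[j] - lo[j])
            assert stats.kstest(u, "uniform").pvalue > 0.01, name


class TestMutate:
    def test_offspring_count_and_clipping(self):
        cfg = EASAConfig(seed=0)
        lo, hi = cfg.bounds
        parent = CandidateGenome(hi.copy(), (hi - lo) / 4, cfg.trait_names)
        rng = np.random.default_rng(1)
        kids = mutate(parent, rng, cfg)
        assert len(kids) == 16
        for k in kids:
            assert np.all(k.traits <= hi + 1e-12)
            assert np.all(k.traits >= lo - 1e-12)
            assert np.all(k.step_sizes > 0)

    def test_tiny_steps_reproduce_parent(self):
        cfg = EASAConfig(seed=0)
        lo, hi = cfg.bounds
        mid = (lo + hi) / 2
        parent = CandidateGenome(mid.copy(), 1e-7 * (hi - lo), cfg.trait_names)
        kids = mutate(parent, np.random.default_rng(2), cfg)
        for k in kids:
            assert np.all(np.abs(k.traits - mid) <= 1e-4 * hi)

    def test_offspring_spread_tracks_step_size(self):
        """Self-adaptation plumbing: larger parent steps give larger
        offspring perturbations (rank correlation over replicates)."""
        cfg = EASAConfig(seed=0)
        lo, hi = cfg.bounds
        mid = (lo + hi) / 2
        rng = np.random.default_rng(3)
        sizes, spreads = [], []
        for _ in range(1000):
            scale = rng.uniform(0.01, 0.5)
            parent = CandidateGenome(mid.copy(), scale * (hi - lo),
                                     cfg.trait_names)
            kids = mutate(parent, rng, cfg)
            dev = np.mean([np.abs((k.traits - mid) / (hi - lo)) for k in kids])
            sizes.append(scale)
            spreads.append(dev)
        rho = stats.spearmanr(sizes, spreads).statistic
        assert rho > 0.5


class TestFeasibility:
    def test_thresholds_inclusive(self):
        cfg = EASAConfig()
        assert fitness_from_yields(10.0, 0.10, 0.64, 100, cfg).feasible
        assert not fitness_from_yields(10.0, 0.12, 0.5, 100, cfg).feasible
        assert not fitness_from_yields(10.0, 0.05, 0.65, 100, cfg).feasible

    def test_infeasible_reason_recorded(self):
        rec = fitness_from_yields(10.0, 0.2, 0.7, 100, EASAConfig())
        assert "CV" in rec.reason and "HI" in rec.reason


class TestSelection:
    def _genome(self, vals, cfg):
        lo, hi = cfg.bounds
        return CandidateGenome(np.asarray(vals, dtype=float),
                               (hi - lo) / 8, cfg.trait_names)

    def test_elitism_when_all_offspring_infeasible(self):
        cfg = EASAConfig()
        lo, hi = cfg.bounds
        parent = (self._genome(lo, cfg),
                  FitnessRecord(8.0, 0.05, 0.5, True, 10))
        kids = [(self._genome(hi, cfg),
                 FitnessRecord(12.0, 0.2, 0.5, False, 10))]
        chosen, rec = select_next_parent([parent] + kids)
        assert rec is parent[1]

    def test_better_offspring_wins(self):
        cfg = EASAConfig()
        lo, hi = cfg.bounds
        parent = (self._genome(lo, cfg), FitnessRecord(12.0, 0.05, 0.5, True, 10))
        kid = (self._genome(hi, cfg), FitnessRecord(12.1, 0.05, 0.5, True, 10))
        chosen, rec = select_next_parent([parent, kid])
        assert rec.mean_yield == 12.1

    def test_tie_break_is_deterministic(self):
        cfg = EASAConfig()
        lo, hi = cfg.bounds
        a = (self._genome(lo, cfg), FitnessRecord(12.0, 0.05, 0.5, True, 10))
        b = (self._genome(hi, cfg), FitnessRecord(12.0, 0.05, 0.5, True, 10))
        first = select_next_parent([a, b])
        for _ in range(5):
            assert select_next_parent([a, b])[0] is first[0]


class TestRunEASA:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_analytic_optimum(self, seed):
        cfg = EASAConfig(seed=seed, n_years=1, max_generations=400,
                         stall_generations=50, rel_tol=1e-7)
        lo, hi = cfg.bounds
        optimum = lo + np.array([0.3, 0.7, 0.5, 0.25, 0.6, 0.4, 0.8]) * (hi - lo)
        weights = np.array([5.0, 3.0, 4.0, 5.0, 2.0, 3.0, 4.0])
        result = run_easa(cfg, analytic_fitness(optimum, weights, cfg), wg.CLAIRE)
        err = np.abs(result.best_genome.traits - optimum) / (hi - lo)
        assert np.all(err < 0.02), err

    def test_all_evaluated_genomes_within_bounds_and_traces_monotone(self):
        cfg = EASAConfig(seed=9, n_years=1, max_generations=60,
                         stall_generations=10)
        lo, hi = cfg.bounds
        optimum = (lo + hi) / 2
        seen = []
        result = run_easa(cfg, analytic_fitness(optimum, np.full(7, 4.0), cfg,
                                                recorder=seen), wg.CLAIRE)
        assert len(seen) == result.n_evaluations
        for g in seen:
            assert np.all(g.traits >= lo - 1e-12)
            assert np.all(g.traits <= hi + 1e-12)
        for tr in result.traces:
            ys = [y for y in tr.best_yield if not np.isnan(y)]
            assert all(a <= b + 1e-12 for a, b in zip(ys, ys[1:]))

    def test_end_to_end_seeded_reproducibility(self):
        cfg = EASAConfig(seed=21, n_years=1, max_generations=30,
                         stall_generations=8)
        lo, hi = cfg.bounds
        optimum = (lo + hi) / 2
        a = run_easa(cfg, analytic_fitness(optimum, np.full(7, 4.0), cfg), wg.CLAIRE)
        b = run_easa(cfg, analytic_fitness(optimum, np.full(7, 4.0), cfg), wg.CLAIRE)
        np.testing.assert_array_equal(a.best_genome.traits, b.best_genome.traits)
        assert a.n_evaluations == b.n_evaluations

    def test_no_feasible_candidate_raises(self):
        cfg = EASAConfig(seed=1, max_generations=3, stall_generations=2)

        def hopeless(genome):
            return FitnessRecord(0.0, 0.5, 0.9, feasible=False, n_years=1)

        with pytest.raises(RuntimeError, match="no feasible"):
            run_easa(cfg, hopeless, wg.CLAIRE)


class TestSimulationDriven:
    def test_designed_ideotype_beats_seeded_reference(self, weather):
        site = wg.get_site("RR")
        series = weather("RR", 9, 42)
        cfg = EASAConfig(mode="water_limited", seed=4, n_years=8,
                         max_generations=6, stall_generations=6, n_parents=3)
        fitness = make_simulation_fitness(series, cfg)
        claire_rec = fitness(init_parents(cfg, wg.CLAIRE)[0])
        result = run_easa(cfg, fitness, wg.CLAIRE)
        assert result.best_fitness.feasible
        assert result.best_fitness.cv_yield <= cfg.cv_threshold
        assert result.best_fitness.mean_HI <= cfg.hi_threshold
        # Claire stays selectable in her lineage, so the optimum dominates her
        assert result.best_fitness.mean_yield >= claire_rec.mean_yield

    def test_potential_mode_excludes_wss(self):
        cfg = EASAConfig(mode="potential")
        assert "W_ss" not in cfg.trait_names
        assert len(cfg.trait_names) == 6
        full = EASAConfig(mode="water_limited")
        assert len(full.trait_names) == 7
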