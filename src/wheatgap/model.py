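"""Model/Results interface over the ideotype designer and gap pipeline.

``IdeotypeModel`` wraps the evolution-strategy search for one site and
water regime; ``fit()`` returns an ``IdeotypeResults`` carrying the
optimized trait estimates, their final mutation scales (a measure of
how sharply each trait is pinned by the fitness surface), the fitness
diagnostics and per-lineage traces, with a ``summary()`` table.

``YieldGapAnalysis`` runs the full sites-x-modes study and exposes the
site reports and country aggregates as DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .crop import ModelConstants, DEFAULT_CONSTANTS
from .cultivar import CLAIRE, TRAIT_BOUNDS, CultivarParams
from .easa import EASAConfig, OptimizationResult, design_ideotype
from .sites import SiteClimate, builtin_sites, get_site
from .yieldgap import reports_to_frame, run_full_analysis, simulate_reference

__all__ = ["IdeotypeModel", "IdeotypeResults", "YieldGapAnalysis", "YieldGapResults"]


class IdeotypeModel:
    """Design a wheat ideotype for one site and water regime.

    Parameters
    ----------
    site : SiteClimate or str
        Target site (or a built-in site code such as ``"RR"``).
    mode : {"water_limited", "potential"}
        Rainfed or irrigated evaluation of candidates.
    config : EASAConfig, optional
        Search settings; defaults to the standard 8-parent, 16-offspring
        configuration with 100 evaluation years.
    """

    def __init__(self, site, mode: str = "water_limited",
                 config: EASAConfig | None = None,
                 reference: CultivarParams = CLAIRE,
                 constants: ModelConstants = DEFAULT_CONSTANTS):
        self.site = get_site(site) if isinstance(site, str) else site
        self.mode = mode
        self.config = config or EASAConfig(mode=mode)
        self.reference = reference
        self.constants = constants

    def fit(self, seed: int | None = None) -> "IdeotypeResults":
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if cfg.mode != self.mode:
            cfg = replace(cfg, mode=self.mode)
        opt = design_ideotype(self.site, self.mode, cfg,
                              reference=self.reference,
                              constants=self.constants)
        ref = simulate_reference(self.site, mode=self.mode, seed=cfg.seed,
                                 n_years=cfg.n_years, cultivar=self.reference,
                                 constants=self.constants)
        return IdeotypeResults(self, opt, ref.mean_yield)


@dataclass
class IdeotypeResults:
    model: IdeotypeModel
    optimization: OptimizationResult
    reference_yield: float

    @property
    def params(self) -> pd.Series:
        g = self.optimization.best_genome
        return pd.Series(dict(zip(g.trait_names, g.traits)), name="estimate")

    @property
    def step_sizes(self) -> pd.Series:
        g = self.optimization.best_genome
        return pd.Series(dict(zip(g.trait_names, g.step_sizes)), name="step_size")

    @property
    def ideotype(self) -> CultivarParams:
        return self.optimization.best_genome.as_cultivar(
            self.model.reference, name=f"ideotype_{self.model.site.site_id}")

    @property
    def mean_yield(self) -> float:
        return self.optimization.best_fitness.mean_yield

    @property
    def yield_gain(self) -> float:
        return self.mean_yield - self.reference_yield

    def summary(self) -> str:
        fit = self.optimization.best_fitness
        g = self.optimization.best_genome
        lines = []
        site = self.model.site
        lines.append("Ideotype design results")
        lines.append("=" * 58)
        lines.append(f"site: {site.site_id} ({site.country})   mode: {self.model.mode}")
        lines.append(f"evaluation years: {fit.n_years}   "
                     f"evaluations: {self.optimization.n_evaluations}")
        lines.append(f"mean yield: {fit.mean_yield:.1f} t/ha   "
                     f"CV: {100 * fit.cv_yield:.1f}%   HI: {fit.mean_HI:.2f}")
        lines.append(f"reference ({self.model.reference.name}): "
                     f"{self.reference_yield:.1f} t/ha   "
                     f"gain: {self.yield_gain:+.1f} t/ha")
        lines.append("-" * 58)
        lines.append(f"{'trait':>8} {'estimate':>12} {'step size':>12} "
                     f"{'bounds':>18}")
        for name, val, sig in zip(g.trait_names, g.traits, g.step_sizes):
            lo, hi = TRAIT_BOUNDS[name]
            lines.append(f"{name:>8} {val:>12.4g} {sig:>12.3g} "
                         f"{f'[{lo:g}, {hi:g}]':>18}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Best feasible yield per generation for every lineage."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tr in self.optimization.traces:
            ax.plot(tr.best_yield, label=f"lineage {tr.lineage_id}")
        ax.set_xlabel("generation")
        ax.set_ylabel("best mean yield (t/ha)")
        ax.legend(fontsize="small")
        return ax


class YieldGapAnalysis:
    """The full yield-gap study: all sites x both water regimes."""

    def __init__(self, sites=None, n_years: int = 100,
                 max_generations: int = 200, stall_generations: int = 15,
                 n_parents: int = 8,
                 constants: ModelConstants = DEFAULT_CONSTANTS):
        self.sites = list(sites) if sites is not None else builtin_sites()
        self.n_years = n_years
        self.max_generations = max_generations
        self.stall_generations = stall_generations
        self.n_parents = n_parents
        self.constants = constants

    def fit(self, seed: int = 0, progress=None) -> "YieldGapResults":
        reports, aggregates, manifest = run_full_analysis(
            seed=seed, n_years=self.n_years,
            max_generations=self.max_generations,
            stall_generations=self.stall_generations,
            n_parents=self.n_parents, sites=self.sites,
            constants=self.constants, progress=progress,
        )
        return YieldGapResults(self, reports, aggregates, manifest)


@dataclass
class YieldGapResults:
    model: YieldGapAnalysis
    reports: list
    aggregates: list
    manifest: dict

    @property
    def site_table(self) -> pd.DataFrame:
        return reports_to_frame(self.reports)

    @property
    def country_table(self) -> pd.DataFrame:
        rows = []
        for a in self.aggregates:
            rows.append({
                "country": a.country, "mode": a.mode,
                "y_m": round(a.y_m, 1), "y_gp": round(a.y_gp, 1),
                "y_g": round(a.y_g, 1), "y_g_pct": round(a.y_g_pct),
                "between_site_var": round(a.between_site_variance, 2),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Yield gap analysis", "=" * 66]
        lines.append(self.site_table.to_string(index=False))
        lines.append("-" * 66)
        lines.append(self.country_table.to_string(index=False))
        lines.append("=" * 66)
        return "\n".join(lines)
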