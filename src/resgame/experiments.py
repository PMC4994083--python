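"""Experiment drivers: diversity measurements and parameter sweeps.

These reproduce, at configurable scale, the standard experimental designs of
the model: a recorded single-community trajectory, diversity versus mutation
rate under several selection intensities (with the neutral-theory curve as
analytic reference), diversity versus community size at fixed ``R_Max`` or
fixed ``R_Max / N``, and the pairwise game census versus ``R_Max``.

Every driver is reproducible from a single master seed: replicate streams are
spawned as ``SeedSequence([master_seed, cell_index, replicate])``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import core, dynamics, theory
from .core import ModelParams
from .dynamics import Trajectory
from .errors import InvalidParameterError

__all__ = [
    "DiversitySummary",
    "SweepResult",
    "measure_diversity",
    "census_over_trajectory",
    "diversity_vs_mutation",
    "diversity_vs_community_size",
    "games_vs_rmax",
    "count_mutation_window",
    "MutationWindowStats",
]


@dataclass(frozen=True)
class DiversitySummary:
    """Time-averaged species richness of one or more trajectories."""

    mean_richness: float
    std_error: float
    n_samples: int
    config_echo: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_richness < 1.0:
            raise InvalidParameterError("mean richness cannot drop below 1")


@dataclass
class SweepResult:
    """One sweep along a named axis.

    ``summaries[i]`` holds the statistics for ``axis_values[i]`` — a dict
    mapping a series label (e.g. ``"w=10"``, ``"diversity"``, ``"games"``,
    ``"neutral_theory"``) to a :class:`DiversitySummary`,
    :class:`~resgame.theory.GameCensus` or float.
    """

    axis_name: str
    axis_values: list
    summaries: list[dict[str, Any]]
    replicate_seeds: list
    diagnostics: dict[str, Any] = field(default_factory=dict)
    config_echo: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.summaries) != len(self.axis_values):
            raise InvalidParameterError(
                "summaries must align one-to-one with axis_values"
            )

    def series(self, label: str) -> np.ndarray:
        """Mean-richness (or scalar) series for one label across the axis."""
        out = []
        for cell in self.summaries:
            v = cell[label]
            out.append(v.mean_richness if isinstance(v, DiversitySummary) else v)
        return np.asarray(out, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for x, cell in zip(self.axis_values, self.summaries):
            for label, v in cell.items():
                if isinstance(v, DiversitySummary):
                    rows.append(
                        dict(axis=self.axis_name, value=x, series=label,
                             statistic="mean_richness", result=v.mean_richness)
                    )
                    rows.append(
                        dict(axis=self.axis_name, value=x, series=label,
                             statistic="std_error", result=v.std_error)
                    )
                elif isinstance(v, theory.GameCensus):
                    for game, frac in v.fractions.items():
                        rows.append(
                            dict(axis=self.axis_name, value=x, series=label,
                                 statistic=f"frac_{game}", result=frac)
                        )
                else:
                    rows.append(
                        dict(axis=self.axis_name, value=x, series=label,
                             statistic="value", result=float(v))
                    )
        return pd.DataFrame(rows)


def _rep_rng(master_seed: int, cell: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, cell, rep]))


def measure_diversity(
    trajectory: Trajectory, config_echo: dict[str, Any] | None = None
) -> DiversitySummary:
    """Time-averaged richness over the sampled generations of a trajectory."""
    richness = trajectory.richness_array()
    if richness.size == 0:
        raise InvalidParameterError("trajectory has no sampled generations")
    mean = float(richness.mean())
    se = float(richness.std(ddof=1) / np.sqrt(richness.size)) if richness.size > 1 else 0.0
    return DiversitySummary(
        mean_richness=mean,
        std_error=se,
        n_samples=int(richness.size),
        config_echo=config_echo or {},
    )


def _pool_replicates(
    summaries: list[DiversitySummary], config_echo: dict[str, Any]
) -> DiversitySummary:
    """Combine replicate summaries: mean of means, SE across replicates."""
    means = np.array([s.mean_richness for s in summaries])
    se = float(means.std(ddof=1) / np.sqrt(means.size)) if means.size > 1 else (
        summaries[0].std_error
    )
    return DiversitySummary(
        mean_richness=float(means.mean()),
        std_error=se,
        n_samples=int(sum(s.n_samples for s in summaries)),
        config_echo=config_echo,
    )


def census_over_trajectory(trajectory: Trajectory) -> theory.GameCensus:
    """Time-averaged pairwise game census of a trajectory.

    Requires the trajectory to carry capability samples.  Each sampled
    community contributes all its unordered species pairs; monomorphic
    samples contribute none.  Fractions are over the pooled pair count.
    """
    if trajectory.capability_samples is None:
        raise InvalidParameterError(
            "trajectory was recorded without capability samples"
        )
    counts = dict.fromkeys(theory.GAME_LABELS, 0.0)
    total = 0
    for mu in trajectory.capability_samples:
        if mu.size < 2:
            continue
        census = theory.game_census(core.payoff_matrix(mu))
        for label, frac in census.fractions.items():
            counts[label] += frac * census.n_pairs
        total += census.n_pairs
    if total == 0:
        return theory.GameCensus(n_pairs=0, fractions={})
    return theory.GameCensus(
        n_pairs=total, fractions={k: v / total for k, v in counts.items()}
    )


def diversity_vs_mutation(
    params: ModelParams,
    mutation_rates: list[float],
    selection_intensities: list[float],
    *,
    generations: int,
    burn_in: int,
    sampling_interval: int = 1,
    replicates: int = 3,
    seed: int = 0,
    init_mode: str = "single",
    init_species: int = 10,
    include_frequency_independent: bool = False,
) -> SweepResult:
    """Mean diversity on a (mutation rate x selection intensity) grid.

    Each cell averages ``replicates`` independent runs; the neutral-theory
    expectation is attached as the analytic reference series
    ``"neutral_theory"``.  Optionally adds a frequency-independent control
    series per selection intensity.
    """
    summaries: list[dict[str, Any]] = []
    rep_seeds = []
    cell = 0
    for nu in mutation_rates:
        row: dict[str, Any] = {
            "neutral_theory": theory.neutral_expected_diversity(
                params.community_size, nu
            )
        }
        for w in selection_intensities:
            variants = [("", True)]
            if include_frequency_independent:
                variants.append(("|freq_indep", False))
            for suffix, freq_dep in variants:
                p = replace(
                    params, selection_intensity=w, mutation_prob=nu,
                    frequency_dependent=freq_dep,
                )
                reps = []
                for r in range(replicates):
                    rep_seeds.append((seed, cell, r))
                    res = dynamics.run(
                        p, generations, burn_in=burn_in,
                        sampling_interval=sampling_interval,
                        init_mode=init_mode, init_species=init_species,
                        rng=_rep_rng(seed, cell, r),
                        record_abundances=False,
                    )
                    reps.append(measure_diversity(res.trajectory))
                row[f"w={w:g}{suffix}"] = _pool_replicates(
                    reps, {"nu": nu, "w": w, "frequency_dependent": freq_dep}
                )
                cell += 1
        summaries.append(row)
    return SweepResult(
        axis_name="mutation_rate",
        axis_values=list(mutation_rates),
        summaries=summaries,
        replicate_seeds=rep_seeds,
        config_echo={
            "params": asdict(params),
            "generations": generations, "burn_in": burn_in,
            "sampling_interval": sampling_interval,
            "replicates": replicates, "seed": seed,
        },
    )


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0


def diversity_vs_community_size(
    params: ModelParams,
    community_sizes: list[int],
    mode: str,
    *,
    ratio: float = 0.5,
    generations: int,
    burn_in: int,
    sampling_interval: int = 1,
    replicates: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Mean diversity versus community size N.

    ``mode="fixed_r_max"`` keeps ``R_Max`` at ``params.r_max`` for every N
    (so larger communities face a relatively harsher environment);
    ``mode="fixed_ratio"`` keeps ``R_Max / N == ratio``.  Diagnostics carry
    the linear-fit R^2 of S vs N (fixed R_Max) or the log-linear-fit R^2 of
    S vs log N (fixed ratio) plus the fitted slope.
    """
    if mode not in ("fixed_r_max", "fixed_ratio"):
        raise InvalidParameterError(f"unknown mode: {mode!r}")
    if list(community_sizes) != sorted(community_sizes):
        raise InvalidParameterError("community_sizes must be increasing")
    summaries = []
    rep_seeds = []
    for cell, n in enumerate(community_sizes):
        r_max = params.r_max if mode == "fixed_r_max" else ratio * n
        p = replace(params, community_size=int(n), r_max=float(r_max))
        reps = []
        for r in range(replicates):
            rep_seeds.append((seed, cell, r))
            res = dynamics.run(
                p, generations, burn_in=burn_in,
                sampling_interval=sampling_interval,
                rng=_rep_rng(seed, cell, r), record_abundances=False,
            )
            reps.append(measure_diversity(res.trajectory))
        summaries.append(
            {"diversity": _pool_replicates(reps, {"N": int(n), "r_max": r_max})}
        )
    n_arr = np.asarray(community_sizes, dtype=float)
    s_arr = np.array([c["diversity"].mean_richness for c in summaries])
    diagnostics: dict[str, Any] = {"mode": mode}
    if len(community_sizes) >= 2:
        if mode == "fixed_r_max":
            slope, _ = np.polyfit(n_arr, s_arr, 1)
            diagnostics["linear_slope"] = float(slope)
            diagnostics["linear_r2"] = _r_squared(n_arr, s_arr)
        else:
            slope, _ = np.polyfit(np.log(n_arr), s_arr, 1)
            diagnostics["log_slope"] = float(slope)
            diagnostics["log_r2"] = _r_squared(np.log(n_arr), s_arr)
    return SweepResult(
        axis_name="community_size",
        axis_values=[int(n) for n in community_sizes],
        summaries=summaries,
        replicate_seeds=rep_seeds,
        diagnostics=diagnostics,
        config_echo={"mode": mode, "ratio": ratio, "generations": generations,
                     "burn_in": burn_in, "replicates": replicates, "seed": seed},
    )


def games_vs_rmax(
    params: ModelParams,
    r_max_values: list[float],
    *,
    generations: int,
    burn_in: int,
    sampling_interval: int = 10,
    replicates: int = 3,
    seed: int = 0,
) -> SweepResult:
    """Game census and diversity as a function of the maximum supply R_Max.

    For each R_Max the community is simulated to its stationary regime; the
    pairwise game census is evaluated at every sampled generation after
    burn-in (monomorphic samples contribute no pairs) and pooled with the
    time-averaged diversity.
    """
    summaries = []
    rep_seeds = []
    for cell, r_max in enumerate(r_max_values):
        p = replace(params, r_max=float(r_max))
        div_reps = []
        counts = dict.fromkeys(theory.GAME_LABELS, 0.0)
        total_pairs = 0
        for r in range(replicates):
            rep_seeds.append((seed, cell, r))
            res = dynamics.run(
                p, generations, burn_in=burn_in,
                sampling_interval=sampling_interval,
                rng=_rep_rng(seed, cell, r),
                record_abundances=False, record_capabilities=True,
            )
            div_reps.append(measure_diversity(res.trajectory))
            census = census_over_trajectory(res.trajectory)
            for label, frac in census.fractions.items():
                counts[label] += frac * census.n_pairs
            total_pairs += census.n_pairs
        games = (
            theory.GameCensus(
                n_pairs=total_pairs,
                fractions={k: v / total_pairs for k, v in counts.items()},
            )
            if total_pairs > 0
            else theory.GameCensus(n_pairs=0, fractions={})
        )
        summaries.append(
            {
                "diversity": _pool_replicates(div_reps, {"r_max": float(r_max)}),
                "games": games,
            }
        )
    return SweepResult(
        axis_name="r_max",
        axis_values=[float(r) for r in r_max_values],
        summaries=summaries,
        replicate_seeds=rep_seeds,
        config_echo={"generations": generations, "burn_in": burn_in,
                     "replicates": replicates, "seed": seed},
    )


@dataclass(frozen=True)
class MutationWindowStats:
    """Speciation-event totals per observation window over replicates."""

    mean: float
    variance: float
    counts: tuple[int, ...]
    expected: float  # binomial expectation N * nu * window


def count_mutation_window(
    params: ModelParams,
    window_generations: int,
    *,
    replicates: int = 30,
    seed: int = 0,
    init_mode: str = "single",
) -> MutationWindowStats:
    """Count speciation events per window of ``window_generations``.

    Each replicate simulates an independent community for the whole window
    and totals the new-species founding events; the binomial expectation is
    ``N * nu * window``.
    """
    if window_generations < 1:
        raise InvalidParameterError("window_generations must be >= 1")
    counts = []
    for r in range(replicates):
        res = dynamics.run(
            params, window_generations, burn_in=0,
            sampling_interval=max(1, window_generations // 100),
            init_mode=init_mode, rng=_rep_rng(seed, 0, r),
            record_abundances=False,
        )
        counts.append(res.trajectory.total_mutations)
    arr = np.asarray(counts, dtype=float)
    return MutationWindowStats(
        mean=float(arr.mean()),
        variance=float(arr.var(ddof=1)) if arr.size > 1 else 0.0,
        counts=tuple(int(c) for c in counts),
        expected=params.community_size * params.mutation_prob * window_generations,
    )
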