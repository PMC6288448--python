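"""Replicated scenarios, mechanism knockouts and parameter sweeps.

A *scenario* is a set of enabled mechanisms plus a simulation configuration,
run over several replicates.  Each replicate draws fresh compatibility
matrices for **all four** mechanisms from seed ``base_seed + k``, so two
scenarios with the same base seed share matrices replicate-for-replicate and
knockout comparisons are paired: the only difference is which mechanisms are
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .compatibility import (
    DEFAULT_P_TRANSFORMABLE,
    DEFAULT_SPC_FRACTION,
    build_phage_host_network,
    conjugation_alpha,
    transduction_alpha,
    transformation_alpha,
    vesicle_alpha,
)
from .dynamics import (
    MINUTES_PER_DAY,
    MINUTES_PER_YEAR,
    MechanismSpec,
    SimulationConfig,
    Trajectory,
    run_simulation,
)
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ALL_MECHANISMS",
    "DEFAULT_GAMMAS",
    "ScenarioSpec",
    "ReplicateResult",
    "ComparisonReport",
    "draw_mechanism_set",
    "run_scenario",
    "knockout_panel",
    "conjugative_ratio",
    "compare_scenarios",
    "parameter_sweep",
    "default_config",
]

ALL_MECHANISMS = ("conjugation", "transformation", "transduction", "vesicle")

#: Per-donor maximal rate constants from the calibration pipeline, rounded to
#: the nearest power of ten (mL cell^-1 min^-1).
DEFAULT_GAMMAS: Mapping[str, float] = {
    "conjugation": 1e-8,
    "transformation": 1e-16,
    "transduction": 1e-15,
    "vesicle": 1e-22,
}

#: Scenario horizons: conjugative plasmids spread in weeks, non-conjugative
#: ones in years, so the two scenario families use different time windows.
CONJUGATIVE_HORIZON_MIN = 60.0 * MINUTES_PER_DAY
NONCONJUGATIVE_HORIZON_MIN = 7.0 * MINUTES_PER_YEAR


def default_config(enabled: Sequence[str] = ALL_MECHANISMS) -> SimulationConfig:
    """Study-condition configuration, with a horizon matched to the scenario."""
    horizon = (
        CONJUGATIVE_HORIZON_MIN
        if "conjugation" in enabled
        else NONCONJUGATIVE_HORIZON_MIN
    )
    return SimulationConfig(total_time=horizon)


@dataclass
class ScenarioSpec:
    """One replicated experiment: enabled mechanisms + config + seeds."""

    name: str
    enabled: tuple[str, ...]
    config: SimulationConfig
    base_seed: int = 0
    n_replicates: int = 5
    gammas: Mapping[str, float] | None = None
    spc_fraction: float = DEFAULT_SPC_FRACTION
    p_transformable: float = DEFAULT_P_TRANSFORMABLE
    n_modules: int | None = None
    vesicle_participation: float = 1.0
    explicit_seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.enabled) - set(ALL_MECHANISMS)
        if unknown:
            raise ConfigurationError(f"unknown mechanisms: {sorted(unknown)}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.explicit_seeds is not None and len(set(self.explicit_seeds)) != len(
            self.explicit_seeds
        ):
            raise ConfigurationError("replicate seeds must be distinct")

    @property
    def seeds(self) -> tuple[int, ...]:
        if self.explicit_seeds is not None:
            return self.explicit_seeds
        return tuple(self.base_seed + k for k in range(self.n_replicates))


@dataclass
class ReplicateResult:
    """Full-spread summary over a scenario's replicates.

    Mean and sample standard deviation are computed over the replicates that
    reached full spread; ``fraction_reached`` reports how many did.
    """

    scenario: str
    times_min: tuple[float | None, ...]
    seeds: tuple[int, ...]
    mean_min: float | None
    sd_min: float | None
    fraction_reached: float

    @property
    def n_replicates(self) -> int:
        return len(self.times_min)

    @property
    def n_reached(self) -> int:
        return sum(t is not None for t in self.times_min)

    @property
    def mean_days(self) -> float | None:
        return None if self.mean_min is None else self.mean_min / MINUTES_PER_DAY

    @property
    def mean_years(self) -> float | None:
        return None if self.mean_min is None else self.mean_min / MINUTES_PER_YEAR


@dataclass(frozen=True)
class ComparisonReport:
    """Two-scenario comparison: difference of means and pooled t-test."""

    mean_difference_min: float
    t_statistic: float
    p_value: float
    sd_intervals_overlap: bool


def draw_mechanism_set(
    n: int,
    seed: int,
    enabled: Sequence[str] = ALL_MECHANISMS,
    gammas: Mapping[str, float] | None = None,
    spc_fraction: float = DEFAULT_SPC_FRACTION,
    p_transformable: float = DEFAULT_P_TRANSFORMABLE,
    n_modules: int | None = None,
    vesicle_participation: float = 1.0,
) -> list[MechanismSpec]:
    """Draw all four compatibility matrices from one seed.

    Matrices are always drawn for all four mechanisms in a fixed order
    (conjugation, transformation, phage-host network, vesicle) so that
    scenarios sharing a seed share matrices regardless of which mechanisms
    are enabled.  ``n_modules`` defaults to ``max(1, round(0.13 n))`` — 13
    modules at the standard community size of 100.
    """
    resolved_gammas = dict(DEFAULT_GAMMAS)
    if gammas:
        unknown = set(gammas) - set(ALL_MECHANISMS)
        if unknown:
            raise ConfigurationError(f"unknown gamma keys: {sorted(unknown)}")
        resolved_gammas.update(gammas)
    if n_modules is None:
        n_modules = max(1, round(0.13 * n))
    rng = np.random.default_rng(seed)
    alphas = {
        "conjugation": conjugation_alpha(n, spc_fraction=spc_fraction, rng_seed=rng),
        "transformation": transformation_alpha(
            n, p_transformable=p_transformable, rng_seed=rng
        ),
        "transduction": transduction_alpha(
            build_phage_host_network(n, n_modules, rng_seed=rng)
        ),
        "vesicle": vesicle_alpha(n, rng_seed=rng, participation=vesicle_participation),
    }
    enabled_set = set(enabled)
    return [
        MechanismSpec(
            name=name,
            gamma=resolved_gammas[name],
            alpha=alphas[name],
            enabled=name in enabled_set,
        )
        for name in ALL_MECHANISMS
    ]


def _summarize(
    scenario: str, seeds: Sequence[int], times: Sequence[float | None]
) -> ReplicateResult:
    reached = [t for t in times if t is not None]
    mean = float(np.mean(reached)) if reached else None
    sd = float(np.std(reached, ddof=1)) if len(reached) >= 2 else None
    return ReplicateResult(
        scenario=scenario,
        times_min=tuple(times),
        seeds=tuple(seeds),
        mean_min=mean,
        sd_min=sd,
        fraction_reached=len(reached) / len(times),
    )


def run_scenario(
    spec: ScenarioSpec, keep_trajectories: bool = False
) -> ReplicateResult | tuple[ReplicateResult, list[Trajectory]]:
    """Run all replicates of a scenario and summarize full-spread times."""
    times: list[float | None] = []
    trajectories: list[Trajectory] = []
    for seed in spec.seeds:
        mechanisms = draw_mechanism_set(
            spec.config.n_species,
            seed,
            enabled=spec.enabled,
            gammas=spec.gammas,
            spc_fraction=spec.spc_fraction,
            p_transformable=spec.p_transformable,
            n_modules=spec.n_modules,
            vesicle_participation=spec.vesicle_participation,
        )
        traj = run_simulation(replace(spec.config, rng_seed=seed), mechanisms)
        times.append(traj.full_spread_time)
        if keep_trajectories:
            trajectories.append(traj)
    result = _summarize(spec.name, spec.seeds, times)
    return (result, trajectories) if keep_trajectories else result


def knockout_panel(base_spec: ScenarioSpec) -> dict[str, ReplicateResult]:
    """Non-conjugative knockout panel with matched seeds.

    Runs the three-mechanism scenario (transformation + transduction +
    vesicle) and its three single-knockout variants, all from the base spec's
    seeds so matrices are shared across panels.
    """
    three = ("transformation", "transduction", "vesicle")
    panels = {
        "no_conjugation": three,
        "minus_transformation": ("transduction", "vesicle"),
        "minus_transduction": ("transformation", "vesicle"),
        "minus_vesicle": ("transformation", "transduction"),
    }
    out: dict[str, ReplicateResult] = {}
    for name, enabled in panels.items():
        spec = replace(base_spec, name=name, enabled=enabled)
        out[name] = run_scenario(spec)
    return out


def conjugative_ratio(
    spec_conjugative: ScenarioSpec, spec_nonconjugative: ScenarioSpec
) -> float:
    """Ratio of mean full-spread times, non-conjugative over conjugative."""
    res_c = run_scenario(spec_conjugative)
    res_nc = run_scenario(spec_nonconjugative)
    if res_c.mean_min is None:
        raise InvalidInputError(
            "conjugative scenario reached full spread in no replicate"
        )
    if res_nc.mean_min is None:
        raise InvalidInputError(
            "non-conjugative scenario reached full spread in no replicate"
        )
    return res_nc.mean_min / res_c.mean_min


def compare_scenarios(
    result_a: ReplicateResult, result_b: ReplicateResult
) -> ComparisonReport:
    """Pooled-variance two-tailed unpaired t-test on full-spread times.

    Identical means are reported as t=0, p=1 (the pooled statistic is 0/0
    for two identical zero-variance samples).
    """
    a = [t for t in result_a.times_min if t is not None]
    b = [t for t in result_b.times_min if t is not None]
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("need >= 2 successful replicates per scenario")
    diff = float(np.mean(a) - np.mean(b))
    if diff == 0.0:
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p_value = float(t_stat), float(p_value)
    overlap = True
    if result_a.sd_min is not None and result_b.sd_min is not None:
        lo_a, hi_a = result_a.mean_min - result_a.sd_min, result_a.mean_min + result_a.sd_min
        lo_b, hi_b = result_b.mean_min - result_b.sd_min, result_b.mean_min + result_b.sd_min
        overlap = lo_a <= hi_b and lo_b <= hi_a
    return ComparisonReport(
        mean_difference_min=diff,
        t_statistic=t_stat,
        p_value=p_value,
        sd_intervals_overlap=overlap,
    )


_SWEEPABLE_GAMMAS = {
    "gamma_conjugation": "conjugation",
    "gamma_transformation": "transformation",
    "gamma_transduction": "transduction",
    "gamma_vesicle": "vesicle",
}


def parameter_sweep(
    base_spec: ScenarioSpec,
    parameter: str,
    multipliers: Sequence[float],
) -> list[dict]:
    """Re-run a scenario with one parameter scaled by each multiplier.

    ``parameter`` is one of the four ``gamma_*`` names, ``competence_rate``
    (which scales the transformation rate constant proportionally), or
    ``vesicle_participation`` (multiplier applied to the base participation
    fraction, capped at 1; zero participation disables vesicle exchange).
    Replicate seeds are reused at every multiplier, so rows differ only
    through the swept parameter.
    """
    known = set(_SWEEPABLE_GAMMAS) | {"competence_rate", "vesicle_participation"}
    if parameter not in known:
        raise ConfigurationError(
            f"unknown sweep parameter {parameter!r}; expected one of {sorted(known)}"
        )
    rows: list[dict] = []
    for mult in multipliers:
        if mult < 0 or (mult == 0 and parameter != "vesicle_participation"):
            raise InvalidInputError("multipliers must be positive")
        spec = replace(base_spec, name=f"{base_spec.name}:{parameter}x{mult:g}")
        gammas = dict(base_spec.gammas or DEFAULT_GAMMAS)
        if parameter in _SWEEPABLE_GAMMAS:
            mech = _SWEEPABLE_GAMMAS[parameter]
            gammas[mech] = gammas.get(mech, DEFAULT_GAMMAS[mech]) * mult
            spec = replace(spec, gammas=gammas)
        elif parameter == "competence_rate":
            # gamma_transformation is linear in the competence rate.
            gammas["transformation"] = (
                gammas.get("transformation", DEFAULT_GAMMAS["transformation"]) * mult
            )
            spec = replace(spec, gammas=gammas)
        else:
            participation = min(1.0, base_spec.vesicle_participation * mult)
            spec = replace(spec, vesicle_participation=participation)
        result = run_scenario(spec)
        rows.append(
            {
                "parameter": parameter,
                "multiplier": float(mult),
                "scenario": spec.name,
                "mean_min": result.mean_min,
                "sd_min": result.sd_min,
                "fraction_reached": result.fraction_reached,
                "times_min": result.times_min,
            }
        )
    return rows
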