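"""Community dynamics: horizontal transfer plus within-species selection.

The community holds N species at fixed, equal total densities.  Each timestep
applies two updates in order:

1. **Horizontal transfer** (forward Euler on the mass-action law): the
   plasmid-positive gain of recipient species ``i`` is

       dB+_i = dt * B-_i * sum_mech gamma_mech * sum_j alpha_mech(j, i) * B+_j

   with the matching loss from ``B-_i``, so per-species totals are conserved.
2. **Vertical spread** (exact logistic/replicator step): the plasmid fraction
   of each species advances as ``f' = f e^{m dt} / (1 + f (e^{m dt} - 1))``
   where ``m`` is the Malthusian fitness advantage of carriers.  The step is
   the exact solution of the selection dynamics, not an Euler approximation,
   and leaves species totals untouched.

Time is in minutes throughout; densities are cells/mL; rate constants are
mL cell^-1 min^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .compatibility import CompatibilityMatrix
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "CommunityState",
    "MechanismSpec",
    "SimulationConfig",
    "Trajectory",
    "ConvergenceReport",
    "hgt_step",
    "growth_step",
    "run_simulation",
    "full_spread_time",
    "convergence_check",
    "MINUTES_PER_DAY",
    "MINUTES_PER_HOUR",
    "MINUTES_PER_YEAR",
    "FULL_SPREAD_THRESHOLD",
]

logger = logging.getLogger(__name__)

MINUTES_PER_HOUR = 60.0
MINUTES_PER_DAY = 1440.0
MINUTES_PER_YEAR = 365.0 * MINUTES_PER_DAY

#: A species counts as converted when >= 99% of its cells carry the plasmid.
FULL_SPREAD_THRESHOLD = 0.99

_FITNESS_UNIT_MINUTES = {
    "per-minute": 1.0,
    "per-hour": MINUTES_PER_HOUR,
    "per-day": MINUTES_PER_DAY,
}


@dataclass
class CommunityState:
    """Per-species plasmid-positive and plasmid-negative densities (cells/mL)."""

    plasmid_pos: np.ndarray
    plasmid_neg: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.plasmid_pos = np.asarray(self.plasmid_pos, dtype=float)
        self.plasmid_neg = np.asarray(self.plasmid_neg, dtype=float)
        if self.plasmid_pos.shape != self.plasmid_neg.shape or self.plasmid_pos.ndim != 1:
            raise InvalidInputError("plasmid_pos and plasmid_neg must be equal-length vectors")
        if (self.plasmid_pos < 0).any() or (self.plasmid_neg < 0).any():
            raise InvalidInputError("densities must be non-negative")

    @property
    def n_species(self) -> int:
        return self.plasmid_pos.size

    @property
    def totals(self) -> np.ndarray:
        return self.plasmid_pos + self.plasmid_neg

    @property
    def fractions(self) -> np.ndarray:
        totals = self.totals
        out = np.zeros_like(totals)
        np.divide(self.plasmid_pos, totals, out=out, where=totals > 0)
        return out


@dataclass
class MechanismSpec:
    """One transfer mechanism: maximal rate constant, compatibility matrix, toggle."""

    name: str
    gamma: float
    alpha: CompatibilityMatrix | None = None
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise InvalidInputError(f"gamma for {self.name!r} must be non-negative")


@dataclass
class SimulationConfig:
    """Simulation settings.

    ``fitness`` is interpreted in ``fitness_input_unit`` (default per day) and
    converted to per-minute internally.  The plasmid starts in
    ``initial_species`` at fraction ``initial_fraction``; every species sits
    at ``per_species_density`` cells/mL for the whole run.
    """

    n_species: int = 100
    total_time: float = 60.0 * MINUTES_PER_DAY  # minutes
    n_steps: int = 10_000
    fitness: float = 0.02
    fitness_input_unit: str = "per-day"
    per_species_density: float = 1e4
    initial_species: int = 0
    initial_fraction: float = 1e-4
    record_every: int = 1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.total_time <= 0:
            raise ConfigurationError("total_time must be positive")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.fitness < 0:
            raise ConfigurationError("fitness must be non-negative")
        if self.fitness_input_unit not in _FITNESS_UNIT_MINUTES:
            raise ConfigurationError(
                f"fitness_input_unit must be one of {sorted(_FITNESS_UNIT_MINUTES)}"
            )
        if self.per_species_density <= 0:
            raise ConfigurationError("per_species_density must be positive")
        if not 0 <= self.initial_species < self.n_species:
            raise ConfigurationError("initial_species out of range")
        if not 0.0 < self.initial_fraction <= 1.0:
            raise ConfigurationError("initial_fraction must be in (0, 1]")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")

    @property
    def fitness_per_min(self) -> float:
        return self.fitness / _FITNESS_UNIT_MINUTES[self.fitness_input_unit]

    @property
    def dt(self) -> float:
        return self.total_time / self.n_steps


@dataclass
class Trajectory:
    """Recorded plasmid-fraction time series of one simulation run."""

    times: np.ndarray  # minutes, shape (n_records,)
    fractions: np.ndarray  # shape (n_records, n_species)
    full_spread_time: float | None
    config: SimulationConfig
    enabled_mechanisms: tuple[str, ...] = ()
    cap_events: int = 0

    @property
    def n_records(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ConvergenceReport:
    n_steps_list: tuple[int, ...]
    full_spread_times: tuple[float | None, ...]
    relative_changes: tuple[float | None, ...]
    cap_events: tuple[int, ...]
    converged: bool


def _combined_transfer_matrix(
    mechanisms: list[MechanismSpec] | tuple[MechanismSpec, ...], n: int
) -> np.ndarray:
    """Recipient-major effective transfer matrix sum_mech gamma * alpha^T."""
    combined = np.zeros((n, n))
    for mech in mechanisms:
        if not mech.enabled:
            continue
        if mech.alpha is None:
            raise ConfigurationError(f"enabled mechanism {mech.name!r} has no matrix")
        if mech.alpha.n != n:
            raise ConfigurationError(
                f"matrix for {mech.name!r} is {mech.alpha.n}x{mech.alpha.n}, expected {n}x{n}"
            )
        combined += mech.gamma * mech.alpha.entries.T
    return np.ascontiguousarray(combined)


def _hgt_delta(
    plasmid_pos: np.ndarray,
    plasmid_neg: np.ndarray,
    transfer_t: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, bool]:
    """Plasmid-positive gain per recipient, capped at the recipient pool."""
    delta = dt * plasmid_neg * (transfer_t @ plasmid_pos)
    capped = bool((delta > plasmid_neg).any())
    if capped:
        delta = np.minimum(delta, plasmid_neg)
    return delta, capped


def hgt_step(
    state: CommunityState,
    mechanisms: list[MechanismSpec] | tuple[MechanismSpec, ...],
    dt: float,
) -> CommunityState:
    """One Euler step of mass-action horizontal transfer across all mechanisms.

    The per-recipient gain is capped at the available plasmid-free pool; a
    binding cap is logged as a warning since it signals a too-coarse timestep.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    transfer_t = _combined_transfer_matrix(mechanisms, state.n_species)
    delta, capped = _hgt_delta(state.plasmid_pos, state.plasmid_neg, transfer_t, dt)
    if capped:
        logger.warning(
            "hgt_step cap engaged at t=%.3g min: dt=%.3g is too coarse", state.time, dt
        )
    return CommunityState(
        plasmid_pos=state.plasmid_pos + delta,
        plasmid_neg=state.plasmid_neg - delta,
        time=state.time + dt,
    )


def _growth_update(
    plasmid_pos: np.ndarray, plasmid_neg: np.ndarray, growth_factor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact logistic advance of each species' plasmid fraction."""
    totals = plasmid_pos + plasmid_neg
    f = np.zeros_like(totals)
    np.divide(plasmid_pos, totals, out=f, where=totals > 0)
    f_new = f * growth_factor / (1.0 + f * (growth_factor - 1.0))
    pos = totals * f_new
    return pos, totals - pos


def growth_step(
    state: CommunityState, fitness_per_min: float, dt: float
) -> CommunityState:
    """Advance within-species selection by ``dt`` minutes (exact update)."""
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if fitness_per_min < 0:
        raise InvalidInputError("fitness must be non-negative")
    if fitness_per_min == 0:
        return replace(state, time=state.time + dt)
    growth_factor = float(np.exp(fitness_per_min * dt))
    pos, neg = _growth_update(state.plasmid_pos, state.plasmid_neg, growth_factor)
    return CommunityState(plasmid_pos=pos, plasmid_neg=neg, time=state.time + dt)


def run_simulation(
    config: SimulationConfig,
    mechanisms: list[MechanismSpec] | tuple[MechanismSpec, ...],
    threshold: float = FULL_SPREAD_THRESHOLD,
) -> Trajectory:
    """Simulate plasmid spread and record per-species fractions.

    Each of ``config.n_steps`` iterations applies the horizontal-transfer
    Euler step and then the exact selection step, with
    ``dt = total_time / n_steps``.  Fractions are recorded at t=0, every
    ``record_every`` steps, and at the final step.  The run is fully
    deterministic given the configuration and matrices; all randomness lives
    in matrix generation.
    """
    n = config.n_species
    transfer_t = _combined_transfer_matrix(mechanisms, n)
    enabled = tuple(m.name for m in mechanisms if m.enabled)
    dt = config.dt
    growth_factor = float(np.exp(config.fitness_per_min * dt))
    apply_growth = config.fitness_per_min > 0

    pos = np.zeros(n)
    pos[config.initial_species] = config.per_species_density * config.initial_fraction
    neg = np.full(n, config.per_species_density) - pos

    record_steps = list(range(0, config.n_steps + 1, config.record_every))
    if record_steps[-1] != config.n_steps:
        record_steps.append(config.n_steps)
    record_at = np.zeros(config.n_steps + 1, dtype=bool)
    record_at[record_steps] = True

    times = np.empty(len(record_steps))
    fractions = np.empty((len(record_steps), n))
    rec = 0
    cap_events = 0

    def record(step: int) -> None:
        nonlocal rec
        times[rec] = step * dt
        totals = pos + neg
        fractions[rec] = pos / totals
        rec += 1

    record(0)
    for step in range(1, config.n_steps + 1):
        delta, capped = _hgt_delta(pos, neg, transfer_t, dt)
        if capped:
            if cap_events == 0:
                logger.warning(
                    "transfer cap engaged at step %d (dt=%.3g min too coarse)", step, dt
                )
            cap_events += 1
        pos = pos + delta
        neg = neg - delta
        if apply_growth:
            pos, neg = _growth_update(pos, neg, growth_factor)
        if record_at[step]:
            record(step)

    traj = Trajectory(
        times=times,
        fractions=fractions,
        full_spread_time=None,
        config=config,
        enabled_mechanisms=enabled,
        cap_events=cap_events,
    )
    traj.full_spread_time = full_spread_time(traj, threshold)
    return traj


def full_spread_time(
    trajectory: Trajectory, threshold: float = FULL_SPREAD_THRESHOLD
) -> float | None:
    """First recorded time every species' plasmid fraction is >= ``threshold``.

    Returns ``None`` when full spread is never reached within the recorded
    horizon.  Detection is at recording resolution; no interpolation.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidInputError("threshold must be in [0, 1]")
    reached = trajectory.fractions.min(axis=1) >= threshold
    if not reached.any():
        return None
    return float(trajectory.times[int(np.argmax(reached))])


def convergence_check(
    config: SimulationConfig,
    mechanisms: list[MechanismSpec] | tuple[MechanismSpec, ...],
    refinements: int = 3,
    tolerance: float = 0.01,
) -> ConvergenceReport:
    """Timestep refinement study on the full-spread time.

    Reruns the simulation with ``n_steps`` doubled at each refinement and
    reports the relative change of the full-spread time between successive
    grids.  Non-convergence is flagged when the final refinement still moves
    the result by more than ``tolerance`` (or full spread flips between
    reached and not reached).
    """
    if refinements < 1:
        raise InvalidInputError("refinements must be >= 1")
    n_steps_list: list[int] = []
    spreads: list[float | None] = []
    caps: list[int] = []
    changes: list[float | None] = []
    for level in range(refinements + 1):
        cfg = replace(config, n_steps=config.n_steps * 2**level)
        traj = run_simulation(cfg, mechanisms)
        n_steps_list.append(cfg.n_steps)
        spreads.append(traj.full_spread_time)
        caps.append(traj.cap_events)
        if level == 0:
            continue
        prev, cur = spreads[-2], spreads[-1]
        if prev is None or cur is None:
            changes.append(None)
        else:
            changes.append(abs(cur - prev) / max(abs(cur), 1e-300))
    last = changes[-1]
    converged = last is not None and last <= tolerance
    return ConvergenceReport(
        n_steps_list=tuple(n_steps_list),
        full_spread_times=tuple(spreads),
        relative_changes=tuple(changes),
        cap_events=tuple(caps),
        converged=converged,
    )
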