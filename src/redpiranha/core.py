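"""Continuous Red Piranha Optimization engine.

The optimizer runs three sequential phases over a fixed iteration budget:

1. **Searching** -- randomly chosen scouts lead clusters; members jump
   relative to their scout with coefficients that keep step magnitudes
   outside [-1, 1] (exploration). A greedy sweep at the end of the phase
   returns each agent to the best position it visited.
2. **Encircling** -- the k fittest agents define a virtual prey (their
   componentwise mean); agents spiral toward it on a logarithmic spiral.
   Greedy selection again closes the phase.
3. **Attacking** -- agents contract toward the prey with coefficients
   drawn from a shrinking interval; each step is accepted only if it
   improves the agent (per-step greedy). Optional pairwise collision
   checks at scheduled checkpoints relocate the weaker of any two agents
   that come closer than twice the safety-shield width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .rng import RandomStream

__all__ = [
    "Sense",
    "ObjectiveSpec",
    "Agent",
    "PhaseSchedule",
    "RPOConfig",
    "IterationRecord",
    "RunResult",
    "ConfigurationError",
    "ObjectiveEvaluationError",
    "partition_iterations",
    "scout_count",
    "select_scouts",
    "sample_search_coefficients",
    "searching_update",
    "greedy_select_phase_best",
    "compute_prey_position",
    "spiral_parameter",
    "encircling_update",
    "attack_coefficient_schedule",
    "attacking_update",
    "cartesian_distance",
    "checkpoint_iterations",
    "detect_and_resolve_collisions",
    "run_rpo",
]


class ConfigurationError(ValueError):
    """Invalid optimizer configuration."""


class ObjectiveEvaluationError(RuntimeError):
    """The objective returned a non-finite value."""


class Sense(str, Enum):
    MINIMIZE = "minimize"
    MAXIMIZE = "maximize"


def _is_better(a: float, b: float, sense: Sense) -> bool:
    return a < b if sense is Sense.MINIMIZE else a > b


def _best_index(values: Sequence[float], sense: Sense) -> int:
    arr = np.asarray(values, dtype=float)
    # argmin/argmax take the first occurrence, which implements the
    # lower-index tie break.
    return int(np.argmin(arr) if sense is Sense.MINIMIZE else np.argmax(arr))


def _ranked_indices(values: Sequence[float], sense: Sense) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    order = np.argsort(arr, kind="stable")
    return order if sense is Sense.MINIMIZE else order[::-1]


@dataclass(frozen=True)
class ObjectiveSpec:
    """A box-bounded scalar objective.

    ``objective`` must be a pure function of a length-``dimension``
    vector; ``sense`` states whether lower or higher values are better.
    """

    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]
    sense: Sense = Sense.MINIMIZE

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if self.dimension < 1:
            raise ConfigurationError("dimension must be a positive integer")
        if lower.shape != (self.dimension,) or upper.shape != (self.dimension,):
            raise ConfigurationError(
                "bounds must be vectors of length equal to the dimension"
            )
        if not np.all(lower < upper):
            raise ConfigurationError("every lower bound must be below its upper bound")
        if not isinstance(self.sense, Sense):
            object.__setattr__(self, "sense", Sense(self.sense))

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def evaluate(self, x: np.ndarray, *, context: str = "") -> float:
        value = float(self.objective(np.asarray(x, dtype=float)))
        if not math.isfinite(value):
            where = f" ({context})" if context else ""
            raise ObjectiveEvaluationError(
                f"objective returned non-finite value {value!r} at {np.asarray(x)}{where}"
            )
        return value


@dataclass
class Agent:
    """A candidate solution with its within-phase position history."""

    position: np.ndarray
    fitness: float
    history: list[tuple[np.ndarray, float]] = field(default_factory=list)
    is_scout: bool = False
    cluster_id: int | None = None

    def record(self) -> None:
        self.history.append((self.position.copy(), self.fitness))


@dataclass(frozen=True)
class PhaseSchedule:
    """The split of a total iteration budget across the three phases."""

    z: int
    z_srch: int
    z_enc: int
    z_att: int

    def __post_init__(self):
        if self.z_srch + self.z_enc + self.z_att != self.z:
            raise ConfigurationError("phase iteration counts must sum to the total")


@dataclass
class RPOConfig:
    """Run parameters for the continuous optimizer.

    ``lam`` (the scout count) is derived as ``ceil(n / xi)`` when left
    unset. ``k`` defaults to ``min(3, n)``.
    """

    n: int = 10
    z: int = 30
    xi: float = 4.0
    lam: int | None = None
    k: int | None = None
    b: float = 1.0
    delta: float = 0.0
    n_ck: int = 0
    collision_enabled: bool = False
    seed: int = 0
    early_stop_enabled: bool = False
    early_stop_tol: float = 1e-7

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("need at least one agent")
        if not (2 <= self.xi <= self.n):
            raise ConfigurationError("the scaling factor must lie in [2, n]")
        if self.lam is None:
            self.lam = scout_count(self.n, self.xi)
        if not (1 <= self.lam <= self.n):
            raise ConfigurationError("scout count must lie in [1, n]")
        if self.k is None:
            self.k = min(3, self.n)
        if not (1 <= self.k <= self.n):
            raise ConfigurationError("leader count k must lie in [1, n]")
        if self.delta < 0:
            raise ConfigurationError("safety-shield width must be non-negative")
        if self.n_ck < 0:
            raise ConfigurationError("checkpoint count must be non-negative")


@dataclass
class IterationRecord:
    phase: str
    iteration: int
    positions: np.ndarray
    fitnesses: np.ndarray
    prey: np.ndarray | None = None


@dataclass
class RunResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[IterationRecord]
    schedule: PhaseSchedule
    realized_iterations: int


# ---------------------------------------------------------------------------
# phase scheduling


def partition_iterations(z: int) -> PhaseSchedule:
    """Split ``z`` iterations uniformly over the three phases.

    Searching and encircling each get ``floor(z / 3)`` iterations; the
    attacking phase absorbs the remainder.
    """
    if z < 3:
        raise ConfigurationError("need at least 3 iterations, one per phase")
    third = z // 3
    return PhaseSchedule(z=z, z_srch=third, z_enc=third, z_att=z - 2 * third)


def scout_count(n: int, xi: float) -> int:
    """Number of leading scouts: ``ceil(n / xi)``."""
    if not (2 <= xi <= n):
        raise ConfigurationError("the scaling factor must lie in [2, n]")
    return math.ceil(n / xi)


def select_scouts(
    n: int, lam: int, rng: RandomStream
) -> tuple[list[int], dict[int, int]]:
    """Pick ``lam`` random scouts and split the rest into ``lam`` clusters.

    Returns the scout indices (cluster ``c`` is led by the ``c``-th scout)
    and a map from each non-scout agent index to its cluster. Every
    cluster holds ``ceil((n - lam) / lam)`` members except possibly the
    last, which may hold fewer (including zero).
    """
    if not (1 <= lam <= n):
        raise ConfigurationError("scout count must lie in [1, n]")
    order = rng.permutation(n)
    scouts = [int(i) for i in order[:lam]]
    members = [int(i) for i in order[lam:]]
    per_cluster = math.ceil((n - lam) / lam) if n > lam else 0
    clusters: dict[int, int] = {}
    for pos, agent in enumerate(members):
        clusters[agent] = pos // per_cluster
    return scouts, clusters


# ---------------------------------------------------------------------------
# searching phase


def sample_search_coefficients(rng: RandomStream) -> tuple[float, float]:
    """Draw the exploration step coefficients ``(A, C)``.

    ``A = r1 * (-2 + r2) + (1 - r1) * (1 + r3)`` with ``r1`` a fair bit,
    ``r2`` uniform on [0, 1) and ``r3`` uniform on (0, 1], so the support
    of ``A`` is [-2, -1) union (1, 2] -- steps never contract.
    ``C = 2 * r4`` with ``r4`` uniform on [0, 1]. One scalar pair is drawn
    per agent per iteration and broadcast over components.
    """
    r1 = rng.r1()
    r2 = rng.r2()
    r3 = rng.r3()
    a = r1 * (-2.0 + r2) + (1 - r1) * (1.0 + r3)
    c = 2.0 * rng.r4()
    return a, c


def searching_update(
    agent: Agent,
    scout_position: np.ndarray,
    a: float,
    c: float,
    spec: ObjectiveSpec,
    *,
    context: str = "searching",
) -> Agent:
    """Move ``agent`` relative to its cluster scout (in place).

    ``D = |C * X_sct - X|`` componentwise, then ``X' = X_sct - A * D``
    clamped to the box; fitness is recomputed and the new state appended
    to the agent's history.
    """
    scout_position = np.asarray(scout_position, dtype=float)
    d = np.abs(c * scout_position - agent.position)
    new_position = spec.clamp(scout_position - a * d)
    agent.position = new_position
    agent.fitness = spec.evaluate(new_position, context=context)
    agent.record()
    return agent


def greedy_select_phase_best(agent: Agent, sense: Sense) -> Agent:
    """Return the agent to the best position in its history; clear it."""
    if not agent.history:
        raise ValueError("greedy selection requires a non-empty history")
    idx = _best_index([f for _, f in agent.history], sense)
    position, fitness = agent.history[idx]
    agent.position = position.copy()
    agent.fitness = fitness
    agent.history = []
    return agent


# ---------------------------------------------------------------------------
# encircling phase


def compute_prey_position(
    positions: Sequence[np.ndarray], fitnesses: Sequence[float], k: int, sense: Sense
) -> np.ndarray:
    """Componentwise mean of the ``k`` best positions (ties: lower index)."""
    n = len(positions)
    if not (1 <= k <= n):
        raise ConfigurationError("leader count k must lie in [1, n]")
    order = _ranked_indices(fitnesses, sense)[:k]
    stacked = np.stack([np.asarray(positions[i], dtype=float) for i in order])
    return stacked.mean(axis=0)


def spiral_parameter(t: int, z_enc: int) -> float:
    """Spiral phase ``l = 1 - 2t / Z_enc``; decreases from near 1 to -1."""
    if z_enc < 1:
        raise ConfigurationError("the encircling phase has no iterations")
    return 1.0 - 2.0 * t / z_enc


def encircling_update(
    agent: Agent,
    prey: np.ndarray,
    t: int,
    z_enc: int,
    b: float,
    spec: ObjectiveSpec,
    *,
    context: str = "encircling",
) -> Agent:
    """Spiral ``agent`` around the prey (in place).

    ``D = |X_prey - X|``, then ``X' = D * e^(b*l) * cos(2*pi*l) + X_prey``
    with ``l`` from :func:`spiral_parameter`, clamped to the box.
    """
    prey = np.asarray(prey, dtype=float)
    d = np.abs(prey - agent.position)
    l = spiral_parameter(t, z_enc)
    new_position = spec.clamp(d * math.exp(b * l) * math.cos(2.0 * math.pi * l) + prey)
    agent.position = new_position
    agent.fitness = spec.evaluate(new_position, context=context)
    agent.record()
    return agent


# ---------------------------------------------------------------------------
# attacking phase


def attack_coefficient_schedule(t: int, z_att: int) -> float:
    """Contraction bound ``a = 2 - 2t / Z_att``; reaches 0 at the last step."""
    if z_att < 1:
        raise ConfigurationError("the attacking phase has no iterations")
    return 2.0 - 2.0 * t / z_att


def sample_attack_coefficients(a: float, rng: RandomStream) -> tuple[float, float]:
    """Draw ``A`` uniformly from [-a, a] (via ``A = 2*a*r1 - a``) and ``C = 2*r2``."""
    big_a = 2.0 * a * rng.uniform() - a
    c = 2.0 * rng.uniform()
    return big_a, c


def attacking_update(
    agent: Agent,
    prey: np.ndarray,
    a: float,
    c: float,
    spec: ObjectiveSpec,
    sense: Sense,
    *,
    context: str = "attacking",
) -> Agent:
    """Contract ``agent`` toward the prey, keeping the better position.

    ``D = |C * X_prey - X|``; the candidate ``X_prey - A * D`` (clamped)
    replaces the current position only if it improves the objective.
    """
    prey = np.asarray(prey, dtype=float)
    d = np.abs(c * prey - agent.position)
    candidate = spec.clamp(prey - a * d)
    candidate_fitness = spec.evaluate(candidate, context=context)
    if _is_better(candidate_fitness, agent.fitness, sense):
        agent.position = candidate
        agent.fitness = candidate_fitness
    agent.record()
    return agent


def cartesian_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float(np.linalg.norm(x - y))


def checkpoint_iterations(z_att: int, n_ck: int) -> set[int]:
    """Attacking-phase iterations at which collisions are checked.

    The i-th checkpoint falls after iteration ``floor(z_att / n_ck) * i - 1``;
    indices outside [1, z_att] are dropped. Empty when ``n_ck == 0``.
    """
    if n_ck < 0:
        raise ConfigurationError("checkpoint count must be non-negative")
    if n_ck == 0:
        return set()
    stride = z_att // n_ck
    return {stride * i - 1 for i in range(1, n_ck + 1) if 1 <= stride * i - 1 <= z_att}


def detect_and_resolve_collisions(
    agents: list[Agent],
    delta: float,
    rng: RandomStream,
    spec: ObjectiveSpec,
    sense: Sense,
) -> list[Agent]:
    """Relocate the weaker of every pair closer than ``2 * delta``.

    All pairs are tested against the pre-resolution positions in a single
    sweep; each losing agent (worse fitness; ties keep the lower index)
    is moved once to a fresh uniform position in the box.
    """
    if delta < 0:
        raise ConfigurationError("safety-shield width must be non-negative")
    if delta == 0:
        return agents
    snapshot = [(agent.position.copy(), agent.fitness) for agent in agents]
    losers: set[int] = set()
    for g in range(len(agents)):
        for h in range(g + 1, len(agents)):
            if cartesian_distance(snapshot[g][0], snapshot[h][0]) < 2.0 * delta:
                if _is_better(snapshot[h][1], snapshot[g][1], sense):
                    losers.add(g)
                else:
                    # ties keep the lower-index agent in place
                    losers.add(h)
    for idx in sorted(losers):
        position = spec.clamp(rng.uniform_box(spec.lower, spec.upper))
        agents[idx].position = position
        agents[idx].fitness = spec.evaluate(position, context="collision relocation")
        agents[idx].record()
    return agents


# ---------------------------------------------------------------------------
# top-level loop


class _BestTracker:
    def __init__(self, sense: Sense):
        self.sense = sense
        self.position: np.ndarray | None = None
        self.fitness: float | None = None

    def offer(self, position: np.ndarray, fitness: float) -> None:
        if self.fitness is None or _is_better(fitness, self.fitness, self.sense):
            self.position = np.asarray(position, dtype=float).copy()
            self.fitness = fitness


def run_rpo(spec: ObjectiveSpec, config: RPOConfig) -> RunResult:
    """Run the full three-phase optimization.

    Draw order, for reproducibility: initialization (one box sample per
    agent), then per searching iteration one scout/cluster permutation
    followed by the non-scout agents' coefficient pairs in agent-index
    order; attacking iterations draw each agent's coefficient pair in
    index order, then any collision relocations.
    """
    schedule = partition_iterations(config.z)
    rng = RandomStream(config.seed)
    sense = spec.sense

    agents: list[Agent] = []
    for m in range(config.n):
        position = rng.uniform_box(spec.lower, spec.upper)
        fitness = spec.evaluate(position, context=f"initialization of agent {m}")
        agent = Agent(position=position, fitness=fitness)
        agent.record()
        agents.append(agent)

    tracker = _BestTracker(sense)
    for agent in agents:
        tracker.offer(agent.position, agent.fitness)

    trace: list[IterationRecord] = []
    realized = 0
    stopped = False
    previous_best = tracker.fitness

    def snapshot(phase: str, t: int, prey: np.ndarray | None = None) -> None:
        trace.append(
            IterationRecord(
                phase=phase,
                iteration=t,
                positions=np.stack([a.position for a in agents]),
                fitnesses=np.array([a.fitness for a in agents]),
                prey=None if prey is None else np.asarray(prey, dtype=float).copy(),
            )
        )

    def check_early_stop() -> bool:
        nonlocal previous_best
        if not config.early_stop_enabled:
            return False
        current = tracker.fitness
        fire = abs(current - previous_best) < config.early_stop_tol
        previous_best = current
        return fire

    # -- searching ----------------------------------------------------------
    for t in range(1, schedule.z_srch + 1):
        scouts, clusters = select_scouts(config.n, config.lam, rng)
        scout_set = set(scouts)
        for m, agent in enumerate(agents):
            agent.is_scout = m in scout_set
            agent.cluster_id = clusters.get(m)
        for m, agent in enumerate(agents):
            if agent.is_scout:
                agent.record()  # scouts hold position but keep their history
                continue
            a, c = sample_search_coefficients(rng)
            scout_position = agents[scouts[agent.cluster_id]].position
            searching_update(
                agent, scout_position, a, c, spec,
                context=f"searching iteration {t}, agent {m}",
            )
            tracker.offer(agent.position, agent.fitness)
        snapshot("searching", t)
        realized += 1
        if check_early_stop():
            stopped = True
            break

    for agent in agents:
        greedy_select_phase_best(agent, sense)
        agent.record()

    # -- encircling ---------------------------------------------------------
    if not stopped:
        for t in range(1, schedule.z_enc + 1):
            prey = compute_prey_position(
                [a.position for a in agents], [a.fitness for a in agents],
                config.k, sense,
            )
            for m, agent in enumerate(agents):
                encircling_update(
                    agent, prey, t, schedule.z_enc, config.b, spec,
                    context=f"encircling iteration {t}, agent {m}",
                )
                tracker.offer(agent.position, agent.fitness)
            snapshot("encircling", t, prey)
            realized += 1
            if check_early_stop():
                stopped = True
                break

    for agent in agents:
        greedy_select_phase_best(agent, sense)

    # -- attacking ----------------------------------------------------------
    if not stopped:
        checkpoints = (
            checkpoint_iterations(schedule.z_att, config.n_ck)
            if config.collision_enabled
            else set()
        )
        for t in range(1, schedule.z_att + 1):
            prey = compute_prey_position(
                [a.position for a in agents], [a.fitness for a in agents],
                config.k, sense,
            )
            a_bound = attack_coefficient_schedule(t, schedule.z_att)
            for m, agent in enumerate(agents):
                big_a, c = sample_attack_coefficients(a_bound, rng)
                attacking_update(
                    agent, prey, big_a, c, spec, sense,
                    context=f"attacking iteration {t}, agent {m}",
                )
                tracker.offer(agent.position, agent.fitness)
            if t in checkpoints:
                detect_and_resolve_collisions(agents, config.delta, rng, spec, sense)
                for agent in agents:
                    tracker.offer(agent.position, agent.fitness)
            snapshot("attacking", t, prey)
            realized += 1
            if check_early_stop():
                break

    return RunResult(
        best_position=tracker.position,
        best_fitness=tracker.fitness,
        trace=trace,
        schedule=schedule,
        realized_iterations=realized,
    )
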