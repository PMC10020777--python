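"""Binary variant of the optimizer for subset-search problems.

Bit vectors stand in for positions. Each continuous update rule from the
core engine is applied to the current bits read as 0/1 reals, and the
result is pushed through a sigmoid transfer function to obtain the next
bit vector. Fitness (higher is better) is evaluated on bit vectors only,
with caching keyed by the bit pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import (
    ConfigurationError,
    PhaseSchedule,
    RPOConfig,
    attack_coefficient_schedule,
    checkpoint_iterations,
    partition_iterations,
    select_scouts,
    sample_search_coefficients,
    spiral_parameter,
)
from .rng import RandomStream

__all__ = [
    "TransferConfig",
    "BinaryAgent",
    "BinaryIterationRecord",
    "BinaryRunResult",
    "sigmoid",
    "binarize",
    "run_brpo",
]

_RULES = ("paper", "conventional")


@dataclass(frozen=True)
class TransferConfig:
    """Which transfer rule converts continuous components to bits.

    ``paper`` sets a bit when the uniform draw is *at least* the sigmoid
    value (the method's original, inverted convention); ``conventional``
    uses the usual opposite comparison. The rule is fixed for a run.
    """

    rule: str = "paper"

    def __post_init__(self):
        if self.rule not in _RULES:
            raise ConfigurationError(f"transfer rule must be one of {_RULES}")


@dataclass
class BinaryAgent:
    bits: np.ndarray
    fitness: float
    history: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def record(self) -> None:
        self.history.append((self.bits.copy(), self.fitness))


@dataclass
class BinaryIterationRecord:
    phase: str
    iteration: int
    bits: np.ndarray
    fitnesses: np.ndarray
    prey: np.ndarray | None = None
    prey_bits: np.ndarray | None = None


@dataclass
class BinaryRunResult:
    best_bits: np.ndarray
    best_fitness: float
    trace: list[BinaryIterationRecord]
    schedule: PhaseSchedule
    realized_iterations: int
    fitness_evaluations: int = 0


def sigmoid(x: float) -> float:
    """Logistic function 1 / (1 + e^-x)."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def binarize(
    x_cont: np.ndarray, rng: RandomStream, cfg: TransferConfig = TransferConfig()
) -> np.ndarray:
    """Map a continuous vector to bits via the configured transfer rule.

    One uniform draw is consumed per component, in component order.
    """
    x_cont = np.asarray(x_cont, dtype=float)
    out = np.empty(x_cont.shape[0], dtype=np.int64)
    for i, value in enumerate(x_cont):
        threshold = sigmoid(float(value))
        draw = rng.uniform()
        if cfg.rule == "paper":
            out[i] = 1 if draw >= threshold else 0
        else:
            out[i] = 1 if draw < threshold else 0
    return out


def _ensure_nonempty(bits: np.ndarray, rng: RandomStream) -> np.ndarray:
    """Fitness of an empty subset is undefined: force one random bit on."""
    if bits.sum() == 0:
        bits[rng.integers(0, bits.shape[0])] = 1
    return bits


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum(a != b))


def run_brpo(
    fitness: Callable[[np.ndarray], float],
    f: int,
    config: RPOConfig,
    tcfg: TransferConfig = TransferConfig(),
    *,
    early_stop_enabled: bool | None = None,
) -> BinaryRunResult:
    """Three-phase subset search over f-dimensional bit vectors.

    ``fitness`` maps a nonempty 0/1 vector to a score to be maximized
    (typically a classifier accuracy). The virtual prey is the
    real-valued mean of the k best bit vectors; it feeds the update
    equations directly and is binarized only for reporting. Early
    stopping on a plateau of the best-so-far score is on by default for
    the binary variant (pass ``early_stop_enabled=False`` to disable);
    collision checks follow ``config.collision_enabled`` (off by
    default) and use Hamming distance against ``2 * config.delta``.
    """
    if f < 1:
        raise ConfigurationError("need at least one feature dimension")
    schedule = partition_iterations(config.z)
    rng = RandomStream(config.seed)
    early = True if early_stop_enabled is None else early_stop_enabled

    cache: dict[bytes, float] = {}
    evaluations = 0

    def fit(bits: np.ndarray) -> float:
        nonlocal evaluations
        key = bits.tobytes()
        if key not in cache:
            try:
                cache[key] = float(fitness(bits))
            except Exception as exc:  # annotate which subset failed
                raise RuntimeError(
                    f"fitness evaluation failed for subset {np.flatnonzero(bits).tolist()}"
                ) from exc
            evaluations += 1
        return cache[key]

    agents: list[BinaryAgent] = []
    for _ in range(config.n):
        bits = _ensure_nonempty(rng.bits(f), rng)
        agent = BinaryAgent(bits=bits, fitness=fit(bits))
        agent.record()
        agents.append(agent)

    best_bits = agents[0].bits.copy()
    best_fitness = agents[0].fitness
    for agent in agents[1:]:
        if agent.fitness > best_fitness:
            best_bits, best_fitness = agent.bits.copy(), agent.fitness

    def offer(bits: np.ndarray, value: float) -> None:
        nonlocal best_bits, best_fitness
        if value > best_fitness:
            best_bits, best_fitness = bits.copy(), value

    trace: list[BinaryIterationRecord] = []
    realized = 0
    stopped = False
    previous_best = best_fitness

    def snapshot(phase, t, prey=None, prey_bits=None):
        trace.append(
            BinaryIterationRecord(
                phase=phase,
                iteration=t,
                bits=np.stack([a.bits for a in agents]),
                fitnesses=np.array([a.fitness for a in agents]),
                prey=None if prey is None else np.asarray(prey, dtype=float).copy(),
                prey_bits=None if prey_bits is None else prey_bits.copy(),
            )
        )

    def check_early_stop() -> bool:
        nonlocal previous_best
        if not early:
            return False
        fire = abs(best_fitness - previous_best) < config.early_stop_tol
        previous_best = best_fitness
        return fire

    def step_to(agent: BinaryAgent, x_cont: np.ndarray, *, greedy: bool) -> None:
        bits = _ensure_nonempty(binarize(x_cont, rng, tcfg), rng)
        value = fit(bits)
        if not greedy or value > agent.fitness:
            agent.bits, agent.fitness = bits, value
        agent.record()
        offer(bits, value)

    def prey_vector() -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(-np.array([a.fitness for a in agents]), kind="stable")
        stacked = np.stack([agents[i].bits for i in order[: config.k]]).astype(float)
        prey = stacked.mean(axis=0)
        return prey, _ensure_nonempty(binarize(prey, rng, tcfg), rng)

    # -- searching ----------------------------------------------------------
    for t in range(1, schedule.z_srch + 1):
        scouts, clusters = select_scouts(config.n, config.lam, rng)
        scout_set = set(scouts)
        for m, agent in enumerate(agents):
            if m in scout_set:
                agent.record()
                continue
            a, c = sample_search_coefficients(rng)
            scout_bits = agents[scouts[clusters[m]]].bits.astype(float)
            x_cont = scout_bits - a * np.abs(c * scout_bits - agent.bits)
            step_to(agent, x_cont, greedy=False)
        snapshot("searching", t)
        realized += 1
        if check_early_stop():
            stopped = True
            break

    for agent in agents:
        idx = int(np.argmax([v for _, v in agent.history]))
        agent.bits, agent.fitness = agent.history[idx][0].copy(), agent.history[idx][1]
        agent.history = [(agent.bits.copy(), agent.fitness)]

    # -- encircling ---------------------------------------------------------
    if not stopped:
        for t in range(1, schedule.z_enc + 1):
            prey, prey_bits = prey_vector()
            l = spiral_parameter(t, schedule.z_enc)
            factor = math.exp(config.b * l) * math.cos(2.0 * math.pi * l)
            for agent in agents:
                d = np.abs(prey - agent.bits)
                step_to(agent, d * factor + prey, greedy=False)
            snapshot("encircling", t, prey, prey_bits)
            realized += 1
            if check_early_stop():
                stopped = True
                break

    for agent in agents:
        idx = int(np.argmax([v for _, v in agent.history]))
        agent.bits, agent.fitness = agent.history[idx][0].copy(), agent.history[idx][1]
        agent.history = [(agent.bits.copy(), agent.fitness)]

    # -- attacking ----------------------------------------------------------
    if not stopped:
        checkpoints = (
            checkpoint_iterations(schedule.z_att, config.n_ck)
            if config.collision_enabled
            else set()
        )
        for t in range(1, schedule.z_att + 1):
            prey, prey_bits = prey_vector()
            a_bound = attack_coefficient_schedule(t, schedule.z_att)
            for agent in agents:
                big_a = 2.0 * a_bound * rng.uniform() - a_bound
                c = 2.0 * rng.uniform()
                d = np.abs(c * prey - agent.bits)
                step_to(agent, prey - big_a * d, greedy=True)
            if t in checkpoints and config.delta > 0:
                snapshot_bits = [(a.bits.copy(), a.fitness) for a in agents]
                losers: set[int] = set()
                for g in range(len(agents)):
                    for h in range(g + 1, len(agents)):
                        if _hamming(snapshot_bits[g][0], snapshot_bits[h][0]) < 2 * config.delta:
                            if snapshot_bits[h][1] > snapshot_bits[g][1]:
                                losers.add(g)
                            else:
                                losers.add(h)
                for idx in sorted(losers):
                    bits = _ensure_nonempty(rng.bits(f), rng)
                    agents[idx].bits = bits
                    agents[idx].fitness = fit(bits)
                    offer(bits, agents[idx].fitness)
            snapshot("attacking", t, prey, prey_bits)
            realized += 1
            if check_early_stop():
                break

    return BinaryRunResult(
        best_bits=best_bits,
        best_fitness=best_fitness,
        trace=trace,
        schedule=schedule,
        realized_iterations=realized,
        fitness_evaluations=evaluations,
    )
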