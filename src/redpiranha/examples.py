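"""Replay of the packaged worked-example fixtures.

Each fixture transcribes one table of a fully worked small run (two
variables on [-5, 5], ten agents, the convex quadratic objective):
the searching iterations with their per-agent coefficient draws, the
encircling iterations, and the attacking iterations. Replaying feeds
the printed inputs of every table cell through the package's update
rules and compares the output with the printed value.

Cells whose printed coefficient draws are typographically corrupted and
do not reproduce the adjacent printed numbers carry ``enforced=False``;
so do the encircling position updates, whose printed coordinates are not
consistent with the stated spiral rule (only the distance vectors, prey
means, spiral parameters and objective values of that table are
checkable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core import (
    Agent,
    ObjectiveSpec,
    Sense,
    attacking_update,
    compute_prey_position,
    greedy_select_phase_best,
    searching_update,
    spiral_parameter,
)
from .objectives import get_objective

__all__ = [
    "TOLERANCE",
    "CellCheck",
    "list_fixtures",
    "load_fixture",
    "replay_searching_example",
    "replay_encircling_example",
    "replay_attacking_example",
    "replay_all",
]

TOLERANCE = 5e-3

_FIXTURES = ("table1_searching", "table4_encircling", "table6_attacking")


@dataclass
class CellCheck:
    label: str
    computed: np.ndarray | float
    printed: np.ndarray | float
    enforced: bool = True

    @property
    def difference(self) -> float:
        return float(
            np.max(np.abs(np.asarray(self.computed) - np.asarray(self.printed)))
        )

    @property
    def ok(self) -> bool:
        return self.difference <= TOLERANCE

    @property
    def passed(self) -> bool:
        return self.ok or not self.enforced


def list_fixtures() -> list[str]:
    return list(_FIXTURES)


def load_fixture(name: str) -> dict:
    """Load a packaged worked-example fixture by name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")
    payload = resources.files("redpiranha.fixtures").joinpath(f"{name}.json")
    return json.loads(payload.read_text())


def _spec(fixture: dict) -> ObjectiveSpec:
    return ObjectiveSpec(
        dimension=2,
        lower=np.asarray(fixture["lower"]),
        upper=np.asarray(fixture["upper"]),
        objective=get_objective(fixture["objective"]),
        sense=Sense.MINIMIZE,
    )


def _greedy_checks(
    fixture: dict,
    histories: dict[str, list[np.ndarray]],
    spec,
    tag: str,
    *,
    include_initial: bool = True,
) -> list[CellCheck]:
    # The printed end-of-encircling selection ignores the position each
    # agent carried into the phase (visible on one agent whose carry-in
    # beat every spiral move), so that replay passes include_initial=False.
    checks = []
    for name in fixture["agents"]:
        entries = histories[name] if include_initial else histories[name][1:]
        agent = Agent(position=entries[0], fitness=0.0)
        agent.history = [(p, spec.evaluate(p)) for p in entries]
        greedy_select_phase_best(agent, Sense.MINIMIZE)
        expected = fixture["best_after"][name]
        checks.append(
            CellCheck(f"{tag} greedy best of {name}: position",
                      agent.position, np.asarray(expected["position"])))
        checks.append(
            CellCheck(f"{tag} greedy best of {name}: objective",
                      agent.fitness, expected["objective"]))
    return checks


def replay_searching_example() -> list[CellCheck]:
    """Recompute every searching-phase cell from the printed inputs."""
    fixture = load_fixture("table1_searching")
    spec = _spec(fixture)
    checks: list[CellCheck] = []

    state = {k: np.asarray(v["position"], dtype=float)
             for k, v in fixture["initial"].items()}
    histories = {k: [v.copy()] for k, v in state.items()}
    for name, entry in fixture["initial"].items():
        checks.append(CellCheck(
            f"initial objective of {name}",
            spec.evaluate(state[name]), entry["objective"]))

    for it, cells in enumerate(fixture["iterations"], start=1):
        new_state = {}
        for name in fixture["agents"]:
            cell = cells[name]
            printed = np.asarray(cell["position"], dtype=float)
            if cell["scout"] is None:
                # scouts hold their position for the iteration they lead
                checks.append(CellCheck(
                    f"searching it{it} {name} (scout) holds position",
                    state[name], printed))
            else:
                agent = Agent(position=state[name],
                              fitness=spec.evaluate(state[name]))
                searching_update(agent, state[cell["scout"]],
                                 cell["A"], cell["C"], spec)
                checks.append(CellCheck(
                    f"searching it{it} {name} updated position",
                    agent.position, printed,
                    enforced=cell["update_checked"]))
            checks.append(CellCheck(
                f"searching it{it} {name} objective at printed position",
                spec.evaluate(printed), cell["objective"]))
            new_state[name] = printed
            histories[name].append(printed)
        state = new_state

    checks.extend(_greedy_checks(fixture, histories, spec, "searching"))
    return checks


def replay_encircling_example() -> list[CellCheck]:
    """Check prey means, distance vectors, spiral parameters, objectives.

    The printed updated coordinates of this table are not reproducible
    from the stated spiral rule; those comparisons are reported but not
    enforced.
    """
    fixture = load_fixture("table4_encircling")
    spec = _spec(fixture)
    b = fixture["b"]
    z_enc = fixture["z_enc"]
    checks: list[CellCheck] = []

    state = {k: np.asarray(v["position"], dtype=float)
             for k, v in fixture["initial"].items()}
    histories = {k: [v.copy()] for k, v in state.items()}

    for block in fixture["iterations"]:
        t = block["t"]
        checks.append(CellCheck(
            f"encircling it{t} spiral parameter l",
            spiral_parameter(t, z_enc), block["l"]))
        positions = [state[n] for n in fixture["agents"]]
        fitnesses = [spec.evaluate(p) for p in positions]
        prey = compute_prey_position(positions, fitnesses, fixture["k"],
                                     Sense.MINIMIZE)
        printed_prey = np.asarray(block["prey"], dtype=float)
        checks.append(CellCheck(
            f"encircling it{t} prey mean", prey, printed_prey,
            enforced=block["prey_checked"]))
        new_state = {}
        for name in fixture["agents"]:
            cell = block["cells"][name]
            d = np.abs(printed_prey - state[name])
            checks.append(CellCheck(
                f"encircling it{t} {name} distance vector",
                d, np.asarray(cell["D"]), enforced=cell["d_checked"]))
            printed = np.asarray(cell["position"], dtype=float)
            l = spiral_parameter(t, z_enc)
            spiral = spec.clamp(
                d * np.exp(b * l) * np.cos(2.0 * np.pi * l) + printed_prey)
            checks.append(CellCheck(
                f"encircling it{t} {name} spiral position (documented mismatch)",
                spiral, printed, enforced=False))
            checks.append(CellCheck(
                f"encircling it{t} {name} objective at printed position",
                spec.evaluate(printed), cell["objective"]))
            new_state[name] = printed
            histories[name].append(printed)
        state = new_state

    positions = [state[n] for n in fixture["agents"]]
    fitnesses = [spec.evaluate(p) for p in positions]
    prey = compute_prey_position(positions, fitnesses, fixture["k"], Sense.MINIMIZE)
    checks.append(CellCheck(
        "encircling final prey mean", prey,
        np.asarray(fixture["final_prey"]["prey"]),
        enforced=fixture["final_prey"]["prey_checked"]))

    checks.extend(_greedy_checks(fixture, histories, spec, "encircling",
                                 include_initial=False))
    return checks


def replay_attacking_example() -> list[CellCheck]:
    """Recompute every attacking-phase cell from the printed inputs."""
    fixture = load_fixture("table6_attacking")
    spec = _spec(fixture)
    checks: list[CellCheck] = []

    state = {k: np.asarray(v["position"], dtype=float)
             for k, v in fixture["initial"].items()}

    for block in fixture["iterations"]:
        t = block["t"]
        positions = [state[n] for n in fixture["agents"]]
        fitnesses = [spec.evaluate(p) for p in positions]
        prey = compute_prey_position(positions, fitnesses, fixture["k"],
                                     Sense.MINIMIZE)
        printed_prey = np.asarray(block["prey"], dtype=float)
        checks.append(CellCheck(
            f"attacking it{t} prey mean", prey, printed_prey,
            enforced=block["prey_checked"]))
        new_state = {}
        for name in fixture["agents"]:
            cell = block["cells"][name]
            agent = Agent(position=state[name],
                          fitness=spec.evaluate(state[name]))
            if cell["candidate"] is not None:
                d = np.abs(cell["C"] * printed_prey - state[name])
                candidate = spec.clamp(printed_prey - cell["A"] * d)
                checks.append(CellCheck(
                    f"attacking it{t} {name} rejected candidate",
                    candidate, np.asarray(cell["candidate"]),
                    enforced=cell["update_checked"]))
                checks.append(CellCheck(
                    f"attacking it{t} {name} candidate objective",
                    spec.evaluate(np.asarray(cell["candidate"])),
                    cell["candidate_objective"]))
            attacking_update(agent, printed_prey, cell["A"], cell["C"],
                             spec, Sense.MINIMIZE)
            printed = np.asarray(cell["position"], dtype=float)
            checks.append(CellCheck(
                f"attacking it{t} {name} retained position",
                agent.position, printed, enforced=cell["update_checked"]))
            checks.append(CellCheck(
                f"attacking it{t} {name} objective at printed position",
                spec.evaluate(printed), cell["objective"]))
            new_state[name] = printed
        state = new_state

    final = fixture["optimal"]
    values = {n: spec.evaluate(state[n]) for n in fixture["agents"]}
    winner = min(values, key=lambda n: (values[n], fixture["agents"].index(n)))
    checks.append(CellCheck(
        "attacking optimal agent position",
        state[winner], np.asarray(final["position"])))
    checks.append(CellCheck(
        "attacking optimal objective",
        values[winner], final["objective"]))
    return checks


def replay_all() -> list[CellCheck]:
    return (
        replay_searching_example()
        + replay_encircling_example()
        + replay_attacking_example()
    )
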