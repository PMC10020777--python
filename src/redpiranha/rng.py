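"""Seeded random streams with the draw supports the update rules require.

The optimizer consumes randomness through a small named-draw interface so
that (a) the draw order is explicit and reproducible and (b) tests can
substitute a scripted list of variates to replay worked examples.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RandomStream", "ScriptedStream"]


class RandomStream:
    """Thin wrapper around :class:`numpy.random.Generator`.

    Draw supports:

    * ``r1`` -- Bernoulli on {0, 1}
    * ``r2`` -- uniform on [0, 1)
    * ``r3`` -- uniform on (0, 1]
    * ``r4`` / ``uniform`` -- uniform on [0, 1]  (realised as [0, 1);
      the endpoint has measure zero)
    * ``uniform_box`` -- componentwise uniform between two bound vectors

    The same seed and the same sequence of calls yield identical variates.
    """

    def __init__(self, seed: int | np.random.Generator):
        if isinstance(seed, np.random.Generator):
            self._gen = seed
        else:
            self._gen = np.random.default_rng(seed)

    def r1(self) -> int:
        return int(self._gen.integers(0, 2))

    def r2(self) -> float:
        return float(self._gen.random())

    def r3(self) -> float:
        # random() is [0, 1); reflect to (0, 1]
        return float(1.0 - self._gen.random())

    def r4(self) -> float:
        return float(self._gen.random())

    def uniform(self) -> float:
        return float(self._gen.random())

    def uniform_box(self, lower, upper, size=None) -> np.ndarray:
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if size is None:
            shape = lower.shape
        else:
            shape = (size, lower.shape[0]) if lower.ndim else (size,)
        return lower + self._gen.random(shape) * (upper - lower)

    def bits(self, n: int) -> np.ndarray:
        return self._gen.integers(0, 2, size=n)

    def integers(self, low: int, high: int) -> int:
        return int(self._gen.integers(low, high))

    def permutation(self, n: int) -> np.ndarray:
        return self._gen.permutation(n)

    def spawn(self) -> "RandomStream":
        """Fork a child stream deterministically."""
        return RandomStream(self._gen.spawn(1)[0])


class ScriptedStream(RandomStream):
    """A stream that replays a fixed list of scalar draws.

    Every named scalar draw (``r1`` .. ``r4``, ``uniform``) pops the next
    value from ``draws``; vector draws are not supported. Used to inject
    printed coefficient values when replaying worked examples.
    """

    def __init__(self, draws):
        super().__init__(np.random.default_rng(0))
        self._draws = list(draws)
        self._cursor = 0

    def _pop(self) -> float:
        if self._cursor >= len(self._draws):
            raise IndexError("scripted draw list exhausted")
        value = self._draws[self._cursor]
        self._cursor += 1
        return float(value)

    def r1(self) -> int:
        return int(self._pop())

    def r2(self) -> float:
        return self._pop()

    def r3(self) -> float:
        return self._pop()

    def r4(self) -> float:
        return self._pop()

    def uniform(self) -> float:
        return self._pop()

    def uniform_box(self, lower, upper, size=None) -> np.ndarray:
        raise NotImplementedError("scripted streams only supply scalar draws")
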