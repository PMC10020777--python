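"""Built-in objective functions and a plug-in registry."""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["register_objective", "get_objective", "list_objectives",
           "example_quadratic", "sphere"]

_REGISTRY: dict[str, Callable[[np.ndarray], float]] = {}


def register_objective(name: str, fn: Callable[[np.ndarray], float]) -> None:
    """Add a named objective; names are case-insensitive."""
    _REGISTRY[name.lower()] = fn


def get_objective(name: str) -> Callable[[np.ndarray], float]:
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown objective {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


def list_objectives() -> list[str]:
    return sorted(_REGISTRY)


def example_quadratic(x: np.ndarray) -> float:
    """f(x1, x2) = x1^2 - x1*x2 + x2^2 + 2*x1 + 4*x2 + 3.

    Convex, with minimum -19/3 at (-8/3, -10/3).
    """
    x1, x2 = float(x[0]), float(x[1])
    return x1 * x1 - x1 * x2 + x2 * x2 + 2.0 * x1 + 4.0 * x2 + 3.0


def sphere(x: np.ndarray) -> float:
    """Sum of squares; minimum 0 at the origin, any dimension."""
    x = np.asarray(x, dtype=float)
    return float(np.dot(x, x))


register_objective("example_quadratic", example_quadratic)
register_objective("sphere", sphere)
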