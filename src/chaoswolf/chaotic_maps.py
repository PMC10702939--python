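"""Deterministic chaotic number generators.

Three one-dimensional chaotic maps — circle, logistic and iterative
(infinite-collapse) — whose orbits replace pseudo-random draws inside the
grey wolf optimizer.  Each map is a simple recurrence z_{m+1} = g(z_m); the
resulting sequences look stochastic (ergodic, spread-spectrum) but are fully
reproducible from the initial value z1, which is the property the chaotic
optimizer variants exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ChaoticMapSpec", "ChaoticStream", "sequence", "MAP_KINDS"]

MAP_KINDS = ("circle", "logistic", "iterative")

#: below this magnitude the iterative map's sin(y*pi/z) is numerically
#: meaningless; the stream reseeds to z1 instead of dividing by ~0.
_ITERATIVE_EPS = 1e-12


@dataclass(frozen=True)
class ChaoticMapSpec:
    """Parameterization of one chaotic map.

    Defaults are the standard choices for these maps: circle-map offsets
    ``y1 = 0.5`` and ``y2 = 0.2``, logistic growth rate ``mu = 4`` (the fully
    chaotic regime), iterative-map parameter ``y = 0.7``, and a shared
    initial value ``z1 = 0.7``.
    """

    kind: str
    y1: float = 0.5
    y2: float = 0.2
    mu: float = 4.0
    y: float = 0.7
    z1: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")
        if not 0.0 < self.z1 <= 1.0:
            raise ValueError(f"z1 must lie in (0, 1], got {self.z1}")
        if not 0.0 < self.y < 1.0:
            raise ValueError(f"iterative-map parameter y must lie in (0, 1), got {self.y}")
        if self.mu <= 0:
            raise ValueError(f"logistic parameter mu must be positive, got {self.mu}")


class ChaoticStream:
    """Stateful iterator over one chaotic orbit.

    ``next_raw`` advances the underlying recurrence and returns the raw map
    value (which may leave [0, 1]: the circle map drifts upward, the
    iterative map ranges over [-1, 1]).  ``next_unit`` is what the optimizer
    consumes: the raw value normalized into [0, 1] — circle reduced modulo 1,
    logistic passed through, iterative taken in absolute value.
    """

    def __init__(self, spec: ChaoticMapSpec) -> None:
        self.spec = spec
        self.z_current: float = spec.z1
        self.m: int = 0

    def next_raw(self) -> float:
        spec = self.spec
        z = self.z_current
        if spec.kind == "circle":
            z_next = z + spec.y2 - (spec.y1 / (2.0 * math.pi)) * math.sin(2.0 * math.pi * z)
        elif spec.kind == "logistic":
            z_next = spec.mu * z * (1.0 - z)
        else:  # iterative
            if abs(z) < _ITERATIVE_EPS:
                z = spec.z1  # reseed: sin(y*pi/z) undefined at z = 0
            z_next = math.sin(spec.y * math.pi / z)
        self.z_current = z_next
        self.m += 1
        return z_next

    def next_unit(self) -> float:
        raw = self.next_raw()
        kind = self.spec.kind
        if kind == "circle":
            return raw % 1.0
        if kind == "iterative":
            return abs(raw)
        return raw  # logistic already lies in [0, 1] for z in [0, 1], mu <= 4


def sequence(spec: ChaoticMapSpec, n: int) -> list[float]:
    """First ``n`` unit-interval values of the orbit starting from ``z1``."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    stream = ChaoticStream(spec)
    return [stream.next_unit() for _ in range(n)]
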