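"""Factorial design of the breath-test image database.

The database crosses five disease stages (A0–A4) with three inhalation flow
rates (27, 30, 33 L/min — a nominal 30 L/min with ±10% uncertainty), nine
particle sizes (0.2–10 μm) and three stochastic replicates per condition:
5 × 3 × 9 × 3 = 405 images.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "FLOW_RATES",
    "PARTICLE_SIZES",
    "REPLICATES",
    "TestCondition",
    "all_conditions",
]

FLOW_RATES: tuple[float, ...] = (27.0, 30.0, 33.0)
PARTICLE_SIZES: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 5.0, 10.0)
REPLICATES: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True, order=True)
class TestCondition:
    """One breath-test condition: (flow rate L/min, particle size μm, replicate)."""

    flow_rate: float
    particle_size: float
    replicate: int

    def __post_init__(self) -> None:
        if self.flow_rate not in FLOW_RATES:
            raise ValueError(f"flow_rate must be one of {FLOW_RATES}, got {self.flow_rate}")
        if self.particle_size not in PARTICLE_SIZES:
            raise ValueError(
                f"particle_size must be one of {PARTICLE_SIZES}, got {self.particle_size}"
            )
        if self.replicate not in REPLICATES:
            raise ValueError(f"replicate must be one of {REPLICATES}, got {self.replicate}")


def all_conditions() -> list[TestCondition]:
    """All 81 test conditions in (flow, size, replicate)-ascending order."""
    return [
        TestCondition(flow_rate=q, particle_size=d, replicate=r)
        for q, d, r in product(FLOW_RATES, PARTICLE_SIZES, REPLICATES)
    ]
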