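"""Geometry of the modelled G7–G9 bronchiole constrictions.

Five disease stages are considered: a normal airway (A0) and four
progressively constricted ones (A1–A4), parameterised by the minimum
bronchiolar diameter, the minimum cross-sectional area at the constriction,
and the volume of the disease-affected region.  Severity is the fractional
loss of cross-sectional area relative to the normal airway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AirwayDiseaseSpec",
    "AIRWAY_STAGES",
    "STAGE_LABELS",
    "SEVERITY_BY_LABEL",
    "area_from_diameter",
    "severity_percent",
    "relative_difference_percent",
]


@dataclass(frozen=True)
class AirwayDiseaseSpec:
    """One disease stage of the modelled small-airway obstruction.

    Parameters
    ----------
    label : str
        Stage identifier, ``"A0"`` (normal) through ``"A4"`` (near-total
        occlusion).
    min_diameter : float
        Minimum bronchiolar diameter at the constriction, mm.
    min_area : float
        Minimum cross-sectional area at the constriction, mm².
    affected_volume : float
        Volume of the disease-affected bronchiolar region, mm³.
    severity : float
        Dimensionless fraction in [0, 1]: ``1 - min_area / min_area(A0)``.
    """

    label: str
    min_diameter: float
    min_area: float
    affected_volume: float
    severity: float

    def __post_init__(self) -> None:
        if self.min_diameter <= 0 or self.min_area <= 0 or self.affected_volume <= 0:
            raise ValueError(f"{self.label}: all airway dimensions must be positive")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"{self.label}: severity must lie in [0, 1], got {self.severity}")


def area_from_diameter(d: float) -> float:
    """Circular cross-sectional area (mm²) from a diameter ``d`` (mm)."""
    if d < 0:
        raise ValueError(f"diameter must be nonnegative, got {d}")
    return math.pi * d * d / 4.0


def severity_percent(spec: AirwayDiseaseSpec, ref: AirwayDiseaseSpec) -> float:
    """Percent constriction of cross-sectional area of ``spec`` relative to ``ref``.

    ``100 * (1 - spec.min_area / ref.min_area)``; e.g. A3 vs A0 gives 94.5%.
    """
    if ref.min_area <= 0:
        raise ValueError("reference area must be positive")
    return 100.0 * (1.0 - spec.min_area / ref.min_area)


def relative_difference_percent(a: float, b: float) -> int:
    """Relative difference ``100 * (a - b) / a`` rounded to the nearest integer.

    The caller orders the operands so that ``a >= b > 0`` (the larger dimension
    first); e.g. the A2 vs A3 diameters 1.13 mm vs 0.87 mm differ by 23%.
    """
    if b <= 0:
        raise ValueError("operands must be positive")
    if b > a:
        raise ValueError(f"operands must satisfy a >= b, got a={a}, b={b}")
    return round(100.0 * (a - b) / a)


def _stage(label: str, d: float, area: float, vol: float, ref_area: float) -> AirwayDiseaseSpec:
    return AirwayDiseaseSpec(
        label=label,
        min_diameter=d,
        min_area=area,
        affected_volume=vol,
        severity=1.0 - area / ref_area,
    )


_A0_AREA = 11.0

#: The five modelled stages: (diameter mm, area mm², affected volume mm³).
AIRWAY_STAGES: tuple[AirwayDiseaseSpec, ...] = (
    _stage("A0", 3.74, 11.0, 189.9, _A0_AREA),
    _stage("A1", 1.88, 2.8, 77.6, _A0_AREA),
    _stage("A2", 1.13, 1.0, 50.5, _A0_AREA),
    _stage("A3", 0.87, 0.6, 46.6, _A0_AREA),
    _stage("A4", 0.25, 0.05, 37.9, _A0_AREA),
)

STAGE_LABELS: tuple[str, ...] = tuple(s.label for s in AIRWAY_STAGES)
SEVERITY_BY_LABEL: dict[str, float] = {s.label: s.severity for s in AIRWAY_STAGES}
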