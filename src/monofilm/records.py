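"""Core data model for Langmuir-monolayer compression isotherms.

An :class:`IsothermRecord` stores one surface pressure–area (π–A) compression
isotherm in canonical form: points ordered by strictly decreasing mean
molecular area (the compression direction), areas in Å²/molecule, pressures in
mN/m, together with film composition and temperature metadata.

Compositions are held as a :class:`CompositionTriple` of mole fractions for
the pseudo-binary system studied here: component 1 is cholesterol, component 2
is POPC (together the model membrane, mixed at a fixed chol:POPC ratio), and
component 3 is the drug (an alkylphosphocholine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_MEMBRANE_RATIO
from .errors import DomainError, ValidationError

__all__ = [
    "CompositionTriple",
    "CollapseInfo",
    "IsothermRecord",
    "make_composition",
]


@dataclass(frozen=True)
class CompositionTriple:
    """Mole fractions of cholesterol (x1), POPC (x2) and drug (x3).

    Invariants: each fraction in [0, 1], fractions sum to 1, and — whenever
    any membrane is present — the cholesterol/POPC ratio equals the
    configured membrane ratio.
    """

    x1: float
    x2: float
    x3: float

    def validate(self, membrane_ratio: Optional[float] = DEFAULT_MEMBRANE_RATIO) -> "CompositionTriple":
        for name, x in (("x1", self.x1), ("x2", self.x2), ("x3", self.x3)):
            if not (0.0 <= x <= 1.0):
                raise ValidationError(f"mole fraction {name}={x} outside [0, 1]")
        total = self.x1 + self.x2 + self.x3
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mole fractions sum to {total!r}, not 1 within 1e-9")
        if membrane_ratio is not None and self.x1 + self.x2 > 0.0:
            if self.x2 == 0.0:
                raise ValidationError("membrane present but POPC fraction is zero")
            ratio = self.x1 / self.x2
            if abs(ratio - membrane_ratio) > 1e-6:
                raise ValidationError(
                    f"chol:POPC ratio {ratio:.8f} differs from configured {membrane_ratio} by more than 1e-6"
                )
        return self

    @property
    def membrane_fraction(self) -> float:
        """x1 + x2, the weight of the membrane pseudo-component."""
        return self.x1 + self.x2


def make_composition(x3: float, membrane_ratio: float = DEFAULT_MEMBRANE_RATIO) -> CompositionTriple:
    """Composition with drug mole fraction ``x3`` and the fixed chol:POPC ratio.

    Solving x1 = r·x2 and x1 + x2 = 1 − x3 gives
    x2 = (1 − x3)/(1 + r), x1 = r·(1 − x3)/(1 + r).
    """
    if not (0.0 <= x3 <= 1.0):
        raise DomainError(f"x3={x3} outside [0, 1]")
    if membrane_ratio <= 0.0:
        raise DomainError(f"membrane_ratio={membrane_ratio} must be positive")
    x2 = (1.0 - x3) / (1.0 + membrane_ratio)
    x1 = membrane_ratio * x2
    triple = CompositionTriple(x1, x2, x3)
    triple.validate(membrane_ratio if x3 < 1.0 else None)
    return triple


@dataclass(frozen=True)
class CollapseInfo:
    """Detected monolayer collapse: pressure, detection rule, and point index."""

    pi_coll: float
    method: str
    point_index: int


@dataclass
class IsothermRecord:
    """One canonicalized π–A compression isotherm.

    ``area`` is strictly decreasing (Å²/molecule); ``pressure`` is in mN/m.
    Use :meth:`from_points` to build a record from raw, possibly unsorted
    data — it sorts, merges exact duplicate areas and validates invariants.
    """

    area: np.ndarray
    pressure: np.ndarray
    composition: Optional[CompositionTriple] = None
    temperature_c: float = 37.0
    label: str = ""
    source: str = "synthetic"
    extra: dict = field(default_factory=dict)

    MIN_POINTS = 10
    PRESSURE_FLOOR = -0.5  # small negative noise tolerated pre-smoothing

    @classmethod
    def from_points(
        cls,
        area: Sequence[float],
        pressure: Sequence[float],
        composition: Optional[CompositionTriple] = None,
        temperature_c: float = 37.0,
        label: str = "",
        source: str = "synthetic",
        extra: Optional[dict] = None,
    ) -> "IsothermRecord":
        a = np.asarray(area, dtype=float)
        p = np.asarray(pressure, dtype=float)
        if a.ndim != 1 or p.ndim != 1 or a.size != p.size:
            raise ValidationError("area and pressure must be 1-D arrays of equal length")
        a, p = _canonicalize(a, p)
        rec = cls(
            area=a,
            pressure=p,
            composition=composition,
            temperature_c=temperature_c,
            label=label,
            source=source,
            extra=dict(extra or {}),
        )
        rec.validate()
        return rec

    def validate(self) -> "IsothermRecord":
        a, p = self.area, self.pressure
        if a.size < self.MIN_POINTS:
            raise ValidationError(f"isotherm has {a.size} points; at least {self.MIN_POINTS} required")
        if not np.all(a > 0.0):
            raise ValidationError("areas must be strictly positive")
        if not np.all(np.diff(a) < 0.0):
            raise ValidationError("areas must be strictly decreasing after canonicalization")
        if p.min() < self.PRESSURE_FLOOR:
            raise ValidationError(f"pressure {p.min():.3f} mN/m below tolerated floor {self.PRESSURE_FLOOR}")
        if p.max() <= 1.0:
            raise ValidationError(f"maximum pressure {p.max():.3f} mN/m must exceed 1 mN/m")
        if self.composition is not None:
            self.composition.validate(membrane_ratio=None)
        return self

    @property
    def n_points(self) -> int:
        return int(self.area.size)

    @property
    def max_pressure(self) -> float:
        return float(self.pressure.max())

    @property
    def min_pressure(self) -> float:
        return float(self.pressure.min())

    def replace_pressure(self, pressure: np.ndarray) -> "IsothermRecord":
        """Copy of this record with a new pressure array (same areas/metadata)."""
        return IsothermRecord(
            area=self.area.copy(),
            pressure=np.asarray(pressure, dtype=float),
            composition=self.composition,
            temperature_c=self.temperature_c,
            label=self.label,
            source=self.source,
            extra=dict(self.extra),
        )


def _canonicalize(area: np.ndarray, pressure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by decreasing area; merge exact duplicate areas by mean pressure.

    Instrument repeats at barrier pauses produce duplicated areas; averaging
    their pressures before the monotonicity check keeps the record strictly
    decreasing.  The result is independent of the input row order.
    """
    order = np.argsort(-area, kind="stable")
    a, p = area[order], pressure[order]
    uniq, inverse = np.unique(-a, return_inverse=True)
    if uniq.size != a.size:
        sums = np.bincount(inverse, weights=p)
        counts = np.bincount(inverse)
        # ascending -area == descending area, so order is already canonical
        a = -uniq
        p = sums / counts
    return a.astype(float), p.astype(float)
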