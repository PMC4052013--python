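"""Pseudo-binary mixing thermodynamics of membrane + drug monolayers.

The cholesterol/POPC model membrane (fixed chol:POPC ratio) is treated as one
pseudo-component with mean area A12 and weight (X1 + X2); the drug is the
second component with area A3 and mole fraction X3.  At each surface pressure
the additivity rule gives the ideal mixed-film area

    A123_id = A12·(X1 + X2) + A3·X3,

and the excess area A123 − A123_id diagnoses non-ideal mixing (negative →
attraction, i.e. drug–membrane affinity).  Integrating the excess area over
pressure and scaling by the Avogadro constant yields the excess free energy
of mixing

    ΔG_exc(π) = N ∫₀^π [A123 − (X1+X2)·A12 − X3·A3] dπ′,

in J/mol with the conversion 1 mN/m·Å² = 1e-23 J.  Negative ΔG_exc means
thermodynamically favourable incorporation of the drug into the membrane.

Measured isotherms begin at a small positive pressure, while the integral
starts at π = 0; by default each area-vs-pressure branch is extrapolated
linearly from its two lowest-pressure points down to π = 0 and the
extrapolated fraction of the integral is reported (``lower_limit="common-min"``
starts at the highest common minimum pressure instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import area_at_pressure, detect_collapse, smooth_isotherm
from .constants import DEFAULT_MEMBRANE_RATIO, DG_SCALE
from .errors import DomainError, RangeError, ValidationError
from .records import IsothermRecord, make_composition

__all__ = [
    "ideal_area",
    "excess_area_curve",
    "excess_free_energy",
    "ExcessFreeEnergy",
    "analyze_mixing_series",
    "MixingAnalysisResult",
    "collapse_vs_composition",
    "CollapseComposition",
    "fit_omega",
]


def ideal_area(a12: float, a3: float, x3: float) -> float:
    """Additivity-rule area A12·(1 − X3) + A3·X3 at one surface pressure."""
    if a12 <= 0.0 or a3 <= 0.0:
        raise DomainError(f"component areas must be positive (a12={a12}, a3={a3})")
    if not (0.0 <= x3 <= 1.0):
        raise DomainError(f"x3={x3} outside [0, 1]")
    return a12 * (1.0 - x3) + a3 * x3


def _require_x3(ternary: IsothermRecord) -> float:
    if ternary.composition is None:
        raise ValidationError("ternary record carries no composition metadata")
    return float(ternary.composition.x3)


def _maybe_smooth(record: IsothermRecord, smoothing: Optional[tuple[int, int]]) -> IsothermRecord:
    return smooth_isotherm(record, *smoothing) if smoothing else record


def _usable_max(record: IsothermRecord) -> float:
    det = detect_collapse(record)
    return float(det.pi_coll) if det is not None else record.max_pressure


def excess_area_curve(
    membrane: IsothermRecord,
    drug: IsothermRecord,
    ternary: IsothermRecord,
    pi_grid: Sequence[float],
    *,
    smoothing: Optional[tuple[int, int]] = None,
) -> list[tuple[float, float]]:
    """Excess area A123 − A123_id at each grid pressure.

    A12 and A3 come from constant-pressure interpolation of the pure
    membrane and drug records, A123 from the ternary record; the ternary's
    composition metadata supplies X3.
    """
    x3 = _require_x3(ternary)
    mem = _maybe_smooth(membrane, smoothing)
    drg = _maybe_smooth(drug, smoothing)
    ter = _maybe_smooth(ternary, smoothing)
    out = []
    for pi in pi_grid:
        a12 = area_at_pressure(mem, float(pi))
        a3 = area_at_pressure(drg, float(pi))
        a123 = area_at_pressure(ter, float(pi))
        out.append((float(pi), a123 - ideal_area(a12, a3, x3)))
    return out


@dataclass(frozen=True)
class ExcessFreeEnergy:
    """ΔG_exc with bookkeeping of the low-pressure extrapolation."""

    dg_exc: float
    pi_target: float
    extrapolated_fraction: float
    lower_limit: str


def excess_free_energy(
    membrane: IsothermRecord,
    drug: IsothermRecord,
    ternary: IsothermRecord,
    pi_target: float,
    *,
    step: float = 0.25,
    lower_limit: str = "extrapolate",
    smoothing: Optional[tuple[int, int]] = None,
    details: bool = False,
):
    """Excess free energy of mixing at ``pi_target``, in J/mol.

    Trapezoidal integration of the excess area on a dense pressure grid
    (default step 0.25 mN/m) from the lower limit to ``pi_target``, scaled by
    the Avogadro constant (1 mN/m·Å² = 1e-23 J).  Exactly zero at X3 = 0 and
    X3 = 1 when the endpoint records are the pure components themselves.

    With ``details=True`` returns an :class:`ExcessFreeEnergy` carrying the
    fraction of the integral contributed by the extrapolated region below the
    records' common minimum pressure.
    """
    if lower_limit not in ("extrapolate", "common-min"):
        raise DomainError(f"unknown lower_limit {lower_limit!r}")
    x3 = _require_x3(ternary)
    mem = _maybe_smooth(membrane, smoothing)
    drg = _maybe_smooth(drug, smoothing)
    ter = _maybe_smooth(ternary, smoothing)
    for rec in (mem, drg, ter):
        cap = _usable_max(rec)
        if pi_target > cap + 1e-9:
            raise RangeError(
                f"pi_target={pi_target:g} mN/m above usable range (≤ {cap:.3f}) of record {rec.label!r}"
            )
    common_min = max(rec.min_pressure for rec in (mem, drg, ter))
    lower = 0.0 if lower_limit == "extrapolate" else common_min
    if pi_target <= lower:
        raise DomainError(f"pi_target={pi_target:g} must exceed the lower integration limit {lower:g}")
    n = max(2, int(np.ceil((pi_target - lower) / step)) + 1)
    grid = np.linspace(lower, pi_target, n)
    a12 = area_at_pressure(mem, grid)
    a3 = area_at_pressure(drg, grid)
    a123 = area_at_pressure(ter, grid)
    excess = a123 - (a12 * (1.0 - x3) + a3 * x3)
    dg = DG_SCALE * float(np.trapezoid(excess, grid))
    if not details:
        return dg
    extrap_frac = 0.0
    if lower_limit == "extrapolate" and common_min > lower:
        mask = grid <= common_min
        if mask.sum() >= 2:
            part = DG_SCALE * float(np.trapezoid(excess[mask], grid[mask]))
            denom = abs(dg) if dg != 0.0 else 1.0
            extrap_frac = abs(part) / denom
    return ExcessFreeEnergy(
        dg_exc=dg, pi_target=float(pi_target), extrapolated_fraction=extrap_frac, lower_limit=lower_limit
    )


@dataclass(frozen=True)
class CollapseComposition:
    """Collapse pressure per composition; span > 1 mN/m flags miscibility."""

    table: pd.DataFrame  # columns: x3, pi_coll (NaN when absent)
    composition_dependent: bool


def collapse_vs_composition(
    records: Iterable[tuple[float, IsothermRecord]],
    *,
    span_threshold: float = 1.0,
    detect_kwargs: Optional[dict] = None,
) -> CollapseComposition:
    """Collapse pressure against film composition.

    A composition-dependent collapse pressure (span above ``span_threshold``)
    is the classical miscibility signature: an immiscible film collapses at
    the pressure of its least stable pure component regardless of X3.
    """
    items = list(records)
    if len(items) < 3:
        raise ValidationError(f"need at least 3 compositions, got {len(items)}")
    kwargs = detect_kwargs or {}
    rows = []
    for x3, rec in items:
        det = detect_collapse(rec, **kwargs)
        rows.append({"x3": float(x3), "pi_coll": float(det.pi_coll) if det else np.nan})
    table = pd.DataFrame(rows).sort_values("x3", ignore_index=True)
    detected = table["pi_coll"].dropna()
    dependent = bool(len(detected) >= 2 and detected.max() - detected.min() > span_threshold)
    return CollapseComposition(table=table, composition_dependent=dependent)


@dataclass
class MixingAnalysisResult:
    """Full mixing table over (X3, π) plus summaries.

    ``table`` columns: x3, pi, A123, A123_id, excess_area, dG_exc.
    ``extremes``: per π, the X3 of extremal (largest-magnitude) ΔG_exc.
    ``collapse``: collapse-pressure-vs-composition miscibility evidence.
    """

    table: pd.DataFrame
    extremes: pd.DataFrame
    collapse: Optional[CollapseComposition]
    inputs: dict

    @property
    def deviation_signs(self) -> pd.DataFrame:
        """Sign of the area deviation per (x3, pi); −1 reads as affinity."""
        df = self.table[["x3", "pi", "excess_area"]].copy()
        df["sign"] = np.sign(df["excess_area"]).astype(int)
        return df


def analyze_mixing_series(
    membrane: IsothermRecord,
    drug: IsothermRecord,
    ternary_set: Iterable[IsothermRecord],
    pi_grid: Sequence[float],
    *,
    step: float = 0.25,
    lower_limit: str = "extrapolate",
    smoothing: Optional[tuple[int, int]] = None,
    membrane_ratio: Optional[float] = None,
) -> MixingAnalysisResult:
    """Additivity-rule and ΔG_exc analysis across a composition series.

    The endpoints X3 = 0 and X3 = 1 are always taken from the pure membrane
    and drug records (so their excess quantities are exactly zero); the
    ternary set must therefore contain interior compositions only, with
    distinct X3 values.
    """
    ternaries = list(ternary_set)
    x3s = [_require_x3(t) for t in ternaries]
    if len(set(x3s)) != len(x3s):
        raise ValidationError(f"duplicate X3 values in ternary set: {sorted(x3s)}")
    if any(x3 in (0.0, 1.0) for x3 in x3s):
        raise ValidationError("endpoint compositions X3=0 and X3=1 are taken from the pure records")

    ratio = membrane_ratio if membrane_ratio is not None else DEFAULT_MEMBRANE_RATIO
    mem_s = _maybe_smooth(membrane, smoothing)
    drg_s = _maybe_smooth(drug, smoothing)
    mem_end = IsothermRecord(
        area=mem_s.area, pressure=mem_s.pressure, composition=make_composition(0.0, ratio),
        temperature_c=membrane.temperature_c, label=membrane.label or "membrane", source=membrane.source,
    )
    drug_end = IsothermRecord(
        area=drg_s.area, pressure=drg_s.pressure, composition=make_composition(1.0, ratio),
        temperature_c=drug.temperature_c, label=drug.label or "drug", source=drug.source,
    )
    interior = [
        IsothermRecord(
            area=_maybe_smooth(t, smoothing).area, pressure=_maybe_smooth(t, smoothing).pressure,
            composition=t.composition, temperature_c=t.temperature_c, label=t.label, source=t.source,
        )
        for t in ternaries
    ]
    series = sorted([mem_end, *interior, drug_end], key=_require_x3)

    rows = []
    for ter in series:
        x3 = _require_x3(ter)
        for pi, exc in excess_area_curve(mem_end, drug_end, ter, pi_grid):
            a12 = area_at_pressure(mem_end, pi)
            a3 = area_at_pressure(drug_end, pi)
            a_id = ideal_area(a12, a3, x3)
            dg = excess_free_energy(mem_end, drug_end, ter, pi, step=step, lower_limit=lower_limit)
            rows.append(
                {"x3": x3, "pi": float(pi), "A123": a_id + exc, "A123_id": a_id,
                 "excess_area": exc, "dG_exc": dg}
            )
    table = pd.DataFrame(rows)

    absdg = table["dG_exc"].abs()
    idx = absdg.groupby(table["pi"]).idxmax()
    extremes = (
        table.loc[idx, ["pi", "x3", "dG_exc"]]
        .rename(columns={"x3": "x3_extremal"})
        .reset_index(drop=True)
    )

    try:
        collapse = collapse_vs_composition([(_require_x3(t), t) for t in series])
    except ValidationError:
        collapse = None

    inputs = {
        "membrane": membrane.label or membrane.source,
        "drug": drug.label or drug.source,
        "ternary": [t.label or t.source for t in ternaries],
    }
    return MixingAnalysisResult(table=table, extremes=extremes, collapse=collapse, inputs=inputs)


def fit_omega(
    x3_values: Sequence[float],
    dg_values: Sequence[float],
    g_integral: float,
) -> float:
    """Least-squares interaction amplitude ω from ΔG_exc(X3) data.

    Fits ΔG_exc = N·ω·X3·(1 − X3)·∫g dπ (the symmetric regular-solution
    shape) to measured values at one pressure; ``g_integral`` is ∫₀^π g(u) du
    of the pressure-shape function.  Closed-form weighted projection.
    """
    x = np.asarray(x3_values, dtype=float)
    d = np.asarray(dg_values, dtype=float)
    w = x * (1.0 - x)
    denom = float(np.sum(w * w))
    if denom == 0.0:
        raise DomainError("all compositions are endpoints; shape fit undefined")
    c = float(np.sum(w * d)) / denom
    return c / (DG_SCALE * g_integral)
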