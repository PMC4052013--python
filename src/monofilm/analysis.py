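"""Per-isotherm numerics.

Smoothing, compression modulus, phase-state classification, collapse
detection, constant-pressure area interpolation, and fluidization deltas.

The compression modulus C_s⁻¹ = −A·(dπ/dA) is the in-plane elastic modulus of
the film; its maximum classifies the monolayer's physical state (gaseous,
liquid-expanded, liquid-condensed, solid) following the conventional band
scheme.  Differentiation uses centered finite differences on the (optionally
smoothed) curve, with second-order one-sided stencils at the ends, and the
modulus is only reported below the detected collapse — across the collapse
plateau it is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import DomainError, InsufficientDataError, RangeError
from .records import CollapseInfo, IsothermRecord

__all__ = [
    "CompressionModulusCurve",
    "PhaseLabel",
    "DEFAULT_PHASE_BANDS",
    "smooth_isotherm",
    "compression_modulus",
    "max_compression_modulus",
    "classify_phase",
    "detect_collapse",
    "area_at_pressure",
    "fluidization_delta",
]

#: Band edges on max C_s⁻¹ (mN/m): gaseous < 12.5 ≤ LE < 100 ≤ LC ≤ 250 < solid.
DEFAULT_PHASE_BANDS = (12.5, 100.0, 250.0)

DEFAULT_SMOOTHING = (11, 3)  # (window, polyorder) typical of trough sampling density


@dataclass
class CompressionModulusCurve:
    """C_s⁻¹ samples against surface pressure, restricted to below collapse."""

    pressure: np.ndarray
    cs_inverse: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.cs_inverse = np.asarray(self.cs_inverse, dtype=float)
        if self.pressure.size and not np.all(np.diff(self.pressure) > 0.0):
            raise DomainError("compression-modulus pressures must be strictly increasing")
        if not np.all(np.isfinite(self.cs_inverse)):
            raise DomainError("compression modulus contains non-finite values")

    def at(self, pi: float) -> float:
        """Linear interpolation of C_s⁻¹ at a pressure inside the curve range."""
        lo, hi = float(self.pressure[0]), float(self.pressure[-1])
        if not (lo <= pi <= hi):
            raise RangeError(
                f"pi={pi} mN/m outside compression-modulus range [{lo:.3f}, {hi:.3f}]"
                f" of curve {self.source_label!r}"
            )
        return float(np.interp(pi, self.pressure, self.cs_inverse))

    def __len__(self) -> int:
        return int(self.pressure.size)


@dataclass(frozen=True)
class PhaseLabel:
    """Monolayer physical state inferred from the maximum compression modulus."""

    label: str
    cs_max: float
    pressure_at_max: float


def smooth_isotherm(record: IsothermRecord, window: int = 11, polyorder: int = 3) -> IsothermRecord:
    """Moving least-squares (local polynomial) smoothing of π as a function of A.

    Each pressure is replaced by the value at its own area of a polynomial of
    degree ``polyorder`` fitted to the ``window`` nearest points; endpoint
    windows shrink one-sidedly.  Unlike a classical convolution-based
    Savitzky–Golay filter this handles the non-uniform area grids of real
    isotherms, and reproduces polynomial segments of degree ≤ polyorder
    exactly.
    """
    n = record.n_points
    if window % 2 == 0 or window < 3 or window > n:
        raise DomainError(f"window={window} must be odd and within [3, {n}]")
    if polyorder >= window:
        raise DomainError(f"polyorder={polyorder} must be smaller than window={window}")
    half = window // 2
    a, p = record.area, record.pressure
    smoothed = np.empty_like(p)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        x = a[lo:hi] - a[i]
        y = p[lo:hi]
        deg = min(polyorder, x.size - 1)
        coeffs = np.polynomial.polynomial.polyfit(x, y, deg)
        smoothed[i] = coeffs[0]
    return record.replace_pressure(smoothed)


def detect_collapse(
    record: IsothermRecord,
    *,
    slope_fraction: float = 0.1,
    pressure_floor: float = 5.0,
    median_window: int = 15,
    min_history: int = 5,
    consecutive: int = 3,
    smoothing: Optional[tuple[int, int]] = None,
) -> Optional[CollapseInfo]:
    """Collapse-pressure detection by slope-drop against a trailing median.

    Scanning toward decreasing area, collapse is declared at the first point
    where |dπ/dA| falls below ``slope_fraction`` of the median of the
    preceding slopes (over the last ``median_window`` of them) while π exceeds
    ``pressure_floor`` — the onset of a plateau or kink.  ``consecutive``
    flat segments are required so a single noisy slope cannot trigger; noisy
    records should be smoothed first (pass ``smoothing=(window, polyorder)``).

    Returns ``None`` when no plateau exists (a valid outcome).
    """
    work = smooth_isotherm(record, *smoothing) if smoothing else record
    a, p = work.area, work.pressure
    slopes = np.abs(np.diff(p) / np.diff(a))
    history: list[float] = []
    run_start: Optional[int] = None
    run_len = 0
    method = f"slope<{slope_fraction:g}*trailing-median, floor {pressure_floor:g} mN/m"
    for j in range(slopes.size):
        triggered = False
        if len(history) >= min_history and p[j] > pressure_floor:
            med = float(np.median(history[-median_window:]))
            if med > 0.0 and slopes[j] < slope_fraction * med:
                triggered = True
        if triggered:
            if run_start is None:
                run_start = j
            run_len += 1
            if run_len >= consecutive:
                return CollapseInfo(pi_coll=float(p[run_start]), method=method, point_index=int(run_start))
        else:
            run_start = None
            run_len = 0
            history.append(float(slopes[j]))
    return None


def compression_modulus(
    record: IsothermRecord,
    *,
    smoothing: Optional[tuple[int, int]] = None,
    collapse: Union[str, CollapseInfo, None] = "auto",
) -> CompressionModulusCurve:
    """Compute the C_s⁻¹(π) curve of one isotherm.

    dπ/dA by centered finite differences (one-sided at the ends) on the
    optionally smoothed curve; C_s⁻¹ = −A·dπ/dA reported against pressure,
    restricted to below the collapse point (``collapse="auto"`` detects it,
    ``None`` disables truncation, or pass a :class:`CollapseInfo`).
    Non-monotone pressure samples (noise) are dropped so the curve is strictly
    increasing in π.
    """
    work = smooth_isotherm(record, *smoothing) if smoothing else record
    if collapse == "auto":
        det = detect_collapse(work)
    elif isinstance(collapse, CollapseInfo):
        det = collapse
    else:
        det = None
    end = det.point_index if det is not None else work.n_points
    a = work.area[:end]
    p = work.pressure[:end]
    if a.size < 5:
        raise InsufficientDataError(f"only {a.size} usable points below collapse; at least 5 required")
    dpda = np.gradient(p, a, edge_order=2)
    cs = -a * dpda
    # keep a strictly increasing pressure branch
    keep = [0]
    for i in range(1, p.size):
        if p[i] > p[keep[-1]]:
            keep.append(i)
    idx = np.asarray(keep)
    return CompressionModulusCurve(pressure=p[idx], cs_inverse=cs[idx], source_label=record.label)


def max_compression_modulus(curve: CompressionModulusCurve) -> tuple[float, float]:
    """(cs_max, pressure_at_max); ties broken toward lower pressure."""
    if len(curve) == 0:
        raise DomainError("empty compression-modulus curve")
    i = int(np.argmax(curve.cs_inverse))  # first occurrence → lowest pressure
    return float(curve.cs_inverse[i]), float(curve.pressure[i])


def classify_phase(
    cs_max: float,
    *,
    pressure_at_max: float = float("nan"),
    bands: Sequence[float] = DEFAULT_PHASE_BANDS,
) -> PhaseLabel:
    """Phase state from the maximum compression modulus.

    Default edges (mN/m): gaseous < 12.5 ≤ liquid-expanded < 100 ≤
    liquid-condensed ≤ 250 < solid.  Edges are configurable since the
    literature convention prints no universal values.
    """
    if cs_max < 0.0:
        raise DomainError(f"cs_max={cs_max} must be non-negative")
    g_le, le_lc, lc_s = bands
    if cs_max < g_le:
        label = "gaseous"
    elif cs_max < le_lc:
        label = "liquid-expanded"
    elif cs_max <= lc_s:
        label = "liquid-condensed"
    else:
        label = "solid"
    return PhaseLabel(label=label, cs_max=float(cs_max), pressure_at_max=float(pressure_at_max))


def area_at_pressure(
    record: IsothermRecord,
    pi_target: Union[float, np.ndarray],
    *,
    extrapolate_low: bool = True,
    collapse: Union[str, CollapseInfo, None] = "auto",
) -> Union[float, np.ndarray]:
    """Mean molecular area at constant surface pressure.

    Piecewise-linear interpolation of A against π on the compression branch
    below collapse; linear, never spline, to preserve monotonicity near
    kinks.  Below the lowest recorded pressure the branch is extrapolated
    linearly from its two lowest-pressure points (needed for integrals that
    start at π = 0); above the usable range a :class:`RangeError` is raised.
    Accepts a scalar or an array of target pressures.
    """
    pis = np.atleast_1d(np.asarray(pi_target, dtype=float))
    if np.any(pis < 0.0):
        raise DomainError("target pressures must be non-negative")
    if collapse == "auto":
        det = detect_collapse(record)
    elif isinstance(collapse, CollapseInfo):
        det = collapse
    else:
        det = None
    end = det.point_index + 1 if det is not None else record.n_points
    a = record.area[:end]
    p = record.pressure[:end]
    cap = float(det.pi_coll) if det is not None else float(p.max())
    if np.any(pis > cap + 1e-9):
        raise RangeError(
            f"pi={pis.max():g} mN/m above usable range (≤ {cap:.3f}) of record {record.label!r}"
        )
    order = np.argsort(p, kind="stable")
    ps, as_ = p[order], a[order]
    out = np.interp(pis, ps, as_)
    low = pis < ps[0]
    if np.any(low):
        if not extrapolate_low:
            raise RangeError(
                f"pi={pis.min():g} mN/m below recorded range (≥ {ps[0]:.3f}) of record {record.label!r}"
            )
        # Least-squares line through the low-pressure foot of the branch
        # (all points within 1 mN/m of the minimum, at least 2).  A two-point
        # extrapolation is exact for linear segments but blows up when noise
        # makes the two lowest pressures nearly coincide.
        k = max(2, int(np.searchsorted(ps, ps[0] + 1.0, side="right")))
        slope, intercept = np.polyfit(ps[:k], as_[:k], 1)
        out[low] = intercept + slope * pis[low]
    return float(out[0]) if np.isscalar(pi_target) or np.asarray(pi_target).ndim == 0 else out


def fluidization_delta(
    reference: CompressionModulusCurve,
    mixed: Iterable[tuple[float, CompressionModulusCurve]],
    pi_eval: float = 15.0,
) -> list[tuple[float, float]]:
    """ΔC_s⁻¹(X3) = C_s⁻¹_reference(π_eval) − C_s⁻¹_mixed(π_eval).

    Positive values mean the drug fluidizes the membrane (lowers its in-plane
    elastic modulus) at the evaluation pressure, 15 mN/m by default.
    """
    ref_value = reference.at(pi_eval)
    return [(float(x3), ref_value - curve.at(pi_eval)) for x3, curve in mixed]
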