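"""Synthetic monolayer data with closed-form oracles.

Pure components follow simple 2-D equations of state — ideal gas
(π·A = k_B·T), Volmer (π·(A − A0) = k_B·T), or a two-segment piecewise-linear
A(π) emulating liquid-expanded/condensed films — optionally terminated by a
collapse plateau and perturbed by seeded Gaussian pressure noise (the
Wilhelmy-plate resolution, ~0.1 mN/m, dominates real instrument noise, so
areas stay noise-free).

Mixed films are constructed directly in A(π) space,

    A(π, X3) = (1 − X3)·A_mem(π) + X3·A_drug(π) + ω·X3·(1 − X3)·g(π),

so the excess area that the thermodynamic analysis integrates is known
exactly: the symmetric (regular-solution) one-parameter law ω·X3·(1 − X3)
vanishes at both endpoints by construction, and g(π) shapes how the
non-ideality develops with pressure.  ``closed_form_dG`` provides the
matching analytic excess free energy for parameter-recovery tests.

Cell-death assay tables are drawn as independent multinomials over the four
staining categories per condition and replicate (~10,000 cells, 3 replicates
by default, matching the biological study design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_MEMBRANE_RATIO, DG_SCALE, THERMAL_CONSTANT_37C
from .errors import DomainError, RangeError, ValidationError
from .records import IsothermRecord, make_composition

__all__ = [
    "CollapseSpec",
    "EOSSpec",
    "GShape",
    "MixtureModelSpec",
    "generate_pure_isotherm",
    "generate_mixture_series",
    "closed_form_dG",
    "generate_assay_counts",
    "membrane_apc_preset",
    "assay_probability_preset",
    "ASSAY_CATEGORIES",
]


@dataclass(frozen=True)
class CollapseSpec:
    """Collapse plateau: onset pressure and residual plateau slope |dπ/dA|."""

    pi_coll: float
    plateau_slope: float = 0.02  # mN/m per Å²


@dataclass(frozen=True)
class EOSSpec:
    """One pure-component 2-D equation of state.

    model : {"ideal_gas", "volmer", "two_segment"}
    thermal_constant : k_B·T in mN/m·Å² (default 37 °C ≈ 428.21)
    a0 : Volmer excluded area, Å²
    lift_off_area, slope1, slope2, break_pressure : two-segment A(π)
        parameters — A(π) = lift_off_area − slope1·π up to the breakpoint,
        then continuing with slope2 (Å² per mN/m).
    """

    model: str = "two_segment"
    thermal_constant: float = THERMAL_CONSTANT_37C
    a0: float = 0.0
    lift_off_area: float = 98.0
    slope1: float = 1.8
    slope2: float = 0.48
    break_pressure: float = 7.0
    collapse: Optional[CollapseSpec] = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_constant <= 0.0:
            raise DomainError("thermal_constant must be positive")
        if self.a0 < 0.0:
            raise DomainError("Volmer excluded area a0 must be non-negative")
        if self.model not in ("ideal_gas", "volmer", "two_segment"):
            raise DomainError(f"unknown EOS model {self.model!r}")

    # --- closed forms ----------------------------------------------------
    def pressure_of_area(self, area: np.ndarray) -> np.ndarray:
        a = np.asarray(area, dtype=float)
        if self.model == "ideal_gas":
            return self.thermal_constant / a
        if self.model == "volmer":
            if np.any(a <= self.a0):
                raise DomainError(f"area grid enters the excluded area (≤ {self.a0} Å²)")
            return self.thermal_constant / (a - self.a0)
        # two_segment: invert piecewise-linear A(π)
        a_break = self.lift_off_area - self.slope1 * self.break_pressure
        pi = np.where(
            a >= a_break,
            (self.lift_off_area - a) / self.slope1,
            self.break_pressure + (a_break - a) / self.slope2,
        )
        return pi

    def area_of_pressure(self, pi: np.ndarray) -> np.ndarray:
        p = np.asarray(pi, dtype=float)
        if self.model == "ideal_gas":
            return self.thermal_constant / p
        if self.model == "volmer":
            return self.a0 + self.thermal_constant / p
        return np.where(
            p <= self.break_pressure,
            self.lift_off_area - self.slope1 * p,
            self.lift_off_area - self.slope1 * self.break_pressure - self.slope2 * (p - self.break_pressure),
        )

    def modulus_of_pressure(self, pi: np.ndarray) -> np.ndarray:
        """Analytic C_s⁻¹(π) = −A·dπ/dA — the oracle for the pipeline."""
        p = np.asarray(pi, dtype=float)
        if self.model == "ideal_gas":
            return p.copy()
        if self.model == "volmer":
            a = self.area_of_pressure(p)
            return a * self.thermal_constant / (a - self.a0) ** 2
        a = self.area_of_pressure(p)
        slope = np.where(p <= self.break_pressure, self.slope1, self.slope2)
        return a / slope


@dataclass(frozen=True)
class GShape:
    """Pressure-shape function g(π) of the excess-area law, with closed-form integral.

    kind : "constant" (g ≡ value), "linear" (g = slope·π + intercept), or
    "saturating" (g = 1 − exp(−π/tau)).
    """

    kind: str = "constant"
    value: float = 1.0
    slope: float = 1.0
    intercept: float = 0.0
    tau: float = 10.0

    def __call__(self, pi):
        p = np.asarray(pi, dtype=float)
        if self.kind == "constant":
            return np.full_like(p, self.value)
        if self.kind == "linear":
            return self.slope * p + self.intercept
        if self.kind == "saturating":
            return 1.0 - np.exp(-p / self.tau)
        raise DomainError(f"unknown g shape {self.kind!r}")

    def integral(self, pi: float) -> float:
        """∫₀^π g(u) du in closed form."""
        if self.kind == "constant":
            return self.value * pi
        if self.kind == "linear":
            return 0.5 * self.slope * pi**2 + self.intercept * pi
        if self.kind == "saturating":
            return pi - self.tau * (1.0 - np.exp(-pi / self.tau))
        raise DomainError(f"unknown g shape {self.kind!r}")


@dataclass(frozen=True)
class MixtureModelSpec:
    """Generator spec for a membrane + drug mixed-film family.

    ``collapse_span`` gives (π_coll at X3=0, π_coll at X3=1); the mixture
    collapse pressure interpolates linearly in X3 between them (set None for
    no collapse).  ``omega`` is the interaction amplitude in Å² (negative →
    attraction/condensation, the drug-affinity pattern).
    """

    membrane_eos: EOSSpec
    drug_eos: EOSSpec
    omega: float = -4.0
    g: GShape = field(default_factory=GShape)
    x3_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    membrane_ratio: float = DEFAULT_MEMBRANE_RATIO
    collapse_span: Optional[tuple] = None
    plateau_slope: float = 0.05  # mN/m per Å² on the appended plateau
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        xs = list(self.x3_grid)
        if len(set(xs)) != len(xs):
            raise ValidationError("x3_grid values must be distinct")
        if any(not (0.0 <= x <= 1.0) for x in xs):
            raise ValidationError("x3_grid values must lie in [0, 1]")

    def pi_coll(self, x3: float) -> Optional[float]:
        if self.collapse_span is None:
            return None
        p0, p1 = self.collapse_span
        return p0 + (p1 - p0) * x3

    def excess_area(self, pi, x3: float):
        """ΔA(π, X3) = ω·X3·(1 − X3)·g(π) — zero at both endpoints."""
        return self.omega * x3 * (1.0 - x3) * self.g(pi)


def membrane_apc_preset(
    *,
    omega: float = -4.0,
    noise_sigma: float = 0.1,
    seed: int = 0,
    collapse_span: Optional[tuple] = (47.0, 41.0),
    g: Optional[GShape] = None,
    x3_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> MixtureModelSpec:
    """Study-condition preset: condensed chol/POPC membrane + liquid APC drug.

    The membrane EOS is a two-segment film whose modulus at 15 mN/m is
    ~170 mN/m (liquid-condensed, collapse near 47 mN/m); the drug EOS is a
    more expanded film (modulus ~65 mN/m at 15 mN/m, collapse near 41 mN/m).
    Defaults: ω = −4 Å² (negative deviations of a few Å², as real mixed APC
    films show), pressure noise 0.1 mN/m (Wilhelmy-plate resolution),
    composition grid {0.1, 0.3, 0.5, 0.7, 0.9}.
    """
    membrane = EOSSpec(model="two_segment", lift_off_area=98.0, slope1=1.8, slope2=0.48, break_pressure=7.0)
    drug = EOSSpec(model="two_segment", lift_off_area=115.0, slope1=3.2, slope2=1.15, break_pressure=11.0)
    return MixtureModelSpec(
        membrane_eos=membrane,
        drug_eos=drug,
        omega=omega,
        g=g if g is not None else GShape(kind="constant", value=1.0),
        x3_grid=x3_grid,
        collapse_span=collapse_span,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def generate_pure_isotherm(
    spec: EOSSpec,
    area_grid: Sequence[float],
    *,
    composition=None,
    label: str = "",
) -> IsothermRecord:
    """One pure-component isotherm on a strictly decreasing area grid.

    Pressure from the closed-form EOS, collapse plateau applied above the
    collapse pressure, then seeded Gaussian noise on pressure.
    """
    a = np.asarray(area_grid, dtype=float)
    if a.ndim != 1 or a.size < 2 or not np.all(np.diff(a) < 0.0):
        raise DomainError("area grid must be 1-D and strictly decreasing")
    p = spec.pressure_of_area(a)
    if spec.collapse is not None:
        c = spec.collapse
        a_coll = float(spec.area_of_pressure(np.asarray(c.pi_coll)))
        mask = a < a_coll
        p = np.where(mask, c.pi_coll + c.plateau_slope * (a_coll - a), p)
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        p = p + rng.normal(0.0, spec.noise_sigma, size=p.size)
    return IsothermRecord.from_points(a, p, composition=composition, label=label, source="synthetic")


def pressure_spaced_area_grid(spec: EOSSpec, pi_min: float, pi_max: float, n: int, *, spacing: str = "geometric") -> np.ndarray:
    """Strictly decreasing area grid whose pressures span [pi_min, pi_max]."""
    if spacing == "geometric":
        pis = np.geomspace(pi_min, pi_max, n)
    elif spacing == "linear":
        pis = np.linspace(pi_min, pi_max, n)
    else:
        raise DomainError(f"unknown spacing {spacing!r}")
    return spec.area_of_pressure(pis)


def generate_mixture_series(
    spec: MixtureModelSpec,
    *,
    pi_min: float = 0.2,
    pi_max: float = 30.0,
    n_points: int = 240,
    plateau_points: int = 12,
) -> list[tuple[float, IsothermRecord]]:
    """Mixed-film records over the composition grid, endpoints included.

    Records are assembled in A(π) space on a common pressure grid and emitted
    as (area, pressure) tables.  Per composition the grid is truncated at the
    collapse law's π_coll(X3) and a short plateau is appended; noise is drawn
    from per-record streams spawned deterministically from the single spec
    seed, so equal configs are bit-identical.
    """
    if spec.collapse_span is None:
        for eos, name in ((spec.membrane_eos, "membrane"), (spec.drug_eos, "drug")):
            if eos.collapse is not None and pi_max > eos.collapse.pi_coll:
                raise RangeError(
                    f"pressure grid max {pi_max} mN/m exceeds the {name} component collapse "
                    f"at {eos.collapse.pi_coll} mN/m"
                )
    base_grid = np.linspace(pi_min, pi_max, n_points)
    x3s = sorted(set((0.0, 1.0)).union(float(x) for x in spec.x3_grid))
    streams = np.random.SeedSequence(spec.seed).spawn(len(x3s))
    out = []
    for x3, stream in zip(x3s, streams):
        pc = spec.pi_coll(x3)
        if pc is not None and pc <= pi_min:
            raise RangeError(f"collapse pressure {pc} mN/m at X3={x3} is below the grid minimum")
        grid = base_grid[base_grid <= pc] if pc is not None else base_grid
        a_m = spec.membrane_eos.area_of_pressure(grid)
        a_d = spec.drug_eos.area_of_pressure(grid)
        area = (1.0 - x3) * a_m + x3 * a_d + spec.excess_area(grid, x3)
        pressure = grid.copy()
        if pc is not None and pc < pi_max:
            # collapse plateau: area keeps falling, pressure nearly constant
            da = max(float(np.mean(-np.diff(area[-6:]))), 1e-3)
            steps = da * np.arange(1, plateau_points + 1)
            area = np.concatenate([area, area[-1] - steps])
            pressure = np.concatenate([pressure, pressure[-1] + spec.plateau_slope * steps])
        if spec.noise_sigma > 0.0:
            rng = np.random.default_rng(stream)
            pressure = pressure + rng.normal(0.0, spec.noise_sigma, size=pressure.size)
        rec = IsothermRecord.from_points(
            area,
            pressure,
            composition=make_composition(x3, spec.membrane_ratio),
            label=f"x3={x3:g}",
            source="synthetic",
        )
        out.append((x3, rec))
    return out


def closed_form_dG(spec: MixtureModelSpec, x3: float, pi: float) -> float:
    """Analytic excess free energy N·ω·X3·(1−X3)·∫₀^π g(u) du, in J/mol.

    The reference value against which the numerical pipeline is validated.
    """
    return DG_SCALE * spec.omega * x3 * (1.0 - x3) * spec.g.integral(pi)


# --------------------------------------------------------------------------
# Cell-death assay synthesis
# --------------------------------------------------------------------------

ASSAY_CATEGORIES = ("viable", "early_apoptotic", "late_apoptotic", "necrotic")


def generate_assay_counts(
    probabilities: dict,
    n_cells: int = 10_000,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial cell-death category counts per condition and replicate.

    ``probabilities`` maps a condition key ``(drug, dose_um, time_h)`` to the
    four category probabilities (viable, early, late, necrotic), which must
    sum to 1 within 1e-9.  Each condition × replicate is an independent
    multinomial draw over ~``n_cells`` cells from a single seeded stream.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key in sorted(probabilities):
        drug, dose, time = key
        probs = np.asarray(probabilities[key], dtype=float)
        if probs.size != 4 or np.any(probs < 0.0):
            raise ValidationError(f"condition {key}: need 4 non-negative probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"condition {key}: probabilities sum to {probs.sum()!r}, not 1 within 1e-9")
        for rep in range(1, replicates + 1):
            counts = rng.multinomial(n_cells, probs)
            rows.append(
                {"drug": drug, "dose_um": float(dose), "time_h": float(time), "replicate": rep,
                 **dict(zip(ASSAY_CATEGORIES, (int(c) for c in counts)))}
            )
    return pd.DataFrame(rows)


def assay_probability_preset() -> dict:
    """Study-condition category probabilities for the Du-145 assay emulation.

    Untreated control: ~94 % viable at 24 h.  Treated conditions follow the
    reported dose/time pattern: low necrosis throughout (~5–7 %), combined
    apoptosis rising with dose for ErPC (up to ~70 % at 50 µM/24 h), roughly
    dose-flat combined apoptosis for HePC at 24 h, and higher apoptosis for
    both drugs at 48 h.  Staurosporine (100 µM) is the positive control.
    """
    return {
        ("none", 0.0, 24.0): (0.94, 0.03, 0.02, 0.01),
        ("staurosporine", 100.0, 24.0): (0.15, 0.45, 0.35, 0.05),
        ("HePC", 12.5, 24.0): (0.59, 0.22, 0.14, 0.05),
        ("HePC", 25.0, 24.0): (0.59, 0.25, 0.11, 0.05),
        ("HePC", 50.0, 24.0): (0.51, 0.28, 0.16, 0.05),
        ("ErPC", 12.5, 24.0): (0.58, 0.23, 0.14, 0.05),
        ("ErPC", 25.0, 24.0): (0.45, 0.30, 0.20, 0.05),
        ("ErPC", 50.0, 24.0): (0.25, 0.40, 0.30, 0.05),
        ("none", 0.0, 48.0): (0.88, 0.05, 0.04, 0.03),
        ("staurosporine", 100.0, 48.0): (0.10, 0.45, 0.37, 0.08),
        ("HePC", 12.5, 48.0): (0.41, 0.27, 0.26, 0.06),
        ("HePC", 25.0, 48.0): (0.38, 0.30, 0.26, 0.06),
        ("HePC", 50.0, 48.0): (0.30, 0.37, 0.26, 0.07),
        ("ErPC", 12.5, 48.0): (0.41, 0.27, 0.26, 0.06),
        ("ErPC", 25.0, 48.0): (0.35, 0.30, 0.29, 0.06),
        ("ErPC", 50.0, 48.0): (0.23, 0.40, 0.30, 0.07),
    }
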