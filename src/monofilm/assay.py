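"""Cell-death quantification statistics.

Counts of viable / early-apoptotic / late-apoptotic / necrotic cells per
drug, dose, time and replicate are normalised to per-row percentages of the
total cell number, averaged over replicates, and combined apoptosis (early +
late together) is compared against the untreated control with a
Mann–Whitney U test on the replicate-level fractions.

With n = 3 independent replicates the exact (enumeration) null distribution
of U is very coarse: the smallest attainable one-sided p is 1/C(6,3)·… = 0.05
and the smallest two-sided p is 0.1.  ``mann_whitney_u`` therefore defaults
to the exact two-sided test for reporting, while ``dose_time_summary`` flags
significance with a one-sided ("treatment increases apoptosis") exact test at
p ≤ α — the only exact rule that can both detect a real effect at n = 3 and
keep the null flag rate at the nominal 5 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "CATEGORIES",
    "GroupComparison",
    "validate_cell_counts",
    "tally_fractions",
    "apoptotic_total",
    "mann_whitney_u",
    "dose_time_summary",
]

CATEGORIES = ("viable", "early_apoptotic", "late_apoptotic", "necrotic")
CONDITION_KEYS = ["drug", "dose_um", "time_h"]
EXACT_MAX_N = 12  # exact enumeration used when n1 + n2 ≤ 12 and no ties


def validate_cell_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-count table invariants; returns the table unchanged."""
    required = CONDITION_KEYS + ["replicate"] + list(CATEGORIES)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"cell-count table missing columns: {missing}")
    counts = table[list(CATEGORIES)]
    if (counts.to_numpy() < 0).any():
        raise ValidationError("cell counts must be non-negative")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[totals <= 0].tolist()
        raise ValidationError(f"rows {bad} have zero total cells")
    dup = table.duplicated(subset=CONDITION_KEYS + ["replicate"])
    if dup.any():
        raise ValidationError("replicate indices must be unique within a condition")
    return table


def tally_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean percentages of the four categories.

    Each row's counts are divided by its own total (× 100, so a row always
    sums to 100 %), then averaged over replicates within each
    (drug, dose, time) condition.
    """
    validate_cell_counts(table)
    df = table.copy()
    totals = df[list(CATEGORIES)].sum(axis=1).astype(float)
    for cat in CATEGORIES:
        df[f"{cat}_pct"] = df[cat] / totals * 100.0
    pct_cols = [f"{c}_pct" for c in CATEGORIES]
    out = df.groupby(CONDITION_KEYS, as_index=False)[pct_cols].mean()
    out["n_replicates"] = df.groupby(CONDITION_KEYS, as_index=False).size()["size"]
    return out


def apoptotic_total(fractions: pd.DataFrame) -> pd.DataFrame:
    """Combined apoptosis (early + late stages together), per condition."""
    out = fractions.copy()
    out["apoptotic_pct"] = out["early_apoptotic_pct"] + out["late_apoptotic_pct"]
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Mann–Whitney U comparison between two groups of observations."""

    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation"
    alternative: str
    n1: int
    n2: int


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> GroupComparison:
    """Mann–Whitney U test; U counts pairs (a, b) with a > b plus half the ties.

    ``method="auto"`` uses the exact null distribution (full enumeration over
    all C(n1+n2, n1) group labelings) when n1 + n2 ≤ 12 and the data are
    tie-free — at three replicates per group the normal approximation is
    unreliable — and otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise DomainError(f"unknown alternative {alternative!r}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        use_exact = (a.size + b.size <= EXACT_MAX_N) and not has_ties
    elif method == "exact":
        use_exact = True
    elif method in ("normal-approximation", "asymptotic"):
        use_exact = False
    else:
        raise DomainError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact" if use_exact else "asymptotic")
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if use_exact else "normal-approximation",
        alternative=alternative,
        n1=int(a.size),
        n2=int(b.size),
    )


def dose_time_summary(
    table: pd.DataFrame,
    control_drug: str = "none",
    *,
    alpha: float = 0.05,
    alternative: str = "greater",
    correction: str = "none",
) -> pd.DataFrame:
    """Category percentages, combined apoptosis and significance per condition.

    Each treated (drug, dose, time) condition's replicate-level combined
    apoptosis fractions are compared against the untreated control at the
    same time point; a condition is flagged significant when the Mann–Whitney
    p-value is ≤ ``alpha`` (optionally Holm-corrected across conditions).
    Both the per-category percentages and the combined metric are emitted.
    Single-replicate comparisons are reported with a low-power warning rather
    than rejected.
    """
    validate_cell_counts(table)
    if correction not in ("none", "holm"):
        raise DomainError(f"unknown correction {correction!r}")
    df = table.copy()
    totals = df[list(CATEGORIES)].sum(axis=1).astype(float)
    df["apoptotic_frac"] = (df["early_apoptotic"] + df["late_apoptotic"]) / totals

    if not (df["drug"] == control_drug).any():
        raise ValidationError(f"control condition {control_drug!r} absent from the table")

    summary = apoptotic_total(tally_fractions(table))
    rows = []
    for _, cond in summary.iterrows():
        drug, dose, time = cond["drug"], cond["dose_um"], cond["time_h"]
        entry = cond.to_dict()
        if drug == control_drug:
            entry.update({"u_statistic": np.nan, "p_value": np.nan, "method": "", "significant": False,
                          "warning": ""})
            rows.append(entry)
            continue
        ctrl = df[(df["drug"] == control_drug) & (df["time_h"] == time)]
        if ctrl.empty:
            ctrl = df[df["drug"] == control_drug]
        treated = df[(df["drug"] == drug) & (df["dose_um"] == dose) & (df["time_h"] == time)]
        cmp = mann_whitney_u(
            treated["apoptotic_frac"].to_numpy(), ctrl["apoptotic_frac"].to_numpy(), alternative=alternative
        )
        warning = ""
        if min(cmp.n1, cmp.n2) < 2:
            warning = "low power: a group has a single replicate"
        entry.update({"u_statistic": cmp.u_statistic, "p_value": cmp.p_value, "method": cmp.method,
                      "significant": False, "warning": warning})
        rows.append(entry)
    out = pd.DataFrame(rows)

    tested = out["p_value"].notna()
    if correction == "holm" and tested.any():
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests(out.loc[tested, "p_value"], alpha=alpha, method="holm")
        out.loc[tested, "p_adjusted"] = p_adj
        out.loc[tested, "significant"] = reject
    else:
        out.loc[tested, "significant"] = out.loc[tested, "p_value"] <= alpha
    out["significant"] = out["significant"].astype(bool)
    return out
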