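"""Screen-level group statistics.

Treatment-group means are standardized by subtracting the DMSO vehicle
control mean per parameter, giving behavioral deltas in percentage points
(degrees for the turn measures).  Each treatment is compared to the vehicle
group with Welch's unequal-variance t-test, Bonferroni-corrected for the
number of compounds screened (the reference screen compared 190 drugs to
vehicle, so significance tiers are 0.05/190, 0.01/190 and 0.001/190).
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_profile import PARAMETERS
from .errors import InputError

DEFAULT_N_COMPARISONS = 190
HEATMAP_VMIN = -10.0
HEATMAP_VMAX = 5.0


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mA - mB) / sqrt(sA^2/nA + sB^2/nB) with Welch-Satterthwaite degrees
    of freedom; suited to groups with unequal n and unequal variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InputError("Welch's t-test needs at least 2 observations per group")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        # identical constant groups: no evidence of a difference
        return WelchResult(0.0, float(na + nb - 2), 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise InputError("number of comparisons must be >= 1")
    return alpha / m


def significance_stars(p: float, m: int = DEFAULT_N_COMPARISONS) -> str:
    """Bonferroni-tiered stars: * / ** / *** at 0.05, 0.01, 0.001 over m."""
    if np.isnan(p):
        return ""
    for stars, alpha in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
        if p < bonferroni_threshold(alpha, m):
            return stars
    return ""


def dmso_standardize(summary: pd.DataFrame, reference: str = "DMSO") -> pd.DataFrame:
    """Subtract the vehicle-control mean from every treatment mean.

    ``summary`` is the long per-group summary (treatment, parameter, mean,
    sd, n).  Returns the screen matrix: treatments x 25 parameters of
    DMSO-subtracted means in percentage points; the reference row is zero by
    construction.
    """
    ref_rows = summary[summary["treatment"] == reference]
    if ref_rows.empty or (ref_rows["n"] < 1).all():
        raise InputError(f"reference group {reference!r} absent or empty")
    means = summary.pivot(index="treatment", columns="parameter", values="mean")
    means = means[PARAMETERS]
    return means.sub(means.loc[reference], axis=1)


def test_treatments_against_reference(
    profiles: pd.DataFrame,
    treatment_map: pd.DataFrame,
    reference: str = "DMSO",
) -> pd.DataFrame:
    """Welch p-values per (treatment, parameter) against the reference larvae.

    Uses non-excluded larvae; NaN where either group has fewer than two
    non-null values.
    """
    merged = profiles.merge(treatment_map[["plate_id", "well_id", "treatment"]],
                            on=["plate_id", "well_id"], how="left")
    alive = merged[~merged["excluded"].astype(bool)]
    ref = alive[alive["treatment"] == reference]
    if len(ref) < 2:
        raise InputError(f"reference group {reference!r} has fewer than 2 larvae")
    treatments = sorted(alive["treatment"].dropna().unique())
    pvals = pd.DataFrame(index=treatments, columns=PARAMETERS, dtype=float)
    for treatment, grp in alive.groupby("treatment"):
        for param in PARAMETERS:
            a = grp[param].dropna().to_numpy()
            b = ref[param].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                pvals.loc[treatment, param] = welch_t(a, b).p
    pvals.index.name = "treatment"
    return pvals


def value_to_hex(value: float, vmin: float = HEATMAP_VMIN, vmax: float = HEATMAP_VMAX
                 ) -> str:
    """Linear red-to-blue color for a profile value, clipped to [vmin, vmax]."""
    if np.isnan(value):
        return "#FFFFFF"
    frac = (np.clip(value, vmin, vmax) - vmin) / (vmax - vmin)
    red = np.array([255, 0, 0])
    blue = np.array([0, 0, 255])
    r, g, b = np.round(red + frac * (blue - red)).astype(int)
    return f"#{r:02X}{g:02X}{b:02X}"


def profile_matrix_export(
    matrix: pd.DataFrame,
    path: str | Path,
    pvalues: pd.DataFrame | None = None,
    m: int = DEFAULT_N_COMPARISONS,
) -> pd.DataFrame:
    """Write the color-coded behavioral-profile TSV.

    Long format: one row per (treatment, parameter) with the standardized
    value, the Welch p-value (if supplied), Bonferroni-tier stars, and the
    hex color on the red(-10) .. blue(+5) heatmap scale.
    """
    if matrix.empty:
        raise InputError("empty screen matrix")
    records = []
    for treatment in matrix.index:
        for param in matrix.columns:
            value = matrix.loc[treatment, param]
            p = np.nan
            if pvalues is not None and treatment in pvalues.index:
                p = pvalues.loc[treatment, param]
            records.append({
                "treatment": treatment,
                "parameter": param,
                "value": value,
                "p": p,
                "significance": significance_stars(p, m) if pvalues is not None else "",
                "color": value_to_hex(value),
            })
    out = pd.DataFrame.from_records(records)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return out
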