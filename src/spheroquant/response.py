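"""Treatment-response statistics for spheroid plate assays.

Works on long-format plate tables (one row per well) with columns
``well, condition, dose_nM, replicate, lum, assay`` as produced by
luminescence plate readers:

* relative viability — ATP-type luminescence normalized to the mean of the
  vehicle-control wells (no blank subtraction by default, available via
  ``blank_label``),
* cytotoxicity index — enzyme-release luminescence expressed as percent of
  the detergent-lysis maximum after background subtraction,
* four-parameter logistic (4PL) dose–response fits with an explicit
  "no IC50" verdict when the response is not well described by a sigmoid:
  the optimizer fails, the fitted IC50 falls outside the tested dose range,
  or the fit's R² is below a configurable cutoff (0.8 by default).  An IC50
  is never extrapolated beyond the tested concentrations — a rule that
  matters for 3D cultures, whose shallow dose responses often cannot
  support an IC50 at all,
* Pearson correlation between spheroid diameter and viability, for
  validating (or rejecting) diameter as an imaging surrogate for viability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import PlateError

__all__ = [
    "PLATE_COLUMNS",
    "DoseResponse",
    "CorrelationResult",
    "validate_plate",
    "relative_viability",
    "cytotoxicity_index",
    "four_param_logistic",
    "fit_dose_response",
    "diameter_viability_correlation",
    "simulate_viability_plate",
]

PLATE_COLUMNS = ("well", "condition", "dose_nM", "replicate", "lum", "assay")

VEHICLE_LABEL = "vehicle"
LYSIS_LABEL = "lysis"


def validate_plate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise PlateError(f"plate table missing columns: {missing}")
    if (table["lum"] < 0).any():
        raise PlateError("luminescence must be >= 0")
    return table


def relative_viability(
    table: pd.DataFrame,
    vehicle_label: str = VEHICLE_LABEL,
    blank_label: str | None = None,
):
    """Per-well and per-dose relative viability.

    Relative viability = well luminescence / mean vehicle-control
    luminescence (after optional blank subtraction of cell-free wells when
    ``blank_label`` is given).  The per-dose summary reports mean ± standard
    deviation over replicates.

    Returns ``(per_well, per_dose)`` DataFrames.
    """
    table = validate_plate(table)
    work = table[table["assay"] == "viability"].copy()
    blank = 0.0
    if blank_label is not None:
        blank_rows = work[work["condition"] == blank_label]
        if blank_rows.empty:
            raise PlateError(f"no blank wells labeled {blank_label!r}")
        blank = blank_rows["lum"].mean()
        work = work[work["condition"] != blank_label]
    controls = work[work["condition"] == vehicle_label]
    if controls.empty:
        raise PlateError(f"no vehicle-control wells labeled {vehicle_label!r}")
    ctrl_mean = controls["lum"].mean() - blank
    if ctrl_mean <= 0:
        raise PlateError("degenerate control: vehicle mean is not positive")

    per_well = work.copy()
    per_well["rel_viability"] = (per_well["lum"] - blank) / ctrl_mean
    treated = per_well[per_well["condition"] != vehicle_label]
    per_dose = (
        treated.groupby(["condition", "dose_nM"], as_index=False)["rel_viability"]
        .agg(mean_viability="mean", sd_viability="std", n="count")
        .sort_values(["condition", "dose_nM"], ignore_index=True)
    )
    return per_well, per_dose


def cytotoxicity_index(
    table: pd.DataFrame,
    lysis_label: str = LYSIS_LABEL,
    background_label: str = VEHICLE_LABEL,
):
    """Per-well and per-dose cytotoxicity as percent of maximum lysis.

    Index = 100 × (signal − background mean) / (lysis mean − background
    mean), clipped at 0.  Background wells are untreated (vehicle) wells of
    the cytotoxicity assay; the lysis wells are the detergent-lysed maximum-
    release controls.
    """
    table = validate_plate(table)
    work = table[table["assay"] == "cytotoxicity"].copy()
    lysis = work[work["condition"] == lysis_label]
    background = work[work["condition"] == background_label]
    if lysis.empty:
        raise PlateError(f"no maximum-lysis wells labeled {lysis_label!r}")
    if background.empty:
        raise PlateError(f"no background wells labeled {background_label!r}")
    bg_mean = background["lum"].mean()
    lysis_mean = lysis["lum"].mean()
    if lysis_mean <= bg_mean:
        raise PlateError("degenerate lysis control: max release <= background")

    treated = work[~work["condition"].isin([lysis_label, background_label])].copy()
    treated["cytotoxicity_pct"] = np.clip(
        100.0 * (treated["lum"] - bg_mean) / (lysis_mean - bg_mean), 0.0, None
    )
    per_dose = (
        treated.groupby(["condition", "dose_nM"], as_index=False)["cytotoxicity_pct"]
        .agg(mean_cytotoxicity="mean", sd_cytotoxicity="std", n="count")
        .sort_values(["condition", "dose_nM"], ignore_index=True)
    )
    return treated, per_dose


@dataclass(frozen=True)
class DoseResponse:
    """4PL fit result, or an explicit "no IC50" verdict with its reason."""

    doses: np.ndarray
    viabilities: np.ndarray
    top: float | None = None
    bottom: float | None = None
    hill: float | None = None
    ic50: float | None = None
    r_squared: float | None = None
    no_ic50: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product–moment correlation with sample size and p-value."""

    r: float
    n: int
    p_value: float


def four_param_logistic(
    dose: np.ndarray, top: float, bottom: float, log10_ic50: float, hill: float
) -> np.ndarray:
    """Descending 4PL: y = bottom + (top - bottom) / (1 + (dose/IC50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / 10.0**log10_ic50) ** hill)


def fit_dose_response(
    doses: Sequence[float],
    viabilities: Sequence[float],
    r2_threshold: float = 0.8,
) -> DoseResponse:
    """Fit a 4PL dose–response curve, or declare that no IC50 exists.

    ``doses`` may contain repeated values — fitting individual replicate
    wells rather than per-dose means is preferred (and is what curve-fitting
    packages such as Prism do by default), since with only a handful of dose
    means a 4-parameter sigmoid can chase noise and masquerade as a real
    response.  Dose 0 (vehicle) rows are excluded from the fit — they serve
    only for normalization.  "No IC50" is reported, with the reason, when
    the optimizer fails, the fitted IC50 lies outside the tested dose range,
    or R² < ``r2_threshold``; an IC50 is never extrapolated.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    keep = doses > 0
    doses, y = doses[keep], y[keep]
    if np.unique(doses).size < 4:
        raise PlateError("insufficient doses: >= 4 distinct nonzero doses required")

    log_d = np.log10(doses)
    p0 = (float(y.max()), float(y.min()), float(np.median(log_d)), 1.0)
    bounds = (
        [0.0, 0.0, log_d.min() - 2.0, 0.1],
        [max(2.0 * y.max(), 1e-6), max(2.0 * y.max(), 1e-6), log_d.max() + 2.0, 10.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            four_param_logistic, doses, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        return DoseResponse(
            doses=doses, viabilities=y, no_ic50=True, reason="optimizer failed"
        )
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    ic50 = 10.0**log_ic50
    fitted = four_param_logistic(doses, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    base = dict(
        doses=doses,
        viabilities=y,
        top=top,
        bottom=bottom,
        hill=hill,
        r_squared=r2,
    )
    if not doses.min() <= ic50 <= doses.max():
        return DoseResponse(
            **base, no_ic50=True, reason="fitted IC50 outside tested dose range"
        )
    if r2 < r2_threshold:
        return DoseResponse(
            **base,
            no_ic50=True,
            reason=f"response not well-defined sigmoidal (R² = {r2:.3f} < {r2_threshold})",
        )
    return DoseResponse(**base, ic50=ic50)


def diameter_viability_correlation(
    diameters: Sequence[float], viabilities: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation between spheroid diameter and relative viability."""
    d = np.asarray(diameters, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.size != v.size:
        raise PlateError("diameter and viability arrays must have equal length")
    if d.size < 3:
        raise PlateError("at least 3 pairs required")
    if np.std(d) == 0 or np.std(v) == 0:
        raise PlateError("degenerate input: zero variance")
    res = stats.pearsonr(d, v)
    return CorrelationResult(r=float(res.statistic), n=d.size, p_value=float(res.pvalue))


def simulate_viability_plate(
    doses: Sequence[float],
    ic50: float,
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    n_replicates: int = 3,
    cv: float = 0.1,
    control_lum: float = 1e5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format viability plate from a known 4PL truth.

    Each well's luminescence is the 4PL expectation times ``control_lum``
    with multiplicative Gaussian noise of coefficient of variation ``cv``
    (10% by default — typical replicate scatter for luminescence endpoints),
    ``n_replicates`` wells per dose plus vehicle controls.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        lum = control_lum * max(0.0, 1.0 + cv * rng.standard_normal())
        rows.append(
            {
                "well": f"V{rep}",
                "condition": VEHICLE_LABEL,
                "dose_nM": 0.0,
                "replicate": rep,
                "lum": lum,
                "assay": "viability",
            }
        )
    for i, dose in enumerate(doses):
        expect = four_param_logistic(
            np.array([dose]), top, bottom, np.log10(ic50), hill
        )[0]
        for rep in range(n_replicates):
            lum = control_lum * max(0.0, expect * (1.0 + cv * rng.standard_normal()))
            rows.append(
                {
                    "well": f"D{i}R{rep}",
                    "condition": "drug",
                    "dose_nM": float(dose),
                    "replicate": rep,
                    "lum": lum,
                    "assay": "viability",
                }
            )
    return pd.DataFrame(rows)
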