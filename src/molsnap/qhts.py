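"""Quantitative HTS dose-response analysis.

Raw plate reader signals are normalized to % Activity against in-plate
controls:

    % Activity = (V_compound - V_dmso) / (V_pos - V_dmso) x 100

so the DMSO-only median maps to 0% and the positive-control median to 100%.
Antagonist-mode plates use the same formula with their own controls; the
series carries its mode as metadata only. Concentration-response series are
fit to the four-parameter logistic (Hill) model

    y(x) = bottom + (top - bottom) / (1 + (ic50 / x)^slope)

and summarized by IC50 and the maximum response over the fitted range.
PubChem-style integer activity scores (0-100) are binarized at 40.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .chem_prep import classify_score


class DegenerateNormalizationError(ValueError):
    """Positive-control and DMSO medians coincide; % Activity is undefined."""


@dataclass(frozen=True)
class WellTriplet:
    """Raw compound well signal with its plate control medians."""

    v_compound: float
    v_dmso: float  # median of DMSO-only wells
    v_pos: float  # median of positive-control wells


@dataclass
class DoseResponseSeries:
    concentrations: np.ndarray  # molar, strictly increasing
    responses: np.ndarray  # % Activity
    mode: str = "agonist"  # agonist | antagonist (metadata only)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class HillFit:
    """Four-parameter logistic fit result."""

    bottom: float
    top: float
    ic50: float  # molar
    hill_slope: float
    converged: bool
    max_response: float = float("nan")  # max fitted response over the data range
    residual_sd: float = float("nan")
    message: str = ""

    def predict(self, x) -> np.ndarray:
        return hill4(np.asarray(x, dtype=float), self.bottom, self.top,
                     self.ic50, self.hill_slope)


def percent_activity(w: WellTriplet) -> float:
    """Plate-normalized % Activity of one compound well.

    Unbounded: super-maximal wells exceed 100 and inhibitory wells go
    negative.
    """
    denom = w.v_pos - w.v_dmso
    if denom == 0:
        raise DegenerateNormalizationError(
            "positive-control median equals DMSO median")
    return (w.v_compound - w.v_dmso) / denom * 100.0


def hill4(x: np.ndarray, bottom: float, top: float, ic50: float,
          slope: float) -> np.ndarray:
    """Four-parameter logistic response at concentration(s) x (molar)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** slope)


def _hill4_logc50(x, bottom, top, log10_ic50, slope):
    # fitting parameterization: IC50 on a log scale keeps it positive and
    # conditions the Jacobian across decades of concentration
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log10_ic50 - np.log10(x))))


def fit_hill4(series: DoseResponseSeries, flat_tol: float = 1e-6) -> HillFit:
    """Least-squares fit of the 4PL model to one concentration-response series.

    Requires at least 5 points. Non-convergence and unidentifiable (flat)
    curves are reported through ``converged=False``; the function never
    raises for bad data.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 concentration points for a 4PL fit")
    x = series.concentrations
    y = series.responses

    span = float(np.max(y) - np.min(y))
    scale = max(abs(float(np.max(y))), abs(float(np.min(y))), 1.0)
    if span <= flat_tol * scale:
        # flat curve: top == bottom, IC50 unidentifiable
        return HillFit(bottom=float(np.mean(y)), top=float(np.mean(y)),
                       ic50=float("nan"), hill_slope=float("nan"),
                       converged=False, max_response=float(np.max(y)),
                       message="flat response; ic50 unidentifiable")

    logx = np.log10(x)
    p0 = (float(np.min(y)), float(np.max(y)), float(np.mean(logx)), 1.0)
    lo = (-np.inf, -np.inf, logx[0] - 3.0, -20.0)
    hi = (np.inf, np.inf, logx[-1] + 3.0, 20.0)
    try:
        popt, _ = curve_fit(_hill4_logc50, x, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except Exception as exc:  # optimizer failure is a result, not a crash
        return HillFit(bottom=float("nan"), top=float("nan"), ic50=float("nan"),
                       hill_slope=float("nan"), converged=False,
                       max_response=float(np.max(y)), message=str(exc))
    bottom, top, log_ic50, slope = popt
    fitted = _hill4_logc50(x, *popt)
    resid_sd = float(np.sqrt(np.mean((y - fitted) ** 2)))
    # slope pinned at a bound means the sigmoid degenerated to a step
    identifiable = abs(top - bottom) > flat_tol * scale and abs(slope) < 20.0 - 1e-6
    return HillFit(bottom=float(bottom), top=float(top),
                   ic50=float(10.0 ** log_ic50), hill_slope=float(slope),
                   converged=bool(identifiable),
                   max_response=float(np.max(fitted)), residual_sd=resid_sd)


def classify_activity_score(score: int) -> str:
    """Binary activity call from a 0-100 integer score: active iff >= 40.

    Scores 1-39 are inconclusive in the three-class scheme but count as
    inactive here; see :func:`score_class3` for the preserved metadata.
    """
    return classify_score(score)


def score_class3(score: int) -> str:
    """Three-class scheme: 0 inactive, 1-39 inconclusive, 40-100 active."""
    if not (0 <= score <= 100):
        raise ValueError(f"activity score must be in [0, 100], got {score}")
    if score == 0:
        return "inactive"
    if score < 40:
        return "inconclusive"
    return "active"


def correct_plate_drift(values: np.ndarray, plate_index: np.ndarray,
                        dmso_start: float, dmso_end: float,
                        n_plates: int) -> np.ndarray:
    """Optional per-plate drift correction from bracketing DMSO-only plates.

    The DMSO baseline measured on compound-free plates run before and after
    the compound stack is linearly interpolated over plate index and
    subtracted.
    """
    values = np.asarray(values, dtype=float)
    plate_index = np.asarray(plate_index, dtype=float)
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    frac = plate_index / max(n_plates - 1, 1)
    baseline = dmso_start + (dmso_end - dmso_start) * frac
    return values - baseline


# ---------------------------------------------------------------------------
# CSV I/O


def read_well_csv(path: str | Path) -> dict[str, WellTriplet]:
    """Read well-level data (plate, well, role, value) into per-plate triplets.

    role is one of compound / dmso / pos; control medians are taken per
    plate. Returns one WellTriplet per plate keyed by plate id, using the
    median compound well value for v_compound.
    """
    df = pd.read_csv(path)
    out: dict[str, WellTriplet] = {}
    for plate, grp in df.groupby("plate"):
        roles = grp.groupby("role")["value"].median()
        missing = {"compound", "dmso", "pos"} - set(roles.index)
        if missing:
            raise ValueError(f"plate {plate}: missing roles {sorted(missing)}")
        out[str(plate)] = WellTriplet(v_compound=float(roles["compound"]),
                                      v_dmso=float(roles["dmso"]),
                                      v_pos=float(roles["pos"]))
    return out


def read_dose_response_csv(path: str | Path) -> dict[str, DoseResponseSeries]:
    """Read dose-response series (compound_id, concentration, response[, mode])."""
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("compound_id"):
        grp = grp.sort_values("concentration")
        mode = str(grp["mode"].iloc[0]) if "mode" in grp else "agonist"
        out[str(cid)] = DoseResponseSeries(
            concentrations=grp["concentration"].to_numpy(),
            responses=grp["response"].to_numpy(), mode=mode)
    return out


def write_hill_fits_csv(fits: dict[str, HillFit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "bottom", "top", "ic50", "hill_slope",
                    "max_response", "converged"])
        for cid, f in fits.items():
            w.writerow([cid, f.bottom, f.top, f.ic50, f.hill_slope,
                        f.max_response, f.converged])
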