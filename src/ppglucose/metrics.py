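"""Glucose prediction accuracy metrics and Clarke error grid analysis.

Regression metrics follow the standard definitions used for glucose
monitors: MAE, MSE, RMSE, MARD (mean absolute relative difference,
in percent) and the coefficient of determination R^2.

The Clarke error grid partitions the (reference, predicted) plane into
five zones of increasing clinical risk:

    A  within 20% of the reference, or both readings < 70 mg/dL —
       clinically accurate;
    B  benign deviations that would not change treatment;
    C  overcorrection errors: predictions past 70-180 band limits that
       would trigger unnecessary treatment
       (ref in [70, 290] and pred >= ref + 110, or
        ref in [130, 180] and pred <= 7/5*ref - 182);
    D  dangerous failures to detect hypo- or hyperglycemia
       (ref >= 240 with pred in [70, 180], or ref <= 70 with pred in
        [70, 180]);
    E  erroneous treatment: hypo read as hyper or vice versa
       (ref <= 70 with pred >= 180, or ref >= 180 with pred <= 70).

Zones are evaluated in the order A, E, C, D, else B — the conventional
rule ordering for this grid; in particular a point exactly on the 20%
boundary belongs to A (ties at the A/B edge resolve to the less severe
zone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairedReadings",
    "CEGReport",
    "regression_metrics",
    "clarke_zone",
    "ceg_report",
]

ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class PairedReadings:
    """Reference and predicted BGL arrays in mg/dL, equal length."""

    reference: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        pred = np.asarray(self.predicted, dtype=float)
        if ref.shape != pred.shape or ref.ndim != 1 or ref.size < 1:
            raise ValueError("reference and predicted must be equal-length 1-D arrays")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "predicted", pred)

    def __len__(self) -> int:
        return self.reference.size


@dataclass(frozen=True)
class CEGReport:
    """Per-pair Clarke zones and per-zone percentages (sum to 100)."""

    zones: np.ndarray
    percentages: dict[str, float]

    @property
    def clinically_acceptable_pct(self) -> float:
        """Zone A + B share — the usual acceptability headline."""
        return self.percentages["A"] + self.percentages["B"]


def regression_metrics(pr: PairedReadings) -> dict[str, float]:
    """MAE, MSE, RMSE, MARD (%) and R^2 for paired readings.

    MARD requires strictly positive references. R^2 is NaN when the
    reference has zero variance (SST = 0 leaves it undefined).
    """
    ref, pred = pr.reference, pr.predicted
    err = pred - ref
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    if np.any(ref <= 0):
        raise ValueError("MARD needs strictly positive reference values")
    mard = float(100.0 * np.mean(np.abs(err) / ref))
    sst = float(np.sum((ref - ref.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")
    return {"MAE": mae, "MSE": mse, "RMSE": rmse, "MARD": mard, "R2": r2}


def _zone_masks(ref: np.ndarray, pred: np.ndarray) -> dict[str, np.ndarray]:
    a = (np.abs(pred - ref) <= 0.2 * ref) | ((ref < 70) & (pred < 70))
    e = ((ref <= 70) & (pred >= 180)) | ((ref >= 180) & (pred <= 70))
    c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= 1.4 * ref - 182)
    )
    d = ((ref >= 240) & (pred >= 70) & (pred <= 180)) | (
        (ref <= 70) & (pred >= 70) & (pred <= 180)
    )
    return {"A": a, "E": e, "C": c, "D": d}


def clarke_zone(ref: float, pred: float) -> str:
    """Clarke zone of a single (reference, predicted) pair, mg/dL."""
    if ref <= 0 or pred <= 0:
        raise ValueError("glucose readings must be positive")
    masks = _zone_masks(np.asarray([ref], dtype=float), np.asarray([pred], dtype=float))
    for zone in ("A", "E", "C", "D"):
        if masks[zone][0]:
            return zone
    return "B"


def ceg_report(pr: PairedReadings) -> CEGReport:
    """Clarke error grid analysis of paired readings.

    Every pair is assigned exactly one zone; percentages sum to 100.
    """
    ref, pred = pr.reference, pr.predicted
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ValueError("glucose readings must be positive")
    masks = _zone_masks(ref, pred)
    zones = np.full(ref.shape, "B", dtype="<U1")
    unassigned = np.ones(ref.shape, dtype=bool)
    for zone in ("A", "E", "C", "D"):
        take = masks[zone] & unassigned
        zones[take] = zone
        unassigned &= ~take
    pct = {z: float(100.0 * np.mean(zones == z)) for z in ZONES}
    return CEGReport(zones=zones, percentages=pct)
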