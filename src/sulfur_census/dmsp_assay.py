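"""Headspace-DMS quantification of DMSP standing stock.

Sediment (or polymetallic-sulfide) samples are lysed in alkali, converting
DMSP quantitatively to DMS, which is measured by headspace GC. A linear
calibration curve of DMS standards maps instrument response to nmol DMS;
amounts below the instrument detection limit (0.015 nmol by default) are
censored. Concentrations are amount per sample mass (nmol g⁻¹) or volume
(nmol L⁻¹). No correction is made for endogenous DMS, so reported values
are total DMSP plus endogenous DMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CalibrationInputError,
    DegenerateCalibrationError,
    DivisionGuardError,
    GroupingError,
    UnitMismatchError,
)

DETECTION_LIMIT_NMOL = 0.015

SEDIMENT_UNIT = "nmol/g"
SEAWATER_UNIT = "nmol/L"

BYSS_ENVIRONMENTS = frozenset({"YS-sediment", "BS-sediment"})
OTSP_ENVIRONMENTS = frozenset({"OT-sediment", "OT-polymetallic-sulfide"})


@dataclass
class CalibrationCurve:
    """Least-squares line mapping DMS amount (nmol) to instrument response."""

    standards: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    detection_limit: float = DETECTION_LIMIT_NMOL


@dataclass
class SampleMeasurement:
    """One site's DMSP determination (replicate responses or a reported mean)."""

    site_id: str
    environment: str
    mass: float  # grams for sediment, litres for seawater
    replicate_responses: list[float] = field(default_factory=list)
    dmsp_mean: float | None = None  # nmol/g or nmol/L
    dmsp_sd: float | None = None
    unit: str = SEDIMENT_UNIT


@dataclass
class Quantification:
    """Replicate-level DMSP quantification for one sample."""

    concentrations: list[float]  # per replicate, censored replicates excluded
    censored: list[bool]  # per replicate
    mean: float | None
    sd: float | None

    @property
    def below_detection(self) -> bool:
        return all(self.censored)


def fit_calibration(
    standards: list[tuple[float, float]],
    detection_limit: float = DETECTION_LIMIT_NMOL,
) -> CalibrationCurve:
    """Ordinary least squares of instrument response on known DMS amount."""
    if len(standards) < 3:
        raise CalibrationInputError(f"{len(standards)} standards; at least 3 required")
    amounts = np.array([s[0] for s in standards], dtype=float)
    responses = np.array([s[1] for s in standards], dtype=float)
    if np.unique(amounts).size < 2:
        raise CalibrationInputError("calibration standards have no spread in amount")
    result = stats.linregress(amounts, responses)
    return CalibrationCurve(
        standards=list(standards),
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue) ** 2,
        detection_limit=detection_limit,
    )


def invert_response(response: float, curve: CalibrationCurve) -> float:
    """DMS amount (nmol) implied by an instrument response."""
    if curve.slope == 0:
        raise DegenerateCalibrationError("calibration slope is zero")
    return (response - curve.intercept) / curve.slope


def quantify_dmsp(
    responses: float | list[float],
    curve: CalibrationCurve,
    mass: float,
) -> Quantification:
    """Convert replicate responses to a DMSP concentration (nmol per unit mass).

    Amounts below the curve's detection limit are censored and excluded from
    the mean/sd summary; a sample whose replicates are all censored reports
    ``below_detection``.
    """
    if mass <= 0:
        raise DivisionGuardError(f"mass {mass} must be positive")
    if isinstance(responses, (int, float)):
        responses = [float(responses)]
    concentrations: list[float] = []
    censored: list[bool] = []
    for response in responses:
        amount = invert_response(response, curve)
        if amount < curve.detection_limit:
            censored.append(True)
        else:
            censored.append(False)
            concentrations.append(amount / mass)
    if concentrations:
        mean = float(np.mean(concentrations))
        sd = float(np.std(concentrations, ddof=1)) if len(concentrations) > 1 else 0.0
    else:
        mean = sd = None
    return Quantification(concentrations=concentrations, censored=censored, mean=mean, sd=sd)


def environment_ratio(
    measurements: list[SampleMeasurement],
    group_a: frozenset | set,
    group_b: frozenset | set,
    allow_unit_bridge: bool = False,
) -> float:
    """Fold ratio of mean per-site DMSP between two environment groups.

    Per-site means (not pooled replicates) enter each group's arithmetic
    mean. Mixing per-gram and per-litre sites in one ratio raises unless
    ``allow_unit_bridge`` is set.
    """
    def group_values(labels) -> list[tuple[float, str]]:
        return [
            (m.dmsp_mean, m.unit)
            for m in measurements
            if m.environment in labels and m.dmsp_mean is not None
        ]

    values_a = group_values(group_a)
    values_b = group_values(group_b)
    if not values_a or not values_b:
        raise GroupingError("both environment groups must contain measured sites")
    units = {u for _, u in values_a} | {u for _, u in values_b}
    if len(units) > 1 and not allow_unit_bridge:
        raise UnitMismatchError(
            f"groups mix units {sorted(units)}; pass allow_unit_bridge=True to force"
        )
    mean_a = sum(v for v, _ in values_a) / len(values_a)
    mean_b = sum(v for v, _ in values_b) / len(values_b)
    if mean_b <= 0:
        raise GroupingError("denominator group has non-positive mean")
    return mean_a / mean_b


def load_table1() -> list[SampleMeasurement]:
    """Packaged per-site DMSP summary of the study's sampling stations.

    Sediment and polymetallic-sulfide sites carry measured mean ± sd in
    nmol g⁻¹; the three seawater stations carry literature totals
    (dissolved + particulate DMSP) in nmol L⁻¹.
    """
    with resources.files("sulfur_census").joinpath("data/table1_dmsp.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    out = []
    for r in frame.itertuples():
        out.append(
            SampleMeasurement(
                site_id=str(r.site_id),
                environment=str(r.environment),
                mass=1.0,
                dmsp_mean=float(r.dmsp_mean),
                dmsp_sd=float(r.dmsp_sd),
                unit=str(r.unit),
            )
        )
    return out


def summarize_replicates(values: list[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of replicate concentrations."""
    if not values:
        raise GroupingError("no replicate values to summarize")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd
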