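"""Calibration, LOD/LOQ, method-validation statistics and product verdicts.

Marker response is modelled as ordinary least squares ``area = a * amount
+ b`` over a calibrated range; detection limits follow the S/N >= 3 and
S/N >= 10 conventions as LOD = 3*sigma/|a| and LOQ = 10*sigma/|a| where
sigma is the noise standard deviation in area units. A product is
"fake" when no marker is detected, "adulteration" when any grass-EBN
marker is detected, and "authentic" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "NoiseEstimate",
    "Quantification",
    "ProductRecord",
    "ClassificationResult",
    "ValidationStats",
    "fit_calibration",
    "lod_loq",
    "quantify",
    "relative_sd",
    "validation_stats",
    "spike_recovery",
    "classify_product",
]

REGRESSOR_PROTEIN = "total_protein_mg"
REGRESSOR_RAW_MATERIAL = "raw_material_mg"


@dataclass(frozen=True)
class CalibrationCurve:
    """One marker's external-calibration line ``area = slope * amount + intercept``."""

    marker_code: str
    slope: float
    intercept: float
    r_squared: float
    amount_range: tuple[float, float]
    lod: float = 0.0
    loq: float = 0.0
    regressor: str = REGRESSOR_PROTEIN

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"R^2 must lie in [0, 1], got {self.r_squared}")
        if not self.amount_range[0] > 0:
            raise ValueError("calibrated range lower bound must be positive")
        if self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")

    def forward(self, amount_mg: float) -> float:
        """Expected peak area at a given analyte amount."""
        return self.slope * amount_mg + self.intercept

    def with_limits(self, lod: float, loq: float) -> "CalibrationCurve":
        return replace(self, lod=lod, loq=loq)


@dataclass(frozen=True)
class NoiseEstimate:
    """Noise standard deviation in area units for one marker's EIC."""

    sigma: float
    source: str = "blank_replicates"  # or "baseline_window"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @classmethod
    def from_blanks(cls, blank_areas: Sequence[float]) -> "NoiseEstimate":
        if len(blank_areas) < 2:
            raise ValueError("need >= 2 blank replicates to estimate noise")
        return cls(float(np.std(blank_areas, ddof=1)), "blank_replicates")


def fit_calibration(
    points: Sequence[tuple[float, float]],
    marker_code: str,
    regressor: str = REGRESSOR_PROTEIN,
) -> CalibrationCurve:
    """Ordinary least squares fit of peak area on analyte amount.

    Requires at least three distinct amounts; a constant design is
    degenerate and rejected.
    """
    if len(points) < 3:
        raise ValueError("calibration requires >= 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(set(x.tolist())) < 2:
        raise ValueError("degenerate calibration design: all amounts equal")
    if len(set(x.tolist())) < 3:
        raise ValueError("calibration requires >= 3 distinct amounts")
    fit = stats.linregress(x, y)
    ss_res = float(np.sum((y - (fit.slope * x + fit.intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(
        marker_code,
        float(fit.slope),
        float(fit.intercept),
        min(r2, 1.0),
        (float(x.min()), float(x.max())),
        regressor=regressor,
    )


def lod_loq(curve: CalibrationCurve, noise: NoiseEstimate) -> tuple[float, float]:
    """Detection and quantitation limits from S/N >= 3 and S/N >= 10.

    LOD = 3*sigma/|slope| and LOQ = 10*sigma/|slope| — the amounts whose
    expected net signal reaches 3x and 10x the noise SD; LOQ/LOD = 10/3.
    """
    if curve.slope == 0:
        raise ValueError("zero slope: limits undefined")
    lod = 3.0 * noise.sigma / abs(curve.slope)
    loq = 10.0 * noise.sigma / abs(curve.slope)
    return lod, loq


@dataclass(frozen=True)
class Quantification:
    """Inverse-calibration result for one marker in one sample."""

    marker_code: str
    amount_mg: float
    detected: bool
    in_range: bool


def quantify(area: float, curve: CalibrationCurve) -> Quantification:
    """Invert the calibration line; amounts below the LOD are not-detected.

    The LOD boundary is inclusive: an estimate exactly at the LOD counts
    as detected. Estimates outside the calibrated range are flagged.
    """
    amount = (area - curve.intercept) / curve.slope
    detected = amount >= curve.lod and amount > 0
    if curve.lod == 0:
        detected = amount > 0
    in_range = curve.amount_range[0] <= amount <= curve.amount_range[1]
    return Quantification(curve.marker_code, amount, detected, in_range)


def relative_sd(values: Sequence[float]) -> float:
    """RSD = 100 * SD / mean (sample SD, ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("RSD requires >= 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class ValidationStats:
    """Repeatability and accuracy summary for one marker assay."""

    intra_day_rsd: float
    inter_day_rsd: float
    recoveries: dict[str, tuple[float, float]] = field(default_factory=dict)
    # level label -> (mean recovery %, RSD of recovery %)


def spike_recovery(
    unspiked: float, spiked_measurements: Sequence[float], amount_spiked: float
) -> tuple[float, float]:
    """Recovery % = 100 * (measured_spiked - measured_unspiked) / spiked.

    Returns the mean recovery and its RSD over the replicates.
    """
    if amount_spiked <= 0:
        raise ValueError("spiked amount must be positive")
    recoveries = [100.0 * (m - unspiked) / amount_spiked for m in spiked_measurements]
    if len(recoveries) == 1:
        return recoveries[0], 0.0
    return float(np.mean(recoveries)), relative_sd(recoveries)


def validation_stats(
    replicates_by_day: Mapping[str, Sequence[float]],
    spikes: Optional[Mapping[str, tuple[float, Sequence[float], float]]] = None,
) -> ValidationStats:
    """Intra-/inter-day repeatability plus optional spike-recovery levels.

    Intra-day RSD is the mean of within-day RSDs; inter-day RSD is the
    RSD of the day means. ``spikes`` maps level label ->
    (unspiked measurement, spiked replicate measurements, amount spiked).
    """
    if not replicates_by_day:
        raise ValueError("need at least one day of replicates")
    for day, reps in replicates_by_day.items():
        if len(reps) < 2:
            raise ValueError(f"day {day!r}: >= 2 replicates required")
    intra = float(np.mean([relative_sd(reps) for reps in replicates_by_day.values()]))
    day_means = [float(np.mean(reps)) for reps in replicates_by_day.values()]
    inter = relative_sd(day_means) if len(day_means) >= 2 else 0.0
    recoveries: dict[str, tuple[float, float]] = {}
    for level, (unspiked, spiked_meas, amount) in (spikes or {}).items():
        recoveries[level] = spike_recovery(unspiked, spiked_meas, amount)
    return ValidationStats(intra, inter, recoveries)


@dataclass(frozen=True)
class ProductRecord:
    """Per-product marker quantities; None encodes "none detected" (ND)."""

    product_id: str
    amounts: Mapping[str, Optional[float]]  # marker code -> mg (or mg/mL), None = ND
    product_type: str = "instant product"
    origin: str = ""

    def __post_init__(self) -> None:
        for code, amount in self.amounts.items():
            if amount is not None and amount < 0:
                raise ValueError(f"{self.product_id}: negative amount for {code}")

    def detected(self, code: str) -> bool:
        if code not in self.amounts:
            raise KeyError(f"{self.product_id}: no detection status for marker {code!r}")
        return self.amounts[code] is not None


VERDICT_AUTHENTIC = "authentic"
VERDICT_ADULTERATION = "adulteration"
VERDICT_FAKE = "fake"


@dataclass(frozen=True)
class ClassificationResult:
    product_id: str
    verdict: str


def classify_product(
    record: ProductRecord,
    white_markers: Iterable[str] = ("W2",),
    ebn_markers: Iterable[str] = ("E7",),
    grass_markers: Iterable[str] = ("G1",),
) -> ClassificationResult:
    """Three-way verdict from marker detection status only.

    All markers not detected -> fake (no EBN); any grass-EBN marker
    detected -> adulteration (grass EBN present, regardless of white
    content); otherwise -> authentic (white-EBN material only). The
    verdict depends on detection flags, never on the magnitudes.
    """
    white = [record.detected(c) for c in white_markers]
    ebn = [record.detected(c) for c in ebn_markers]
    grass = [record.detected(c) for c in grass_markers]
    if not any(white + ebn + grass):
        return ClassificationResult(record.product_id, VERDICT_FAKE)
    if any(grass):
        return ClassificationResult(record.product_id, VERDICT_ADULTERATION)
    return ClassificationResult(record.product_id, VERDICT_AUTHENTIC)
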