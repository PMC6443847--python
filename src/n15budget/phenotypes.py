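"""Yield-component and canopy arithmetic.

Covers the phenotype side of the luxury-N story: the size of the luxury
reserve (difference in whole-plant N at silking between vegetative N
treatments at equal biomass), spikelet abortion, mean kernel weight, and
leaf-area estimation from ruler or dry-weight calibrations used to track
green leaf area through grain fill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LeafCalibrationPair",
    "LeafAreaModel",
    "PhenotypeError",
    "luxury_reserve",
    "abortion_fraction",
    "kernel_weight",
    "fit_leaf_area_model",
    "estimate_leaf_area",
    "green_leaf_area_series",
    "round_half_away_from_zero",
]


class PhenotypeError(ValueError):
    """Invalid input to a phenotype operation."""


def round_half_away_from_zero(x: float, ndigits: int = 0) -> float:
    """Report-layer rounding: halves round away from zero (so 0.5 → 1,
    −0.5 → −1), unlike Python's banker's rounding."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def luxury_reserve(uptake_high: float, uptake_low: float) -> float:
    """Luxury N reserve (g N plant⁻¹): whole-plant N at silking under the
    high-N vegetative treatment minus the low-N treatment, meaningful when
    biomass is equivalent.  Negative values (low > high) are returned with
    a warning."""
    if uptake_high < 0 or uptake_low < 0:
        raise PhenotypeError("N uptakes must be >= 0")
    reserve = uptake_high - uptake_low
    if reserve < 0:
        warnings.warn(
            f"luxury reserve is negative ({reserve:.3g} g): low-N uptake "
            "exceeds high-N uptake; check treatment ordering",
            stacklevel=2,
        )
    return reserve


def abortion_fraction(spikelet_count: float, kernel_number: float) -> float:
    """Percent of spikelets that failed to become kernels:
    100·(1 − kernel_number/spikelet_count).

    ``kernel_number`` may be a treatment-mean (non-integer).  A kernel
    number exceeding the spikelet count yields a negative fraction, which
    is returned raw with a warning.  Integer rounding is left to the
    report layer."""
    if spikelet_count <= 0:
        raise PhenotypeError(f"spikelet_count must be > 0; got {spikelet_count!r}")
    if kernel_number < 0:
        raise PhenotypeError(f"kernel_number must be >= 0; got {kernel_number!r}")
    if kernel_number > spikelet_count:
        warnings.warn(
            "kernel number exceeds spikelet count; abortion fraction is negative",
            stacklevel=2,
        )
    return 100.0 * (1.0 - kernel_number / spikelet_count)


def kernel_weight(grain_mass: float, kernel_number: float) -> float:
    """Mean kernel weight (mg kernel⁻¹): 1000·grain_mass/kernel_number."""
    if kernel_number <= 0:
        raise PhenotypeError(f"kernel_number must be > 0; got {kernel_number!r}")
    if grain_mass < 0:
        raise PhenotypeError(f"grain_mass must be >= 0; got {grain_mass!r}")
    return 1000.0 * grain_mass / kernel_number


@dataclass(frozen=True)
class LeafCalibrationPair:
    """One leaf measured both by ruler/balance and by an area meter."""

    length: float  # cm
    width: float  # cm
    dry_weight: float  # g
    area: float  # cm^2, from the area meter

    def __post_init__(self) -> None:
        for name in ("length", "width", "dry_weight", "area"):
            if getattr(self, name) <= 0:
                raise PhenotypeError(f"{name} must be > 0")


@dataclass(frozen=True)
class LeafAreaModel:
    """A fitted leaf-area regression.

    ``dimensions`` mode predicts area = k·length·width (shape-factor form,
    optionally with an intercept); ``dry_weight`` mode predicts
    area = slope·weight + intercept.
    """

    mode: str  # "dimensions" | "dry_weight"
    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, predictor: float) -> float:
        return self.slope * predictor + self.intercept


def fit_leaf_area_model(
    pairs: Sequence[LeafCalibrationPair],
    mode: str = "dimensions",
    with_intercept: bool | None = None,
) -> LeafAreaModel:
    """Fit a leaf-area regression by ordinary least squares.

    ``dimensions`` regresses area on the length×width product through the
    origin by default (the classic shape-factor form for maize, k ≈ 0.75);
    ``dry_weight`` regresses area on dry weight with an intercept by
    default.  ``with_intercept`` overrides either default.
    """
    if mode not in ("dimensions", "dry_weight"):
        raise PhenotypeError(f"unknown mode {mode!r}")
    if len(pairs) < 3:
        raise PhenotypeError(f"need >= 3 calibration pairs; got {len(pairs)}")
    if with_intercept is None:
        with_intercept = mode == "dry_weight"

    if mode == "dimensions":
        x = np.array([p.length * p.width for p in pairs], dtype=float)
    else:
        x = np.array([p.dry_weight for p in pairs], dtype=float)
    y = np.array([p.area for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise PhenotypeError("constant predictor: cannot fit regression")

    if with_intercept:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    residuals = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(residuals**2)) / ss_tot
    if slope <= 0:
        raise PhenotypeError(f"fitted slope is non-positive ({slope:.3g})")
    return LeafAreaModel(
        mode=mode, slope=slope, intercept=intercept, r_squared=r2, n=len(pairs)
    )


def estimate_leaf_area(
    model: LeafAreaModel,
    *,
    length: float | None = None,
    width: float | None = None,
    dry_weight: float | None = None,
) -> float:
    """Predict leaf area (cm²) from a fitted model.

    ``dimensions`` models need ``length`` and ``width``; ``dry_weight``
    models need ``dry_weight``.  Predictions that would be negative are
    clamped to zero with a warning."""
    if model.mode == "dimensions":
        if length is None or width is None or dry_weight is not None:
            raise PhenotypeError("dimensions model needs length= and width= only")
        if length <= 0 or width <= 0:
            raise PhenotypeError("length and width must be > 0")
        predictor = length * width
    else:
        if dry_weight is None or length is not None or width is not None:
            raise PhenotypeError("dry_weight model needs dry_weight= only")
        if dry_weight <= 0:
            raise PhenotypeError("dry_weight must be > 0")
        predictor = dry_weight
    area = model.predict(predictor)
    if area < 0:
        warnings.warn(
            f"predicted leaf area {area:.3g} cm^2 is negative; clamped to 0",
            stacklevel=2,
        )
        area = 0.0
    return area


def green_leaf_area_series(
    initial_area: float,
    senesced_weights: Sequence[float],
    weight_model: LeafAreaModel,
) -> list[float]:
    """Green leaf area through grain fill (cm² per timepoint).

    ``senesced_weights`` are the dry weights of leaf material newly
    senesced at each timepoint; each increment is converted to area with
    the dry-weight regression and subtracted cumulatively from
    ``initial_area``.  The series is non-increasing and floored at zero
    (with a warning when the floor binds)."""
    if initial_area <= 0:
        raise PhenotypeError(f"initial_area must be > 0; got {initial_area!r}")
    if weight_model.mode != "dry_weight":
        raise PhenotypeError("green_leaf_area_series needs a dry_weight model")
    series: list[float] = []
    remaining = initial_area
    floored = False
    for w in senesced_weights:
        if w < 0:
            raise PhenotypeError(f"senesced weight must be >= 0; got {w!r}")
        lost = weight_model.predict(w) if w > 0 else 0.0
        remaining -= max(lost, 0.0)
        if remaining < 0:
            remaining = 0.0
            floored = True
        series.append(remaining)
    if floored:
        warnings.warn(
            "cumulative senesced area exceeded the initial leaf area; "
            "series floored at 0",
            stacklevel=2,
        )
    return series
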