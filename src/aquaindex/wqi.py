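"""Weighted arithmetic water quality index (WAWQI).

The index aggregates per-parameter quality ratings

    q_i = 100 * (v_i - v_io) / (s_i - v_io)

with unit weights inversely proportional to the permissible standards,

    w_i = k / s_i,   k = 1 / sum_i(1 / s_i),

into

    WQI = sum_i(q_i * w_i) / sum_i(w_i).

Because the k normalisation makes the weights sum to one, WQI is a convex
combination of the ratings: 0 when every parameter sits at its ideal value,
100 when every parameter sits at its permissible standard. Scores are graded
into five status bands (excellent/good/poor/very poor/unsuitable).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InputError, MissingDataError, StandardsValidationError
from .standards import ParameterSpec, StandardsTable

__all__ = [
    "Status",
    "WaterSample",
    "WeightVector",
    "WQIResult",
    "unit_weights",
    "quality_rating",
    "compute_wqi",
    "classify_wqi",
    "ward_wqi",
]

logger = logging.getLogger(__name__)


class Status(str, enum.Enum):
    """WQI grade bands."""

    EXCELLENT = "excellent"
    GOOD = "good"
    POOR = "poor"
    VERY_POOR = "very_poor"
    UNSUITABLE = "unsuitable"


#: Canonical zone labels of the three-zone sampling design.
ZONES = ("north", "south_west", "south_east")


@dataclass
class WaterSample:
    """One measured sample: ward/zone identifiers, optional WGS84 coordinates
    (x = longitude, y = latitude, decimal degrees), and the measured values
    v_i keyed by parameter name."""

    sample_id: str
    ward: str
    zone: str
    values: dict[str, float]
    x: Optional[float] = None
    y: Optional[float] = None

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise InputError(f"sample {self.sample_id}: {name} is not finite")
            if name == "ph":
                if not 0.0 < v < 14.0:
                    raise InputError(f"sample {self.sample_id}: pH {v} outside (0, 14)")
            elif v < 0:
                raise InputError(f"sample {self.sample_id}: negative {name} ({v})")
        for axis in ("x", "y"):
            c = getattr(self, axis)
            if c is not None and not math.isfinite(c):
                raise InputError(f"sample {self.sample_id}: non-finite coordinate {axis}")


@dataclass(frozen=True)
class WeightVector:
    """Unit weights w_i = k/s_i and the normalising constant k."""

    weights: Mapping[str, float]
    k: float

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise StandardsValidationError("unit weights must all be positive")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise StandardsValidationError(f"unit weights sum to {total!r}, expected 1")


@dataclass(frozen=True)
class WQIResult:
    """A WQI score with the ratings and weights it was built from.

    ``mode`` records whether signed or absolute quality ratings were used.
    """

    entity_id: str
    score: float
    ratings: Mapping[str, float]
    weights: WeightVector
    status: Status
    mode: str = "signed"

    def recompute_score(self) -> float:
        """Re-derive the score from the stored ratings and weights."""
        return _weighted_mean(self.ratings, self.weights.weights)


def _weighted_mean(ratings: Mapping[str, float], weights: Mapping[str, float]) -> float:
    """Weighted mean of the ratings, centred on the first rating so that a
    constant rating vector (all at ideal, all at standard) is reproduced
    exactly rather than to within summation round-off."""
    names = list(weights)
    q0 = ratings[names[0]]
    num = math.fsum(weights[p] * (ratings[p] - q0) for p in names)
    den = math.fsum(weights[p] for p in names)
    return q0 + num / den


def unit_weights(
    standards: StandardsTable, subset: Optional[Sequence[str]] = None
) -> WeightVector:
    """Unit weights over the table (or a subset of its parameters).

    w_p = k / s_p with k = 1 / sum_p(1 / s_p); by construction the weights sum
    to one, so parameters with stricter (smaller) permissible standards weigh
    more.
    """
    table = standards if subset is None else standards.subset(subset)
    for spec in table:
        if spec.standard_value <= 0:
            raise StandardsValidationError(
                f"{spec.name}: standard_value must be > 0 for unit weights"
            )
    k = 1.0 / sum(1.0 / spec.standard_value for spec in table)
    weights = {spec.name: k / spec.standard_value for spec in table}
    return WeightVector(weights=weights, k=k)


def quality_rating(value: float, spec: ParameterSpec, mode: str = "signed") -> float:
    """Quality rating q_i relating a measured value to the permissible standard.

    ``signed`` is the literal formula 100*(v - v_io)/(s - v_io): values on the
    far side of the ideal from the standard (e.g. acidic pH against an upper
    standard) rate negative. ``absolute`` uses magnitudes of both deviations,
    so any departure from the ideal raises the rating.
    """
    if not math.isfinite(value):
        raise InputError(f"{spec.name}: value must be finite")
    if mode == "signed":
        return 100.0 * (value - spec.ideal_value) / (spec.standard_value - spec.ideal_value)
    if mode == "absolute":
        return 100.0 * abs(value - spec.ideal_value) / abs(spec.standard_value - spec.ideal_value)
    raise InputError(f"unknown quality-rating mode {mode!r}")


def classify_wqi(score: float) -> Status:
    """Map a WQI score to its grade band.

    Bands are half-open with inclusive upper bounds: (-inf, 25] excellent,
    (25, 50] good, (50, 75] poor, (75, 100] very poor, (100, inf) unsuitable.
    Negative scores (possible under signed ratings) grade excellent with a
    logged warning.
    """
    if not math.isfinite(score):
        raise InputError(f"WQI score must be finite, got {score!r}")
    if score < 0:
        logger.warning("negative WQI score %.4g graded as excellent", score)
        return Status.EXCELLENT
    if score <= 25:
        return Status.EXCELLENT
    if score <= 50:
        return Status.GOOD
    if score <= 75:
        return Status.POOR
    if score <= 100:
        return Status.VERY_POOR
    return Status.UNSUITABLE


def compute_wqi(
    values: Mapping[str, float],
    standards: StandardsTable,
    mode: str = "signed",
    missing_policy: str = "strict",
    entity_id: str = "",
) -> WQIResult:
    """Aggregate measured values into a WQI score and grade.

    ``strict`` requires every parameter of the table to be present;
    ``renormalize`` recomputes the unit weights over the parameters actually
    present (not a rescaling of the full-table weights).
    """
    if not values:
        raise InputError("values must be non-empty")
    if missing_policy not in ("strict", "renormalize"):
        raise InputError(f"unknown missing_policy {missing_policy!r}")

    present = [name for name in standards.names if name in values]
    if missing_policy == "strict":
        missing = [name for name in standards.names if name not in values]
        if missing:
            raise MissingDataError(
                f"{entity_id or 'input'}: missing parameter(s) {', '.join(missing)}"
            )
    if not present:
        raise MissingDataError(
            f"{entity_id or 'input'}: no parameter overlaps the standards table"
        )

    wv = unit_weights(standards, subset=present)
    ratings = {
        name: quality_rating(values[name], standards[name], mode=mode) for name in present
    }
    score = _weighted_mean(ratings, wv.weights)
    return WQIResult(
        entity_id=entity_id,
        score=score,
        ratings=ratings,
        weights=wv,
        status=classify_wqi(score),
        mode=mode,
    )


def ward_wqi(
    samples: Iterable[WaterSample],
    standards: StandardsTable,
    mode: str = "signed",
    missing_policy: str = "strict",
) -> list[WQIResult]:
    """Per-ward WQI: parameter-wise arithmetic means over the ward's samples,
    then one index per ward from the mean vector.

    Returned in first-appearance ward order; ``entity_id`` is the ward id.
    A parameter missing from some of a ward's samples is averaged over the
    samples that do carry it; a parameter missing from all of them falls under
    ``missing_policy``.
    """
    by_ward: dict[str, list[WaterSample]] = {}
    for s in samples:
        if not s.ward:
            raise InputError(f"sample {s.sample_id}: ward id required for ward-level WQI")
        by_ward.setdefault(s.ward, []).append(s)
    if not by_ward:
        raise InputError("no samples given")

    results = []
    for ward, group in by_ward.items():
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for s in group:
            for name, v in s.values.items():
                sums[name] = sums.get(name, 0.0) + v
                counts[name] = counts.get(name, 0) + 1
        means = {name: sums[name] / counts[name] for name in sums}
        results.append(
            compute_wqi(means, standards, mode=mode, missing_policy=missing_policy,
                        entity_id=ward)
        )
    return results


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for all reported percentages/scores."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
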