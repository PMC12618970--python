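"""Zone/ward summary statistics and permissible-limit exceedance analysis.

Produces, per group (zone or ward) and parameter: n, min, max, mean, sample
standard deviation, and the count/percentage of samples outside the
permissible limit — the monitoring-report view of a sample table — plus the
distribution of WQI status grades across the entities of each zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InputError, UnknownParameterError
from .standards import ParameterSpec, StandardsTable
from .wqi import Status, WaterSample, WQIResult, round_half_up

__all__ = [
    "ZoneSummary",
    "StatusDistribution",
    "exceeds_limit",
    "summarize",
    "status_distribution",
    "summaries_to_frame",
    "distributions_to_frame",
]


@dataclass(frozen=True)
class ZoneSummary:
    """Summary of one parameter within one group of samples.

    ``pct_exceed`` is half-up rounded to 2 decimals for display;
    ``pct_exceed_raw`` keeps full precision. ``empty`` flags a group with no
    non-missing values for the parameter (all numeric fields are NaN then).
    """

    zone: str
    parameter: str
    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float
    n_exceed: int
    pct_exceed: float
    pct_exceed_raw: float
    empty: bool = False


@dataclass(frozen=True)
class StatusDistribution:
    """Percentage of a zone's entities in each WQI grade band."""

    zone: str
    percentages: Mapping[Status, float]

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 0.05:
            raise InputError(f"{self.zone}: status percentages sum to {total}, not 100")


def exceeds_limit(value: float, spec: ParameterSpec) -> bool:
    """True iff the value is outside its permissible limit.

    Upper-only limits: value > high. Two-sided bands (pH, dissolved oxygen):
    deviation in either direction counts. Values exactly at a bound pass.
    """
    if not math.isfinite(value):
        raise InputError(f"{spec.name}: value must be finite")
    if value > spec.permissible_high:
        return True
    if spec.permissible_low is not None and value < spec.permissible_low:
        return True
    return False


def summarize(
    samples: Iterable[WaterSample],
    standards: StandardsTable,
    group_key: str = "zone",
) -> list[ZoneSummary]:
    """Per-group, per-parameter summary with exceedance counts.

    Statistics use the sample SD (n-1 denominator). Parameters missing from a
    sample are simply skipped for that sample (n reduced accordingly); a group
    with no values at all for a parameter yields an ``empty`` row rather than
    an error. Output order: groups by first appearance, parameters in
    standards-table order. Invariant in the ordering of the input samples.
    """
    if group_key not in ("zone", "ward"):
        raise InputError(f"group_key must be 'zone' or 'ward', got {group_key!r}")
    samples = list(samples)
    if not samples:
        raise InputError("no samples given")

    records = []
    group_order: list[str] = []
    for s in samples:
        group = getattr(s, group_key)
        if not group:
            raise InputError(f"sample {s.sample_id}: empty {group_key} label")
        if group not in group_order:
            group_order.append(group)
        for name, v in s.values.items():
            if name not in standards:
                raise UnknownParameterError(
                    f"sample {s.sample_id}: unknown parameter {name!r}"
                )
            records.append((group, name, v))
    frame = pd.DataFrame(records, columns=["group", "parameter", "value"])

    out = []
    for group in group_order:
        gframe = frame[frame["group"] == group]
        for spec in standards:
            # sorted so the summation order (hence the floating-point result)
            # does not depend on the input sample order
            vals = np.sort(gframe.loc[gframe["parameter"] == spec.name, "value"].to_numpy())
            if vals.size == 0:
                out.append(
                    ZoneSummary(group, spec.name, 0, math.nan, math.nan, math.nan,
                                math.nan, 0, math.nan, math.nan, empty=True)
                )
                continue
            n = int(vals.size)
            n_exceed = int(sum(exceeds_limit(v, spec) for v in vals))
            pct_raw = 100.0 * n_exceed / n
            out.append(
                ZoneSummary(
                    zone=group,
                    parameter=spec.name,
                    n=n,
                    minimum=float(vals.min()),
                    maximum=float(vals.max()),
                    mean=float(vals.mean()),
                    sd=float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                    n_exceed=n_exceed,
                    pct_exceed=round_half_up(pct_raw, 2),
                    pct_exceed_raw=pct_raw,
                )
            )
    return out


def status_distribution(
    results: Iterable[WQIResult],
    zone_of: Optional[Mapping[str, str]] = None,
) -> list[StatusDistribution]:
    """Percentage of entities per WQI grade, by zone.

    ``zone_of`` maps entity_id to zone label; if omitted, all entities are
    pooled under the label ``"all"``. Every grade band is reported, absent
    ones as 0; percentages are half-up rounded to 2 decimals.
    """
    results = list(results)
    if not results:
        raise InputError("no WQI results given")

    counts: dict[str, dict[Status, int]] = {}
    zone_order: list[str] = []
    for r in results:
        if zone_of is None:
            zone = "all"
        else:
            try:
                zone = zone_of[r.entity_id]
            except KeyError:
                raise UnknownParameterError(
                    f"entity {r.entity_id!r} has no zone mapping"
                ) from None
        if zone not in zone_order:
            zone_order.append(zone)
        counts.setdefault(zone, {s: 0 for s in Status})[r.status] += 1

    out = []
    for zone in zone_order:
        total = sum(counts[zone].values())
        out.append(
            StatusDistribution(
                zone=zone,
                percentages={
                    s: round_half_up(100.0 * c / total, 2)
                    for s, c in counts[zone].items()
                },
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[ZoneSummary]) -> pd.DataFrame:
    """Tidy frame: one row per (group, parameter)."""
    return pd.DataFrame(
        {
            "zone": s.zone,
            "parameter": s.parameter,
            "n": s.n,
            "min": s.minimum,
            "max": s.maximum,
            "mean": s.mean,
            "sd": s.sd,
            "n_exceed": s.n_exceed,
            "pct_exceed": s.pct_exceed,
            "pct_exceed_raw": s.pct_exceed_raw,
            "empty": s.empty,
        }
        for s in summaries
    )


def distributions_to_frame(dists: Iterable[StatusDistribution]) -> pd.DataFrame:
    """Tidy frame: one row per (zone, status)."""
    return pd.DataFrame(
        {"zone": d.zone, "status": status.value, "pct": d.percentages[status]}
        for d in dists
        for status in Status
    )
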