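"""Synthetic ward-sample generator for the three-zone supply-water design.

The study design is 67 wards in three municipal zones (north 21, south-west
21, south-east 25) with five sampling locations per ward — 335 samples. Only
per-zone min/max/mean/SD summaries of the ten physicochemical parameters are
available, so each parameter is drawn independently from a normal(mean, sd)
truncated to [min, max]; the four printed statistics pin the family down
without asserting more structure than is known. Truncation shifts the
realised moments away from (mean, sd): :func:`truncated_normal_moments`
returns the distribution's true moments for comparisons.

Ward centroids are placed uniformly in the study bounding box and the five
samples of a ward are jittered around the centroid, so spatial workflows have
plausible coordinates; no spatial autocorrelation of the parameter fields is
modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .standards import ParameterSpec
from .wqi import WaterSample

__all__ = [
    "STUDY_BBOX",
    "SOUTH_EAST_EXCEEDANCE_COUNTS",
    "NORTH_STATUS_COUNTS",
    "ParamStats",
    "ZoneProfile",
    "builtin_zone_profiles",
    "truncated_normal_moments",
    "generate_samples",
    "calibrate_exceedance",
    "apply_exceedance_calibration",
]

logger = logging.getLogger(__name__)

#: Study bounding box (lon min, lat min, lon max, lat max): 85°44'-85°55' E,
#: 20°12'-20°25' N in decimal degrees.
STUDY_BBOX = (85.733, 20.200, 85.917, 20.417)

#: Fraction of the bbox span used to jitter a ward's sample locations.
_JITTER_FRACTION = 0.01

#: South-east zone exceedance counts reported by the survey (n = 125 samples):
#: inputs for reconstructing the printed exceedance percentages via
#: :func:`apply_exceedance_calibration`.
SOUTH_EAST_EXCEEDANCE_COUNTS = {
    "conductivity": 90,
    "hardness": 56,
    "dissolved_oxygen": 19,
    "ph": 8,
}

#: North-zone ward grade counts reported by the survey (21 wards): inputs for
#: reconstructing the printed status distribution.
NORTH_STATUS_COUNTS = {"excellent": 5, "good": 16}


@dataclass(frozen=True)
class ParamStats:
    """Printed summary of one parameter in one zone."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum <= self.mean <= self.maximum:
            raise InputError(
                f"require minimum <= mean <= maximum, got {self}"
            )
        if self.sd < 0:
            raise InputError("sd must be >= 0")


@dataclass(frozen=True)
class ZoneProfile:
    """Sampling design and parameter statistics of one zone."""

    zone: str
    n_wards: int
    samples_per_ward: int
    params: Mapping[str, ParamStats]

    def __post_init__(self) -> None:
        if self.n_wards < 1 or self.samples_per_ward < 1:
            raise InputError("n_wards and samples_per_ward must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_wards * self.samples_per_ward


def builtin_zone_profiles() -> tuple[ZoneProfile, ZoneProfile, ZoneProfile]:
    """The study's three zone profiles: design counts and the per-zone
    min/max/mean/SD of the ten parameters."""

    def p(minimum, maximum, mean, sd):
        return ParamStats(mean=mean, sd=sd, minimum=minimum, maximum=maximum)

    north = ZoneProfile(
        zone="north", n_wards=21, samples_per_ward=5,
        params={
            "ph": p(5.56, 8.61, 7.66, 0.70),
            "dissolved_oxygen": p(5.91, 8.38, 7.50, 0.52),
            "conductivity": p(58.25, 480.30, 255.42, 90.63),
            "alkalinity": p(16.00, 128.00, 58.83, 21.85),
            "hardness": p(13.12, 262.40, 118.45, 60.24),
            "chloride": p(18.46, 87.03, 33.86, 11.65),
            "tds": p(37.86, 312.20, 166.02, 58.91),
            "bod": p(0.58, 4.98, 2.54, 1.32),
            "sulphate": p(3.0, 30.0, 15.57282, 8.307334),
            "nitrate": p(0.2, 24.9, 11.80777, 7.346517),
        },
    )
    south_west = ZoneProfile(
        zone="south_west", n_wards=21, samples_per_ward=5,
        params={
            "ph": p(5.56, 8.61, 7.73, 0.69),
            "dissolved_oxygen": p(5.91, 8.95, 7.54, 0.54),
            "conductivity": p(67.70, 519.90, 251.01, 85.78),
            "alkalinity": p(16.00, 128.00, 59.64, 21.97),
            "hardness": p(13.12, 229.60, 116.96, 57.98),
            "chloride": p(18.46, 87.03, 34.29, 10.76),
            "tds": p(44.01, 337.94, 163.16, 55.75),
            "bod": p(0.58, 4.98, 2.75, 1.26),
            "sulphate": p(3.0, 30.0, 17.14286, 8.105588),
            "nitrate": p(3.0, 30.0, 16.41905, 7.595268),
        },
    )
    south_east = ZoneProfile(
        zone="south_east", n_wards=25, samples_per_ward=5,
        params={
            "ph": p(6.23, 8.59, 7.56, 0.48),
            "dissolved_oxygen": p(5.91, 8.20, 7.43, 0.49),
            "conductivity": p(173.16, 581.47, 342.97, 73.69),
            "alkalinity": p(22.00, 78.00, 46.05, 13.75),
            "hardness": p(98.40, 268.96, 186.09, 40.78),
            "chloride": p(21.30, 64.61, 38.84, 7.61),
            "tds": p(112.56, 377.96, 222.93, 47.90),
            "bod": p(0.55, 4.60, 2.39, 1.00),
            "sulphate": p(3.0, 30.0, 16.88, 8.048843),
            "nitrate": p(3.0, 30.0, 16.88, 8.062858),
        },
    )
    return north, south_west, south_east


def _truncnorm(ps: ParamStats) -> stats.rv_continuous:
    a = (ps.minimum - ps.mean) / ps.sd
    b = (ps.maximum - ps.mean) / ps.sd
    return stats.truncnorm(a, b, loc=ps.mean, scale=ps.sd)


def truncated_normal_moments(ps: ParamStats) -> tuple[float, float]:
    """True (mean, sd) of normal(mean, sd) truncated to [minimum, maximum]."""
    if ps.sd == 0 or ps.minimum == ps.maximum:
        return ps.mean, 0.0
    m, v = _truncnorm(ps).stats(moments="mv")
    return float(m), float(np.sqrt(v))


def _draw(ps: ParamStats, size: int, rng: np.random.Generator) -> np.ndarray:
    if ps.minimum == ps.maximum:
        return np.full(size, ps.minimum)
    if ps.sd == 0:
        logger.info("sd = 0 with min < max: degenerate draw at the mean")
        return np.full(size, ps.mean)
    return _truncnorm(ps).rvs(size=size, random_state=rng)


def generate_samples(
    profiles: Iterable[ZoneProfile],
    seed: int,
    bbox: Optional[tuple[float, float, float, float]] = None,
    oversample: int = 1,
) -> list[WaterSample]:
    """Generate a full sample table under the given zone profiles.

    For each zone, ``n_wards * samples_per_ward * oversample`` samples; each
    parameter drawn i.i.d. from its truncated normal; ward centroids uniform
    in ``bbox`` (default: the study box) with per-sample jitter. The same seed
    always reproduces the same table (PCG64 generator).

    ``oversample`` multiplies the samples per ward — used for statistical
    checks that need more draws than the field design provides.
    """
    profiles = list(profiles)
    if not profiles:
        raise InputError("no zone profiles given")
    if oversample < 1:
        raise InputError("oversample must be >= 1")
    if bbox is None:
        bbox = STUDY_BBOX
    xmin, ymin, xmax, ymax = bbox
    if not (xmin < xmax and ymin < ymax):
        raise InputError("invalid bbox")
    rng = np.random.default_rng(seed)
    jitter_x = (xmax - xmin) * _JITTER_FRACTION
    jitter_y = (ymax - ymin) * _JITTER_FRACTION

    samples: list[WaterSample] = []
    ward_counter = 0
    for profile in profiles:
        per_ward = profile.samples_per_ward * oversample
        n_total = profile.n_wards * per_ward
        # one matrix of draws per parameter, then slice per ward
        draws = {
            name: _draw(ps, n_total, rng) for name, ps in profile.params.items()
        }
        centroids_x = rng.uniform(xmin, xmax, size=profile.n_wards)
        centroids_y = rng.uniform(ymin, ymax, size=profile.n_wards)
        for w in range(profile.n_wards):
            ward_counter += 1
            ward_id = f"ward_{ward_counter:02d}"
            xs = np.clip(
                centroids_x[w] + rng.uniform(-jitter_x, jitter_x, size=per_ward),
                xmin, xmax,
            )
            ys = np.clip(
                centroids_y[w] + rng.uniform(-jitter_y, jitter_y, size=per_ward),
                ymin, ymax,
            )
            for k in range(per_ward):
                idx = w * per_ward + k
                samples.append(
                    WaterSample(
                        sample_id=f"{ward_id}_loc{k + 1:03d}",
                        ward=ward_id,
                        zone=profile.zone,
                        x=float(xs[k]),
                        y=float(ys[k]),
                        values={name: float(draws[name][idx]) for name in profile.params},
                    )
                )
    return samples


def apply_exceedance_calibration(
    samples: Sequence[WaterSample],
    profile: ZoneProfile,
    counts: Mapping[str, int],
    standards,
) -> list[WaterSample]:
    """Return copies of a zone's samples with the listed parameters adjusted so
    that exactly ``counts[parameter]`` samples exceed their permissible limit
    (see :func:`calibrate_exceedance`). Samples from other zones pass through
    unchanged."""
    zone_idx = [i for i, s in enumerate(samples) if s.zone == profile.zone]
    adjusted = {name: dict() for name in counts}
    for name, n_exceed in counts.items():
        ps = profile.params[name]
        draws = [samples[i].values[name] for i in zone_idx]
        new = calibrate_exceedance(draws, n_exceed, standards[name],
                                   (ps.minimum, ps.maximum))
        adjusted[name] = dict(zip(zone_idx, new))
    out = []
    for i, s in enumerate(samples):
        if i not in zone_idx:
            out.append(s)
            continue
        values = dict(s.values)
        for name in counts:
            values[name] = float(adjusted[name][i])
        out.append(WaterSample(sample_id=s.sample_id, ward=s.ward, zone=s.zone,
                               x=s.x, y=s.y, values=values))
    return out


def calibrate_exceedance(
    values: Sequence[float],
    n_exceed: int,
    spec: ParameterSpec,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Post-adjust draws so that exactly ``n_exceed`` exceed the limit.

    The ``n_exceed`` largest draws are mapped (order-preservingly) into the
    interval just above the upper permissible limit, the remainder into the
    pass region; everything stays within ``bounds``. Used to reconstruct a
    printed exceedance count when only the summary table of a survey is
    available.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = bounds
    if not 0 <= n_exceed <= x.size:
        raise InputError(f"n_exceed must be within [0, {x.size}]")
    limit = spec.permissible_high
    if n_exceed > 0 and hi <= limit:
        raise InputError(
            f"{spec.name}: upper bound {hi} does not exceed the limit {limit}; "
            "cannot place exceeding draws"
        )
    # pass region inside the bounds (for range limits, stay above the low bound
    # too, else a 'passing' draw would exceed on the low side)
    pass_lo = max(lo, spec.permissible_low) if spec.permissible_low is not None else lo
    pass_hi = min(hi, limit)
    if pass_lo > pass_hi:
        raise InputError(f"{spec.name}: empty pass region within bounds {bounds}")

    order = np.argsort(x, kind="stable")
    out = np.empty_like(x)
    low_idx = order[: x.size - n_exceed]
    top_idx = order[x.size - n_exceed :]

    def remap(idx: np.ndarray, target_lo: float, target_hi: float) -> None:
        if idx.size == 0:
            return
        seg = x[idx]
        smin, smax = seg.min(), seg.max()
        if smin == smax:
            out[idx] = 0.5 * (target_lo + target_hi)
        else:
            out[idx] = target_lo + (seg - smin) * (target_hi - target_lo) / (smax - smin)

    remap(low_idx, pass_lo, pass_hi)
    if n_exceed > 0:
        eps = (hi - limit) * 1e-6
        remap(top_idx, limit + eps, hi)
    return out
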