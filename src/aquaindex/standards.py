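"""Drinking-water parameter standards: permissible limits and WQI reference values.

Each parameter carries two distinct reference values used by the weighted
arithmetic WQI:

* ``ideal_value`` (v_io) — the concentration at which the water is considered
  unpolluted for that parameter (0 for most solutes, 7 for pH, 14.6 mg/l for
  dissolved oxygen, the saturation value of pristine water).
* ``standard_value`` (s_i) — the permissible value entering both the quality
  rating q_i and the unit weight w_i = k/s_i.

Separately, ``permissible_low``/``permissible_high`` define the regulatory
pass band used for exceedance counting (IS 10500 limits by default); for most
parameters only an upper bound exists.
"""

from __future__ import annotations

import configparser
import math
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .errors import InputError, StandardsValidationError, UnknownParameterError

__all__ = [
    "ParameterSpec",
    "StandardsTable",
    "builtin_is10500",
    "load_standards",
    "write_standards",
]


@dataclass(frozen=True)
class ParameterSpec:
    """Reference values for one water-quality parameter.

    ``limit_kind`` is derived: ``"range"`` when a lower permissible bound is
    present (pH, dissolved oxygen), else ``"upper_only"``.
    """

    name: str
    unit: str
    ideal_value: float
    standard_value: float
    permissible_high: float
    permissible_low: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise StandardsValidationError("parameter name must be non-empty")
        if not self.unit:
            raise StandardsValidationError(f"{self.name}: unit must be non-empty")
        for field in ("ideal_value", "standard_value", "permissible_high"):
            v = getattr(self, field)
            if not math.isfinite(v):
                raise StandardsValidationError(f"{self.name}: {field} must be finite")
        if self.standard_value == self.ideal_value:
            raise StandardsValidationError(
                f"{self.name}: standard_value equals ideal_value "
                "(quality-rating denominator would be zero)"
            )
        if self.permissible_low is not None:
            if not math.isfinite(self.permissible_low):
                raise StandardsValidationError(f"{self.name}: permissible_low must be finite")
            if not self.permissible_low < self.permissible_high:
                raise StandardsValidationError(
                    f"{self.name}: permissible_low ({self.permissible_low}) must be "
                    f"< permissible_high ({self.permissible_high})"
                )

    @property
    def limit_kind(self) -> str:
        return "range" if self.permissible_low is not None else "upper_only"


class StandardsTable:
    """Ordered, name-unique collection of :class:`ParameterSpec`."""

    def __init__(self, specs: Iterable[ParameterSpec]):
        specs = tuple(specs)
        if not specs:
            raise StandardsValidationError("standards table must be non-empty")
        seen = set()
        for spec in specs:
            if spec.name in seen:
                raise StandardsValidationError(f"duplicate parameter name: {spec.name}")
            seen.add(spec.name)
        self._specs = specs
        self._by_name = {spec.name: spec for spec in specs}

    @property
    def specs(self) -> tuple[ParameterSpec, ...]:
        return self._specs

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self._specs)

    def __getitem__(self, name: str) -> ParameterSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise UnknownParameterError(
                f"unknown parameter {name!r}; known: {', '.join(self.names)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StandardsTable):
            return NotImplemented
        return self._specs == other._specs

    def __repr__(self) -> str:
        return f"StandardsTable({list(self.names)})"

    def subset(self, names: Sequence[str]) -> "StandardsTable":
        """Restrict to the given parameters, preserving table order."""
        if not names:
            raise InputError("subset must name at least one parameter")
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise UnknownParameterError(
                f"unknown parameter(s): {', '.join(sorted(missing))}"
            )
        return StandardsTable(s for s in self._specs if s.name in wanted)


def builtin_is10500() -> StandardsTable:
    """Default table of IS 10500 (2012) drinking-water limits for the ten
    physicochemical parameters of the supply-water assessment.

    For upper-bounded parameters the WQI standard value s_i equals the
    permissible limit and the ideal value is 0. pH and dissolved oxygen carry
    two-sided pass bands (6.5-8.5 and 6.5-8 mg/l) with ideals 7 and 14.6; their
    s_i defaults to the upper bound of the band, so q_i runs from 0 at the
    ideal to 100 at the permissible bound.
    """
    return StandardsTable(
        [
            ParameterSpec("ph", "dimensionless", 7.0, 8.5, 8.5, 6.5),
            ParameterSpec("dissolved_oxygen", "mg/l", 14.6, 8.0, 8.0, 6.5),
            ParameterSpec("conductivity", "uS/cm", 0.0, 300.0, 300.0),
            ParameterSpec("alkalinity", "mg/l", 0.0, 200.0, 200.0),
            ParameterSpec("hardness", "mg/l", 0.0, 200.0, 200.0),
            ParameterSpec("chloride", "mg/l", 0.0, 250.0, 250.0),
            ParameterSpec("tds", "mg/l", 0.0, 500.0, 500.0),
            ParameterSpec("bod", "mg/l", 0.0, 5.0, 5.0),
            ParameterSpec("sulphate", "mg/l", 0.0, 200.0, 200.0),
            ParameterSpec("nitrate", "mg/l", 0.0, 45.0, 45.0),
        ]
    )


_KNOWN_KEYS = {"unit", "ideal", "standard", "low", "high"}
_REQUIRED_KEYS = {"unit", "ideal", "standard", "high"}


def load_standards(path: os.PathLike | str) -> StandardsTable:
    """Load a standards table from a flat key-value config file.

    One section per parameter::

        [nitrate]
        unit = mg/l
        ideal = 0
        standard = 45
        high = 45
        # low = ...   (optional: makes the pass band two-sided)

    Unknown keys are rejected; all :class:`ParameterSpec` invariants are
    enforced with the offending parameter named in the error.
    """
    if not os.path.exists(path):
        raise InputError(f"standards file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        with open(path, encoding="utf-8") as fh:
            parser.read_file(fh)
    except configparser.Error as exc:
        raise InputError(f"cannot parse standards file {path}: {exc}") from exc

    specs = []
    for section in parser.sections():
        keys = set(parser[section].keys())
        unknown = keys - _KNOWN_KEYS
        if unknown:
            raise StandardsValidationError(
                f"{section}: unknown field(s) {', '.join(sorted(unknown))}"
            )
        missing = _REQUIRED_KEYS - keys
        if missing:
            raise StandardsValidationError(
                f"{section}: missing field(s) {', '.join(sorted(missing))}"
            )
        sec = parser[section]
        try:
            spec = ParameterSpec(
                name=section,
                unit=sec["unit"],
                ideal_value=float(sec["ideal"]),
                standard_value=float(sec["standard"]),
                permissible_high=float(sec["high"]),
                permissible_low=float(sec["low"]) if "low" in sec else None,
            )
        except ValueError as exc:
            raise StandardsValidationError(f"{section}: {exc}") from exc
        specs.append(spec)
    return StandardsTable(specs)


def write_standards(table: StandardsTable, path: os.PathLike | str) -> None:
    """Write a table in the config dialect read by :func:`load_standards`."""
    parser = configparser.ConfigParser()
    for spec in table:
        block = {
            "unit": spec.unit,
            "ideal": repr(spec.ideal_value),
            "standard": repr(spec.standard_value),
            "high": repr(spec.permissible_high),
        }
        if spec.permissible_low is not None:
            block["low"] = repr(spec.permissible_low)
        parser[spec.name] = block
    with open(path, "w", encoding="utf-8") as fh:
        parser.write(fh)
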