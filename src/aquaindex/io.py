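"""Readers, writers, run configuration, and the end-to-end pipeline.

Canonical sample CSV: header ``sample_id,ward,zone,x,y`` followed by one
column per parameter; decimal point, UTF-8; blank cells are missing values.
Output files start with a ``#`` provenance comment (tool version and config
hash) and are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import __version__
from .errors import InputError, UnknownParameterError
from .idw import IDWConfig, SpatialPoint, idw_grid, write_asc
from .standards import StandardsTable, builtin_is10500, load_standards
from .summary import distributions_to_frame, status_distribution, summaries_to_frame, summarize
from .synth import STUDY_BBOX, builtin_zone_profiles, generate_samples
from .wqi import WaterSample, compute_wqi, round_half_up, ward_wqi

__all__ = [
    "SAMPLE_COLUMNS",
    "RunConfig",
    "normalize_zone",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "write_samples_geojson",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Fixed leading columns of the canonical sample CSV.
SAMPLE_COLUMNS = ("sample_id", "ward", "zone", "x", "y")

_ZONE_ALIASES = {
    "north": "north",
    "northzone": "north",
    "southwest": "south_west",
    "south_west": "south_west",
    "southeast": "south_east",
    "south_east": "south_east",
}


def normalize_zone(label: str) -> str:
    """Normalise a zone label to {north, south_west, south_east};
    unrecognised labels pass through untouched (user-defined studies)."""
    key = label.strip().lower().replace("-", "").replace(" ", "").replace("_", "")
    # keep underscores meaningful only after collapsing variants
    return _ZONE_ALIASES.get(key, label)


def samples_to_frame(samples: Iterable[WaterSample]) -> pd.DataFrame:
    """Canonical tabular view; parameter columns in first-appearance order."""
    rows = []
    param_order: list[str] = []
    for s in samples:
        for name in s.values:
            if name not in param_order:
                param_order.append(name)
        row = {"sample_id": s.sample_id, "ward": s.ward, "zone": s.zone,
               "x": s.x, "y": s.y}
        row.update(s.values)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.reindex(columns=list(SAMPLE_COLUMNS) + param_order)


def _provenance_line(config_repr: str) -> str:
    digest = hashlib.sha256(config_repr.encode("utf-8")).hexdigest()[:12]
    return f"# aquaindex {__version__} config_hash={digest}"


def _write_csv(frame: pd.DataFrame, path: Path, config_repr: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_line(config_repr) + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def write_samples(samples: Iterable[WaterSample], path: os.PathLike | str,
                  config_repr: str = "samples") -> None:
    _write_csv(samples_to_frame(samples), Path(path), config_repr)


def read_samples(
    path: os.PathLike | str,
    known_parameters: Optional[Sequence[str]] = None,
) -> list[WaterSample]:
    """Read the canonical sample CSV.

    Columns beyond :data:`SAMPLE_COLUMNS` are parameter columns; if
    ``known_parameters`` is given (default: the builtin standards' names),
    unknown columns raise an error listing the known names. Blank cells become
    missing values. Non-numeric cells raise an error naming row and column.
    """
    if not os.path.exists(path):
        raise InputError(f"sample file not found: {path}")
    if known_parameters is None:
        known_parameters = builtin_is10500().names
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ("sample_id", "ward", "zone") if c not in frame.columns]
    if missing_cols:
        raise InputError(f"{path}: missing required column(s) {', '.join(missing_cols)}")
    param_cols = [c for c in frame.columns if c not in SAMPLE_COLUMNS]
    unknown = [c for c in param_cols if c not in known_parameters]
    if unknown:
        raise UnknownParameterError(
            f"{path}: unknown parameter column(s) {', '.join(unknown)}; "
            f"known: {', '.join(known_parameters)}"
        )

    def parse_cell(raw: str, row: int, col: str) -> Optional[float]:
        raw = raw.strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise InputError(
                f"{path}: non-numeric value {raw!r} at row {row}, column {col!r}"
            ) from None

    samples = []
    for i, rec in frame.iterrows():
        row_no = int(i) + 2  # header is line 1 (after comments)
        values = {}
        for col in param_cols:
            v = parse_cell(rec[col], row_no, col)
            if v is not None:
                values[col] = v
        x = parse_cell(rec["x"], row_no, "x") if "x" in frame.columns else None
        y = parse_cell(rec["y"], row_no, "y") if "y" in frame.columns else None
        samples.append(
            WaterSample(
                sample_id=rec["sample_id"],
                ward=rec["ward"],
                zone=normalize_zone(rec["zone"]),
                x=x,
                y=y,
                values=values,
            )
        )
    logger.info("read %d samples x %d parameter columns from %s",
                len(samples), len(param_cols), path)
    return samples


def write_samples_geojson(samples: Iterable[WaterSample], path: os.PathLike | str) -> None:
    """Write samples with coordinates as a GeoJSON FeatureCollection of Points."""
    features = []
    for s in samples:
        if s.x is None or s.y is None:
            continue
        props = {"sample_id": s.sample_id, "ward": s.ward, "zone": s.zone}
        props.update(s.values)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
                "properties": props,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        fh.write("\n")


@dataclass
class RunConfig:
    """End-to-end pipeline settings."""

    out_dir: str
    samples_path: Optional[str] = None     # read samples from here, or ...
    simulate_seed: Optional[int] = None    # ... simulate with this seed
    standards_path: Optional[str] = None   # None -> builtin IS 10500 table
    mode: str = "signed"
    missing_policy: str = "strict"
    per_ward: bool = True
    idw: IDWConfig = field(default_factory=IDWConfig)
    surface_parameters: tuple[str, ...] = ()
    grid_ncols: int = 40
    grid_nrows: int = 40
    log_level: str = "INFO"

    def repr_for_hash(self) -> str:
        """Stable representation of the analysis settings; excludes the output
        directory so the same analysis is byte-identical wherever it is written."""
        import dataclasses

        fields = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                  if f.name != "out_dir"}
        return repr(sorted(fields.items()))


def load_run_config(path: os.PathLike | str) -> RunConfig:
    """Load a RunConfig from the flat key-value config dialect (section [run],
    optional section [idw])."""
    if not os.path.exists(path):
        raise InputError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    with open(path, encoding="utf-8") as fh:
        parser.read_file(fh)
    if "run" not in parser:
        raise InputError(f"{path}: missing [run] section")
    run = parser["run"]
    idw_cfg = IDWConfig()
    if "idw" in parser:
        sec = parser["idw"]
        idw_cfg = IDWConfig(
            power=sec.getfloat("power", 2.0),
            max_neighbors=sec.getint("max_neighbors", 12),
            cutoff_distance=sec.getfloat("cutoff_distance", fallback=None),
            distance_metric=sec.get("distance_metric", "planar"),
        )
    surfaces = tuple(
        p.strip() for p in run.get("surface_parameters", "").split(",") if p.strip()
    )
    return RunConfig(
        out_dir=run.get("out_dir", "aquaindex_out"),
        samples_path=run.get("samples_path", fallback=None),
        simulate_seed=run.getint("simulate_seed", fallback=None),
        standards_path=run.get("standards_path", fallback=None),
        mode=run.get("mode", "signed"),
        missing_policy=run.get("missing_policy", "strict"),
        per_ward=run.getboolean("per_ward", True),
        idw=idw_cfg,
        surface_parameters=surfaces,
        grid_ncols=run.getint("grid_ncols", 40),
        grid_nrows=run.getint("grid_nrows", 40),
        log_level=run.get("log_level", "INFO"),
    )


def _load_standards(config: RunConfig) -> StandardsTable:
    if config.standards_path:
        return load_standards(config.standards_path)
    return builtin_is10500()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run the full assessment: samples -> WQI -> summaries -> surfaces -> report.

    Writes per-entity WQI CSV, the zone summary CSV, the status-distribution
    CSV, optional .asc surfaces, and a markdown report. Returns a map of
    artifact name -> path. On any stage error the partially written outputs
    are removed and the error re-raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = config.repr_for_hash()
    written: list[Path] = []
    artifacts: dict[str, str] = {}

    def emit_csv(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        _write_csv(frame, path, cfg_repr)
        written.append(path)
        artifacts[name] = str(path)

    try:
        standards = _load_standards(config)
        if config.samples_path:
            samples = read_samples(config.samples_path, known_parameters=standards.names)
        elif config.simulate_seed is not None:
            samples = generate_samples(builtin_zone_profiles(), seed=config.simulate_seed)
            emit_csv("samples.csv", samples_to_frame(samples))
        else:
            raise InputError("config must set samples_path or simulate_seed")

        zone_of_ward = {s.ward: s.zone for s in samples}
        if config.per_ward:
            results = ward_wqi(samples, standards, mode=config.mode,
                               missing_policy=config.missing_policy)
            zone_of = zone_of_ward
        else:
            results = [
                compute_wqi(s.values, standards, mode=config.mode,
                            missing_policy=config.missing_policy, entity_id=s.sample_id)
                for s in samples
            ]
            zone_of = {s.sample_id: s.zone for s in samples}

        emit_csv(
            "wqi.csv",
            pd.DataFrame(
                {
                    "entity_id": r.entity_id,
                    "zone": zone_of[r.entity_id],
                    "wqi": round_half_up(r.score, 2),
                    "wqi_raw": r.score,
                    "status": r.status.value,
                }
                for r in results
            ),
        )
        emit_csv("summary.csv", summaries_to_frame(summarize(samples, standards)))
        emit_csv(
            "status_distribution.csv",
            distributions_to_frame(status_distribution(results, zone_of)),
        )

        for pname in config.surface_parameters:
            points = [
                SpatialPoint(s.x, s.y, s.values[pname])
                for s in samples
                if s.x is not None and s.y is not None and pname in s.values
            ]
            if not points:
                raise InputError(f"no located samples carry parameter {pname!r}")
            surface = idw_grid(points, STUDY_BBOX, config.grid_ncols,
                               config.grid_nrows, config.idw)
            path = out_dir / f"surface_{pname}.asc"
            write_asc(surface, path)
            written.append(path)
            artifacts[path.name] = str(path)

        report = out_dir / "report.md"
        with open(report, "w", encoding="utf-8") as fh:
            fh.write("# aquaindex run report\n\n")
            fh.write(f"- tool version: {__version__}\n")
            fh.write(f"- config: `{cfg_repr}`\n")
            fh.write(f"- samples: {len(samples)}\n")
            fh.write(f"- entities scored: {len(results)} "
                     f"({'per ward' if config.per_ward else 'per sample'})\n")
            fh.write(f"- artifacts: {', '.join(sorted(artifacts))}\n")
        written.append(report)
        artifacts["report.md"] = str(report)
        return artifacts
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:  # pragma: no cover
                pass
        raise
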