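#!/usr/bin/env python
"""Interpolate parameter and WQI surfaces over the study area.

IDW (power 2, 12 nearest neighbours) on the sampled locations, evaluated on a
regular grid over the study bounding box. Writes ESRI ASCII grids under
results/: one per chosen parameter plus one for the per-ward WQI placed at the
ward centroids.
"""

import argparse
from pathlib import Path

import numpy as np

from aquaindex import (
    IDWConfig,
    STUDY_BBOX,
    SpatialPoint,
    builtin_is10500,
    idw_grid,
    read_samples,
    ward_wqi,
    write_asc,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
PARAMETERS = ("hardness", "conductivity")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--ncols", type=int, default=30)
    parser.add_argument("--nrows", type=int, default=30)
    args = parser.parse_args()

    samples = read_samples(RESULTS / "samples.csv")
    config = IDWConfig(power=2.0, max_neighbors=12)

    for name in PARAMETERS:
        points = [SpatialPoint(s.x, s.y, s.values[name])
                  for s in samples if name in s.values]
        surface = idw_grid(points, STUDY_BBOX, args.ncols, args.nrows, config)
        out = RESULTS / f"surface_{name}.asc"
        write_asc(surface, out)
        print(f"{name}: grid {args.nrows}x{args.ncols}, "
              f"range {surface.values.min():.1f} .. {surface.values.max():.1f} -> {out}")

    # WQI surface from ward scores at ward centroids
    results = ward_wqi(samples, builtin_is10500())
    centroid = {}
    for s in samples:
        centroid.setdefault(s.ward, []).append((s.x, s.y))
    points = [
        SpatialPoint(*np.mean(centroid[r.entity_id], axis=0), r.score)
        for r in results
    ]
    surface = idw_grid(points, STUDY_BBOX, args.ncols, args.nrows, config)
    out = RESULTS / "surface_wqi.asc"
    write_asc(surface, out)
    print(f"wqi: grid {args.nrows}x{args.ncols}, "
          f"range {surface.values.min():.1f} .. {surface.values.max():.1f} -> {out}")


if __name__ == "__main__":
    main()
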