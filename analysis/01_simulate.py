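#!/usr/bin/env python
"""Generate the synthetic supply-water sample table.

Emulates the three-zone monitoring design — 21 north, 21 south-west and 25
south-east wards, five sampling locations per ward (335 samples) — with each
parameter drawn from the zone's truncated normal and coordinates placed in the
study bounding box. Writes results/samples.csv.
"""

import argparse
from pathlib import Path

from aquaindex import builtin_zone_profiles, generate_samples, write_samples

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    profiles = builtin_zone_profiles()
    samples = generate_samples(profiles, seed=args.seed)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "samples.csv"
    write_samples(samples, out, config_repr=f"simulate seed={args.seed}")

    per_zone = {}
    for s in samples:
        per_zone[s.zone] = per_zone.get(s.zone, 0) + 1
    print(f"wrote {len(samples)} samples to {out}")
    for zone, n in per_zone.items():
        print(f"  {zone}: {n} samples ({n // 5} wards x 5 locations)")


if __name__ == "__main__":
    main()
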