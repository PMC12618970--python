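#!/usr/bin/env python
"""Score every ward's water quality index and grade it.

Averages each parameter over a ward's five samples, aggregates the ratings
into the weighted arithmetic WQI, and grades each ward. Reads
results/samples.csv (run 01_simulate.py first) and writes results/ward_wqi.csv.
"""

from pathlib import Path

import pandas as pd

from aquaindex import builtin_is10500, read_samples, round_half_up, ward_wqi

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    samples = read_samples(RESULTS / "samples.csv")
    standards = builtin_is10500()
    results = ward_wqi(samples, standards)
    zone_of = {s.ward: s.zone for s in samples}

    frame = pd.DataFrame(
        {
            "ward": r.entity_id,
            "zone": zone_of[r.entity_id],
            "wqi": round_half_up(r.score, 2),
            "status": r.status.value,
        }
        for r in results
    )
    out = RESULTS / "ward_wqi.csv"
    frame.to_csv(out, index=False, lineterminator="\n")

    print(f"scored {len(frame)} wards -> {out}")
    print("grade counts by zone:")
    print(frame.groupby(["zone", "status"]).size().to_string())
    print(f"score range: {frame.wqi.min():.2f} .. {frame.wqi.max():.2f}")


if __name__ == "__main__":
    main()
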