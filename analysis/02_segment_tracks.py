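"""Segment raw fix streams into strategies and migration events.

Applies the 100-km / 1-November migration definition, departure detection
(first in-flight fix after leaving the colony), and the 12-h stopover /
20-day non-breeding dwell rules.  Writes strategies.csv and events.csv and
prints the per-event summary the study tabulates (departure date,
destination, duration, distance, mean/max speed).
"""

import argparse
from pathlib import Path

import pandas as pd

from flamingotrack.pipeline import stage_segment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("scratch/run"))
    args = ap.parse_args()

    ev = stage_segment(args.outdir)
    print(f"{len(ev)} migration events")
    if len(ev):
        print(f"mean distance {ev.total_distance_km.mean():.0f} km "
              f"(range {ev.total_distance_km.min():.0f}-{ev.total_distance_km.max():.0f}); "
              f"mean speed {ev.mean_speed_kmh.mean():.1f} km/h; "
              f"max speed {ev.max_speed_kmh.max():.1f} km/h")
    print(f"tables written under {args.outdir / 'tables'}")


if __name__ == "__main__":
    main()
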