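"""Annotate the analysis datasets with interpolated weather.

Builds the four model tables: the case-control departure design (colony
weather, route-bearing tailwind, hours after sunset), the consecutive-speed
segments (segment-bearing tailwind, cumulative distance, final segment
excluded), the phenology table, and the route-averaged distance table.
"""

import argparse
from pathlib import Path

from flamingotrack.pipeline import stage_annotate


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("scratch/run"))
    args = ap.parse_args()

    tables = stage_annotate(args.outdir)
    cases = tables["cases"]
    n1 = int((cases["label"] == 1).sum())
    print(f"case-control: {len(cases) - n1} control rows / {n1} departures "
          f"({(cases['tailwind'][cases.label == 1] > 0).mean():.0%} with tailwind)")
    print(f"speed segments: {len(tables['speed'])}; "
          f"distance rows: {len(tables['distance'])}")


if __name__ == "__main__":
    main()
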