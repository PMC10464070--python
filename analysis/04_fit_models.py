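"""Fit the full analysis suite.

Biometric LMs, the SMI-propensity logistic model, the binomial departure
GLMM (with the tailwind x distance variant), the consecutive-speed LMM
(with the sex x tailwind variant), phenology and distance LMs, and the
per-colony departure-direction vs seasonal-wind Poisson GLMs.  Each fit is
written as a tidy coefficient CSV under <outdir>/tables/.
"""

import argparse
from pathlib import Path

from flamingotrack.pipeline import stage_fit


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("scratch/run"))
    args = ap.parse_args()

    results = stage_fit(args.outdir)
    dep = results["departure"]
    print("departure GLMM (standardized scale):")
    for term in ("tailwind", "crosswind", "hours_after_sunset", "hours_after_sunset^2"):
        if term in dep.params:
            print(f"  {term:>22}: {dep.params[term]:+.2f} "
                  f"[{dep.ci_low[term]:+.2f}, {dep.ci_high[term]:+.2f}]")
    spd = results["speed"]
    print("speed LMM:")
    for term in ("sex[M]", "tailwind", "cumulative_km", "cumulative_km^2"):
        if term in spd.params:
            print(f"  {term:>22}: {spd.params[term]:+.2f} "
                  f"[{spd.ci_low[term]:+.2f}, {spd.ci_high[term]:+.2f}]")
    prop = results["propensity"]
    print(f"propensity: SMI slope {prop.params['smi_g']:+.2f}, "
          f"McFadden R^2 {prop.fit_stats['mcfadden_r2']:.2f}")


if __name__ == "__main__":
    main()
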