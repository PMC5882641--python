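#!/usr/bin/env python
"""Growth-parameter calibration report.

Regrows populations with the shipped default growth parameters and prints
the population morphometrics next to the calibration targets (young-adult
mouse hippocampal neurons), plus the mean Sholl peak locations.  Used to
(re)tune the free constants the literature does not pin down — the alpha
schedule, per-step taper rate, terminal-length mean and bounding volumes —
after any change to the growth engine.

Usage:  python scripts/calibrate_growth.py [--n 30] [--seed 7]
"""

from __future__ import annotations

import argparse

import numpy as np

from dendrisnip import grow_population, growth_defaults, sholl, summarize

TARGETS = {
    ("GCL", "all"): dict(total_length=(926.10, 127.14), n_branch_points=(12.9, 3.5),
                         n_branches=(26.7, 7.8), mean_bifurcation_angle=(56.02, 4.03)),
    ("CA1", "apical"): dict(total_length=(855.45, 109.21), n_branch_points=(16.9, 4.3),
                            mean_bifurcation_angle=(48.5, 2.7)),
    ("CA1", "basal"): dict(total_length=(733.6, 131.4), n_branch_points=(15.3, 3.5),
                           mean_bifurcation_angle=(49.2, 2.5)),
    ("CA1", "all"): dict(total_length=(1589.1, 240.6)),
}
PEAK_BANDS = {("CA1", "apical"): (80.0, 120.0), ("CA1", "basal"): (30.0, 70.0)}


def mean_sholl_peak(pop, compartment, step=10.0):
    profs = [sholl(n, step, compartment) for n in pop]
    size = max(len(p.intersections) for p in profs)
    acc = np.zeros(size)
    for p in profs:
        acc[: len(p.intersections)] += p.intersections
    return step * (int(np.argmax(acc[1:])) + 1)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=30)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    pops = {cls: grow_population(growth_defaults(cls), args.n, args.seed)
            for cls in ("GCL", "CA1")}
    for (cls, comp), targets in TARGETS.items():
        summaries = [summarize(n, comp) for n in pops[cls]]
        print(f"{cls} / {comp}  (n={args.n})")
        for attr, (mean_t, sd_t) in targets.items():
            vals = np.array([getattr(s, attr) for s in summaries], dtype=float)
            flag = "ok" if abs(vals.mean() - mean_t) < sd_t else "OFF"
            print(f"  {attr:26s} {vals.mean():8.2f} +- {vals.std(ddof=1):7.2f}"
                  f"   target {mean_t} +- {sd_t}  [{flag}]")
        if (cls, comp) in PEAK_BANDS:
            lo, hi = PEAK_BANDS[(cls, comp)]
            peak = mean_sholl_peak(pops[cls], comp)
            flag = "ok" if lo <= peak <= hi else "OFF"
            print(f"  {'sholl_peak_radius':26s} {peak:8.1f}              "
                  f"target [{lo}, {hi}]  [{flag}]")


if __name__ == "__main__":
    main()
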