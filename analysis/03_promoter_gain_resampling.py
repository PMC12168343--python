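#!/usr/bin/env python
"""Target-set promoter gain against the random-gene-set resampling null.

Condition 2 adds a 4x promoter-proximal gain at 50 designated genes only;
the differential TSS signal of the target set is compared with 100
equal-size random sets of the remaining genes, repeated over seeds.
"""

import json
from pathlib import Path

from chromadapt.experiments import promoter_gain_detection

SEEDS = range(5)


def main() -> None:
    runs = {s: promoter_gain_detection(seed=s) for s in SEEDS}
    Path("results").mkdir(exist_ok=True)
    with open("results/03_promoter_gain.json", "w") as fh:
        json.dump(runs, fh, indent=1)
    for s, r in runs.items():
        print(f"seed {s}: observed {r['observed_summary']:+.2f} RPM vs null "
              f"max {r['null_max_summary']:+.2f}, p = {r['empirical_p']:.4f}")
    n_detected = sum(r["exceeds_null_max"] for r in runs.values())
    print(f"target set exceeded the 100-trial null max in "
          f"{n_detected}/{len(runs)} runs")


if __name__ == "__main__":
    main()
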