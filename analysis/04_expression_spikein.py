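#!/usr/bin/env python
"""Spike-in-normalized expression quantification under a library distortion.

Simulates counts with known fold changes and a 2x global library-scale shift
in condition 2, normalizes on spike-in RPKM sums, classifies genes by fold
change, and reports recovery of the truly changed genes.
"""

import json
from pathlib import Path

from chromadapt.experiments import spikein_recovery


def main() -> None:
    res = spikein_recovery(seed=1)
    Path("results").mkdir(exist_ok=True)
    with open("results/04_expression.json", "w") as fh:
        json.dump(res, fh, indent=1)
    print(f"spike-in sums equal across samples to "
          f"{res['spike_sum_max_rel_dev']:.1e} relative deviation")
    print(f"fold-change classification recovered "
          f"{100 * res['recovery_rate']:.1f}% of {res['n_changed']} "
          f"|log2 FC| >= 2 genes")


if __name__ == "__main__":
    main()
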