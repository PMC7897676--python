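#!/usr/bin/env python
"""Multi-deposition co-addition and the limit of identification (LOI).

Simulates a weak analyte repeatedly deposited on the IR disc, measures the
median QMF against the clean reference as depositions accumulate, and
records the smallest deposition count at which the spectrum becomes library
searchable (QMF >= 80) and confidently identified (>= 90). Writes
results/deposition_ladder.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from isoformid.ir import (DepositionSimConfig, limit_of_identification,
                          median_qmf_ladder)
from isoformid.simulate import IRSimConfig, simulate_ir_library


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--out", type=Path,
                        default=Path("results/deposition_ladder.csv"))
    args = parser.parse_args()

    library, _ = simulate_ir_library(IRSimConfig(seed=0))
    config = DepositionSimConfig(reference=library["fam1-iso1"],
                                 seed=args.seed)
    ladder = median_qmf_ladder(config)
    frame = pd.DataFrame({"n_depositions": range(1, len(ladder) + 1),
                          "median_qmf": [round(v, 1) for v in ladder]})
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False)
    print(frame.to_string(index=False))

    loi80 = limit_of_identification(config, 80.0)
    loi90 = limit_of_identification(config, 90.0)
    print(f"\nLOI at QMF threshold 80: {loi80} depositions")
    print(f"LOI at QMF threshold 90: {loi90} depositions")
    print("finding: a single weak deposit is unsearchable (QMF "
          f"{ladder[0]:.0f}); consecutive co-added depositions raise the "
          "median QMF monotonically past the identification threshold.")


if __name__ == "__main__":
    main()
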