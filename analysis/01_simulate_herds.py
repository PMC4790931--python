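#!/usr/bin/env python
"""Generate the two synthetic datasets the analyses run on.

Writes, under ``results/data/``:

* ``herd/`` — a 5 000-cow, 25-herd seasonal population over three parities
  with the 2-day male gestation offset and no true calf-gender effect
  (s1 lactations, s2 pedigree, s3 parity-1 test days, truth.json);
* ``testday_herd/`` — a single 50-cow herd with 8-10 monthly herd tests per
  cow, the input for Wood's-curve fitting and the bias study.
"""

import argparse
from pathlib import Path

from lactbias.synthetic_data import SimulationConfig, simulate_herd, write_herd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20160314)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    herd_cfg = SimulationConfig(n_herds=25, cows_per_herd=200, seed=args.seed)
    herd = simulate_herd(herd_cfg)
    paths = write_herd(herd, args.out / "herd")
    print(f"population herd: {len(herd.lactation_records)} lactation records, "
          f"{len(herd.pedigree)} pedigree entries -> {paths['s1'].parent}")

    td_cfg = SimulationConfig(n_herds=1, cows_per_herd=50, n_herd_tests=9,
                              seed=args.seed + 1)
    td = simulate_herd(td_cfg)
    paths = write_herd(td, args.out / "testday_herd")
    counts = [len(s.tests) for s in td.testday_series]
    print(f"test-day herd: 50 cows with {min(counts)}-{max(counts)} herd tests "
          f"-> {paths['s3']}")


if __name__ == "__main__":
    main()
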