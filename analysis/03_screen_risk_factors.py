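"""Screen clinical variables for significant association with each disorder.

Reads results/cohort.csv and, for every disorder class present, compares each
attribute's tracked-state proportion against the no-disorder group with the
pooled two-proportion z-test (two-sided, alpha 0.05).  Writes
results/screening.csv and prints the significant factors per class.
"""

import argparse
from pathlib import Path

import pandas as pd

from vdtsurv.cohort import CLASS_LABELS
from vdtsurv.pipeline import read_cohort
from vdtsurv.propstats import results_to_dataframe, screen_risk_factors


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--out", type=Path, default=Path("results/screening.csv"))
    args = parser.parse_args()

    records = read_cohort(args.cohort)
    frames = []
    for cls in CLASS_LABELS:
        if cls == "none" or not any(r.disorder == cls for r in records):
            continue
        results = screen_risk_factors(records, cls, alpha=args.alpha)
        frames.append(results_to_dataframe(results))
        hits = [r.variable for r in results if r.significant]
        print(f"{cls:<18} significant at alpha={args.alpha}: {', '.join(hits) or '(none)'}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
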