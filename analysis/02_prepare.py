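#!/usr/bin/env python
"""Apply the inclusion/exclusion criteria to a cohort CSV and report the
per-criterion removal counts."""

import argparse
import json
from pathlib import Path

from audmix.cohort_prep import apply_filters
from audmix.synthetic_data import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path, default=Path("results/data/contaminated.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/data/contaminated_filtered.csv"))
    ap.add_argument("--report", type=Path, default=Path("results/filter_report.json"))
    args = ap.parse_args()

    records = read_cohort(args.inp)
    filtered, report = apply_filters(records)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    filtered.to_csv(args.out, index=False)
    args.report.parent.mkdir(parents=True, exist_ok=True)
    args.report.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    print(json.dumps(report.to_dict(), indent=2))


if __name__ == "__main__":
    main()
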