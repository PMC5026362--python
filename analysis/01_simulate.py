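#!/usr/bin/env python
"""Generate the study cohorts: clean three-cluster, contaminated, random-
effects, and drift variants. Writes record and ground-truth CSVs."""

import argparse
from pathlib import Path

from audmix.synthetic_data import (
    GeneratorConfig,
    generate_cohort,
    generate_drift_cohort,
    write_cohort,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-pefs", type=int, default=300)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    configs = {
        "clusters": GeneratorConfig(n_pefs=args.n_pefs, seed=args.seed),
        "contaminated": GeneratorConfig(
            n_pefs=args.n_pefs, contamination_rate=0.2, seed=args.seed + 1
        ),
        "random_effects": GeneratorConfig(
            n_pefs=args.n_pefs,
            k_true=1,
            cluster_betas=((30.0, 1.0, 2.0, 0.3),),
            cluster_sigmas=(4.0,),
            mixing=(1.0,),
            random_effect_sd=(10.0, 2.0, 0.0, 0.0),
            seed=args.seed + 2,
        ),
        "drift": GeneratorConfig(
            n_pefs=args.n_pefs,
            k_true=1,
            cluster_betas=((30.0, 1.0, 2.0, 0.3),),
            cluster_sigmas=(4.0,),
            mixing=(1.0,),
            random_effect_sd=(10.0, 2.0, 0.0, 0.0),
            drift_rate=4.0,
            seed=args.seed + 3,
        ),
    }
    for name, cfg in configs.items():
        gen = generate_drift_cohort if cfg.drift_rate > 0 else generate_cohort
        records, truth = gen(cfg)
        write_cohort(
            records,
            args.out / f"{name}.csv",
            truth=truth,
            truth_path=args.out / f"{name}_truth.csv",
        )
        print(f"{name}: {len(records)} records -> {args.out / name}.csv")


if __name__ == "__main__":
    main()
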