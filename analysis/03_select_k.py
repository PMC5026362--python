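#!/usr/bin/env python
"""Select the number of latent clusters by held-out prediction accuracy:
fit k = 1, 2, ... on a training split, score each on withheld PEFs, and stop
at the accuracy plateau (or when a cluster is pruned)."""

import argparse
from pathlib import Path

import numpy as np

from audmix.cohort_prep import prepare
from audmix.evaluation import make_newpatient_split
from audmix.mixture_model import select_k
from audmix.prediction import predict_for_task
from audmix.synthetic_data import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path, default=Path("results/data/clusters.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/k_selection.csv"))
    ap.add_argument("--k-max", type=int, default=6)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    ds, _ = prepare(read_cohort(args.inp))
    split = make_newpatient_split(ds, 0.25, seed=args.seed)
    train, heldout = ds.subset(~split.test_mask), ds.subset(split.test_mask)

    def heldout_mse(model, resp):
        p = predict_for_task(model, resp, heldout, mode="new_pef")
        return float(np.mean((p.predicted_db - p.observed_db) ** 2))

    chosen, table = select_k(train, heldout_mse, k_max=args.k_max, seed=args.seed, n_starts=5)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    print(f"chosen k = {chosen}")


if __name__ == "__main__":
    main()
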