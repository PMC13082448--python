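#!/usr/bin/env python
"""Harmonize the dialect extracts and run the preprocessing chain.

Maps both survey dialects onto the canonical schema, derives smoking
cessation duration, encodes the 56-column feature matrix, imputes missing
cells (mean init + iterative linear regression), applies SVD denoising,
splits 70/30 at person level and balances the training classes with SMOTE.
Writes the processed arrays and a step-by-step log.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import risktransfer as rt

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

steps = []
for name, dialect in (("hrs_like", "hrs"), ("charls_like", "charls")):
    cohort = rt.harmonize(args.data / f"{name}.csv", dialect)
    steps.append((name, "harmonize", len(cohort.records), len(cohort.records.columns)))
    cohort = rt.derive_cessation(cohort)

    truth = pd.read_csv(args.data / f"{name}_truth.csv")
    cohort.records = cohort.records.merge(
        truth[["person_id", "wave_index", "latent_state"]],
        on=["person_id", "wave_index"],
    )
    fm = rt.build_feature_matrix(cohort, label="latent_state")
    steps.append((name, "encode", fm.n, len(fm.columns)))

    fm, converged = rt.impute(fm)
    steps.append((name, f"impute(converged={converged})", fm.n, len(fm.columns)))
    fm = rt.svd_denoise(fm, rank="auto")
    steps.append((name, "svd_denoise", fm.n, len(fm.columns)))

    if name == "hrs_like":
        train, test = rt.split(fm, (0.7, 0.3), seed=args.seed)
        balanced = rt.smote_balance(train, k=5, seed=args.seed)
        steps.append((name, "split_train", train.n, len(train.columns)))
        steps.append((name, "split_test", test.n, len(test.columns)))
        steps.append((name, "smote_train", balanced.n, len(balanced.columns)))
        for tag, part in (("train", balanced), ("test", test)):
            np.savez_compressed(
                args.data / f"features_{tag}.npz",
                X=part.X, y=part.y, columns=np.array(part.columns),
                person_id=part.ids["person_id"].to_numpy(),
                wave_index=part.ids["wave_index"].to_numpy(),
            )
    else:
        np.savez_compressed(
            args.data / "features_external.npz",
            X=fm.X, y=fm.y, columns=np.array(fm.columns),
            person_id=fm.ids["person_id"].to_numpy(),
            wave_index=fm.ids["wave_index"].to_numpy(),
        )

log = pd.DataFrame(steps, columns=["cohort", "step", "rows", "cols"])
log.to_csv(args.data / "preprocess_log.csv", index=False)
print(log.to_string(index=False))
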