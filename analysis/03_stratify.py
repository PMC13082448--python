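#!/usr/bin/env python
"""Train the weight-score network and stratify the cohorts.

Fits the 56-22-22-22-1 rectifier network by mini-batch SGD (lr 0.01,
batch 32, 30 epochs) on the balanced training split, scores every split,
applies the year-1992 weight thresholds (0.2 / 0.5 / 0.71 / 0.93) and
reports calibration and the confusion matrix against the hidden state.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import risktransfer as rt
from risktransfer.stratifier import DNNTrainConfig, calibrate, confusion, train_dnn

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--data", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

train = np.load(args.data / "features_train.npz", allow_pickle=True)
params, log = train_dnn(
    train["X"], train["y"], DNNTrainConfig(target="ordinal", seed=args.seed)
)
log.to_csv(args.data / "dnn_training_log.csv", index=False)
print(f"trained {len(log)} epochs; loss {log.loss.iloc[0]:.4f} -> {log.loss.iloc[-1]:.4f}")

summary = {}
for tag in ("train", "test", "external"):
    data = np.load(args.data / f"features_{tag}.npz", allow_pickle=True)
    scores = rt.forward(params, data["X"])
    strata = rt.stratify_scores(scores)
    out = pd.DataFrame(
        {
            "person_id": data["person_id"],
            "wave_index": data["wave_index"],
            "weight_score": scores,
            "stratum": strata,
        }
    )
    out.to_csv(args.data / f"strata_{tag}.csv", index=False)

    true = np.asarray(rt.RISK_STATES, dtype=object)[data["y"].astype(int)]
    mat, acc, per_class = confusion(strata, true)
    cal = calibrate(np.clip(scores, 0, 1), (data["y"].astype(int) == 0).astype(float))
    summary[tag] = {
        "n": int(len(out)),
        "accuracy": round(float(acc), 4),
        "per_class_accuracy": {k: round(v, 4) for k, v in per_class.items()},
        "brier_high_risk": round(cal.brier, 4),
        "log_loss_high_risk": round(cal.log_loss, 4),
    }
    print(f"{tag}: stratification accuracy vs hidden state {acc:.4f}")

(args.data / "stratifier_summary.json").write_text(json.dumps(summary, indent=1))
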