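#!/usr/bin/env python
"""Train the 14/10/8-channel ANN myoelectric controllers.

Generates the prompted-posture EMG dataset (32 postures x 10 reps) from
the default synergy model, applies the data hygiene steps (outlier
repetition exclusion; dead-channel detection is reported for reference —
the channel subsets already exclude the two noise-only channels), trains
one ANN per channel subset, and saves the models with their offline
test-split R^2 per DOF.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from smbench.ann_controller import save_model
from smbench.emg_features import CHANNEL_SUBSETS, detect_nonresponsive_channels
from smbench.pipeline import prepare_training_trials, train_controller
from smbench.synthetic_data import default_synergy_model


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/controllers"))
    args = ap.parse_args()

    synergy = default_synergy_model(seed=0)
    trials = prepare_training_trials(synergy, seed=args.seed)
    print(f"{len(trials)} trials retained after outlier-repetition exclusion")

    flags, ratios = detect_nonresponsive_channels(trials)
    print(
        "noise-only channels detected:",
        np.flatnonzero(flags).tolist(),
        "(movement/rest WFL ratios:",
        np.round(ratios, 2).tolist(),
        ")",
    )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    report = {}
    for subset in CHANNEL_SUBSETS:
        _, model = train_controller(trials, subset, seed=args.seed)
        save_model(model, args.out_dir / f"{subset}.json")
        r2 = np.round(model.test_r2, 3).tolist()
        report[subset] = {"epochs": model.n_epochs, "test_r2_per_dof": r2}
        print(f"{subset}: {model.n_epochs} epochs, test R^2 per DOF {r2}")

    (args.out_dir / "training_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
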