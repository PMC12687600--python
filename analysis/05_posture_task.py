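#!/usr/bin/env python
"""Closed-loop virtual posture-matching evaluation of the controllers.

Loads the trained 14/10/8-channel models, runs the paper-style session
counts (2/3/3 sessions of 80 pseudo-random targets) with the synthetic
user in the loop, and writes per-trial outcomes plus a per-controller
summary (match %, time-to-target, path efficiency as mean +/- SE over
per-posture session averages).
"""

import argparse
from pathlib import Path

import pandas as pd

from smbench.ann_controller import ControllerSpec, load_model
from smbench.emg_features import CHANNEL_SUBSETS
from smbench.pipeline import run_posture_sessions
from smbench.posture_task import summarize_task
from smbench.synthetic_data import default_synergy_model

N_SESSIONS = {"table_14ch": 2, "table_10ch": 3, "table_8ch": 3}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--models-dir", type=Path, default=Path("results/controllers"))
    ap.add_argument("--out", type=Path, default=Path("results/posture_task.csv"))
    args = ap.parse_args()

    synergy = default_synergy_model(seed=0)
    trial_rows, summary_rows = [], []
    for subset, n_sessions in N_SESSIONS.items():
        model = load_model(args.models_dir / f"{subset}.json")
        spec = ControllerSpec(channel_ids=CHANNEL_SUBSETS[subset], model=model)
        results, idx = run_posture_sessions(
            spec, synergy, n_sessions=n_sessions, n_targets=80, seed=args.seed
        )
        for i, (r, posture) in enumerate(zip(results, idx)):
            trial_rows.append(
                {
                    "controller": subset,
                    "session": i // 80 + 1,
                    "posture": posture,
                    "matched": r.matched,
                    "time_to_target_s": r.time_to_target,
                    "path_efficiency": r.path_efficiency,
                }
            )
        s = summarize_task(results, idx)
        summary_rows.append(
            {
                "controller": subset,
                "n_trials": s.n_trials,
                "match_pct": round(s.match_pct, 1),
                "time_to_target_s": None
                if s.time_to_target_mean is None
                else round(s.time_to_target_mean, 2),
                "time_to_target_se": round(s.time_to_target_se, 2),
                "path_efficiency_pct": None
                if s.path_efficiency_mean is None
                else round(100 * s.path_efficiency_mean, 1),
                "path_efficiency_se_pct": round(100 * s.path_efficiency_se, 1),
            }
        )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(trial_rows).to_csv(args.out, index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(args.out.with_name("posture_task_summary.csv"), index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
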