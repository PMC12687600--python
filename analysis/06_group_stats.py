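#!/usr/bin/env python
"""Statistical comparison of the three controllers.

Fisher's exact tests on matched/unmatched counts (match percentages) and
one-way ANOVA with Tukey HSD post-hoc on per-posture session-averaged
time-to-target and path efficiency, at alpha = 0.05.
"""

import argparse
import json
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from smbench.group_stats import anova_tukey, fisher_exact, mean_se


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=Path, default=Path("results/posture_task.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats.json"))
    args = ap.parse_args()

    df = pd.read_csv(args.trials)
    out = {"fisher_match_pct": {}, "anova": {}}

    counts = {
        c: (int(g["matched"].sum()), int((~g["matched"]).sum()))
        for c, g in df.groupby("controller")
    }
    for a, b in combinations(sorted(counts), 2):
        table = np.array([counts[a], counts[b]])
        out["fisher_match_pct"][f"{a} vs {b}"] = float(
            f"{fisher_exact(table):.3g}"
        )

    matched = df[df["matched"]]
    for metric in ("time_to_target_s", "path_efficiency"):
        per_posture = (
            matched.groupby(["controller", "posture"])[metric].mean().reset_index()
        )
        groups = {
            c: g[metric].to_numpy() for c, g in per_posture.groupby("controller")
        }
        res = anova_tukey(groups)
        out["anova"][metric] = {
            "F": round(res["F"], 3),
            "p": float(f"{res['p']:.3g}"),
            "tukey": {
                f"{a} vs {b}": float(f"{p:.3g}")
                for (a, b), p in res["pairwise"].items()
            },
            "group_mean_se": {
                c: [round(v, 3) for v in mean_se(vals)]
                for c, vals in groups.items()
            },
        }

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
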