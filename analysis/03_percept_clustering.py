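#!/usr/bin/env python
"""Unique-percept-location counts via Jaccard + complete-linkage clustering.

Reads the simulated sessions, clusters each session's non-painful
hand-clipped percepts, sweeps the dissimilarity cutoff over 0.01..1.00,
and reports cluster counts (mean +/- SE across sessions) at the reference
cutoffs 0.7 and 0.9 — overall and for per-nerve electrode subsets.
"""

import argparse
from pathlib import Path

import pandas as pd

from smbench.percept_clustering import (
    cluster_curve,
    nonpainful_predicate,
    summarize_sessions,
)
from smbench.percept_maps import clip_to_hand, load_session_manifest

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
load_template = import_module("02_percept_coverage").load_template


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--percepts-dir", type=Path, default=Path("results/percepts"))
    ap.add_argument("--out", type=Path, default=Path("results/cluster_curves.csv"))
    args = ap.parse_args()

    template = load_template(args.percepts_dir)
    curves, rows = [], []
    for manifest in sorted(args.percepts_dir.glob("*/session*/manifest.json")):
        rec = load_session_manifest(manifest)
        drawings = [clip_to_hand(d, template) for d in rec.drawings]
        curve = cluster_curve(
            drawings, system_id=rec.system_id, session_id=rec.session_id
        )
        curves.append(curve)
        for cutoff, count in zip(curve.cutoffs, curve.counts):
            rows.append(
                {
                    "system": rec.system_id,
                    "session": rec.session_id,
                    "subset": "all",
                    "cutoff": cutoff,
                    "clusters": count,
                }
            )
        # per-nerve subsets (median vs ulnar interfaces)
        for nerve in ("median", "ulnar"):
            sub = [d for d in drawings if d.nerve == nerve]
            kept = [d for d in sub if nonpainful_predicate(d) and d.mask.any()]
            if len(kept) < 2:
                continue
            c = cluster_curve(
                sub, system_id=f"{rec.system_id}:{nerve}",
                session_id=rec.session_id, subset=nerve,
            )
            curves.append(c)
            for cutoff in (0.7, 0.9):
                rows.append(
                    {
                        "system": rec.system_id,
                        "session": rec.session_id,
                        "subset": nerve,
                        "cutoff": cutoff,
                        "clusters": c.count_at(cutoff),
                    }
                )

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    summary = summarize_sessions(curves, cutoffs=(0.7, 0.9))
    print("unique percept clusters (mean +/- SE across sessions):")
    for system, per_cutoff in sorted(summary.items()):
        for cutoff, (mean, se) in per_cutoff.items():
            print(f"  {system:20s} cutoff {cutoff:.1f}: {mean:.1f} +/- {se:.1f}")


if __name__ == "__main__":
    main()
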