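#!/usr/bin/env python
"""Cumulative percept-location coverage per system, session and category.

Reads the session manifests written by 01_simulate_percepts.py, clips
drawings to the hand, and tabulates cumulative coverage (all percepts and
the tactile-only / proprioception-only / pain-only subsets) plus mean
single-contact percept areas in % of hand area and cm^2.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from smbench.percept_maps import (
    HandTemplate,
    clip_to_hand,
    cumulative_coverage,
    load_mask_png,
    load_session_manifest,
    percept_area,
)


def load_template(pdir: Path) -> HandTemplate:
    meta = json.loads((pdir / "template.json").read_text())
    mask = load_mask_png(pdir / "template.png")
    n = mask.shape[0]
    labels = np.full(mask.shape, "background", dtype=object)
    labels[:, :n][mask[:, :n]] = "palmar"
    labels[:, n:][mask[:, n:]] = "dorsal"
    return HandTemplate(
        mask=mask,
        panel_labels=labels,
        wrist_row=meta["wrist_row"],
        cm_per_pixel=meta["cm_per_pixel"],
    )


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--percepts-dir", type=Path, default=Path("results/percepts"))
    ap.add_argument("--out", type=Path, default=Path("results/coverage.csv"))
    args = ap.parse_args()

    template = load_template(args.percepts_dir)
    rows = []
    for manifest in sorted(args.percepts_dir.glob("*/session*/manifest.json")):
        rec = load_session_manifest(manifest)
        drawings = [clip_to_hand(d, template) for d in rec.drawings]
        areas = [100 * percept_area(d, template) for d in drawings]
        row = {
            "system": rec.system_id,
            "session": rec.session_id,
            "n_evoked": rec.n_evoked,
            "n_tested": len(rec.tested_contacts),
            "mean_area_pct": np.mean(areas) if areas else 0.0,
            "mean_area_cm2": np.mean(
                [percept_area(d, template, "cm2") for d in drawings]
            )
            if drawings
            else 0.0,
        }
        for filt in ("all", "tactile-only", "proprioceptive-only", "pain-only"):
            row[f"coverage_pct_{filt}"] = 100 * cumulative_coverage(
                drawings, template, None if filt == "all" else filt
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.2f")
    print(df.to_string(index=False))
    print("\nper-system means:")
    print(
        df.groupby("system")[
            ["coverage_pct_all", "coverage_pct_tactile-only", "mean_area_pct"]
        ].agg(["mean", "sem"]).round(1).to_string()
    )


if __name__ == "__main__":
    main()
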