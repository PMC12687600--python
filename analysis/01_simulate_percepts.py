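#!/usr/bin/env python
"""Simulate percept-drawing sessions for both stimulation systems.

Generates the shared hand template plus three sessions each for the
sparse 16-contact and dense 60-contact electrode models, and writes the
drawings as PNG masks with JSON session manifests — the same on-disk
format the downstream coverage/clustering drivers consume.
"""

import argparse
import json
from pathlib import Path

from smbench.percept_maps import save_mask_png
from smbench.synthetic_data import (
    generate_hand_template,
    generate_percept_sessions,
    isens_60contact_model,
    percutaneous_16ch_model,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sessions", type=int, default=3)
    ap.add_argument("--out-dir", type=Path, default=Path("results/percepts"))
    args = ap.parse_args()

    template = generate_hand_template(256)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    save_mask_png(template.mask, args.out_dir / "template.png")
    (args.out_dir / "template.json").write_text(
        json.dumps(
            {
                "wrist_row": template.wrist_row,
                "cm_per_pixel": template.cm_per_pixel,
                "total_hand_area_px": template.total_hand_area_px,
            },
            indent=2,
        )
    )

    systems = {
        "16ch": percutaneous_16ch_model(),
        "60contact": isens_60contact_model(),
    }
    for system_id, model in systems.items():
        sessions = generate_percept_sessions(
            model, template, args.sessions, seed=args.seed, system_id=system_id
        )
        for rec in sessions:
            sdir = args.out_dir / system_id / rec.session_id
            sdir.mkdir(parents=True, exist_ok=True)
            entries = []
            for d in rec.drawings:
                fname = f"{d.contact_id}.png"
                save_mask_png(d.mask, sdir / fname)
                entries.append(
                    {
                        "contact_id": d.contact_id,
                        "nerve": d.nerve,
                        "electrode_id": d.electrode_id,
                        "file": fname,
                        "qualities": sorted(d.qualities),
                    }
                )
            manifest = {
                "system_id": system_id,
                "session_id": rec.session_id,
                "drawings": entries,
                "tested_contacts": list(rec.tested_contacts),
            }
            (sdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            print(
                f"{system_id}/{rec.session_id}: {rec.n_evoked} of "
                f"{len(rec.tested_contacts)} tested contacts evoked hand percepts"
            )


if __name__ == "__main__":
    main()
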