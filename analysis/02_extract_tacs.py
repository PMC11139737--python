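#!/usr/bin/env python
"""Extract per-organ time-activity curves from the simulated study.

Reads the dynamic PET and segmentations written by 01_simulate_study.py,
computes mean decay-corrected concentrations per organ and frame, appends
the total-body remainder row, and writes one TAC CSV per examination to
results/tacs/.
"""

import json
from pathlib import Path

from rb82dose.io import read_dynamic_nifti, read_labelmap_nifti
from rb82dose.tacs import add_remainder, extract_tacs, write_tac_csv

STUDY = Path(__file__).parent.parent / "scratch" / "study"
OUT = Path(__file__).parent.parent / "results" / "tacs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((STUDY / "ground_truth.json").read_text())
    for stem, meta in manifest["examinations"].items():
        dyn = read_dynamic_nifti(STUDY / f"pet_{stem}.nii.gz")
        labels = read_labelmap_nifti(STUDY / f"seg_{stem}.nii.gz")
        tacs = add_remainder(
            extract_tacs(dyn, labels, meta["injected_MBq"]), dyn, labels
        )
        write_tac_csv(tacs, OUT / f"tacs_{stem}.csv")
        peak = tacs.frames["mean_kBq_per_mL"].max()
        print(f"{stem}: {len(tacs.organ_ids)} TAC rows, peak {peak:.1f} kBq/mL")
    print(f"wrote TAC tables to {OUT}")


if __name__ == "__main__":
    main()
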