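#!/usr/bin/env python
"""Transfer atlas region meshes between two phantoms via SDT registration.

One phantom acts as the annotated reference atlas, the second as the
subject; signed-distance surrogates drive rigid -> affine -> deformable
registration, region meshes ride the deformation, and per-region Dice
against the subject's ground truth goes to ``results/label_transfer.csv``.
"""

from pathlib import Path

import pandas as pd

from innerear.experiments import label_transfer_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = label_transfer_experiment()
    table = pd.DataFrame(
        sorted(result["region_dice"].items(), key=lambda kv: kv[1]),
        columns=["region", "dice"])
    table.to_csv(RESULTS / "label_transfer.csv", index=False)
    print(table.to_string(index=False))
    print(f"whole-labyrinth dice {result['whole_labyrinth_dice']:.3f}; "
          f"final narrow-band mismatch "
          f"{result['final_band_mismatch_mm']:.3f} mm")


if __name__ == "__main__":
    main()
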