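#!/usr/bin/env python
"""Build multivariate templates from a phantom cohort.

Six phantoms with independent noise and residual crop offsets are iteratively
aligned and averaged; the per-channel template/individual SNR gain and the
convergence history go to ``results/template_snr.csv`` and
``results/template_convergence.csv``.
"""

from pathlib import Path

import pandas as pd

from innerear.experiments import template_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = template_experiment(seed=7, n_subjects=6)
    snr = pd.DataFrame(
        [(c, r) for c, r in result["snr_ratio_per_channel"].items()],
        columns=["channel", "template_over_individual_snr"])
    snr.to_csv(RESULTS / "template_snr.csv", index=False)
    pd.DataFrame({
        "metric": ["history_first", "history_last", "mean_displacement_mm",
                   "mirror_asymmetry", "mirror_noise_sigma"],
        "value": [result["history_first"], result["history_last"],
                  result["mean_displacement_mm"], result["mirror_asymmetry"],
                  result["mirror_noise_sigma"]],
    }).to_csv(RESULTS / "template_convergence.csv", index=False)
    print(snr.to_string(index=False))
    print(f"mean SNR gain: {result['mean_snr_ratio']}")
    print(f"mirror asymmetry {result['mirror_asymmetry']:.4f} "
          f"(noise floor {result['mirror_noise_sigma']})")


if __name__ == "__main__":
    main()
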