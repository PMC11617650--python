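"""Cross-validate the three models and krige the predictive-ability surface.

Leave-one-trial-out and leave-region-out validation of the baseline
(irrigation + pedigree), kernel (marker kernels) and random-regression
(reaction-norm ensemble) models; metrics are per-trial Pearson/Spearman/RMSE
averaged over trials. The reaction-norm model's per-trial abilities are
interpolated over the grid by ordinary kriging with a spherical variogram.
"""

import pandas as pd

from enviromics.pipeline import stage_validate

from importlib import import_module

RUN_DIR = import_module("01_simulate").RUN_DIR
DEMO_CONFIG = import_module("01_simulate").DEMO_CONFIG


def main() -> None:
    report, summary = stage_validate(RUN_DIR, DEMO_CONFIG)
    print("cross-validation summary (mean +/- sd over trials):")
    print(summary.round(3).to_string())
    loo = summary.xs("loo", level="scheme")
    best = loo[("pearson", "mean")].idxmax()
    print(f"\nbest LOO model by mean per-trial Pearson: {best}")
    vario = pd.read_csv(RUN_DIR / "variogram.csv", index_col=0)["0"]
    print(f"fitted spherical variogram of LOO abilities: nugget {vario['nugget']:.4f}, "
          f"partial sill {vario['partial_sill']:.4f}, range {vario['range_km']:.0f} km")


if __name__ == "__main__":
    main()
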