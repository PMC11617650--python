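"""Delineate breeding zones and recommend genotypes and parents per bin.

Ward-clusters the bin-by-bin genetic correlations into four breeding zones,
summarises per-zone selection gain, and applies the two-step recommendation
(statistical ties, then geographic representativeness) plus the additive
parental-line recommendation.
"""

import pandas as pd

from enviromics.pipeline import stage_recommend, stage_zones

from importlib import import_module

RUN_DIR = import_module("01_simulate").RUN_DIR
DEMO_CONFIG = import_module("01_simulate").DEMO_CONFIG


def main() -> None:
    zones, table = stage_zones(RUN_DIR, DEMO_CONFIG)
    winners, occ, parents = stage_recommend(RUN_DIR, DEMO_CONFIG)
    print("breeding-zone summary (zone 1 = most productive):")
    print(table.round(3).to_string())
    print("\ntop 5 genotypes by area occupation:")
    cols = ["bins_won", "occupation_pct", "trial_bins_measured", "angle_mean"]
    print(occ.head(5)[cols].round(2).to_string())
    print(f"\nmost recommended cross: "
          f"{parents['cross'].value_counts().index[0]} "
          f"({parents['cross'].value_counts().iloc[0]} bins)")


if __name__ == "__main__":
    main()
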