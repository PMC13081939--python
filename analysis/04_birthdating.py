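"""Photoconversion birthdating series and topographic soma counts.

Simulates a conversion-timepoint series (18-54 hpf) in which dorsal nIII
neurons are born early and ventral nIII / nIV neurons late, classifies
cells as born-before from a max-of-controls red threshold, builds the
cumulative birthdate curve per region, and compares per-fish soma counts
between a control and a mutant cohort in which ventral nIII is depleted.

Writes results/birthdate_curves.csv and results/count_comparisons.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from omnquant.birthdating import (BIRTHDATING_TIMEPOINTS, REGIONS,
                                  RegionBoundaries, assign_region,
                                  classify_converted, control_threshold,
                                  count_by_region,
                                  cumulative_birthdate_curve)
from omnquant.stats import compare_counts
from omnquant.synthetic import generate_fluorescence_table

OUT = Path(__file__).resolve().parents[1] / "results"
BOUNDARIES = RegionBoundaries(cuts=(0.0, 30.0, 60.0, 90.0))

# mean birth time (hpf, normal sd 6) per region: dorsal early, ventral late
BIRTH_MEAN = {"dorsal_nIII": 26.0, "ventral_nIII": 42.0, "nIV": 40.0}
Z_RANGE = {"dorsal_nIII": (0.0, 29.9), "ventral_nIII": (30.1, 59.9),
           "nIV": (60.1, 89.9)}


def birthdate_series(seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    frames = []
    for tp in BIRTHDATING_TIMEPOINTS:
        for region in REGIONS:
            # fraction of this region born before the conversion timepoint
            frac = float(np.mean(rng.normal(BIRTH_MEAN[region], 6.0, 2000)
                                 <= tp))
            n = 40
            n_conv = int(round(frac * n))
            cells, controls = generate_fluorescence_table(
                n_conv, n - n_conv, n_controls=15, separation=8.0,
                seed=int(rng.integers(0, 2 ** 31)),
                z_range=Z_RANGE[region], timepoint_hpf=tp,
                fish_id=f"tp{tp}")
            cells = classify_converted(cells,
                                       control_threshold(controls))
            frames.append(assign_region(cells, BOUNDARIES))
    return pd.concat(frames, ignore_index=True)


def count_cohorts(seed: int) -> pd.DataFrame:
    """Per-fish soma counts: mutants lose ~half of ventral nIII."""
    rng = np.random.default_rng(seed)
    region_mean = {"WT": {"dorsal_nIII": 60, "ventral_nIII": 55, "nIV": 25},
                   "Mut": {"dorsal_nIII": 60, "ventral_nIII": 28, "nIV": 25}}
    rows = []
    for genotype, means in region_mean.items():
        for i in range(5):
            zs, ids = [], []
            for region, mu in means.items():
                n = max(int(rng.normal(mu, 5)), 0)
                zs += list(rng.uniform(*Z_RANGE[region], n))
            cells = pd.DataFrame({
                "cell_id": [f"c{j}" for j in range(len(zs))],
                "fish_id": f"{genotype.lower()}{i}", "z_um": zs})
            counted = count_by_region(assign_region(cells, BOUNDARIES))
            for region in REGIONS:
                rows.append({"fish_id": counted.loc[0, "fish_id"],
                             "genotype": genotype, "region": region,
                             "count": int(counted.loc[0, region])})
    return pd.DataFrame(rows)


def main(seed: int = 1):
    classified = birthdate_series(seed)
    curves = []
    for region in REGIONS:
        c = cumulative_birthdate_curve(classified, region)
        c.insert(0, "region", region)
        curves.append(c)
    curves = pd.concat(curves, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    curves.to_csv(OUT / "birthdate_curves.csv", index=False)
    half = {r: curves[(curves["region"] == r)
                      & (curves["fraction_born"] >= 0.5)]
            ["timepoint_hpf"].min() for r in REGIONS}
    print("timepoint by which half the region is born (hpf):", half)
    print(f"monotonicity violations: "
          f"{int(curves['monotone_violation'].sum())}")

    counts = count_cohorts(seed + 1)
    comparison = compare_counts(counts, regions=list(REGIONS))
    comparison.to_csv(OUT / "count_comparisons.csv", index=False)
    with pd.option_context("display.float_format", "{:.3g}".format):
        print(comparison.to_string(index=False))
    print(f"wrote {OUT / 'birthdate_curves.csv'} and "
          f"{OUT / 'count_comparisons.csv'}")
    return curves, comparison


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    main(seed)
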