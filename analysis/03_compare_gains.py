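"""Compare per-fish VOR gains across genotypes (ANOVA + Tukey HSD).

Reads results/fish_gains.csv (from 01_simulate_behavior.py) and runs,
per tilt direction, a one-way ANOVA with all-pairs Tukey HSD.  With the
simulated mutant deficit, wildtype-vs-mutant and heterozygote-vs-mutant
comparisons should be strongly significant and wildtype-vs-heterozygote
should not.

Writes results/gain_comparisons.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from omnquant.stats import GenotypeGroup, anova_tukey

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> pd.DataFrame:
    gains = pd.read_csv(OUT / "fish_gains.csv")
    rows = []
    for direction in ("gain_up", "gain_down"):
        sub = gains.dropna(subset=[direction])
        dropped = len(gains) - len(sub)
        if dropped:
            print(f"{direction}: dropped {dropped} fish with missing gain")
        groups = [GenotypeGroup(g, v[direction].to_numpy())
                  for g, v in sub.groupby("genotype")]
        res = anova_tukey(groups)
        for c in res.comparisons:
            rows.append({"direction": direction.removeprefix("gain_"),
                         "comparison": f"{c.group_a} vs {c.group_b}",
                         "mean_difference": c.mean_difference,
                         "q": c.q, "p_tukey": c.adjusted_p,
                         "F": res.F, "p_anova": res.p_anova})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "gain_comparisons.csv", index=False)
    with pd.option_context("display.float_format", "{:.3g}".format):
        print(df.to_string(index=False))
    print(f"wrote {OUT / 'gain_comparisons.csv'}")
    return df


if __name__ == "__main__":
    main()
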