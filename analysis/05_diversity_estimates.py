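"""Clonotype and sequence diversity: cross-tissue incidence, Chao richness
estimates, rarefaction curves and fraction sweeps per animal.
"""

import pandas as pd

from study_common import RESULTS, simulate_study
from vdjcompare import (assign_clonotypes, build_incidence, chao1, chao2,
                        diversity_vs_fraction, rarefaction)
from vdjcompare.diversity import _expand_keys

OUT = RESULTS / "diversity"


def main() -> None:
    study = simulate_study()
    OUT.mkdir(parents=True, exist_ok=True)
    rows, curves, sweeps = [], [], []
    for sid, entry in study.items():
        ln, sp = entry["lymph_node"], entry["spleen"]
        table = build_incidence(assign_clonotypes(ln), assign_clonotypes(sp))
        est2 = chao2(table)
        counts = pd.Series(_expand_keys(list(ln) + list(sp))).value_counts()
        est1 = chao1(counts.to_numpy())
        rows.append({"subject": sid, "s_obs": table.s_obs, "q1": table.q1,
                     "q2": table.q2, "chao2": est2.estimate,
                     "chao1": est1.estimate})
        curve = rarefaction(list(ln) + list(sp), seed=3)
        curve.insert(0, "subject", sid)
        curves.append(curve)
        for unit in ("clonotype", "sequence"):
            sweep = diversity_vs_fraction(ln, sp, fractions=[0.2, 0.5, 1.0],
                                          seed=4, unit=unit)
            sweep.insert(0, "unit", unit)
            sweep.insert(0, "subject", sid)
            sweeps.append(sweep)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "chao_estimates.tsv", sep="\t", index=False)
    pd.concat(curves).to_csv(OUT / "rarefaction.tsv", sep="\t", index=False)
    pd.concat(sweeps).to_csv(OUT / "diversity_vs_fraction.tsv", sep="\t",
                             index=False)
    for _, r in table.iterrows():
        print(f"{r['subject']}: S_obs {r['s_obs']}, Q1 {r['q1']}, "
              f"Q2 {r['q2']}, Chao2 {r['chao2']:.0f}, Chao1 {r['chao1']:.0f}")


if __name__ == "__main__":
    main()
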