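"""Public clonotype sharing.

Two levels are reported:

* subject level — sharing among the simulated animals' observed clonotype
  sets (small at this sampling depth: convergent clonotypes have generation
  probabilities that only deep pools can detect);
* pool level — deep per-species clonotype pools drawn directly from the
  preset models (120k rearrangements each), where the restricted rat-like
  preset shows markedly higher intra-species sharing than cross-species
  sharing, plus pool overlap, shared-vs-unshared CDRH3 lengths and position
  frequency matrices for sequence logos.
"""

import numpy as np
import pandas as pd

from study_common import RESULTS, pooled, simulate_study
from vdjcompare import (assign_clonotypes, cdr3_logo, compare_shared_unshared,
                        multiway_sharing, pairwise_sharing, pool_overlap,
                        simulate_rearrangements, species_preset)
from vdjcompare.diversity import record_key

OUT = RESULTS / "sharing"
POOL_DRAWS = 120_000


def deep_pool(preset: str, seed: int) -> set:
    model, _ = species_preset(preset)
    recs = simulate_rearrangements(model, POOL_DRAWS,
                                   np.random.default_rng(seed))
    return {record_key(r) for r in recs if r.productive}


def main() -> None:
    study = simulate_study()
    OUT.mkdir(parents=True, exist_ok=True)

    # --- subject level -----------------------------------------------------
    keys = {sid: assign_clonotypes(rep).keys()
            for sid, rep in pooled(study).items()}
    rats = {s: k for s, k in keys.items() if s.startswith("rat")}
    rows = []
    rat_ids = list(rats)
    for i, a in enumerate(rat_ids):
        for b in rat_ids[i + 1:]:
            res = pairwise_sharing(rats[a], rats[b], labels=(a, b))
            rows.append({"level": "subject", "a": a, "b": b,
                         **{m: res.fractions[m] for m in ("union", "mean")}})
    print(f"subject-level mean pairwise sharing (union): "
          f"{100 * np.mean([r['union'] for r in rows]):.3f}% "
          f"(shallow sampling; see pool level)")

    # --- pool level --------------------------------------------------------
    pools = {f"ratpool{i}": deep_pool("omnirat_like", 200 + i)
             for i in (1, 2, 3)}
    human_pool = deep_pool("human_like", 300) | deep_pool("human_like", 301)
    ids = list(pools)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = pairwise_sharing(pools[a], pools[b], labels=(a, b))
            rows.append({"level": "pool", "a": a, "b": b,
                         **{m: res.fractions[m] for m in ("union", "mean")}})
    pairs = pd.DataFrame(rows)
    pairs.to_csv(OUT / "pairwise_sharing.tsv", sep="\t", index=False)
    pool_pairs = pairs[pairs["level"] == "pool"]
    print(f"pool-level mean pairwise rat sharing (union): "
          f"{100 * pool_pairs['union'].mean():.3f}%")

    multi = multiway_sharing(pools)
    pd.DataFrame([{"region": "+".join(sorted(k)), "size": v}
                  for k, v in multi.venn_regions.items()]
                 ).to_csv(OUT / "venn_regions.tsv", sep="\t", index=False)
    print(f"clonotypes shared by all three rat pools: "
          f"{100 * multi.fractions['union']:.3f}% of the union")

    overlap = pool_overlap(pools, human_pool)
    print("fraction of each rat pool found in the human pool: "
          + ", ".join(f"{s} {100 * f:.3f}%"
                      for s, f in overlap.per_subject.items())
          + f"; combined {100 * overlap.combined:.3f}%")
    cross = pairwise_sharing(set.union(*pools.values()), human_pool,
                             labels=("rat_pool", "human_pool"))
    print(f"rat-pool vs human-pool sharing (union): "
          f"{100 * cross.fractions['union']:.3f}% — intra-rat sharing "
          f"exceeds cross-species sharing "
          f"({pool_pairs['union'].mean() > cross.fractions['union']})")

    rat_union = set.union(*pools.values())
    comp = compare_shared_unshared(rat_union, human_pool)
    out_rows = [{"side": "unshared", "mean_cdr3": comp.unshared_lengths.mean,
                 "n": comp.n_unshared}]
    if comp.shared_lengths is not None:
        out_rows.insert(0, {"side": "shared",
                            "mean_cdr3": comp.shared_lengths.mean,
                            "n": comp.n_shared})
        print(f"shared clonotypes mean CDRH3 {comp.shared_lengths.mean:.2f} "
              f"aa vs unshared {comp.unshared_lengths.mean:.2f} aa")
    pd.DataFrame(out_rows).to_csv(OUT / "shared_vs_unshared.tsv", sep="\t",
                                  index=False)

    for length in (8, 13):
        for side, pool in (("shared", rat_union & human_pool),
                           ("unshared", rat_union - human_pool)):
            try:
                pfm = cdr3_logo(pool, length)
            except ValueError:
                continue
            pfm.to_tsv(OUT / f"logo_{side}_len{length}.tsv")


if __name__ == "__main__":
    main()
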