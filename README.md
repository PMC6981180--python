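# vdjcompare

Comparative analysis of antibody repertoires, built around the question of
how well a humanized rodent model (an OmniRat-style animal carrying human
V, D and J gene segments) reproduces the human heavy- and kappa-chain
repertoire. The package provides, as one tested library:

* a **V(D)J recombination simulator** with species-like presets and full
  ground truth (true clones, true generative model, two-tissue sampling,
  isotype mixture, somatic hypermutation), so every downstream statistic can
  be validated against known parameters;
* **repertoire statistics**: gene-segment usage with z-score heatmap
  matrices and hierarchical clustering (Euclidean distance, average
  linkage), pairwise usage regressions, CDR3/insertion length
  distributions, DH3-family x JH6 co-usage, cumulative long-CDRH3 curves,
  isotype frequencies and SHM summaries;
* **recombination-model inference and comparison**: a factorized generative
  model P(V) P(D,J) P(vTrim|V) P(dTrim5,dTrim3|D) P(jTrim|J) P(N1) P(N2)
  estimated from annotated rearrangements, synthetic-sequence generation
  from a model, and per-event / complete Kullback–Leibler divergence
  (forward, in bits, chain rule over events);
* **diversity estimation**: exact-identity clonotypes (V gene, J gene,
  CDRH3 amino-acid sequence), lymph-node/spleen capture–recapture incidence,
  the Chao2 estimator `S_obs + (1/2) Q1^2 / (2 Q2)` (with the bias-corrected
  form when Q2 = 0) and Chao1, rarefaction curves and fraction sweeps;
* **public clonotype sharing**: exact Venn regions by inclusion–exclusion,
  pool overlap, shared-vs-unshared CDRH3 length and V-family contrasts, and
  position frequency matrices for CDR3 sequence logos.

Inputs are AIRR-C rearrangement TSVs and IMGT-style germline FASTA; all
tables the package writes are TSV/JSON/Newick.

## Worked example

```python
import numpy as np
from vdjcompare import (species_preset, simulate_rearrangements, infer_model,
                        kl_complete, length_distribution, chao2,
                        build_incidence, assign_clonotypes,
                        simulate_repertoire)
from vdjcompare.records import Repertoire

rat, rat_cfg = species_preset("omnirat_like")
hum, _ = species_preset("human_like")
rng = np.random.default_rng(0)
rat_reads = Repertoire(simulate_rearrangements(rat, 20_000, rng)).productive()
hum_reads = Repertoire(simulate_rearrangements(hum, 20_000, rng)).productive()
print(length_distribution(rat_reads, "cdr3_length").mean)   # 12.10 aa
print(length_distribution(hum_reads, "cdr3_length").mean)   # 14.92 aa

inferred = infer_model(rat_reads, template=hum)
print(kl_complete(rat, inferred))   # 0.184 bits (close to its source)
print(kl_complete(rat, hum))        # 0.999 bits (species apart)

rat_cfg.n_clones, rat_cfg.n_reads_per_compartment = 1000, 10_000
rat_cfg.tissue_overlap_prob, rat_cfg.seed = 1.0, 7
rat_cfg.shm_rate_igm = rat_cfg.shm_rate_igg = 0.0
ln, sp, truth = simulate_repertoire(rat_cfg)
est = chao2(build_incidence(assign_clonotypes(ln, include_nonproductive=True),
                            assign_clonotypes(sp, include_nonproductive=True)))
print(est.estimate, est.s_obs)      # 979, 950 — true richness is 1000
```

The rat-like preset produces shorter CDRH3s than the human-like preset
because it draws shorter non-templated insertions and favours short D
segments; the inferred model sits ~5x closer (in complete KL) to its
generating model than the two species presets sit to each other; and the
two-compartment Chao2 estimate recovers the simulated clonal richness.

## Analysis scripts

`analysis/01_simulate_study.py` … `06_clonotype_sharing.py` run the full
comparative study on synthetic data (three rat-like animals with lymph-node
and spleen compartments, two human-like subjects): usage clustering, CDR3
and junction statistics, recombination-model inference with KL comparison,
Chao diversity and rarefaction, and clonotype sharing. Each script prints
what it found and writes its tables under `results/`. The same pipeline is
available as a CLI (`vdjcompare run-all --config study.yaml`), including a
`simulate` subcommand that writes AIRR TSVs plus a ground-truth sidecar.

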