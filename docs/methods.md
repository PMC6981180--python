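# Methods

## The generative model of heavy-chain V(D)J recombination

A rearrangement scenario is factorized into independent events:

    P(scenario) = P(V) · P(D, J) · P(vTrim3 | V) · P(dTrim5, dTrim3 | D)
                  · P(jTrim5 | J) · P(N1) · P(N2)

with non-templated (N) insertion nucleotides drawn from a first-order
Markov chain over {A,C,G,T} and optional P nucleotides — palindromic
duplications of at most 2 nt that can occur only at an untrimmed coding
end (length probabilities 0.5/0.3/0.2 for 0/1/2 nt). The kappa chain uses
the analogous V–J factorization with a single insertion event.

Sequences are assembled on toy germline sets packaged with the library
(12 V, 9 D, 6 J heavy; 10 V, 5 J kappa; all sequences synthetic). Each V
ends in a conserved Cys codon followed by a short trimmable tail; each J
carries its conserved Trp/Phe codon at a known offset. The junction runs
from the Cys codon to the end of the W/F codon, `junction_aa` includes
both anchors, and `cdr3_aa` excludes them (IMGT convention). A record is
productive when the junction length is a multiple of three, the
translation starts with C, ends with W or F, and contains no stop codon.
Non-productive draws are kept and flagged, not redrawn; every statistic
excludes them by default (`include_nonproductive=True` overrides, and is
the right view for quantities that are properties of the read rather than
of the junction, e.g. isotype fractions and raw SHM load).

### Species presets

`human_like` and `omnirat_like` share one germline reference — required
for their models to be KL-comparable — and differ only in event
distributions. The presets were calibrated once, by analytic expectation
over the factorization, to the regime of the system they emulate:

| quantity | rat-like | human-like |
|---|---|---|
| mean CDRH3 (aa, productive) | ~12.1 | ~15.0 |
| mean VD / DJ insertion (nt) | 4.0 | 6.0 |
| D3-family × J6 co-usage | ~0.010 | ~0.028 |
| 5-aa CDRL3 frequency | ~0.06 % | ~0.7 % |
| IgG fraction (lymph node / spleen) | 0.15 / 0.003 | 0.16 / 0.16 |
| SHM mean, IgM / IgG (nt) | 2 / 10 | 4 / 20 |

Trim laws are truncated geometrics (means 1.5–2.5 nt; the rat-like preset
trims the D 3' end harder), insertion laws are zero-inflated negative
binomials (r = 4; zero-weight 0.20 rat-like, 0.10 human-like). The zero
inflation models TdT-independent junctions; these insertion-free
rearrangements carry essentially all convergent-recombination
("public clonotype") probability mass, and without them inter-animal
sharing would be structurally zero at any sampling depth. The rat-like
preset also biases D-segment choice toward the short D1/D5/D6/D7 toy
segments, mirroring the shorter wild-type rat D germline (a separate pair
of synthetic D-only FASTA sets is packaged for the germline length
contrast itself). Quantities for which only a direction is known
(trim means, the exact rat insertion law) are tuning choices and marked
as such here.

### Two-compartment repertoire simulation

Each of `n_clones` clones is one independent rearrangement. A clone seeds
both lymph node and spleen with probability `tissue_overlap_prob`
(default 0.05), otherwise one compartment uniformly. Clone sizes follow a
Zipf law with exponent α = 2.0 (capped at 10^5); reads are multinomial in
clone size within each compartment, and each read independently receives
an isotype (Bernoulli by tissue) and a Poisson number of point
substitutions uniform over its V region (junction positions included;
CDR3 and productivity are recomputed). One root seed drives fixed,
independent subsystem streams, so identical configurations give
byte-identical AIRR output.

The α = 2.0 clone-size law is deliberately heavy-tailed to exercise the
rarefaction/Chao machinery, with a consequence worth knowing: the largest
clone holds roughly 10 % of reads at any depth, so *read-weighted*
cross-repertoire comparisons are dominated by a handful of clones at desk
scale. Cross-repertoire analyses (usage clustering, regressions, species
contrasts of CDR3/insertion lengths) therefore use `collapse="clonotype"`
— each unique clonotype counted once — which is also standard practice on
real AIRR data. Read-weighted mode remains the default of every statistic.

## Inference and KL divergence

`infer_model` is annotation-based: each record contributes its single best
annotation (no marginalization over hidden recombination scenarios, an
explicit simplification relative to EM-based tools), and every event
distribution is `(count + c) / (total + c·|support|)` with pseudocount
c = 0.5 over a declared support fixed by a template model, so that models
inferred from different repertoires stay comparable and divergences stay
finite. Insertion-nucleotide Markov parameters are not inferred (records
carry lengths, not insertion strings) and are excluded from KL.

KL divergence is forward, D(p‖q), base 2. Conditional events take the
expectation over the parent's marginal under p, so the sum over all seven
events equals the KL between the full joint scenario distributions — an
identity tested against exhaustive enumeration on a 256-cell toy model.
A symmetrized (Jeffreys) option exists. With 20k–100k training sequences
the inferred-vs-truth complete KL is below 0.01–0.05 bits, far below the
~1 bit separating the two presets; training sets of tens of sequences
(e.g. the unmutated survivors of a shallow, heavily mutated repertoire)
give noise-dominated divergences, which is why the species-contrast KL
analyses train on deep SHM-free draws.

## Diversity estimation

Clonotype = exact (allele-stripped V gene, J gene, CDRH3 aa) identity.
The two tissues are the m = 2 sampling units of an incidence design:
Q1 = clonotypes in exactly one unit, Q2 = in both,

    Chao2 = S_obs + ((m−1)/m) · Q1² / (2·Q2),

bias-corrected `S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1))` when Q2 = 0. Chao1
is the abundance analogue on singleton/doubleton counts; "sequence
diversity" uses unique full V(D)J nucleotide strings as the unit.
Both are lower-bound-type estimators. Rarefaction subsamples reads
without replacement (duplicate counts expanded), 10 replicates per
fraction except the 1.0 fraction, which is computed once.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses assume —
factorized recombination with species-distinct event laws, clonal
abundance skew, two-compartment clone sharing, isotype-dependent SHM —
and so validates the estimators and the direction of every species
contrast. It does not reproduce: real germline allele diversity (toy gene
sets, tens of genes), SHM hotspot targeting (substitutions are
position-uniform), sequencing error (assumed corrected upstream), the
lambda locus, or real repertoire scale. Scale matters most for sharing:
with realistic generation-probability concentration, repertoires of ~10³
observed clonotypes essentially cannot overlap, so sharing magnitudes
here come from deep pools of ≥10⁵ draws per species and are scaled-down
(~0.2 % pairwise between rat-like pools vs ~0.09 % rat–human) relative to
full-scale studies where millions of clonotypes per animal yield sharing
in the percent-to-tens-of-percent range. The direction — restricted
rat-like repertoires share far more among themselves than with a
human-like pool, and shared clonotypes have shorter CDRH3s — is
depth-independent and is what the tests assert.

## Numerical and design choices

* Gene calls are analysed allele-stripped (`IGHV4-34*01` → `IGHV4-34`);
  the verbatim call is preserved.
* Usage z-scores use the population (n-denominator) SD; zero-variance
  rows map to all-zeros. Clustering is average-linkage on Euclidean
  distance; labels are pre-sorted lexicographically so ties resolve
  reproducibly. Usage regressions renormalize over the intersection of
  gene supports.
* Sharing fractions are always reported under three normalizations
  (union / mean set size / per-set); union (Jaccard) is the default.
  Shared-vs-unshared contrasts weight each unique clonotype once.
* Sequence-logo matrices flag the first 2 and last 2 positions as torso;
  residue categories: polar GSTYCQN, basic KRH, acidic DE, hydrophobic
  AVLIPWFM.
* All probability vectors must sum to 1 within 1e-9; model JSON
  round-trips exactly at double precision.
* Degenerate inputs: empty repertoires, empty groups, single-record
  groups (SEM 0 with a flag), Q2 = 0, F2 = 0 and missing-length columns
  all have defined behaviour tested explicitly.

## Problem sizes

Tests and the acceptance script run the study at desk scale, chosen as
the package's own working sizes: 6,000 clones and 2 × 8,000 reads per
simulated animal (3 rat-like + 2 human-like), 100,000 training sequences
for model recovery, 30,000 for each model in the KL species contrast,
60,000 kappa draws per preset, 120,000-draw clonotype pools for sharing,
and S = 1,000 true clones at 10× depth for Chao2 recovery. Full-scale
data (10⁶–10⁷ reads per animal) would be consumed through the same AIRR
ingestion path via the pipeline's `inputs` config.

## Known limitations

Annotation-based inference is consistent only when the input annotations
are exact (true for simulator output; real annotators introduce their own
biases). The Chao estimators are lower bounds and undershoot under strong
abundance skew at low depth. The toy germline sets make absolute usage
and sharing values incomparable to real repertoires; only directions and
estimator behaviour transfer. Kappa-chain modelling is simulation-only
(no KL machinery), matching its analysis role.
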