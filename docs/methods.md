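# Methods

This note documents the models behind `polycross`, the defaults that matter,
what the simulator does and does not emulate, and the design choices that
were genuinely open.

## Genotypic-analysis scores

All three scores are unweighted proportions over markers; a marker enters a
score only when every vector that score reads (the sample; one or both
parents) is observed there, so numerator and denominator shrink together and
every defined score lies in [0, 1]. A score with an empty denominator is NaN
and the individual is excluded from clustering with a warning — at realistic
marker counts this is a degenerate case (it requires, e.g., a parent with no
observed nulliplex marker).

GA-II's denominator is the count of markers at which the *parent* is an
observed nulliplex, not all markers. This is what makes the score's
theoretical value for a selfed offspring equal to 1: under polysomic
inheritance a parent without the alternate allele at a locus cannot transmit
it, so selfed progeny are nulliplex wherever the parent is. Against the
non-selfing parent, hybrids score well below 1 because the other parent's
gametes carry alternate alleles at many of those loci.

GA-III relies on the gamete-dosage interval: with bivalent pairing and no
double reduction, a parent of dosage d in a 2h-ploid transmits between
max(0, d−h) and min(h, d) alternate copies, and every value in between is
attainable (any subset of h chromosomes can end up in one gamete). The
compatible offspring set is therefore the interval sum of the two parental
gamete intervals. The same formula serves tetraploids and hexaploids; unit
tests verify it against brute-force enumeration of all (2h choose h)
chromosome subsets for ploidy 2, 4 and 6. Double reduction, which can
produce gametes outside the interval at loci distal to a crossover, is not
modeled; at realistic frequencies its effect on a genome-wide proportion is
far below the contaminant signal.

## Classifier

Features are the 5-vectors (GA-I×2, GA-II×2, GA-III), unscaled — all five
are already proportions on [0, 1]. Distances are Euclidean; clustering is
average linkage (UPGMA, `scipy.cluster.hierarchy`); the dendrogram is cut
at every k in 2..15 (cuts that collapse to the same effective cluster count
are considered once).

The cluster count is chosen by majority vote of nine internal validity
indexes: Calinski–Harabasz, mean silhouette, Dunn, Davies–Bouldin, C-index,
McClain–Rao, point-biserial, Baker–Hubert gamma, and the SD index (its
dispersion weight taken at the largest usable k). Calinski–Harabasz,
silhouette and Davies–Bouldin come from scikit-learn; the others are
implemented from their standard definitions in `polycross.indices`. Ties are
broken toward smaller k; the top three vote-getters are retained because
examining the three leading schemes measurably improves recovery of
contaminant types on benchmark populations.

Classification is sequential on cluster-level GA medians with a single
ad-hoc threshold (default 0.75): the reference hybrid cluster is the one
with the minimum median GA-III (ties go to the larger cluster), and it can
never be called contaminant — this protects low-diversity crosses in which
hybrids share many parental dosages. Rule 1 (AC) may fire for several
clusters and attributes the parent with the larger GA-I median; clones of
either parent also satisfy the GA-II rule, which is why the AC rule runs
first. A non-reference cluster matching no rule is called HP with a warning
rather than being forced into a contaminant class.

## Simulator

The generator mirrors the validation study design end to end:

- **Map**: 8 chromosomes, lengths uniform in 90–120 cM, 600–900 markers per
  chromosome placed on a 0.1 cM lattice (which enforces the minimum
  adjacent-marker spacing by construction), centromere position (metadata)
  uniform in 10–50 cM.
- **Parents**: each marker's dosage is drawn from a per-parent dosage-rate
  profile, then placed on that many uniformly chosen homologs. The four
  shipped profiles are explicitly made up: P1/P2 emulate two related crossing
  parents of one species, P3/P4 two unrelated foreign founders of a
  different species, and they are deliberately distinct — distinct genotypes
  have distinct dosage spectra, and the distinctness of P3 vs P4 is what
  makes the two half-sib families separable GA populations, as observed in
  real multi-founder contamination. All profiles are overridable.
- **Meiosis**: homologs pair uniformly at random into bivalents (preferential
  pairing zero); the transmitted chromatid follows one homolog and switches
  at the points of a Poisson process of rate 1 per Morgan, i.e. the Haldane
  no-interference model, reproducing r = (1 − e^(−2d))/2 exactly (verified
  against the closed form in tests). Quadrivalent pairing and double
  reduction are omitted as second-order for genome-wide dosage proportions;
  crossover interference is not modeled.
- **Noise**: 5% of non-missing progeny genotypes are replaced by one of the
  other ploidy dosage values uniformly (never their own value); per marker a
  missing rate u ~ U(1%, 5%) is drawn and round(u·n) progeny cells are
  blanked. Parent rows stay error-free and complete — they serve as
  references, and consensus rows from replicated parent genotyping justify
  treating them as far cleaner than progeny.
- **Benchmark populations**: 200 individuals, contaminant count uniform in
  1..50, split over {AC(P1), SP(P1), HS(P1×P3), HS(P1×P4), FC(P3×P4)} by
  type probabilities uniform in [0.1, 0.8], normalized and rounded by
  largest remainder. One map and parent quartet are shared across replicate
  populations (a single simulated marker universe); each population draws
  its own marker subset, meiosis, errors and missingness. Marker subsets are
  taken by restricting the map *before* simulating meiosis — a gamete's
  alleles at a marker subset depend only on that subset's positions, so this
  is distributionally identical to simulating everything and dropping
  columns, at a fraction of the cost.

What the simulator does not emulate: read-depth-dependent dosage-calling
error (errors here are uniform over wrong dosages, whereas real dosage
callers confuse adjacent dosages preferentially), somaclonal mutation,
null alleles, segregation distortion, and linkage disequilibrium inherited
from population structure. One visible consequence: simulated clones score
GA-I ≈ 0.95 against their parent under the 5% error model, whereas real
apomictic clones tend to land around 0.8–0.9 because additional biological
and technical divergence accumulates; passing tests therefore bound the
noise model, not every real-data artifact.

## NIPALS PCA

Columns are mean-centered over observed entries only; no unit-variance
scaling (dosages share one scale; whether to scale was left open by
precedent and centering-only is the common default for dosage data).
Components are extracted by alternating score/loading regressions that skip
missing cells, with deflation between components; defaults tol = 1e-6,
max_iter = 1000, 2 components. Signs are fixed by making the
largest-magnitude loading positive. On complete data the result matches the
eigendecomposition of the covariance of the centered matrix (tested to
1e-6), and per-component variance fractions equal eigenvalue fractions. With
missing data the variance fractions are computed against the total observed
sum of squares. PCA is deliberately only a screening device: the package
draws no automated conclusion from PC coordinates, because leading
components fail to expose contamination below roughly 3% of the progeny;
the artificial-clone injection (default 25% of the progeny, rows tagged
synthetic and excluded from GA and reports) is the supported workaround.

## Problem sizes and determinism

Benchmark defaults are 50 replicate populations per marker-set size at
sizes 2,758 / 1,379 / 689 / 344 — large enough that the mean rates are
stable to a couple of percent, small enough to run in minutes on one CPU;
the replicate count is configurable upward. All stochastic stages consume a
caller-supplied seeded generator; identical (configuration, seed) pairs
reproduce matrices, labels, votes and reports bit-for-bit. Cut, vote and
classification are invariant to individual and marker order.

## Known limitations

- Bivalent-only meiosis: no quadrivalents, no double reduction, preferential
  pairing fixed at zero.
- HS and FC are a single call class (HSFC); distinguishing them needs the
  foreign parents' genotypes, which the method assumes unavailable.
- The validity-index battery is a fixed, documented set of nine indexes;
  other index collections can shift the voted k on borderline populations.
- Parents must be supplied as one consensus row each; replicate parent rows
  are not merged by the package.
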