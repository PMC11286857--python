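# Methods

## Model overview

`syndrumnet` predicts synergistic drug combinations for a query disease
from the topology of an undirected human molecular interaction network and
from expression signatures, without training on known combinations. The
assumptions are those of the network-medicine framework: disease
susceptibility genes and drug response genes form localised modules on the
interactome; a drug perturbs a disease when its module lies close to the
disease module; and two drugs act synergistically when each covers part of
the disease neighbourhood while the two drug modules remain topologically
separated ("Complementary Exposure"), rather than hitting the same region
twice.

All distances are unweighted shortest-path lengths (hops) on the giant
component of the network, so every distance is finite. Edges are
undirected and unweighted; self-loops and duplicate edges are removed at
load time.

### Proximity

The closest distance d(Q,A) averages, over drug-module genes, the hop
distance to the nearest disease-module gene. Raw distances depend heavily
on module sizes and hub content, so d is standardised against a
permutation null: in each of n_perm = 100 repetitions, both gene sets are
replaced by uniform draws from degree bins matching the originals' size
and degree profile, and z = (d_obs − μ)/σ over the null sample. Exact-
degree bins are merged upward until each holds ≥ 100 nodes (configurable);
the merge threshold trades degree fidelity against bin-exhaustion risk and
100 is the conventional floor for interactome-scale graphs. If the null is
degenerate (σ = 0, possible only on toy graphs), z is set to 0 and the
result flagged. Sign-inverted min–max scaling across the drug collection
maps the most disease-proximal drug to P = 1, the least to P = 0; the
scaling population is the full drug collection of the run.

### Separation

s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2, with ⟨d_AA⟩ the mean distance of each
module gene to its nearest *other* module gene (0 for singletons) and
⟨d_AB⟩ the mean, over all genes of both modules, of the distance to the
nearest gene of the opposite module (genes shared by both modules
contribute 0). Positive s means the modules occupy distinct network
neighbourhoods. No permutation null is used for s: with ~10⁶ drug pairs a
resampled null per pair would dominate the run time, and the score only
consumes the sign of s.

### Topological classes and the T component

The triple (z_QA < 0, z_QB < 0, separated) defines six classes for an
unordered pair. Class II (both z negative, modules separated) is
Complementary Exposure and earns T = 2; all others earn 0. *Separated*
means s_AB > 0 by default: the separation measure is constructed so that
positive values indicate disjoint neighbourhoods, and the published
high-scoring pairs all combine T = 2 with positive s. A
`separation_sign="negative"` switch inverts the convention for
compatibility with texts that state the class-II inequality the other way
round.

### Transcriptional correlation and propagation

C_QA is the cosine (not Pearson — no centering) of the two signature value
vectors restricted to the genes shared by the disease and drug modules.
Raw module overlaps are typically below 10 genes, which makes the cosine
noisy or undefined; below `min_overlap` (default 3 — enough genes for the
cosine to carry sign information at all) the correlation is treated as
undefined and the pair is scored with C = 0 and a flag rather than
dropped, so rankings always cover all pairs.

To enlarge the overlaps, modules are expanded by propagation with prior
knowledge. The network is normalised symmetrically (W′ = D^(−1/2)W
D^(−1/2), spectral radius ≤ 1) and F_t = αW′F_{t−1} + (1−α)Y is iterated to
its fixed point F* = (1−α)(I−αW′)^(−1)Y. The prior Y is 1 on the entity's
own module genes and, for genes outside it, the maximum similarity of any
related entity whose module contains the gene (`prior_agg="max"`, the
strongest-evidence heuristic; `"sum"` is available). Disease priors use
network-based disease similarity (proximity z to other diseases' gene
sets, sign-inverted and unit-scaled); drug priors use chemical fingerprint
similarity (generalized Jaccard on non-negative feature counts). Expansion
admits the top-k propagation-scored network neighbours of the module
(default k = module size, applied identically to disease and drug
modules); the no-prior variant admits all neighbours. Defaults α = 0.5,
tol = 10⁻⁶, max_iter = 1000 are declared package defaults: α = 0.5 weights
network smoothing and prior evidence equally, and the tolerance is far
below any score difference the expansion rule can act on.

### Ranking and evaluation

score = T + P_QAB + C_QAB with P_QAB and C_QAB the pair means of P and
|C|. All C(n,2) pairs are ranked descending, ties broken lexicographically
so output is independent of input order. ROC AUC is computed in the
Mann–Whitney form (average ranks; ties count ½) and cross-checked in the
tests against a brute-force pairwise comparison.

### Synergy statistics

Effects are inhibition fractions e = 1 − survival; survival above 100%
(stimulation) clamps the effect to 0 with a flag. Bliss independence
expects a combined effect CI_mix = 1 − (1−v)(1−w); the synergy call is
*observed effect > CI_mix* (excess over Bliss), because the tabulated rule
"CI ≥ 1 ⇒ synergy" cannot be satisfied by the CI_mix formula itself, whose
range is [0, 1]. Both the raw CI_mix and the excess are reported, and a
separate helper applies the tabulated ≥ 1 rule to already-printed IA score
columns. Loewe additivity computes TU = C_a/EC_u^A + C_b/EC_u^B at the
combination's observed effect level u; TU < 1 (strict) calls synergy. EC_u
is interpolated log-linearly between bracketing measured points — no
parametric (4PL) fit is imposed — with isotonic cleanup of non-monotone
curves and no extrapolation outside the observed effect range (the toxic
unit is then undefined and flagged).

### Pathway analytics

Over-representation uses the one-sided hypergeometric tail with a
caller-supplied background universe and no multiplicity correction by
default (significance at raw p < 0.05), matching common practice for
module-level screens. Pathway coverage is |target ∩ drug-union| / |target|
over enriched pathway sets. Within-pathway clustering is measured by the
largest connected component (LCC) of the module genes in the pathway's
induced subgraph, standardised against uniform same-size draws from the
pathway's genes — degree matching is unnecessary at pathway scale
(tens of genes) — with the conventional z > 1.95 cutoff. DEG filtering
keeps genes with |log2FC| ≥ threshold (boundary included), default 1.

## The synthetic benchmark

The generator plants the statistical structure the method exploits, at a
scale where the full pipeline runs in seconds:

* **Network**: preferential-attachment graph (2,000 genes, m = 2),
  connected with a heavy-tailed degree distribution — the two interactome
  features the proximity machinery is sensitive to. It does not reproduce
  interactome clustering coefficients, community structure, or annotation
  biases.
* **Disease module**: the 80-gene breadth-first neighbourhood of the
  highest-degree node, i.e. a localised cluster.
* **Planted drugs**: 10 modules of 40 genes grown from distinct anchors on
  the disease module's boundary, mutually disjoint, each sharing a small
  fraction (5%, two genes) with the disease module itself. Consecutive
  drugs on a ring form the 10 labelled synergistic pairs, giving 10
  positives among C(50,2) = 1,225 candidate pairs. Cross pairs of planted
  drugs are topologically indistinguishable from labelled pairs; they cap
  the achievable AUC slightly below 1 and are kept deliberately as
  realistic look-alikes.
* **Decoys**: 40 uniform random 40-gene modules.
* **Signatures**: dense latent fields over all genes. The disease field is
  standard normal; planted drug fields mix it at correlation ρ = 0.6 with
  independent noise; decoy fields are pure noise. Each entity's own module
  genes are amplified (×3) so the top-fraction rule approximately recovers
  the planted module from its signature. Dense fields (rather than zeros
  off-module) are used because cosine correlations restricted to small
  overlaps of sparse vectors degenerate to ±1 noise, inflating decoy
  correlations — real expression signatures are dense.
* **Fingerprints**: partner drugs share a 20-feature block per pair plus
  private features; decoys are all-private, so chemical similarity is
  informative for partners and zero otherwise.
* **Auxiliary diseases**: two near-duplicates of the query module (60%
  shared genes) and two random modules, giving the disease-similarity
  prior both signal and contrast.
* **Plates**: Hill survival curves (EC50 log-uniform in [0.1, 10], slope
  uniform in [1, 3]) over a 7-point twofold dilution series with Gaussian
  measurement noise (sd 0.03). Additive combination wells sit on the Loewe
  additivity line (the concentration-addition null); synergistic wells
  take the Bliss-predicted survival times (1 − ε), ε = 0.3. Placing the
  additive wells on the Loewe line rather than the Bliss prediction keeps
  the additive plant a true null for the toxic-unit statistic: Bliss and
  Loewe references differ for Hill slopes near 1, so a Bliss-additive well
  would register spurious Loewe synergy.

With these conditions the propagation-based mode reaches a median ranking
AUC ≈ 0.94 over 20 seeds and matches or beats the no-propagation baseline
in every seed; the mechanism mirrors the intended one (raw module overlaps
below the cosine minimum for almost all pairs, recovered by expansion).
Passing on this benchmark demonstrates that the implementation integrates
its components correctly and that the score responds to planted proximity,
separation and correlation signal; it does not demonstrate performance on
real interactomes, whose module geometry, annotation bias and signature
noise are outside the generator's scope.

## Numerical choices and degenerate inputs

* Shortest paths run on a CSR adjacency via multi-source BFS; results are
  exact integers.
* Randomisation: one integer seed; every permutation and generator
  artifact draws from a counter-offset substream, so any piece regenerates
  identically in isolation and results do not depend on evaluation order.
* Ties: top-fraction cutoffs, expansion candidates and ranked pairs break
  ties by lexicographic gene/drug id.
* Degenerate cases: σ = 0 permutation nulls flag the result and set z = 0;
  all-identical z collections refuse min–max scaling; empty modules,
  all-zero signatures, all-zero fingerprints and empty queries raise
  errors naming the entity.
* The toxic unit inherits discretisation error from log-linear
  interpolation of the 7-point measured curves (a few percent at
  plate scale), which is why plate-level synergy decisions should use a
  margin rather than the strict TU < 1 boundary; the test suite checks
  that the additive plant is unbiased (mean TU ≈ 1) and that confident
  calls (all wells TU < 0.9) stay at the few-percent level.

## Known limitations

* The interactome itself is consumed, not constructed; identifier
  normalisation is a preprocessing concern.
* Fingerprints are read from file; no chemistry is computed.
* The separation measure's s(A,A) is −⟨d_AA⟩ (not 0) for multi-gene
  modules under the shared-genes-contribute-0 convention; only the
  singleton identical-module case yields exactly 0.
* No disease-subtype resolution: one module per disease.
* Problem sizes in the tests and the acceptance script (2,000-gene
  network, 50 drugs, 100 permutations, 20 seeds) are the package's
  reference benchmark conditions; all are configurable upward.
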