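# Methods

## Model overview

`pathscore` treats a curated signalling pathway as a connected set of
interactions.  Each interaction has input molecules — *promoters* and/or
*inhibitors* — and one or more *output* molecules.  Expression data enter the
model only through p(A), the per-sample posterior probability that gene A is
in its highly expressive ("up") state.  Everything downstream — molecule
probabilities, interaction scores, pathway scores and association tests — is
a deterministic function of these probabilities and the network structure.

## Up/down normalisation

For each probeset, intensities across samples are modelled as a mixture of
two gamma distributions,

    f(x) = w · Gamma(x; k_d, θ_d) + (1 − w) · Gamma(x; k_u, θ_u),

with components labelled so that the "up" component has the larger mean
k·θ.  The posterior of the up component is the probeset's unit-scale
expression value.  This shares one scale across probes, samples and
experiments, which is what makes multiplying probabilities of different
genes meaningful later.

Numerical choices:

* **Fitting** is by EM.  The weighted gamma M-step solves
  log k − ψ(k) = log(mean) − mean(log) with Newton iteration from the Minka
  closed-form start; the scale is mean/k.
* **Initialisation**: two deterministic starts — a below/above-median split
  and the exact one-dimensional 2-means split — each run to convergence; the
  higher log-likelihood wins.  No random restarts, so a fit is a pure
  function of the data.
* **Convergence**: relative log-likelihood change below `tol = 1e-6`, capped
  at `max_iter = 500`.
* **Degeneracy**: zero-variance probesets, or fits in which one component's
  weight falls below 1e-3, are flagged degenerate; their posteriors default
  to the uninformative 0.5 rather than an arbitrary hard call.
* **Input scale**: intensities are assumed linear and nonnegative (zeros are
  lifted by a tiny floor since the gamma support is open at 0).  Log2 data
  must be exponentiated first (`--unlog2`).
* `updown_normalize` runs a vectorised batch EM over all probesets at once —
  identical update equations to the per-vector `fit_gamma_mixture`, with
  rows leaving the active set as they converge; the test suite asserts
  agreement between the two paths at 1e-8.

A caveat worth knowing: EM's log-likelihood flattens faster than its
parameters converge, so two *independently refitted* datasets that are exact
rescalings of one another agree in their posteriors only to about 1e-4 at
any practical stopping tolerance.  The scale family itself absorbs a factor
c > 0 exactly (multiply both scale parameters by c), and the tests verify
that identity at 1e-12.

## Interaction and pathway scores

With molecule probability p(m) = ∏ member-gene probabilities (a complex is
present only when all members are up) and gene probability = mean posterior
over the gene's mapped probesets:

    activity     A = ∏_promoters p(m) · ∏_inhibitors (1 − p(m))
    consistency  C = A · P_out + (1 − A) · (1 − P_out),  P_out = ∏_outputs p(m)

Activity is the probability that the interaction *can* fire: 1 exactly when
every promoter is certainly up and every inhibitor certainly down.
Consistency is the probability that the realised output state agrees with
that potential: 1 at full agreement, 0 at full contradiction, identically
0.5 when A = 0.5 (no potential to confirm or contradict).  It is symmetric
under joint complementation, C(A, P) = C(1−A, 1−P).

Pathway scores are unweighted means over interactions — activity over all
scoreable interactions, consistency over those with at least one measured
output — so a perturbation of size δ anywhere in an n-interaction pathway
moves the pathway score by δ/n regardless of topology.  This also means
small informative sub-networks can be diluted inside large pathways; that is
a property of the score, not an implementation artefact.

Measurement policy (all deliberately neutral rather than punitive):

* unmeasured molecule in a partially measured role set → imputed at 0.5;
* interaction with no measured input at all → excluded from the activity
  mean (not scored 0);
* interaction with no measured output → contributes activity but not
  consistency;
* pathway with no scoreable interaction → missing (NaN), flagged.

## Association tests

* **Binary class**: two-sample Wilcoxon rank-sum per pathway×metric.  Exact
  enumeration p (via the exact Mann-Whitney null) when min(n₁,n₂) ≤ 10 with
  no ties; tie-corrected normal approximation otherwise.  Constant scores
  give p = 1.
* **Continuous variable**: Pearson ρ with the Student-t transform
  t = ρ√(n−2)/√(1−ρ²), two-sided, n−2 df.
* **Survival**: scores are split by the *exact* one-dimensional 2-means
  partition (all contiguous splits of the sorted scores scanned; ties break
  toward the smaller low group; user-settable minimum group size, default
  5), followed by a Kaplan-Meier/logrank comparison of the two groups.  The
  1-D exact scan replaces iterative Lloyd clustering: it is deterministic
  and globally optimal, which Lloyd is not.
* **Gene hits**: per sample s with ≥ 1 altered gene,
  p_s = P(X ≥ k_s), X ~ Hypergeom(N, K, n_s) over the assayed-gene universe;
  samples with no alterations are excluded so the omnibus degrees of freedom
  stay meaningful.  Fisher's omnibus X = −2 Σ ln p_s is referred to χ² with
  2S df.
* **Correction**: Bonferroni by default (Benjamini-Hochberg optional),
  applied across the full family of pathway×metric hypotheses in a run; the
  family size is the number of hypotheses actually tested.  Activity and
  consistency are corrected as one family.

## Clustering and exports

The heatmap clusters rows (pathway×metric) and columns (samples)
independently with agglomerative linkage (correlation distance, average
linkage by default — the common choice for expression heatmaps; Euclidean
and complete linkage available).  Alongside the image, the reordered matrix
is written as `*.ordered.tsv` so orderings are testable and diffable without
pixel comparison.  A `top_variance(k)` filter keeps the k rows with highest
sample-wide variance.

Network exports (DOT or GraphML) contain one node per molecule and per
interaction.  Molecule fill interpolates white → turquoise with expression
probability, interaction node size scales 0.2 → 1.0 with activity, output
edges are coloured dark green → bright blue with consistency, and altered
genes are outlined yellow.  The exact numeric values ride along as
attributes, so files diff cleanly.  The DOT writer is a minimal in-package
emitter; GraphML goes through networkx.

## Synthetic data: what it emulates, and what it does not

The generator exists so that every claim the tests make can be checked
against known ground truth without downloads.

* **Expression**: each probeset's values are drawn from its own two-gamma
  mixture (defaults w = 0.5, Gamma(2,1) vs Gamma(8,1) — clearly separated
  but overlapping components) with the true component labels retained.  Two
  probesets per covered gene emulate multi-probeset array designs.
* **Pathways**: random connected promoter/inhibitor/output networks of 5–15
  interactions; each interaction after the first promotes from an earlier
  output, so connectivity holds by construction.  Every molecule carries a
  fresh synthetic Entrez id: decoy pathways share no genes with the target,
  making "the planted pathway ranks first" a well-posed question.
* **Planted signal**: one target pathway gets a per-sample activation level
  α, drawn switch-like (half the samples ~ U(0.65, 0.95), half
  ~ U(0.05, 0.35)); its activating genes are up with probability α, its
  inhibiting genes with 1 − α.  The four clinical tables derive from the
  same α: class labels (α above/below 0.5), a continuous readout
  y = α + N(0, 0.1), exponential survival with hazard 0.1 multiplied by 3
  in the high regime (independent Exp(0.02) censoring, ≈ 15–20% censored),
  and an alteration matrix with per-gene rate 0.05 outside vs 0.25 inside
  the target pathway.  The two-regime α reflects switch-like pathway
  behaviour — the regime the survival group-split is designed to detect;
  with a diffuse unimodal α the dichotomised hazard assignment is dominated
  by boundary misclassification and no test of this design can see it.

Not emulated: probe-level noise models, batch and spatial chip effects,
correlated genes outside the planted pathway, non-exponential survival,
many-to-many probe ambiguity beyond what the mapping format allows.  Passing
tests therefore demonstrate correctness of the algorithms and recoverability
of signals *under the model's own assumptions*, not robustness to real
microarray artefacts.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use: mixture recovery at n = 1000 × 20 replicates;
null calibration at n = 28 samples (a cell-line-panel scale) × 1000
replicates in the test suite (500 in the acceptance script); four-test
planted recovery on 21 pathways × 60 samples over 50 replicates (15 in the
script); shuffle control on 100 pathways × 40 samples over 50 replicates
(15 in the script) with 10 label shuffles.  These sizes give the binomial
margins the assertions need while keeping a full run in the minutes range.

## Known limitations

* Only established pathway structures are scored; nothing is inferred from
  the data, and scores inherit any curation ambiguity in the input networks.
* The consistency formula is this package's documented interpretation of
  "agreement between potential and realised outputs"; it is isolated in one
  function (`interaction_consistency`) so alternative formulations can be
  swapped in.
* Whether consistency should average over interactions with unmeasured
  outputs (imputing them) is an open modelling question; this implementation
  excludes them from the denominator.
* Protein states (phosphoforms etc.) are flattened to molecules in the
  interchange format.
* Cox regression, multi-class comparisons and permutation FDR are out of
  scope; Bonferroni/BH cover multiple testing.
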