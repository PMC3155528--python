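# Methods

## Problem and data model

The package analyses a region-resolved expression profile of the adult
mouse central nervous system: an RMA-style summarized log2 intensity
matrix of array probe sets over ~48 small CNS regions, each profiled in
duplicate. The pipeline asks, per gene: does expression fall into a
single log-normal state across regions, or into several discrete states
("multi-state" expression)? The answers drive four downstream analyses —
regional marker candidates, internal-control (stable housekeeping)
candidates, category enrichment of up-states, and inferred
ligand–receptor connectivity among regions.

The core in-memory objects are an `ExpressionMatrix` (probe × sample
frame plus region/replicate metadata) and a `RegionProfile`: per-region
replicate means, the per-region replicate error variance (unbiased, n−1
denominator; for duplicates this is twice the squared half-difference),
and each probe's median error variance over regions.

## Multi-state calling by variational Bayes

Each probe's 48 per-region means are fit with univariate Gaussian
mixtures of K = 1..6 components, every component carrying its own
variance, under conjugate priors

    pi ~ Dirichlet(alpha0 1_K)
    lambda_k ~ Gamma(a0, b0)
    mu_k | lambda_k ~ Normal(m0, 1 / (beta0 lambda_k)).

The fit is mean-field VB-EM (Dirichlet + Normal–Gamma updates). The
variational lower bound (ELBO) is evaluated after each E-step, where its
data term collapses to the sum of the responsibility normalizers and the
rest is the KL divergence of the Dirichlet and Normal–Gamma factors from
their priors; evaluated this way the trajectory is non-decreasing by
construction, which the tests assert on every fit and which was verified
against a Monte-Carlo estimate of the bound (4×10⁵ posterior samples,
agreement to 3 decimals at K = 1, 2, 6) and against a numerical double
integral for K = 1 (1e-6).

Fitting uses the **region means, not the 96 replicate values**: replicate
information enters only through the precision prior. `determine_prior`
moment-matches a Gamma distribution to the empirical precisions
1/median-error-variance across all probes (population moments), giving
(a0, b0); m0 is the grand mean of the matrix; zero variances are floored
at 1e-6 before reciprocals. When the precisions have no spread the shape
falls back to 2 with the rate preserving the mean precision.

Model selection refits at every K and keeps the best final ELBO (ties to
the smaller K), rather than relying on K = 6 self-pruning alone — the
explicit comparison is deterministic and testable. Components with no
argmax-assigned region are pruned; components i, j are then merged when
|mu_i − mu_j| ≤ c·max(sigma_i, sigma_j) with c = 2 (sigma from the
posterior mean precision), applied transitively, which captures the case
of a narrow state nested inside a broad one. Surviving states are
ordered by mean; the lowest state binarizes to "down" and every other
state to "up" (middle and high are deliberately not distinguished).

Initialization is quantile seeding: component means start at the
quantiles linspace(0, 1, K) of the sorted profile — the levels span the
extremes so that a singleton extreme state (a marker gene's single high
region) always receives a seed; interior mid-quantile seeding loses
roughly a tenth of planted markers because no restart ever isolates the
outlier. Jittered restarts (default 5, jitter sd = half the profile sd)
guard against local optima under a fixed master seed, so results are
reproducible and invariant to component relabeling.

Defaults: alpha0 = 1.0, beta0 = 0.01, tol = |ΔELBO| < 1e-8,
max_iter = 500. `tune_alpha0` grid-searches alpha0 against a reference
set of true multi-state probes (synthetic truth, or marker candidates at
a chosen FDR) minimizing FPR + FNR; the full trade-off curve is returned.

Gene aggregation: probes map to genes via the annotation's symbols; a
gene is multi-state if any of its probes is, and its up regions are the
union over those probes. The dataset totals are G (unique multi-state
genes), U (total up-state region assignments over those genes) and R
(regions), giving the up-state probability p0 = U / (G·R).

Whole-dataset classification is vectorized: all probes are fit jointly
at each K (restarts batched alongside), with converged profiles dropped
from the working set each iteration. 5,000 probes × K = 1..6 × 5
restarts complete in about 4 minutes on one core.

## Markers

A multi-state probe is a marker candidate for a region when its highest
(or lowest) state contains exactly that one region; high and low calls
are independent. "Largest expression change" is operationalized as the
range of state means (max − min, log2) — on the log scale this is the
fold change. `top_markers` takes up to k = 3 high-direction probes per
region by descending range (ties broken by probe ID), deduplicated by
gene; the region subset (e.g. excluding spinal cord, retina, pituitary,
pineal) is a parameter, not hardcoded.

## Internal controls (one-state variability)

One-state probes pass a presence filter: with a P/M/A detection-call
matrix, a probe is kept when at least one region has every replicate
called P. Without calls, a documented proxy applies (best region mean
above the dataset's 25th percentile of all values) and the output is
flagged as having used the fallback. Scores: probes are sorted by mean;
the running median of the across-region SD uses a centred window of 501
probes (truncated at the edges; the window is configurable — the choice
is a smoothness/locality trade-off and wide windows give a smooth trend);
v = log2(sd / running-median-sd). v < −1 is "stable", v > +1 "variable",
boundaries strictly excluded. Scores are invariant to global shifts of
the matrix, and the median score is ~0 by construction whenever the
running median is a consistent estimate of the conditional median SD.

## Enrichment statistics

All tests are gene-level. (1) Per (category, region): one-sided binomial
with success probability p0, Bonferroni over the tested
categories × regions grid (the multiplicity is reported in the output),
significant at adjusted p < 0.05. (2) Category over-representation among
multi-state genes: one-sided Fisher exact (hypergeometric tail) over a
configurable universe defaulting to all annotated genes. (3) Term
enrichment of a selected gene list: hypergeometric tail per term with
Benjamini–Hochberg FDR within each term class (e.g. the three GO
namespaces), reporting terms at FDR ≤ 0.01. Binomial and hypergeometric
tails are exact and are checked against enumeration oracles to 1e-12.

## Connections

Only pathways with at least one multi-state ligand gene and one
multi-state receptor gene are used. For each ordered region pair (A, B)
the count is the number of pathways with some ligand gene up in A and
some receptor gene up in B; the diagonal holds intrinsic (same-region)
signalling. Edges require (i) count strictly above the upper 0.05
empirical quantile of all pair counts (floored to an integer — the
"0.05 quantile" of the count distribution is its upper tail: with ~68
pathways and pair probability p0² ≈ 0.09 the mean count is ~6, so only
~5% of pairs can exceed the cutoff) and (ii) a one-sided binomial test
X ~ Binomial(n_pathways, p0²) surviving Bonferroni over all R² ordered
pairs at p < 0.01. Intrinsic ligand–receptor gene pairs are ranked by
the number of shared up regions.

## Synthetic data

The generator emits the study conditions: 48 regions × 2 replicates;
one-state genes as Gaussians on the log2 scale (sd 0.1 stable / 1.2
variable, 70:30); K-state genes (K = 2..6) with adjacent state means
separated by Δ = 3.0 log2 and within-state spread 0.3 log2 across
regions; per-probe replicate noise variances from Gamma(shape 2, scale
0.02) (right-skewed, mean 0.04); expression centred near 8 within
[2, 14] log2. 20% of multi-state genes are planted markers (singleton
top state); every non-top state owns ≥ 2 regions. The pathway catalog
defaults to 118 pathways (the scale of a neurohormone/neurotransmitter
catalog), 10% intrinsic, the extrinsic ones concentrated on a single hub
region pair by default so planted connections accumulate counts well
above the binomial null; ligand/receptor genes are dedicated 2-state
genes up in the designated region plus 2 others.
Everything is recorded in a truth table, including each gene's realized
state separation: K = 5 and 6 cannot fit a 3.0 separation inside the
[2, 14] range, so their separation shrinks to (hi−lo−1)/(K−1) (2.75 and 2.2), and truth-based scoring can restrict to genes at the full stated
separation.

By default the regions beyond the per-state minima spread uniformly
across states, so synthetic multi-state genes are up in roughly half of
the regions (dataset p0 ~ 0.42) — more than on the real arrays (p0 ~
0.30); `SyntheticSpec.up_fraction` enables a bottom-heavy occupancy that
matches the observed rate at the cost of small, harder-to-resolve upper
states.

What the generator does **not** emulate: probe-level (pre-summarization)
effects, mean-variance coupling of array noise, correlated regions
(anatomical similarity), shared probes per gene beyond the 1:1 default,
or circadian structure (the design pools time points). Passing recovery
tests therefore demonstrate correctness of the inference machinery under
the stated noise model, not performance on arrays with untracked
artefacts.

## Numerical choices and degenerate inputs

Replicate variances of zero are floored at 1e-6 before reciprocals.
Constant profiles collapse to one effective state. A constant-profile
region makes correlation distance undefined; the clusterer raises by
default or assigns the maximal distance 2.0 when configured. Region IDs
are sorted before linkage so exact distance ties resolve to the lowest
pair. Missing values are rejected at load (summarized arrays are
complete). ELBO ties across K go to the smaller K. Quantile cutoffs use
linear interpolation floored to an integer, applied strictly.

## Known limitations

- At K = 5–6 with near-uniform weights on 48 points, the bound can
  honestly prefer a smaller model even when the components are visually
  evident — the mixing-entropy cost (ln K per point) nearly cancels the
  sharpness gain. This is a property of the model, not a fitting defect
  (the bound is Monte-Carlo-verified); marker recovery for such genes
  degrades accordingly.
- The Fisher universe and the exact Bonferroni family of the published
  category grid are configurable because neither is uniquely determined;
  outputs always report the multiplicity used.
- The running-median window and the alpha0 grid are data-scale dependent
  and should be revisited for platforms with very different probe counts.

## Problem sizes used in the shipped checks

The full-scale property checks run 5,000 spec-class probes (plus 236
pathway probes and 10 controls) through the complete pipeline; the
variability score checks use a dedicated 5,000-probe one-state table;
the connection null calibration uses 500 Monte-Carlo replicates of 68
pathways over 20 regions; statistics oracles enumerate n ≤ 25.
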