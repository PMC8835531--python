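# Methods

This note documents the models, estimators and numerical choices behind
`evomet`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Data model and conventions

All genomic coordinates are 1-based inclusive internally (the GFF3
convention); BED export converts to 0-based half-open at the boundary and
the conversion is self-inverse. Strand is carried but ignored by all
window logic. The PoPoolation2 `sync` dialect (A:T:C:G:N:del counts per
population) is collapsed to biallelic ref/alt by taking the two
nucleotides with the highest summed counts across populations, keeping
the file's reference base in the ref role when it is one of them; a
native two-column ref/alt dialect round-trips byte-exactly. Missing
metabolite cells are rejected by default; an optional `halfmin` policy
imputes half the per-metabolite observed minimum (the common MS
detection-limit convention).

The study design maps each population to a treatment and a replicate
stratum. Strata are matched replicate sets — at most one population per
treatment per stratum — and are an explicit user input: nothing in the
data dictates how replicates pair across treatments, so the package never
guesses.

## Generalized CMH scan

Read counts are used directly as the CMH cell counts, as pool-seq E&R
practice does; no overdispersion correction is applied to the statistic
itself because threshold calibration is delegated to the permutation
plug-in FDR, which preserves the drift-driven null inflation exactly.
Strata with total < 2 or a zero row/column margin contribute zero to both
the score vector and its covariance. The covariance is eigen-decomposed
per SNP (vectorized across SNPs); eigenvalues below 1e-12 × the leading
eigenvalue are treated as exact rank deficiency — the statistic is then
the pseudo-inverse quadratic form when the score lies in the retained
range, and the SNP is flagged unusable (Q = 0, p = 1) otherwise, e.g. at
monomorphic sites. No continuity correction. The implementation is
cross-checked in the tests against R's `mantelhaen.test` (generalized
I × J × K form) and against margin-preserving Monte-Carlo permutation.

## Plug-in FDR calibration

Treatment labels are shuffled over populations, preserving group sizes.
Stratum labels are kept when the shuffled assignment is still a valid
matched layout, and otherwise re-drawn uniformly among valid assignments
(independent uniform permutations of stratum labels within each shuffled
treatment group). Exceedance is strict (">") on both observed and
permuted counts, ties breaking toward conservatism. The candidate
threshold grid is the sorted union of observed and permuted statistics —
the complete set of transition points of the plug-in FDR curve, so the
returned threshold is exactly the minimal feasible one. With strict
exceedance the top grid point always has R = V̂ = 0, so a feasible
threshold always exists; a heavy permuted tail simply yields an empty
significant set. Permuted scans reuse the in-memory count table.

## Marker windows

Windows are disjoint 50-kb tiles anchored at position 1 of each
chromosome arm. Sliding windows were rejected to keep window counts
stable and "one marker per window" well defined. "Most significant"
means largest Q; ties break toward the smaller position.

## FLAM

The objective is

    ½‖y − β₀1 − Σ_j θ_j‖² + λ Σ_j [ α·TV_j(θ_j) + (1−α)·‖θ_j‖₂ ],

with TV_j the total variation of θ_j in x_j-sorted order, tied x_j values
fused into one level (FLSA weights = tie-group sizes), and every θ_j
constrained to mean zero (β₀ = ȳ). Each block update solves the weighted
FLSA subproblem exactly, centers, then group-soft-thresholds — the exact
block minimizer, so the objective is non-increasing (asserted in tests).
Defaults: α = 0.5 (equal fusion/sparsity mix), convergence at relative
objective change < 1e-7 or 200 cycles (non-convergence warns and returns
the current iterate).

**FLSA solver.** The inner 1-D problem min ½Σ w_i(r_i−u_i)² + λΣ|u_{i+1}−u_i|
is solved by dynamic-programming message passing on piecewise-linear
derivative functions (forward clipping at ±λ, backward clamping), exact
up to floating point; the tests verify it against a box-constrained dual
QP solved independently.

**Penalty tuning.** λ is chosen by 5-fold cross-validation over a
20-point log-spaced grid spanning three decades down from λ_max (the
smallest penalty, found by bisection, at which one descent pass from the
zero fit stays at zero), with warm starts along the path and the
one-standard-error rule. Prediction at held-out points uses each
component's step function evaluated at the nearest training x_j (ties to
the smaller x).

**Stability selection.** A single fit can recover at most n (populations)
predictors and the finite descent path depends on block order, so
selection is repeated (default 100 runs) with predictor columns shuffled;
each run's selected set is truncated to n by descending component norm;
markers selected in at least 50% of runs (inclusive) form the stable set.
λ is tuned once on the unshuffled design and reused across runs: the CV
objective does not depend on column order, so per-run re-tuning would add
only fold-resampling noise at roughly 150× the cost
(`retune_per_run=True` restores it). Per-run and per-metabolite seeds are
spawned deterministically from one root seed.

**Response resolution.** FLAM needs one response per population; the
generator emits per-population sample replicates and the pipeline uses
population means. When only treatment-level measurements exist, a mapping
that assigns each population its treatment mean can be supplied — with
the caveat that within-treatment variation, the signal stability
selection exploits, is then absent.

## Metabolomics statistics

Classical equal-variance one-way ANOVA by default (Welch variant behind a
flag), BH adjustment across metabolites at q = 0.01, Tukey HSD (scipy)
and Fisher LSD (pairwise t with the pooled ANOVA MSE, hand-implemented)
post-hocs, and a literal Bonferroni gate at p ≤ 1.2 × 10⁻⁵ (a
configurable constant; its derivation is not specified upstream, so it is
taken as given). Metabolites with zero variance in every group get F = NA
and fail the gate. PCA autoscales (mean-center, unit variance) before the
SVD, dropping zero-variance metabolites with a warning — autoscaling is
the default pretreatment of the common metabolomics web services. ORA is
the upper-tail hypergeometric test with fold-enrichment = hits/expected
(expected = n·M/N; fold undefined and flagged when expected = 0), BH
across sets. Focal metabolites are the Bonferroni passers, optionally
intersected with the membership of the top-k pathways by ORA p (ties by
set id).

## Gene mapping

"5-kb window around a marker" is read as a total span of 5 kb centered on
the marker (± 2.5 kb), clipped at position 1; a flag switches to ± 5 kb
since the phrase is ambiguous. A gene is a candidate when its body
overlaps the window by ≥ 1 bp; promoters and UTR extensions are not
modeled. Term enrichment reuses the ORA machinery over gene identifiers.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
30 populations (3 treatments × 10 replicate strata), biallelic SNPs on
five 1-Mb chromosome arms, ancestral frequencies p₀ ~ U(0.05, 0.95),
treatment means shifted by ±δ at causal loci (the shifted treatment drawn
at random per locus, direction chosen away from the nearer boundary,
clipped to [0.01, 0.99]), population frequencies drawn Balding–Nichols,
Beta(p(1−F)/F, (1−p)(1−F)/F), coverage Poisson(60) clipped to [20, 200],
and binomial read counts. Balding–Nichols drift was chosen over
generation-by-generation Wright–Fisher because it matches the analysis's
exchangeability assumptions at a fraction of the cost.

Each causal locus is realized as a cluster of 5 SNPs inside one distinct
50-kb tile sharing the locus's per-population frequency (read noise
independent per SNP) — a minimal stand-in for a selected haplotype block.
Without such within-window signal sharing the ≥ 3-significant-SNPs window
rule could never fire on a single causal SNP, and window-level recovery
would be undefined. Background (between-window) linkage disequilibrium is
*not* modeled.

Metabolites are linear in causal-locus frequencies: population value
= 10 + Σ w·p_pop + N(0, 0.1) per sample, 3 samples per population,
weights ±1 on 3 loci per causal metabolite assigned round-robin so every
causal locus influences at least one metabolite; 10 of 20 metabolites are
causal by default. These effect sizes are strong but realistic for the
"clear multivariate separation" regime the design targets; passing
recovery tests therefore demonstrates correctness of the chain under
favorable signal, not power under weak effects, and says nothing about
instrument noise, signal drift, or platform batch structure, none of
which are modeled.

All randomness flows from the config seed; identical configs give
byte-identical fixture bundles (set iteration is avoided anywhere results
could depend on Python's hash randomization).

## Pipeline

One YAML config drives all stages; one root seed is fanned out per stage
via spawned seed sequences. Every stage writes plain-text outputs plus a
manifest entry (parameter/input fingerprint, output checksums, wall
time). A stage re-executes when its fingerprint changes, an output is
missing or altered, or any upstream stage re-executed in the same run;
otherwise it is skipped and its outputs are reloaded.

## Problem sizes

Defaults were sized for a desk-scale study: 5,000 SNPs across 5 Mb, B =
100 calibration permutations, 100 stability runs per metabolite. The
recovery benchmark averages 25 independent synthetic replicates; the
global-null FDR experiment uses 2,000 SNPs × 50 permutations × 200
replicates. The acceptance script reports a 5-seed recovery average and a
25-replicate null experiment alongside one full pipeline pass.

## Known limitations

- Read counts, not individual flies, are the CMH units; no effective
  pool-size correction is offered.
- No background LD, no explicit selection dynamics, no instrument-noise
  model in the generator.
- The FLAM response must be per population; treatment-mean mapping loses
  the within-treatment signal.
- ORA assumes the candidate list is a subset of the reference metabolome;
  identifier harmonization is the caller's job.
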