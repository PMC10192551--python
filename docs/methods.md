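# Methods

This note documents the models and procedures implemented in `modcog`, the
assumptions behind them, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## 1. Scrubbing, filtering, nuisance regression (`modcog.preprocess`)

**Framewise displacement (FD).** FD(0) = 0 and
FD(t) = Σ|Δtranslationᵢ| + r·Σ|Δrotationᵢ|, with rotations in radians
converted to arc length on a sphere of radius r = 50 mm. The flag for an
exceeding frame-to-frame difference is carried by the *later* frame of the
pair; the alternative (flagging both frames) is subsumed by the 1-back
dilation below.

**DVARS.** The series is rescaled so its grand mean equals 1000 (a mode-1000
analogue at parcel granularity), and DVARS(t) is the root-mean-square over
nodes of the frame-to-frame difference, as percent of that scale. The
statistic is therefore invariant to rescaling the raw signal, and it is
computed on the *unfiltered* series: bandpassing removes the mean, after
which percent-signal-change is undefined. A mean-free input raises a
degenerate-input error rather than silently producing huge values.

**Temporal mask.** Frames with FD > 0.5 mm and frames with DVARS > 0.5% are
flagged; each criterion's flag set is dilated 1 frame back and 2 forward
(clipped at the series ends) *before* the two sets are intersected. Dilating
before combining follows the order in which the source pipeline describes
the steps; a `union` switch and a dilate-after-combining switch exist for
sensitivity analyses. Censoring removes rows; it never reorders or
interpolates.

**Bandpass.** Zero-phase frequency-domain masking: the response is 1 on
[0.008, 0.1] Hz, falls to 0 over a raised-cosine transition of width
0.002 Hz outside each edge, and the DC bin is zeroed exactly. Zero-phase
masking avoids group delay; the narrow transition keeps the pass band ≥ 95%
and the stop band (≥ 2× the high edge) ≤ 10% in amplitude. The same filter
is applied to the six motion parameters before they enter the nuisance
regression, so regressors and signal live in the same band.

**Nuisance regression.** Ordinary least squares of every node signal on an
intercept plus the supplied regressors (filtered motion; white-matter/CSF
proxies can be appended when available). Collinear columns are detected by
pivoted QR and dropped with a warning. Residuals are orthogonal to every
retained regressor by construction.

**Pipeline order** (default): DVARS/FD on raw data → bandpass signal and
motion → nuisance regression → mask construction → censoring → connectivity.

## 2. Connectivity (`modcog.connectivity`)

Pearson correlation over kept frames (requires ≥ 3 kept frames and nonzero
node variance), symmetrized, diagonal zeroed, entries clipped to [−1, 1].
No thresholding or binarization is applied by default.

**Negative weights.** The configuration null model in the modularity quality
function is defined for non-negative weights, so the default policy zeroes
negative correlations before community detection. `absolute` (magnitudes)
and `retained` (signed, non-standard) are available; an all-negative matrix
is an empty graph and is rejected.

## 3. Modularity and the Louvain search (`modcog.community`)

The quality function is

    Q(γ) = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/(2m)] δ(cᵢ, cⱼ)

with kᵢ the weighted degree, 2m the total weight, and the i = j null terms
included — so the all-in-one partition has Q = 1 − γ·1 = 0 exactly at γ = 1,
and two disjoint unit triangles under the two-triangle partition give
Q = 1 − γ/2 (0.5 at γ = 1, 0 at γ = 2). These closed forms anchor the tests.

**Search.** Stochastic two-phase greedy maximization. Phase 1 sweeps nodes
in an rng-shuffled order (reshuffled every pass), moving each node to the
candidate community with the largest *strictly positive* gain; ties keep the
current community, otherwise the lowest community id wins — so a run is a
deterministic function of (matrix, γ, seed). Phase 2 aggregates communities
into super-nodes whose self-loops carry the intra-community weight, and the
process repeats until a pass makes no move. Gains use the standard
O(degree) increment formula with the total weight held fixed across levels;
the Q returned is always recomputed from the final partition on the original
graph, and tests assert the two agree to 1e-12.

**Resolution sweep and median Q.** γ sweeps 0.5–3.0 in steps of 0.5 (larger
γ favours more, smaller communities). Because runs end in different local
optima, each (session, γ) is summarized by the *median* Q over `n_runs`
(default 100) runs, run r seeded as `seed + r`. An exact maximizer by
enumeration of set partitions (refuses > 10 nodes) serves as the oracle:
on random ≤ 8-node graphs the search never exceeds it and matches it in
≥ 90% of runs.

Note that for γ well above 1 on dense graphs even the best partition can
have Q ≤ 0; such rows cannot enter the log-link model below and are dropped
by the pipeline with a logged warning.

## 4. Log-link mixed model (`modcog.mixed_model`)

For participant i, row t (one row per time point × γ):

    y_it ~ Normal(exp(x_itᵀβ + bᵢ), σₑ²),   bᵢ ~ Normal(0, σᵦ²)

with x = (1, Group, Time, Group×Time), Group UAA = 0 / AE = 1, Time pre = 0 /
post = 1. The log link keeps the conditional mean positive while the outcome
stays Gaussian; β₃ is the multiplicative Group × Time effect on the log
scale. γ enters only as replicate rows within participant × time (the model
formula names no γ term); a `per_gamma` mode fits each resolution separately.

**Estimation.** Maximum likelihood over (β, log σᵦ, log σₑ). The random
intercept is integrated per participant by *adaptive* Gauss–Hermite
quadrature: an inner damped Newton locates the posterior mode of bᵢ, the
integrand is re-centered there and scaled by its curvature, and a 15-node
Hermite rule is applied (refining to 41 nodes changes the log-likelihood by
< 1e-6 on test fixtures). The gradient uses the Fisher identity (posterior
expectation of the joint score) on the same nodes; its agreement with finite
differences is ~1e-9 relative on fixtures. Optimization is quasi-Newton
(L-BFGS-B) started from a log-scale least-squares fit. ML rather than a
REML-type criterion because Wald z tests on the fixed effects are the
target. Standard errors come from the inverse observed information
(central-difference Hessian at the optimum).

If σᵦ collapses below 1e-4 the model is refit as a fixed-effects log-link
GLM (damped Gauss–Newton — IRLS on this likelihood) with a note in the fit
message; that GLM also matches an independent statsmodels fit to 1e-6 in
the tests. Calibration on synthetic tables (90 participants/arm, σᵦ = 0.05,
σₑ = 0.02): the planted interaction 0.04 is recovered to ±0.005 on average
over 200 replicates, and the Wald test of β₃ rejects at 5% ± 2% under the
null over 500 replicates.

## 5. Discriminant chain (`modcog.discriminant`)

**Control-anchored residualization.** Per task, OLS of post on pre using
control-arm complete pairs only; the fitted law is applied to *all*
subjects. An intervention subject's residual is their observed post score
minus the post score expected had they followed the control law — a
counterfactual-anchored change score. Assumes the control post-on-pre
relation is linear and would have applied to the intervention arm absent
treatment (plausible under randomization).

**Studentization.** Residuals are divided by the control fit's root mean
squared error (df = n_control − 2); no leverage correction by default
(a corrected option exists). The residualize → studentize composition is
exactly invariant to per-task affine rescaling of the raw scores (the slope
absorbs the scale; the divisor absorbs the units), which is why task scores
are generated on their natural, wildly different scales.

**PLS-DA.** PLS1 via NIPALS on column-centered predictors against the
centered 0/1 group indicator. With one component the weight vector is
exactly the normalized cross-covariance Xᵀy (asserted against the closed
form and against scikit-learn). One component is the default because the
selection rule below is then the clean identity VIPⱼ = √p·|wⱼ|/‖w‖ with
Σ VIP² = p, and a single printed loading per task is what such analyses
report. Explained X-variance and explained Y-variance are both reported
(when a published analysis states one "variance explained" figure without
naming which, neither is asserted).

**Selection and error.** Tasks with VIP > 1 are "discriminant".
Classification error is leave-one-out: refit on n − 1 rows, project the
held-out row through the training rotation, assign to the nearer class
centroid in latent space; resubstitution error is also reported. With
planted 0.8 SD effects on 3 of 7 tasks at 90 subjects/arm, the chain selects
exactly the planted set in ≥ 90% of replicates with ≤ 10% false selections.

**Logistic interaction models.** One model per discriminant task:
logit P(AE) = β₀ + β₁·ΔQ + β₂·task + β₃·ΔQ×task, with ΔQ the post-minus-pre
change in median Q averaged over the γ grid and `task` the studentized post
residual; both are z-scored before the product is formed to keep the
interaction well-scaled. Fit by IRLS (Newton with step halving); complete or
quasi-complete separation (diverging coefficients, |β| > 15 on standardized
predictors) is flagged and warned about, never silently returned. No
multiple-testing correction is applied across the per-task models —
mirroring the analysis convention this pipeline reproduces — so readers
should treat the per-task p-values as descriptive.

**Two-sample t from summary statistics.** Pooled-variance by default with a
Welch option. When checking published tables computed from rounded
descriptives (means/SDs printed to 1 decimal), the recomputed t is only
determined to roughly ±0.01; the verification surface therefore reports both
variants and the tests assert exact 2-decimal agreement only where the
printed inputs permit it. (Empirically the Welch form — the default of the
R environment such analyses typically run in — reproduces more of the
printed values.)

## 6. Synthetic cohorts (`modcog.synthetic_data`)

**What is emulated.** (i) Modular resting-state signal: multivariate
Gaussian draws with block-constant correlation — r_within inside modules,
r_between across, unit variance — shifted by a constant scanner-units
baseline (default 1000) so DVARS rescaling is well defined; the AE arm's
post session uses r_within + Δ. (ii) Motion: slow low-amplitude sinusoids
per axis plus Bernoulli step displacements of ±2 mm on the x translation at
interior frames, so FD ground truth is analytic (FD at a spike frame equals
the spike magnitude up to a negligible baseline term). (iii) A correlated
7-task battery: compound-symmetric intercorrelation (default 0.3), pre→post
autocorrelation 0.7 with variance-preserving noise, and group × time shifts
(in units of each task's SD) applied to the AE arm at post. Task means/SDs
default to typical older-adult control values so studentization is
nontrivial. Defaults: 90 subjects/arm, 264 nodes in 10 modules, 180 frames
at TR = 2 s, r_within 0.35, r_between 0.10, Δ = 0.10, spike rate 0.02, and a
0.3 SD effect on the three updating tasks.

**Seeding.** A master seed spawns per-(subject, session) substreams keyed by
a CRC32 of the identifiers, so a subject's data are identical regardless of
cohort size, and identical spec + seed reproduces cohort files byte for
byte.

**What is not emulated — and what a green test therefore does not
establish.** No haemodynamic response, spatial smoothness, physiological
noise, scanner drift, or temporal autocorrelation by default (an AR(1)
option exists); no missing sessions or attrition; motion spikes do not
corrupt the signal itself, so censoring efficacy is tested with separately
planted signal artifacts; the block-constant covariance is far cleaner than
real parcel covariance. Passing recovery tests establish that the
*estimators* are correct and calibrated on data satisfying their
assumptions, not that the original study's effect sizes are reproducible
from raw scans — those are not bundled.

## 7. Pipeline (`modcog.pipeline`, `modcog.cli`)

Configuration is a validated dataclass (unknown keys rejected, overlapping
input/output paths refused) loadable from YAML/JSON. Runs are deterministic
functions of (config, seed, inputs); per-(subject, session) community seeds
derive from the identifiers, so results are independent of processing
order. Stage outputs are plain text; the expensive community stage is
cached on disk keyed by a hash of the config (minus the output path) and
reused on reruns. Per-session censored-frame counts are logged. The report
contains no timestamps, so identical configs yield byte-identical reports.

## Known limitations

- The Louvain implementation is dense-matrix oriented; it is comfortable at
  a few hundred nodes but not designed for graphs with tens of thousands.
- The mixed model supports a random intercept only (no random slopes), one
  grouping level, and the specific 2×2 fixed-effect design.
- The logistic stage reports per-task models without multiplicity
  adjustment, by design (see above).
- Q ≤ 0 rows are dropped before the log-link fit; at high γ this can
  remove a substantial share of rows on dense synthetic graphs.
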