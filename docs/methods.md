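# Methods

`rsgca` implements a seed-based analysis of directed and instantaneous
connectivity in resting-state fMRI parcel/voxel time series, together with a
synthetic cohort generator that reproduces the study conditions the analysis
was designed for. This note documents the models, the calibration strategy,
the numerical choices, and what the synthetic data do and do not emulate.

## The directed-connectivity estimator

For a seed series $x_t$ and a target series $y_t$ (both z-scored), the
signed path coefficient of $x$ on $y$ is the OLS coefficient $b_{xy}$ of the
lagged seed in the bivariate first-order model

$$ y_t = b_0 + b_{yy}\, y_{t-1} + b_{xy}\, x_{t-1} + e_t, \qquad t = 2\ldots T , $$

with the lag fixed at one repetition time (TR = 2.5 s). Positive
coefficients are read as excitatory influence, negative as inhibitory. The
reverse direction $b_{yx}$ is fitted symmetrically, so bidirectional
influences of opposite sign can coexist; the net causal flow of a pair is
$b_{xy} - b_{yx}$. Z-scoring makes the coefficients scale free and
comparable across targets and subjects; a raw (unstandardized) option exists
and is used by the exact-arithmetic tests. The intercept is always included;
collinear or zero-variance targets produce explicit flags, never silent
zeros. Instantaneous functional connectivity (FC) is the Pearson correlation
of seed and target with Fisher's $z = \operatorname{atanh} r$; it is a
deliberately distinct quantity, and the suite verifies that purely
instantaneous coupling yields large $r$ with null directed coefficients.

## Preprocessing

The conditioning chain is: discard the first 5 volumes, remove each column's
least-squares line, apply an ideal zero-phase band-pass of 0.01–0.08 Hz
(binary DFT mask; no phase distortion that could bias lagged coefficients),
then regress out nuisance channels. We follow the stated order
(detrend → filter → regression); confounds are detrended and filtered with
the same operators before the regression so the nuisance projection remains
exact in-band. In simulation mode the confounds are the generator's stored
nuisance channels (the analogue of measured motion/global/WM/CSF
regressors); a data-derived global mean over parcels is available as an
option but is not the default, because parcel-mean global-signal regression
redistributes neural signal and has no analogue in the calibrated estimand.
Seed extraction supports named parcels and 6 mm spheres in world
millimetres; voxel membership uses voxel *centers* mapped through the image
affine (0-based indices internally, MNI millimetres externally).

## Group inference

One-sample and covariate-adjusted (age, gender) two-sample t maps are
computed per target. Familywise error is controlled by permutation maxT —
sign flipping for one-sample maps, group-label permutation with
Freedman–Lane residualization under covariates — with the add-one corrected
$p = (1 + \#\{\max T \ge |t|\})/(B+1)$. Search-volume masks come from the
one-sample maps (both directions, maxT-corrected at $\alpha$). Cluster
extent filtering (primary threshold plus $k \ge 30$) uses face connectivity
(6-neighbour in 3D, 4 in 2D), positive and negative exceedances clustered
separately. Follow-up per-group one-sample tests report raw and
Bonferroni-adjusted p values for a family of eight comparisons (whether the
original follow-ups were reported raw or adjusted is ambiguous, so both are
kept). Cluster summaries use the first eigenvariate: the leading left
singular vector of the column-centred subject × target matrix, unit
variance, sign-aligned with the per-subject row mean. The default
permutation count is 5,000; the test suite and reduced examples use ≤ 500.

## Mediation and severity models

Mediation follows the simple (Preacher–Hayes) model: diagnosis → FC
eigenvariate → seed-to-DLPFC outflow, fitted by three OLS regressions with a
case-resampling bootstrap (default 5,000 iterations) for the indirect effect
$ab$; the bias-corrected percentile interval is the default, plain
percentile an option. For linear paths with shared covariates the
decomposition $c = c' + ab$ is exact, and the suite asserts it to 1e-10.
The proportion mediated $ab/c$ is reported but flagged unstable when $|c|$
is small.

Severity analysis builds three first-principal-component composites —
illness severity over six clinical variables, loop integrity over the three
net flows among rAI/rDLPFC/dACC, visual inflow over the four most
group-discriminating rAI coefficients — and regresses the severity
composite on the two brain composites plus antipsychotic dose in a single
step, reporting standardized betas, $F$, $R^2$ and a variance-inflation
check. PCA is performed on the correlation matrix because the inputs mix
units; component signs are fixed by the convention that the loading sum is
non-negative. The processing-speed and functioning scores are recorded with
higher = better and are sign-flipped before the severity PCA so that all
loadings point toward greater severity.

## The synthetic cohort generator

The generator's defaults are the emulated study conditions: 35 controls and
38 patients; 300 retained volumes (≈ 12.5 min at TR 2.5 s, a typical
resting-state duration chosen because no scan length is stated) after 5
discarded ones; control ages 33.5 ± 9.1 years, patients 34.5 ± 9.1;
female fractions 10/35 and 9/38; chlorpromazine-equivalent doses
400 ± 150 mg for patients.

**Neural model.** Each group has a stationary VAR over eight named regions
(rAI, rDLPFC, dACC, precuneus, left/right cuneus, right hippocampus, right
temporal pole). Off-diagonal weights are directed influences at a lag of
one TR; diagonals are autoregressive terms at the simulation step (0.5 s
micro-step in hemodynamic mode). Innovations are Gaussian; a 100-step
burn-in removes initial-condition effects; stationarity is enforced via the
companion-form spectral radius.

**Observation model.** Neural series are convolved with a canonical
double-gamma response (peak 6 s, undershoot 16 s, ratio 1/6), per-region
delays jittered N(6, 0.5²) s per subject, decimated to TR 2.5 s,
standardized, and contaminated with shared nuisance channels (six
pseudo-motion AR(1) series, a slow global component, linear and sinusoidal
drifts; overall scale 0.5) plus white observation noise (SD 0.3 relative to
the unit-variance signal).

**Estimand calibration.** Group weights are not set to the published
coefficients directly — autoregression, convolution, decimation, noise and
band-passing all reshape what the estimator recovers. Instead, the
population value of the estimator through the *entire* observation chain is
computed spectrally (micro-step lag covariances by companion Lyapunov
equation and recursion; hemodynamic convolution as a kernel-autocorrelation
weighting; decimation by covariance sampling; band mask as a lag-domain
convolution with the mask's inverse DFT), and the weights are solved
numerically so that these population coefficients equal the published group
means for every named edge — e.g. rAI→rDLPFC 0.103 in controls and 0.027 in
patients — and so the population zero-lag rAI–temporal-pole correlation
equals the published FC means (0.211 / 0.005). A deterministic Monte-Carlo
refinement (fixed internal seed, 2,000 simulated subjects per group)
absorbs the residual finite-sample bias of the estimator at 300 volumes.
The Monte-Carlo suite verifies that the spectral population value matches
the estimator's empirical mean through the simulated chain.

**Between-subject structure.** Published per-edge SDs contain estimation
noise; the generator assumes an estimation-noise SD of 0.06 and gives each
edge a true between-subject spread $\sqrt{\max(\mathrm{SD}^2 - 0.06^2, 0)}$.
Because the low-pass observation chain renders the *symmetric* perturbation
of a bidirectionally calibrated pair nearly invisible to the estimator (its
Jacobian is close to singular in that direction), subject variation on such
pairs is placed on the antisymmetric (net-flow) mode, with amplitude the RMS
of the two per-edge spreads; single-direction edges get independent deltas.
Each subject's weights are then re-solved exactly (damped quasi-Newton with
the calibration Jacobian as preconditioner) so that the subject's population
estimands equal the group targets plus these deltas; unreachable extremes
near the stability boundary are shrunk symmetrically, which leaves group
means unbiased. Within-pair perturbations are therefore perfectly
anti-correlated — a known simplification; across pairs, loop edges share a
latent loop-integrity factor (fraction 0.6) and visual-inflow edges a latent
visual factor, which is what makes the net-flow and inflow composites
coherent, as in the published correlations among them.

**Mediation pathway.** Subjects carry a latent FC factor: their
rAI–temporal-pole innovation correlation is the group mean plus N(0, 0.13²),
and the same factor shifts the rAI→rDLPFC net-flow mode by 0.111 estimand
units per SD. The generative decomposition therefore assigns
0.111 × 0.205 ≈ 0.023, i.e. 30% of the 0.076 group gap, to the mediated
path. With the mediator observed without error the fitted proportion
recovers 30%; with the eigenvariate of *estimated* FC values, measurement
error attenuates the b path (classical errors-in-variables), so the fitted
proportion is smaller — an attenuation the original analysis was equally
subject to, and which the suite checks explicitly rather than hides.

**Clinical table.** Six severity variables (three symptom-domain scores,
duration of illness, processing speed, functioning) are generated from a
6 × 6 population correlation matrix calibrated to two published summaries
at once: mean absolute pairwise correlation 0.34 and a first-component
variance share of 40%. These two are not independently free — any
correlation matrix whose entries can be sign-aligned has a first-eigenvalue
share of at least $(1 + 5\bar r)/6 = 0.45$ at $\bar r = 0.34$ — so the
calibrated matrix blends the aligned pattern with a conference-matrix
(maximally sign-frustrated) pattern, solving for the two blend weights.
Variables are generated through the eigenbasis with the first component set
to the latent severity factor, which is itself
$-0.45\,\ell - 0.20\,v + \text{noise}$ in the standardized loop-integrity
and visual latents; dose is coupled to severity at 0.25. With only the
mean-|r| target configured, the matrix is equicorrelated.

**What the generator does not emulate.** No voxel-level spatial structure,
smoothing or cluster geometry (parcels are the atoms; the cluster-extent
code is exercised on synthetic grids); no physiological (cardiac or
respiratory) noise; no real head motion beyond nuisance-regressor leakage;
no non-Gaussian innovations or nonstationarity; no site or scanner effects.
Passing tests therefore demonstrate that the estimators and inference are
correct and calibrated under these idealized conditions, not that the
pipeline is robust to everything real data contain.

## Numerical choices and problem sizes

- Band mask bounds are inclusive within 1e-12; the DC bin is always removed.
- Degenerate inputs raise typed errors (zero variance, empty seed sphere,
  rank-deficient confounds with the offending columns named).
- Population covariance truncation horizon scales with the companion
  spectral radius (error target 1e-10, capped at 600 TR lags).
- The subject-level quasi-Newton solve uses damping 0.9, tolerance 2e-4 in
  estimand units, and a stability guard at companion radius 0.97.
- Calibration and refinement results are cached per parameter set within a
  process.
- Test problem sizes are scaled to keep the suite fast while preserving
  statistical resolution: familywise-error calibration uses 500 reduced null
  cohorts (two groups of 15, four regions, 150 volumes, no hemodynamics)
  with 500 permutations; bootstrap coverage uses 500 replicates of 60
  subjects with 500 resamples; parameter recovery averages 20 full-size
  cohorts. These sizes are the package's chosen compromise between
  Monte-Carlo error and runtime.

## Known limitations

- The estimand calibration targets the *population* value plus a
  finite-sample offset estimated at the default series length; cohorts run
  at very different lengths recalibrate (cached per length).
- Printed per-edge SDs smaller than the assumed estimation noise floor
  (0.06) yield zero between-subject spread for that edge.
- The published "top group difference" contrast between the rDLPFC and
  precuneus targets is close (standardized gaps 0.95 vs ≈ 0.9): in any
  single simulated cohort either may carry the larger |t|; the rDLPFC edge
  is the one that survives maxT correction inside the one-sample mask, as
  in the emulated analysis.
- The proportion mediated is intrinsically noisy at n = 73 with a weak
  b path; single-cohort values scatter widely around the generating 30%.
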