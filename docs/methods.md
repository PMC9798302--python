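# Methods

`specdcm` implements a complete resting-state effective-connectivity
analysis for a fixed eight-node visual network: subject-level spectral
dynamic causal modelling (DCM), hierarchical group inference by
parametric empirical Bayes (PEB), factorial Bayesian model comparison
with Bayesian model averaging (BMA), an automatic greedy search, and two
validation analyses — leave-one-out (LOO) prediction of hallucination
status and a canonical variate analysis (CVA) against hallucination
severity. A synthetic-cohort generator with known ground truth drives
all quantitative tests.

## The network and its taxonomy

The network comprises left/right LGN (4 mm spheres), medial thalamus and
V1 (midline; 8 and 10 mm), left/right hippocampus and left/right
dorsolateral PFC (8 mm), with a fixed hierarchy
LGN < V1 < hippocampus < medial thalamus < PFC. All 64 directed pairs
are modelled: 56 extrinsic couplings in Hz and 8 intrinsic self-couplings
parameterized as unitless log-scalings of an inherently negative
self-connection, `-0.5·exp(a_self)` Hz.

Each extrinsic connection is labelled bottom-up (source lower in the
hierarchy), top-down, or lateral (equal levels), and intra- or
inter-hemispheric. Two conventions are deliberate:

* **Midline nodes belong to both hemispheres**, so any connection with a
  midline endpoint is intra-hemispheric.
* **Lateral connections are untouched by the direction factor** (they
  are neither top-down nor bottom-up).

These two conventions are validated indirectly but sharply: they are the
only natural reading under which the factorial model space reproduces
the published counts (29 regional families from 31 nonempty subsets, 261
family combinations, 179 unique models). Both are checked by tests.

## The generative model

Neural dynamics are linear and stochastic, `dx/dt = A x + u`, with
`A`'s off-diagonal entries the extrinsic couplings and diagonal entries
`-0.5·exp(a_self)`. Endogenous fluctuations `u` and observation noise
have power-law spectra `amp · f^(-exp)` per region, with log-amplitude
and log-exponent parameters (prior mean 0 maps to a 1/f spectrum). Each
region's activity drives a balloon (hemodynamic) model linearized about
its fixed point; free hemodynamic parameters are per-region log-scalings
of signal decay and transit time plus one global log-scaling of the
intra/extravascular signal ratio. Remaining balloon constants are fixed
at canonical values (kappa 0.64 s^-1, gamma 0.32 s^-1, tau 2 s, alpha
0.32, E0 0.4, V0 4, TE 30 ms). Because everything is linear, the
cross-spectral density (CSD) has the closed form
`S(f) = T(f) G_u(f) T(f)* + G_e(f)`, with `T` the composed
neural-hemodynamic transfer function. The 8-region model has 113 free
parameters (56 + 8 neural, 17 hemodynamic, 32 noise).

The power-law baseline amplitude (`noise_floor = 5.6e-5`) is chosen so
that the prior-mean prediction has unit mean diagonal magnitude over the
analysis band. This makes three calibrations consistent at once: observed
spectra are rescaled to unit diagonal scale before inversion, the
log-amplitude priors then sit in the bulk of their mass, and the data
log-precision hyperprior (mean 6, i.e. residual sd ≈ 0.05 on unit-scale
data) is of the right order. The rescaling is absorbed by the noise
log-amplitudes and leaves coupling estimates in Hz untouched.

## Empirical spectra

ROI series are high-pass filtered by regressing out the mean and
discrete-cosine components below 0.0078 Hz (for 105 volumes at TR 3.36 s
this is 5 cosine regressors — the same count as a 128 s high-pass). Note
that drifts that are not exactly in the truncated cosine span leave a
small leakage residual (a 0.002 Hz cosine retains ≈ 4% of its norm), and
single noise realizations can lose a few percent of in-band energy to
the projection; both effects are properties of any truncated-basis
filter and are quantified in the tests. Cross-spectra are then estimated
by ordinary-least-squares vector autoregression (default order 8,
statsmodels) and evaluated parametrically on 32 linearly spaced
frequencies in [0.0078, 0.1] Hz. The CSD convention is two-sided: an
AR(1) channel has spectrum `sigma^2·dt / |1 - phi·e^(-2*pi*i*f*dt)|^2`.

## Variational Laplace inversion

The subject-level posterior is Gaussian, found by maximizing the
variational free energy F = accuracy − complexity with Gauss-Newton
steps under Levenberg-Marquardt damping. Implementation points that
matter:

* **Data vector** — the non-redundant stacking of the Hermitian CSD
  (real upper triangle incl. diagonal + imaginary strict upper
  triangle), 2048 real numbers at 32 frequencies.
* **Exact Jacobians** — the derivative of the CSD w.r.t. a coupling
  `A[dst,src]` is the rank-2 Hermitian update `u a^H + a u^H` with
  `u = T[:,dst]` and `a = T (G_u ∘ conj(Tn[src,:]))`; noise-spectrum
  derivatives are also analytic; only the 17 hemodynamic log-scalings
  use central differences of the closed-form regional response. A
  finite-difference consistency test holds at 1e-4 relative tolerance.
* **Step control** — candidate steps are screened with a surrogate F
  that reuses the current Jacobian, and accepted only if the exact F
  (Jacobian recomputed at the candidate) increases; the accepted trace
  is therefore monotone by construction. Unstable proposals (neural
  Jacobian with a non-negative real eigenvalue) are shrunk toward the
  prior mean by bisection.
* **Precision hyperparameter** — a single log-precision for the whole
  data vector with a Gaussian hyperprior N(6, 1/128), updated by guarded
  Newton steps.
* **Stopping** — |ΔF| < 1e-2 nats for 4 consecutive iterations, or 128
  iterations. Strongly coupled subjects occasionally exhaust the budget
  while F still crawls along a ridge; `invert_subject` then raises a
  diagnostic error carrying the F trace (the pipeline driver downgrades
  this to a warning and keeps the last iterate, which is in practice
  indistinguishable in parameter space).

Priors (one table, configurable): extrinsic N(0, 1/64) Hz², intrinsic /
hemodynamic / epsilon log-scalings N(0, 1/256), noise log-parameters
N(0, 1/64). Parameters with (near-)zero prior variance are clamped at
their prior mean and excluded from optimization, which yields the exact
nesting behaviour BMR assumes.

## Second level (PEB)

Subject neural posteriors (64 means + covariances) enter a Bayesian GLM
with design (mean, VH, age, sex); age and sex are mean-centred, VH is
0/1, and a constant VH column is dropped with a warning. The model is
`mu_i = (x_i ⊗ I) beta + eps_i + nu_i` with `eps_i ~ N(0, Sigma_i)` (the
subject's posterior covariance — full densities, not point estimates)
and isotropic between-subject noise `nu_i ~ N(0, I/gamma)`. Given gamma
the model is conjugate, so the beta posterior and the log evidence are
exact; gamma is set by maximizing evidence plus a log-precision
hyperprior N(0, 1/16) (bounded scalar search). Group-level priors on
beta are N(0, 1/16) per element. Hemodynamic and noise parameters stay
first-level.

## Model space, BMR, BMA, greedy search

Reduced group models clamp selected connection effects by shrinking
their group-level prior variance to 1e-8 ("switched off"). Because
everything is Gaussian, a reduced model's posterior and evidence follow
analytically from the full model (Bayesian model reduction); for
diagonal zero-mean priors the whole computation collapses to the
|S|×|S| block of the posterior covariance over the clamped set S, which
is what makes scoring all 179² = 32,041 (commonalities × differences)
hypotheses take seconds.

The factorial space crosses direction (top-down off / bottom-up off /
both on), laterality (inter off / intra off / both on) and regional
involvement (edges "to and from" each nonempty subset of the five
bilateral groups; 29 distinct families). Intrinsic connections stay on
except in the added null model; duplicates are removed on the extrinsic
edge-set, giving exactly 179 models. A deduplicated mask can arise from
several family combinations; it keeps the labels of its first generating
combination in a fixed lexicographic enumeration. Family tables reweight
model probabilities so each family carries equal prior mass, and report
the null model as its own cell.

BMA averages reduced posterior means weighted by model probability;
presence probability of a parameter is the summed probability of models
in which it is free, and parameters at or below the 0.95 reporting
threshold are zeroed (probability retained). The greedy search
repeatedly scores single-parameter removals, enumerates all 2^8 = 256
on/off combinations of the eight most dispensable parameters on top of
the current reduction, applies the best combination (near-ties resolved
toward the sparser model, so an uninformative posterior prunes to the
null), and stops when no reduction raises the evidence; the final 256
models are model-averaged.

## LOO and CVA

LOO refits the PEB on all-but-one subject using only the k connections
with the largest model-averaged group difference (default k = 5, ranking
recomputed from the current BMA). The held-out subject's VH score is
inferred by Bayesian regression of their (known-covariate-adjusted)
parameter means on the group-difference betas; the observation
covariance adds the subject posterior, the between-subject covariance
and the propagated uncertainty of the known-covariate betas (the VH beta
itself enters as a point estimate). The prior over the unknown score
uses full-sample moments rather than training-fold moments: a
training-fold mean differs systematically between groups and, whenever
the likelihood is weak, anti-correlates predictions with labels (the
leave-one-out mean artifact). Even so, LOO predictions share training
folds, so the null distribution of the point-biserial r is overdispersed
relative to 1/sqrt(n) and slightly negative — quantified in the tests.

CVA residualizes the k connection values and the severity score on
(intercept, age, sex) and computes canonical correlations via SVD of the
orthonormalized blocks; the first-pair scores are sign-aligned so their
correlation is nonnegative (canonical correlations are nonnegative by
construction; for k = 1 the first correlation equals the absolute
partial correlation). Significance uses Bartlett's chi-square
approximation of Wilks' lambda with the confound degrees of freedom
removed.

Cohort summary statistics (pooled t from printed means/SDs, Pearson
chi-square without continuity correction, Fisher exact with the
conditional-MLE odds ratio, Mann-Whitney U) delegate to scipy.stats.

## Synthetic cohorts

The generator emulates the study conditions: TR 3.36 s, 110 volumes with
the first five discarded, two groups with covariates loosely matching
the cohort demographics (ages ≈ N(64, 8) / N(65, 9); female fraction
31/75 vs 11/15). Group-mean connectivity carries a documented
"commonalities" pattern (homologous interhemispheric couplings +0.25 Hz,
geniculate and prefrontal input to V1 +0.15…0.2 Hz, mildly negative
thalamic afferents to PFC); the hallucinating group receives the six
reported extrinsic differences at their printed magnitudes (lLGN→V1
−0.39, lLGN→medThal −0.32, lLGN→lPFC +0.35, lPFC→medThal +0.33, lPFC→V1
+0.38, rPFC→V1 −0.36 Hz) plus intrinsic offsets of ±0.2 log-units with
the reported signs. Subject neural parameters scatter about the group
means with sd 0.1 Hz; hemodynamic and noise parameters are drawn from
their priors. Unstable draws are resampled (bounded, counted).

Observations are, by default, complex-Wishart samples of the true CSD
with 40 degrees of freedom per frequency — a deliberately generous
stand-in for the sampling variability of a spectral estimate from ~100
volumes. A time-series mode synthesizes stationary BOLD series directly
in the frequency domain (Fourier coefficients shaped by a matrix square
root of the predicted spectrum), which is distribution-exact for the
stationary linear model and avoids integration bias; the independent
Euler-Maruyama/Welch check of the forward model lives in the test suite
instead. Severity for hallucinators is a noisy linear readout of the
five key connection deviations (amplitude SNR 2), scaled into a
questionnaire-like range.

What the generator does not emulate: scanner artefacts, motion-correlated
signal, physiological noise beyond the power-law terms, non-stationarity,
and spatial/voxel-level structure (eigenvariate extraction is tested on
synthetic voxel matrices, not images). Passing recovery tests therefore
demonstrates the statistical machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes and defaults

Recovery analyses use 20 subjects per group — the regime where the six
±0.35 Hz effects are detectable but first-level attenuation is visible —
and 10 simulation seeds; the full pipeline on one such cohort (40
inversions, 32,041-model comparison, BMA, 40-fold LOO, CVA) runs in a
couple of minutes on one CPU. Collinearity among V1's seven afferents
means individual-subject estimates of, e.g., lLGN→V1 are strongly
shrunk; the group difference usually survives with the right sign but
its model-averaged magnitude underestimates the generating value. This
attenuation is expected behaviour of shrinkage priors under limited
spectral information, and is why sign rather than magnitude is the
recovery criterion.

## Known limitations

* The variational scheme is a local optimizer; strongly coupled subjects
  can terminate at the iteration cap with the free energy still creeping
  (parameter estimates plateau much earlier).
* The single isotropic between-subject precision is the simplest
  random-effects model; per-parameter components are config-extensible
  but not implemented.
* LOO predictive densities treat the group-difference beta as known at
  its posterior mean.
* The outlier rule of motion QC ("outliers > 30%") requires an outlier
  definition; volumes with FD > 0.5 mm is a convention, configurable.
* Real-data quantities (89.6% mean variance explained, winning-model
  probabilities, LOO r = 0.25, CVA r = 0.864) depend on the unavailable
  cohort fMRI and are not reproduced here; synthetic-cohort analogues
  are computed instead.
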