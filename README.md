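# specdcm

Spectral dynamic causal modelling of the resting-state visual network,
with hierarchical group inference and cross-validated prediction of
visual-hallucination status.

## What this package is for

Visual hallucinations in Parkinson's disease are thought to arise from
aberrant hierarchical processing: weakened bottom-up sensory signalling
together with overweighted top-down perceptual priors. Testing that
account needs *directed* (effective) connectivity, which ordinary
resting-state functional connectivity cannot provide. `specdcm`
implements the full analysis chain for an eight-node visual network
(left/right LGN, medial thalamus, V1, left/right hippocampus, left/right
dorsolateral PFC):

1. **Subject level** — spectral DCM: a linear stochastic neural model
   with a linearized balloon hemodynamic response predicts BOLD
   cross-spectral densities `S(f) = T(f) G_u(f) T(f)* + G_e(f)`;
   variational Laplace finds the Gaussian posterior over 56 extrinsic
   couplings (Hz), 8 intrinsic log-scaled self-couplings, hemodynamic
   and power-law noise parameters by maximizing the free energy
   F = accuracy − complexity.
2. **Group level** — parametric empirical Bayes (PEB): a Bayesian GLM
   over subject posteriors with design (mean, VH, age, sex).
3. **Hypothesis testing** — a factorial model space over direction
   (top-down/bottom-up/both), laterality (inter/intra/both) and regional
   involvement (29 families), giving 179 reduced models each for the
   commonalities and the VH differences (179² = 32,041 joint
   hypotheses), scored analytically by Bayesian model reduction and
   summarized by family pooling and Bayesian model averaging (reporting
   threshold: 95% posterior probability of being present).
4. **Validation** — an automatic greedy search (256 models averaged at
   the final iteration), leave-one-out prediction of group membership
   from the top connections (point-biserial r), and a canonical variate
   analysis of connectivity against hallucination severity adjusted for
   age and sex.

Because no subject-level fMRI is publicly available for the motivating
cohort, the package ships a first-class synthetic-cohort generator
(`specdcm.synthesize`) that reproduces the study's statistical structure
— TR 3.36 s, 110 volumes, group effects on named connections, severity
linked to connectivity — so every stage is exercised against known
ground truth.

It is written for neuroimaging methodologists who want a transparent,
tested, pure-Python implementation of this analysis style: estimator
classes (`SpectralDCM`, `PEB`) follow scikit-learn conventions, the rest
is composable functions plus a thin `specdcm` command-line interface.

## Worked example

Simulate a 40-subject cohort (20 hallucinators, 20 non-hallucinators)
with the six reported connection differences, run the whole pipeline,
and print the headline numbers:

```python
from specdcm import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1, n_per_group=20))
print(f"variance explained: {bundle['variance_explained']['mean']:.1f}%")
print(f"best joint model probability: {bundle['joint_best']['joint_probability']:.2f}")
print(f"key effect signs recovered: {bundle['recovery']['n_key_sign_ok']}/5")
print(f"LOO r_pb = {bundle['loo']['r_pb']:.2f}  (p = {bundle['loo']['p_value']:.1e})")
print(f"CVA first canonical r = {bundle['cva']['r']:.2f}")
```

```
variance explained: 98.3%
best joint model probability: 0.84
key effect signs recovered: 4/5
LOO r_pb = 0.85  (p = 4.8e-12)
CVA first canonical r = 0.41
```

Reading the output: the DCM fits explain ~98% of the observed
cross-spectral variance; Bayesian model comparison concentrates on one
(commonalities, differences) model pair; the model-averaged group
differences recover the generating sign on 4 of the 5 key connections
(collinearity among V1's afferents shrinks the weakest one to zero);
leave-one-out prediction of hallucination status from the top-5
connections is strongly positive (real-data effects are far smaller);
and the first canonical correlation between connectivity and severity is
positive in the hallucinating group.

The same run from the shell:

```bash
specdcm run --seed 1 --out results/
```

Table-style cohort statistics from printed group summaries:

```python
from specdcm import cohort_stats
cohort_stats([
    {"variable": "smell", "test": "t", "mean1": 7.92, "sd1": 3.16, "n1": 75,
     "mean2": 6.40, "sd2": 3.29, "n2": 15},
    {"variable": "motor dominance", "test": "chi2",
     "table": [[29, 42, 4], [7, 8, 0]]},
])
#           variable  test  statistic   p_value
# 0            smell     t    1.68939  0.094685
# 1  motor dominance  chi2    1.01600  0.601698
```

## Layout

```
src/specdcm/
  network.py     # 8-node network, connection indexing and taxonomy
  params.py      # parameter layout and shrinkage priors
  forward.py     # linearized neural + balloon model, predicted CSD
  spectra.py     # CSD container, MAR spectral estimation
  invert.py      # variational Laplace, SpectralDCM estimator
  preprocess.py  # motion QC, cosine detrending, eigenvariates
  peb.py         # design construction, PEB estimator
  modelspace.py  # BMR, factorial space, joint BMC, BMA, greedy search
  validate.py    # LOO prediction, CVA, cohort statistics
  synthesize.py  # synthetic cohorts with known ground truth
  pipeline.py    # end-to-end driver
  cli.py         # `specdcm` command line
docs/methods.md  # model, priors, numerical choices, limitations
```
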