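# rsgca

Seed-based **signed-path-coefficient Granger causality** and **functional
connectivity** analysis for resting-state fMRI time series, with
random-effects group inference under permutation familywise-error control,
bootstrap mediation, PCA severity composites — and a **calibrated synthetic
cohort generator** that provides ground truth for every stage.

## The scientific problem

Large-scale brain networks — the salience network anchored on the right
anterior insula (rAI) and dorsal anterior cingulate (dACC), and the central
executive network anchored on the dorsolateral prefrontal cortex (DLPFC) —
interact through directed influences that zero-lag correlation cannot
resolve. In schizophrenia, the *feedforward* excitatory drive from the rAI
to the right DLPFC and the reciprocal feedback appear to break down, and the
degree of breakdown tracks illness severity. Testing such claims requires a
pipeline that (i) estimates, per subject, the directed lag-1 influence of a
seed on every target and back,

```
y_t = b0 + b_yy * y_{t-1} + b_xy * x_{t-1} + e_t    (both series z-scored)
```

where `b_xy` is the signed path coefficient of seed `x` on target `y`
(positive = excitatory, negative = inhibitory; lag = 1 TR = 2.5 s), together
with zero-lag functional connectivity `z = atanh(r)`; (ii) takes the
per-subject maps to random-effects group inference with familywise-error
control (permutation maxT, Freedman–Lane under age/gender covariates),
search-volume masks, cluster extent filtering and Bonferroni follow-ups;
(iii) asks, via Preacher–Hayes bootstrap mediation, how much of the
diagnostic effect on seed→DLPFC outflow flows through aberrant seed FC; and
(iv) relates PCA composites of the directed coefficients to a PCA composite
of illness severity by multiple regression.

Because lag-based inference on BOLD signals can be confounded by regional
hemodynamic-delay differences and by zero-lag correlation "bleeding into"
lagged estimates, the package also ships the two confound diagnostics as
simulations, and its synthetic cohorts include hemodynamic convolution with
per-subject delay jitter so that those arguments can be checked rather than
assumed.

The generator is *estimand-calibrated*: network weights are solved so that
the population value of the estimator — through hemodynamic convolution,
decimation to the TR, observation noise and the 0.01–0.08 Hz band mask —
equals published group-mean coefficients (e.g. rAI→rDLPFC 0.103 in
controls, 0.027 in patients), so recovery tests have exact targets. See
`docs/methods.md` for the models and calibration details.

## A worked example

```python
import numpy as np
from rsgca import pairwise_gca

rng = np.random.default_rng(0)
c = 0.103                      # generating lag-1 influence, x -> y
est = []
for _ in range(35):            # 35 subjects, 300 volumes each
    x = rng.standard_normal(300)
    e = np.sqrt(1 - c**2) * rng.standard_normal(300)
    y = np.concatenate([[e[0]], c * x[:-1] + e[1:]])
    est.append(pairwise_gca(x, y)[0])
print(round(float(np.mean(est)), 4))
```

prints

```
0.1072
```

the subject-averaged signed path coefficient, landing on the generating
value 0.103 within Monte-Carlo error (SE ≈ 0.01 at this sample size). The
same estimator applied to a full simulated cohort
(`rsgca.simulate_cohort(rsgca.CohortConfig())`) recovers the calibrated
group means after the complete preprocessing chain; `examples/` walks
through each capability:

- `01_simulate_cohort.py` — generate a two-group cohort with ground truth
- `02_granger_basics.py` — the estimator on a transparent toy system
- `03_group_analysis.py` — seed maps, masks, maxT-corrected group contrast
- `04_mediation_severity.py` — the full pipeline report
- `05_hemodynamic_confound.py` — the delay-confound argument by simulation

An end-to-end run is also available from the shell:

```bash
rsgca all --seed 1 --out results/run      # simulate + analyze everything
rsgca simulate --seed 1 --out cohort/     # just write a cohort as TSVs
```

`rsgca all` writes per-subject map TSVs, group tables, the mediation and
severity results, and a manifest with config, seeds and per-file checksums;
a fixed seed reproduces the manifest byte for byte.

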