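# somatoprf

Two-dimensional population receptive field (pRF) mapping of the hand
representation in somatosensory cortex, for vibrotactile fMRI on a 4 x 4
stimulation grid (digits D2-D5 x proximal-distal sites PD1-PD4).

Phase-encoded ("travelling-wave") designs locate each voxel's preferred
stimulus but say nothing about receptive-field *size* or *shape*. pRF
modelling fits an explicit receptive-field model to each voxel's BOLD
time course and recovers both. This package provides the full analysis
chain for the 2D digit-grid setting, plus a synthetic-session generator
so the chain can be validated end to end without scanner data:

* travelling-wave stimulus construction (between-digit, within-digit and
  diagonal sweeps; forward/reverse runs; session concatenation),
* four pRF model families — a separable 2D Gaussian
  `w(d, pd) = exp(-[(d0-d)^2/(2 sigma_d^2) + (pd0-pd)^2/(2 sigma_pd^2)])`,
  two sets of four scaled 1D Gaussians (between-digit and within-digit),
  and an unconstrained 16-weight model as the fit ceiling — each with a
  5-parameter double-gamma HRF (9 / 16 / 16 / 21 free parameters),
* voxel-wise bounded nonlinear least squares with grid-search
  initialisation; adjusted r^2 and AIC for model comparison,
* the Fourier travelling-wave reference analysis: coherence, phase,
  amplitude, exact coherence p-values with Hommel correction, and
  phase-binned digit/PD labels,
* Dice label agreement, AIC preference matrices, ROI aggregation with
  ANOVA + Tukey HSD, and pRF coverage maps (bicubic upsampling, Laplace
  extrapolation, PCA summary, peak alignment).

The fitting front ends are scikit-learn-style estimators
(`PRFEstimator`, `TravelingWaveAnalyzer`) with `fit`, fitted `*_`
attributes and `get_params`/`set_params`; a `click` CLI (`somatoprf`)
orchestrates simulate → tw → fit → evaluate → coverage → report.

## Worked example

Simulate a small somatotopic patch under the study protocol (one
between-digit forward/reverse pair, two within-digit pairs, one diagonal
run; 744 volumes at TR 2 s), preprocess, fit the 2D Gaussian family, and
score recovery against the planted ground truth:

```python
import numpy as np
from somatoprf import (generate_patch, simulate_session, SimulationConfig,
                       preprocess_timeseries, PRFEstimator, score_recovery)

patch = generate_patch(shape=(6, 6))          # 36 voxels, D2->D5 gradient
cfg = SimulationConfig(tsnr=50.0, seed=42)    # study protocol, 744 volumes
sess = simulate_session(patch, cfg)

psc = preprocess_timeseries(sess.data, cfg.tr,
                            run_boundaries=sess.seq.run_boundaries)
est = PRFEstimator(seq=sess.seq, model="2d_gaussian").fit(psc)
df = est.results_frame()
print(df[["voxel", "preferred_digit", "preferred_pd",
          "sigma_d", "sigma_pd", "adjusted_r2"]].head(3).round(3))

rec = score_recovery(sess.truth, df)
print(f"median |d0 error|   : {rec['d0']['median_abs_error']:.3f} grid units")
print(f"pooled sigma corr   : {rec['sigma_pooled_correlation']:.3f}")
print(f"digit-label Dice    : {rec['dice_digit']:.3f}")
```

Output:

```
   voxel  preferred_digit  preferred_pd  sigma_d  sigma_pd  adjusted_r2
0      0            1.338         0.500    0.367     1.667        0.556
1      1            1.658         1.027    0.812     1.702        0.628
2      2            2.158         0.927    0.986     2.025        0.676
median |d0 error|   : 0.048 grid units
pooled sigma corr   : 0.943
digit-label Dice    : 0.970
```

Each row is one voxel's fitted pRF: its preferred digit and
proximal-distal location in grid units (1 = D2 / tip, 4 = D5 / base),
its size sigma along each axis, and the parameter-penalised goodness of
fit. The summary lines compare estimates with the generator's ground
truth: at temporal SNR 50 the preferred digit is recovered to ~0.05 grid
units (median), pRF sizes correlate at ~0.94 with the planted values,
and 97% Dice overlap of discretised digit labels.

The same chain is available from the shell:

```bash
somatoprf all --out run/ --seed 1          # full pipeline, TSV artefacts
somatoprf simulate --config cfg.yaml --out run/
```

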