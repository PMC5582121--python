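# apmoments

Estimation of the probability density function (PDF) of ionic-conductance
multipliers of cardiac action-potential (AP) models from sets of variable AP
measurements, by observable moment matching under the maximum-entropy
principle.

Instead of fitting each measurement individually, the method treats the
measurement set as a whole: conductances are modelled as random variables,
a simulation database is pre-computed on a Sobol discretization of the
parameter box, and the density is found point-wise on the collocation points
by maximizing entropy subject to matching the empirical moments of selected
observables (AP time-series values, or biomarkers and their pairwise
products). The inverse step performs **zero** additional forward
simulations.

## Components

| module | role |
| --- | --- |
| `apmoments.cell_models` | paced AP simulation (stiff ODE integration, pre-pacing to a permanent regime); ships the Courtemanche et al. 1998 human atrial model and a fast two-variable pulse model with a closed-form solution used as the test fixture |
| `apmoments.biomarkers` | APD90/50/30/20, APA, RMP, V20, dV/dt max, V_notch, AUC and all pairwise products |
| `apmoments.database` | parameter box, unscrambled Sobol collocation, simulation database with evaluation counter, HDF5 persistence |
| `apmoments.observable_selection` | regression-based sensitivities + Ward agglomerative clustering to pick a small set of representative time steps |
| `apmoments.omm_core` | empirical moment constraints (standardized, products as mean constraints), damped-Newton maximum-entropy dual solver with Hessian regularization, parameter-moment augmentation for combined scenarios |
| `apmoments.postprocess` | parameter moments, weighted-KDE marginal densities, observable pushforward densities |
| `apmoments.calibration` | representative-sample selection and CMA-ES calibration of non-varying conductances with the regularized cost and the 5x g_Na cap |
| `apmoments.synthetic_data` | ground-truth-known synthetic sets: truncated-normal conductances, trace-level Gaussian noise at a stated SNR (dB), drug-block and multi-frequency scenario modifiers |
| `apmoments.cli` | YAML-configured pipeline (`gen-synthetic → build-db → select-steps → estimate → postprocess`) with run manifests and JSON-line logs |

## CLI

```sh
apmoments run --config cfg.yaml --out run_output/
apmoments build-db --config cfg.yaml --out db.h5
apmoments select-steps --db db.h5 --n-clusters 30 --out steps.json
apmoments estimate --db db.h5 --measurements samples.csv --nm 2 --steps steps.json --out pdf.h5
apmoments postprocess --pdf pdf.h5 --out marginals.csv
```

Minimal config (fixture model):

```yaml
seed: 3
model: toy               # or: courtemanche
protocol: {n_prepace: 0}
box: {names: [g_dep, g_decay], lower: 0.5, upper: 2.0}
observables: {kind: timeseries, step_ms: 10.0}
synthetic: {n_samples: 200, snr_db: 41.0}
database: {n_points: 1024}
select_steps: {n_clusters: 5}
estimate: {n_m: 2}
```

## Notes on numerics

- Observable columns are affinely standardized against the measurement set
  before powers are taken; pairwise products enter as additional mean
  constraints (this convention reproduces the 54/119 counts).
- Moment targets that provably cannot be met on the database (e.g. noise
  pushes an empirical moment outside the simulated range at a
  low-information observable) can be dropped with
  `omm_core.filter_feasible`; the solver itself reports per-constraint
  infeasibility and returns its best iterate when not converged.
- Failed forward simulations are flagged and excluded from all quadratures
  rather than raised, so database construction survives extreme parameter
  corners.
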