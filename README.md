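# ctrlnet

Optimal-control energetics of brain-state transitions on structural
connectomes.

`ctrlnet` models region-level brain activity as a linear dynamical system
on a weighted structural connectome and quantifies, per subject:

- the **control energy** of steering the system between two activation
  states (finite-horizon optimal control, solved as a linear two-point
  boundary value problem via the matrix exponential of the augmented
  state/costate system);
- the **stability** of a state, defined as the inverse log10 of the
  energy needed to maintain it against its own dynamics;
- the **control impact** of each region, the change in transition energy
  when that region is removed from the network;
- the **variability of suboptimal trajectories**, obtained by
  discretizing the dynamics with a zero-order hold at a tenth of the
  fastest mode's rise time, perturbing the optimal control inputs with
  seeded Gaussian noise, and summarizing the per-timestep dispersion of
  the resulting state cloud along its first principal component;
- **cohort statistics** over these quantities: two-level repeated-measures
  contrasts (exact difference-score ANCOVA), group contrasts, and
  covariate-adjusted regressions on scalar gene scores.

Because no public reference dataset exists for these analyses, the package
ships a fully seeded synthetic generator (`ctrlnet.synth`) that produces
modular FA-like connectomes, paired low/high-demand activation states,
weight-preserving connectome degradation for a patient-like group, and
standardized gene-score covariates with configurable injected effects.
Everything on disk is plain CSV/JSON/YAML.

## CLI

A single config (YAML or JSON, see `ctrlnet.config.RunConfig` for all
keys and defaults) drives the pipeline; one master seed fixes every
artifact byte-for-byte.

```sh
ctrlnet simulate   --config config.yaml            # synthetic cohort + manifest
ctrlnet energy     --config config.yaml            # energies, stabilities, impact
ctrlnet suboptimal --config config.yaml            # perturbation deviation table
ctrlnet stats      --config config.yaml            # inferential battery
ctrlnet all        --config config.yaml --seed 7   # everything, seed override
```

Outputs land in `<out_dir>/`: `data/` (per-subject connectome and state
CSVs, `cohort.csv`), `energy.csv`, `stability.csv`,
`nodal_energy_{0to2,2to0}.csv`, `suboptimal.csv`, `results.csv`,
`manifest.json`, and `run.log`. Tables carry a `# config_hash=` header
line.

## Library sketch

```python
import numpy as np
from ctrlnet import (
    make_connectome, make_state_pair, stabilize,
    TransitionSpec, optimal_control, state_stability,
    discretize, repeat_analysis,
)

conn = make_connectome(n_nodes=50, n_modules=4, seed=0)
system = stabilize(conn)                       # strictly stable dynamics
pair = make_state_pair(conn, seed=0)
res = optimal_control(system, TransitionSpec(
    x0=pair.state_0back, xT=pair.state_2back))
print(res.total_energy, res.nodal_energy.shape)

stab = state_stability(system, pair.state_2back)
rep = repeat_analysis(discretize(system), res, sigma=0.05, seed=1)
print(stab.stability, rep.mean_deviation)
```

## Acceptance

The acceptance suite is property-based (`tests/test_acceptance.py`): the
solver is checked against an independent sparse quadratic-program oracle,
the controllability-Gramian minimum-energy limit, and the closed-form
scalar boundary solution; discretization against closed forms and RK4
integration; the perturbation summary against a covariance-eigenvalue
oracle; and the statistical layer for type-I calibration and power on
seeded synthetic cohorts.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke of the pipeline and writes the (empty) numeric
target map — the reference cohort statistics depend on access-restricted
participant-level data and cannot be recomputed offline.
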