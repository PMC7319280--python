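# p53pool

Subpopulation-based modeling of pulsatile p53 single-cell dynamics and
screening for the network processes targeted by a pathway perturbation.

## The problem

After ionizing radiation, single cells show pulses of nuclear p53 with
near-uniform amplitude and a ~5.5 h period, driven by two delayed negative
feedbacks (Mdm2, which degrades p53, and Wip1, which deactivates both
damage-sensing ATM and active p53).  Cell-to-cell variability in
production rates desynchronises these pulses, so population averages blur
the dynamics, and pharmacological perturbations of an interacting pathway
(e.g. IKK2/NF-κB inhibition) shift pulse timing and damping in ways a
single-cell, subpopulation-resolved model can attribute to specific
biochemical processes.

`p53pool` implements that workflow end to end, for computational biologists
studying signaling crosstalk:

1. a seven-variable ODE model of the ATM–p53–Mdm2–Wip1 network
   (22 kinetic parameters, 6 of them — the production rates — allowed to be
   subpopulation specific);
2. trajectory processing: Gaussian smoothing, alternating extrema
   detection, and ten pulse features per cell (t^max, t^min, IPI, F^max,
   F^min, dampening factor DF_n = F^max_1/F^max_n, amplitude, width,
   slopes), with Wilcoxon/Holm feature comparisons;
3. hierarchical clustering of trajectories into subpopulations with
   Calinski–Harabasz selection of the cluster number and *peak-based means*
   (mean peak timings/values) per cluster;
4. calibration of a **model pool** — shared kinetics plus a K×6 matrix of
   log10 fold changes — fitted simultaneously to all peak-based means with
   L1 regularization identifying dispensable fold changes;
5. a crosstalk screen: feature-based sensitivity analysis of single and
   signed-pair parameter perturbations, inference of perturbation fold
   changes for parameter pairs/triplets, weighted-χ² ranking, time-variant
   onset validation, qualitative population-readout filters, and mechanism
   grouping;
6. a synthetic single-cell data generator with ground-truth records, so
   every stage is testable in closed loop.

The estimation core follows the Model/Results convention:
`ModelPoolCalibration(targets).fit()` returns `PoolCalibrationResults` with
the fitted pool, residual diagnostics and a `summary()` table.

## Worked example

Simulate the reference cell, sample it like a 15-min imaging experiment and
extract pulse features:

```python
import numpy as np
from p53pool import (REFERENCE_PARAMETERS, simulate, observe_p53, Trajectory)
from p53pool.trajectories import features_dataframe

res = simulate(REFERENCE_PARAMETERS, t_span=(0.0, 24.0))   # step damage at t=0
t, y = observe_p53(res)
grid = 0.5 + 0.25 * np.arange(95)                          # 0.5..24 h frames
cell = Trajectory("cell_0001", grid, np.interp(grid, t, y))
table = features_dataframe([cell])
print(table.query("feature in ('t_max','ipi','df') and peak_index <= 4")
      .pivot(index="feature", columns="peak_index", values="value").round(3))
```

prints

```
peak_index     1      2      3       4
feature
df          1.00  1.121   1.15   1.167
ipi         5.75  5.500   5.25     NaN
t_max       2.00  7.750  13.25  18.500
```

i.e. four p53 pulses at 2.0/7.75/13.25/18.5 h — inter-peak intervals of
5.25–5.75 h — whose amplitudes decay only mildly (the fourth pulse still
reaches 1/1.167 ≈ 86% of the first): pulsing with near-uniform amplitude
under persistent damage.

A complete demo — generate a heterogeneous synthetic dataset, cluster it,
calibrate a pool, fit candidate perturbation combinations and write a
mechanism report — runs from the shell:

```bash
p53pool pipeline -o demo_run --seed 0
```

and leaves trajectory/feature/cluster CSVs, the calibrated pool JSON, a
combination ranking and `mechanism_groups.json` in `demo_run/`.

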