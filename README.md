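# capsulepk

Two-compartment pharmacokinetics of **intraperitoneal (IP) encapsulated-cell
cytokine factories**: alginate capsules carrying engineered cells that
secrete IL2 directly into the peritoneal cavity. Because the peritoneal wall
transports cytokine to the circulation slowly while the kidneys clear it
quickly, a local depot sustains a therapeutic IP concentration while keeping
blood levels orders of magnitude lower — the premise this package lets you
simulate, fit, and design dosing regimens for.

## Model

The IP space (volume `V1`) and blood (volume `V2`) are well-mixed
compartments. `N(t)` viable capsules each produce IL2 at `k_prod` pg/day;
the foreign-body response silences capsules with first-order rate `λ`;
IL2 crosses between compartments at rate `k_trans` and is renally cleared
at `k_clr` ml/day:

```
dN/dt  = -λ N
dC1/dt = k_prod N / V1 - k_trans (C1 - C2)
dC2/dt = k_trans (V1/V2)(C1 - C2) - k_clr C2 / V2
```

Units are fixed package-wide: days, pg/ml, ml. The augmented state
`(N, C1, C2)` obeys a constant-coefficient linear system, so an exact
matrix-exponential solution exists alongside the stiff numerical
integrator; the two are cross-checked to 1e-6 relative error in the tests.

What the package provides, per module:

- `capsulepk.model` — simulation (capsule and constant-infusion variants),
  exact closed-form oracle, therapeutic-window and peak/ratio summaries.
- `capsulepk.fitting` — the LOD-aware normalized-MSE objective
  `Σ (μ−P)²/(μ²+μ0²)` (censored points below the 30 pg/ml detection limit
  cost nothing when the model also predicts below it), particle-swarm
  estimation in log-parameter space with literature bounds per species, and
  a one-parameter fit of the human transport rate from infusion data.
- `capsulepk.dosing` — redosing by block integration (capsules accumulate
  at each event) and dose-interval optimization against a target trough.
- `capsulepk.species` — mouse/NHP/human parameter assembly: `V2 = 65·m` for
  NHP blood volume, the human `V1:V2` ratio for NHP IP volume, linear
  clearance–mass scaling, and infusion rates from body-surface-area dosing.
- `capsulepk.synth` — synthetic measurement campaigns with the real
  designs' structure: sparse day 1–30 grids, 5 replicate animals per time
  point, lognormal multiplicative noise, censoring at the assay LOD.
- `capsulepk.cli` — `capsulepk simulate | infuse | fit | optimize-dose | synth`.

## Worked example

Simulate a human-scale single dose of 5000 capsules using the shipped
(synthetic, reconstructed) human parameter table:

```python
import numpy as np
from capsulepk import load_parameters, simulate, summary_metrics, therapeutic_window

params, thr = load_parameters("configs/human_synthetic_s6.yaml")
tc = simulate(params, 5000, np.linspace(0, 40, 2001))
m = summary_metrics(tc)
w = therapeutic_window(tc, thr.effector)
print(f"peak IP IL2:   {m.peak_C1:,.0f} pg/ml at day {m.t_peak_C1:.2f}")
print(f"peak blood IL2:  {m.peak_C2:,.1f} pg/ml at day {m.t_peak_C2:.2f}")
print(f"days above effector threshold ({thr.effector:,.0f} pg/ml): {w.longest:.1f}")
```

prints

```
peak IP IL2:   1,612,384 pg/ml at day 1.77
peak blood IL2:  134.3 pg/ml at day 1.80
days above effector threshold (21,000 pg/ml): 13.6
```

IP IL2 peaks near 1.6 µg/ml about two days after implantation while blood
stays four orders of magnitude lower — the local/systemic gradient that
makes the depot tolerable — and the IP concentration holds above the
effector-T-cell threshold for roughly two weeks before capsule decay ends
production. The same trajectory from the command line:

```
capsulepk simulate --params configs/human_synthetic_s6.yaml --n0 5000 --out-dir out/
```

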