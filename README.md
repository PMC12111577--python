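# mhckin

Kinetic modelling of myosin heavy chain (MHC) polymerization and proteolytic
degradation during the heating of surimi (salt-ground fish paste) gels.

Surimi gels set because MHC, the ~220 kDa myofibrillar protein, cross-links
into a network on heating. In species with protease-rich muscle — golden
threadfin bream (*Nemipterus virgatus*) is the motivating example — heat also
activates endogenous proteases that cut MHC, so the gel first strengthens and
then disintegrates (*modori*/*himodori*). `mhckin` is a small toolkit for
food scientists and modellers who want to quantify this competition from
SDS-PAGE densitometry time courses: it simulates the kinetics, fits the rate
constants, and generates the synthetic data needed to validate the whole
pipeline end to end.

## Model

Let `X(t)` be the normalized amount of MHC monomer, `P(t)` the normalized
amount of disulfide-polymerized MHC, and `T(t)` the sample core temperature
(°C, time in minutes):

```
dX/dt = -k1 · s(T) · X  -  k2 · g(T) · X
dP/dt = +k1 · s(T) · X  -  k2 · g(T) · P
dT/dt =  α · (T_max - T)
```

with initial values `X(0) = 1`, `P(0) = 0`, `T(0) = T_init`, and two
temperature gates:

* `s(T) = (T/T1)^d / (1 + (T/T1)^d)` — sigmoid thermal-unfolding gate
  (denatured fraction of MHC; only unfolded monomer polymerizes), inflection
  `T1`, steepness `d`;
* `g(T) = exp(-(T - T_opt)² / (2β²))` — Gaussian protease-activity gate with
  optimum `T_opt` and width `β`.

Electrophoresis under reducing conditions reports `X + P` (disulfide bonds
broken), under non-reducing conditions `X` alone — two observation channels
for one latent state. Degraded mass leaves the system; enzymatic (TGase)
cross-linking is deliberately absent, matching systems where its activity is
negligible.

`(k1, k2, β)` are estimated by coarse-to-fine grid search minimizing the
joint residual sum of squares over both channels; `(T1, d)` come from a
thermal denaturation curve and `α` from a logged core-temperature trace,
both by damped least squares.

## Worked example

```python
import numpy as np
from mhckin import (default_parameters, simulate, onset_time, GridSpec,
                    grid_search_fit, make_observations, NoiseModel)

k, h, design = default_parameters()          # reference 60 °C heating run
traj = simulate(k, h, t_end=60.0, dt_out=0.01)
print(round(onset_time(traj, "non_reduced", 0.95), 2))  # 3.45
print(round(onset_time(traj, "reduced", 0.95), 2))      # 18.84

obs = make_observations(k, h, design, NoiseModel(kind="none"), seed=0)
fit = grid_search_fit(obs, GridSpec(), h,
                      fixed={"T1": k.T1, "d": k.d, "T_opt": k.T_opt})
print(round(fit.best.k1, 4), round(fit.best.k2, 5), round(fit.best.beta, 4))
# 0.044 0.05304 0.2138
```

The two onset times say that monomeric MHC (non-reduced channel) starts
disappearing about 3.5 min into heating — as soon as the core passes the
unfolding inflection — while total MHC (reduced channel) only declines after
~19 min, once the core is close enough to the 60 °C protease optimum for the
narrow Gaussian gate to open. The fit recovers the generating rate constants
(k1 = 0.044/min, k2 = 0.053/min, β = 0.214 °C) to the grid's final
resolution (≤ 0.001 on every axis).

The same workflow is available from the shell:

```sh
mhckin gen-data --noise-sd 0.05 --replicates 3 --seed 1 --out obs.csv
mhckin fit --obs obs.csv --out fit.json
mhckin simulate --out trajectory.csv
mhckin recover --reps 20 --noise-sd 0.05 --seed 1 --out recovery.csv
```

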