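# thermogate

Thermodynamics of temperature-gated ion channels under the two-state
(bistable) model: forward open-probability curves, closed-form design
calculations, and maximum-likelihood inference of the gating parameters
from patch-clamp-style count data.

Heat- and cold-activated TRP channels (TRPV1, TRPM8, …) switch between a
closed and an open conformation separated by a free-energy difference

```
ΔG_C(T) = ΔH − TΔS = ΔS (T½ − T),        P_open(T) = 1 / (1 + exp[ΔG_C/(RT)])
```

so the whole temperature response is captured by two parameters: the
midpoint temperature **T½** (where P_open = 0.5) and the molar opening
entropy **ΔS** (reported in units of the gas constant R). A steep
heat-activated channel that rises from ~0 to ~1 over 10 K near 313 K has
ΔS ≈ 4R·T/ΔT = 125R, hence ΔH = T½·ΔS ≈ 325 kJ/mol; shifting T½ by −10 K at
fixed ΔS costs ΔΔH ≈ −4RT (about two hydrogen bonds). `thermogate` computes
these quantities exactly, classifies channels (type-I/II × hyper-/
hypothermic), extends ΔG_C additively with a gating-charge voltage term for
polymodal channels, simulates seeded binomial gating datasets, and fits
(T½, ΔS) to open/trial counts by binomial maximum likelihood with
parametric-bootstrap confidence intervals.

It is intended for channel biophysicists who want model curves, mutation-
design arithmetic, or parameter estimates from measured open-probability
data, without writing the fitting machinery themselves.

## Worked example

Simulate a TRPV1-like channel (ΔS = 125R, T½ = 316 K) on a 298–328 K grid,
500 sweeps per temperature, then fit it back:

```
$ cat demo.toml
[true_params]
delta_S_in_R = 125
T_half_K = 316.0

[grid]
T_min_K = 298.0
T_max_K = 328.0
n_points = 31

n_trials = 500
seed = 42

$ thermogate simulate --config demo.toml --out demo.csv
$ thermogate fit demo.csv --channel-type type-I --boot 1000 --seed 7 --out fit.json
```

`fit.json` then contains (abridged):

```
"T_half_K": 316.097,            "ci_T_half_K": [315.795, 316.400],
"delta_S_in_R": 124.04,         (95% CI 115.7 – 132.5 R)
"delta_H_kJ_per_mol": 325.99,
"linear_rise_width_K": 10.19,
"T_thr_K": 308.77,
"entropy_class": "type-I",      "temperature_class": "hyperthermic"
```

Reading: the fit recovers the midpoint within 0.1 K and the entropy within
1% of the simulated truth; the derived enthalpy (~326 kJ/mol) is the 125RT½
the steepness implies, the linearized rise spans ~10 K, and at a 310 K
resting temperature the channel is a type-I hyperthermic (TRPV1-like)
gater whose activation threshold (P_open = 0.05) sits near 308.8 K.

The same operations are available as a library:

```python
import thermogate as tg

trpv1 = tg.GatingParams(delta_S=125 * tg.R, T_half=316.0)
tg.open_probability(trpv1, 310.0)        # 0.082
tg.delta_enthalpy_for_shift(trpv1, 306.0).ddH_in_RT  # -3.96 (10 K downshift)
tg.classify(trpv1, T_rest=310.0)         # type-I, hyperthermic
```

Other CLI subcommands: `curve` (tabulate T, ΔG_C, P_open), `design`
(ΔΔH for a target midpoint shift), `classify`. All accept `--celsius` for
Celsius-valued inputs and record the resolved configuration and seed in
their output.

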