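# Methods

## The two-state gating model

`thermogate` treats a temperature-gated ion channel (a thermo-TRP such as
TRPV1 or TRPM8) as a bistable system: the closed and open conformations are
two thermodynamic states separated by a conformational free-energy difference

    ΔG_C(T) = ΔH − TΔS = ΔS (T½ − T),

with the open probability given by the Boltzmann occupancy of the two-state
system,

    P_open(T) = 1 / (1 + exp[ΔG_C(T) / (RT)])
              = 1 / (1 + exp[(T½ − T) ΔS / (RT)]).

The second line is the reparameterization the package uses everywhere: the
midpoint temperature T½ = ΔH/ΔS (where ΔG_C = 0 and P_open = 0.5) and the
molar opening entropy ΔS are the two independent parameters; ΔH is always
derived as T½·ΔS and never stored separately. The general (ΔH, ΔS) form is
available through `open_probability_general` for cases without a defined
midpoint (e.g. ΔS = 0).

Assumptions inherited from the model:

- **Equilibrium only.** No kinetics: no rates, dwell times, desensitization
  or hysteresis. The curve describes the stationary open fraction at each
  temperature.
- **Temperature-independent ΔH and ΔS** (ΔCp = 0). The only temperature
  dependence is the explicit T in ΔG_C and in the RT denominator.
- **Two states.** Intermediate or inactivated conformations are absorbed
  into whichever of the two states they resemble.

Because T appears in the denominator of the exponent as well, the curve is
not a logistic function of T: it is slightly skewed, losing more probability
on the cold side of T½ than it gains symmetrically on the warm side, and its
high-temperature plateau is 1/(1 + exp(−ΔS/R)) rather than exactly 1 (for
ΔS = 125R the deficit is below 1e−50 and invisible in float64; the tests
check it through a stable closed form).

## Derived quantities

All are closed forms of (ΔS, T½):

| quantity | formula | canonical value (ΔS = 125R, T½ = 313.15 K) |
|---|---|---|
| enthalpy ΔH | T½·ΔS | 325.5 kJ/mol (= 125 RT½) |
| midpoint slope | ΔS/(4R·T½) | 0.0998 K⁻¹ |
| linear-rise width | 4R·T½/\|ΔS\| | 10.02 K |
| entropy from width | 4R·T½/ΔT | 125.2R for ΔT = 10 K at 313 K |
| threshold temperature | T½ / (1 + R·ln(1/p_thr − 1)/ΔS) | 305.9 K at p_thr = 0.05 |
| design ΔΔH | ΔS·(T½′ − T½) | −10.39 kJ/mol ≈ −4 RT½ for a 10 K downshift |

The threshold temperature operationalizes the loosely defined "temperature
at which opening starts" as the point where P_open reaches a small fixed
probability; the default p_thr = 0.05 keeps T_thr on the steep flank for
steep channels while remaining attainable. The closed-form inversion refuses
probabilities above the saturation plateau with an explicit error rather
than returning a spurious extreme temperature.

Channel classification is sign arithmetic: type-I (ΔS > 0, opens on
heating) versus type-II (ΔS < 0, opens on cooling), and hyperthermic
(T½ > T_rest) versus hypothermic. The same formulas serve both types — a
cold-activated channel is simply negative ΔS, never a mirrored equation.

The polymodal extension adds free energies: ΔG_C = ΔS(T½ − T) +
zF(V½ − V), so a gating charge z at midpoint voltage V½ shifts the thermal
curve and the model reduces exactly to the pure thermal one at V = V½. This
additive form is deliberately the simplest consistent coupling; fuller joint
models (ligand, tension) are out of scope.

## Numerical choices

- Internal temperatures are kelvin; Celsius exists only at I/O boundaries
  (CSV column `temperature_C`, CLI `--celsius`), converted with 273.15.
- Constants are CODATA 2018: R = 8.314462618 J mol⁻¹ K⁻¹,
  F = 96485.332 C mol⁻¹; never user-settable.
- Exponent arguments are clipped at ±700 before `exp`, so extreme
  temperatures saturate the probability instead of overflowing. The clipped
  tail probability is ~1e−304, far below any statistical resolution.
- Probabilities entering logs in the likelihood are floored at 1e−12.

## Inference

Counts are modelled as n_open ~ Binomial(n_trials, P_open(T)) independently
per record — a "trial" abstracts one sweep (or channel × sweep) observation,
which the equilibrium model treats as exchangeable. The binomial
log-likelihood is maximized over (T½, s = ln|ΔS|), with the entropy sign
fixed a priori by the declared channel type. The log-magnitude
parameterization keeps both coordinates on comparable scales and makes sign
flips impossible; L-BFGS-B with the analytic gradient does the work and a
tight Nelder-Mead pass polishes the optimum (tolerances 1e−10 on
parameters, 1e−12 on the objective). Non-convergence is flagged on the
result; the bootstrap and report functions refuse unconverged fits.

Starting values come from the curve itself: T½ from the linearly
interpolated first 0.5-crossing of the pooled proportions (or the
temperature nearest 0.5 when the data never cross), and |ΔS| from the
steepness relation 4R·T½/ΔT with ΔT read off as twice the 0.25–0.75
crossing span, falling back to the canonical 125R when the quartiles are
not bracketed.

Degenerate inputs raise typed errors rather than returning numbers: fewer
than three distinct temperatures (under-determined), all-closed or all-open
counts (T½ unidentifiable — the likelihood increases monotonically as the
midpoint leaves the observed range), and, for the least-squares route,
exactly constant proportions (|ΔS| unidentifiable).

The least-squares estimator minimizes Σ(p_obs − p_model)² and exists for
proportion-only data; it agrees with the MLE on noiseless data and pays
roughly its usual efficiency price under binomial noise (its typical error
stays within about twice the MLE's in the seeded comparison study).

Uncertainty is a parametric bootstrap: counts are resampled from the fitted
curve, refit starting at the point estimate, and percentile intervals taken
at the requested level. Everything random takes an explicit seed; there is
no global random state anywhere in the package.

A brute-force grid search over (T½, ln|ΔS|) (`grid_search_mle`, exact
binomial log-pmf evaluated by enumeration) serves as an independent check
that the optimizer finds the global maximizer; the test suite requires
agreement within one grid cell. It is a verification tool, not part of the
fitting path.

## Synthetic data

The generator draws from exactly the statistical model the estimator
assumes: the true curve plus binomial sampling. That makes recovery and
coverage tests clean checks of the estimation machinery, and means passing
them says nothing about model misspecification in real recordings —
temperature-ramp kinetics, rundown/desensitization, gating-mode shifts,
unequal channel counts per sweep and temperature-measurement error are all
absent by design. An `exact` noise mode (round-half-to-even of n·p) gives
noise-free proportions for round-trip tests.

Default study conditions, chosen to look like a realistic steep thermo-TRP
experiment and fixed once:

- truth ΔS = 125R with T½ = 313.15 K for the canonical design (the value
  implied by a 10 K rise near 313 K); fixtures use TRPV1-like
  (+125R, 316 K) and TRPM8-like (−125R, 299 K) parameters;
- temperature grids span 30 K in ~1 K steps (298–328 K warm, 283–313 K
  cold), bracketing each midpoint by ≥1.5 linear-rise widths so both
  plateaus are sampled;
- 500 trials per temperature for the main design; a 20-trial set stands in
  for sparse recordings, and an all-closed set exercises the degenerate
  path.

## Problem sizes in the checked studies

The recovery study fits 100 seeded replicates of the 25-temperature ×
500-trial design (median |T̂½ − T½| and median relative ΔS error are the
reported statistics) and cross-checks 10 of them against a 400 × 400 grid
search. The coverage study wraps 200 outer replicates around a 200-replicate
parametric bootstrap at the 95% level. The consistency study uses 40
replicates at each of n_trials ∈ {50, 200, 1000}.

## Known limitations

- Single-channel-model fits only: no pooling across datasets, no random
  effects, no model comparison.
- The binomial noise model is an assumption standing in for unstated
  measurement error in real P_open estimates; intervals are only as good as
  that assumption.
- The percentile bootstrap can undercover slightly in very weak designs
  (few temperatures on one flank); the fitter will flag, not fix, such data.
- Q10, ligand and membrane-tension energetics, and structural calculations
  are out of scope.
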