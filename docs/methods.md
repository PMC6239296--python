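# Methods

## Model

The model describes maximal running efforts between roughly one minute
and several hours through four parameters per runner:

| parameter | units | meaning | typical range |
|---|---|---|---|
| `t_c` | min | crossover time: duration separating supra-maximal from sub-maximal efforts, approximately how long maximal aerobic power can be held | 4–25 (5–6 for elite men) |
| `v_m` | m/min | crossover velocity: smallest velocity nominally eliciting crossover power | 210–420 |
| `gamma_s` | — | endurance exponent of the short (supra-maximal) regime; *larger* is better | 0.05–0.17 |
| `gamma_l` | — | endurance exponent of the long (sub-maximal) regime; *smaller* is better | 0.04–0.06 |

All intensities are fractions of the aerobic power reserve
`P_m − P_b`. The maximal average power sustainable over a duration `T`
is `p_max(T) = 1 − γ·ln(T/t_c)` with `γ = gamma_s` below `t_c` and
`gamma_l` above. This is the exact solution of the self-consistency
relation `p_max(T) + p_sup(T) = (1/T)∫₀ᵀ p_max(T−t) dt`, where the
supplemental power `p_sup` (economy drift plus anaerobic contribution)
is `gamma_s` below the crossover and `(γ_s−γ_l)t_c/T + γ_l` above.
`verify_self_consistency` confirms the identity by adaptive quadrature
(integral split at `t_c`; the integrable log singularity at 0 is handled
by the adaptive rule); residuals are pure quadrature error, observed at
~1e−16 and asserted below 1e−8.

Key modelling assumptions:

- running economy is linear in velocity (`p = v/v_m`), valid in the
  running (not walking) regime;
- a single sharp crossover time separates the two energetic regimes;
- the instantaneous power at time `t` of a race of duration `T` equals
  the maximal power sustainable for the remaining `T − t`;
- race times and paces depend only on the four relative parameters;
  `P_b` and `P_m` (W/kg) are optional annotations for an absolute power
  scale, with `P_b` defaulting to 1.2 W/kg when requested but absent.

Internal units are fixed — metres, minutes, m/min — matching the scale
on which `v_m` and `t_c` are conventionally quoted; clock notation and
per-km paces exist only at the I/O boundary (half-up rounding at
0.01 s).

## Lambert W numerics

Race times invert to the real branch `W₋₁` on `[−1/e, 0)`. The solver is
authored in-package: initialisation from the asymptotic expansion
`L1 − L2 + L2/L1 + (L2² − 2L2)/(2L1²)` (`L1 = ln(−z)`,
`L2 = ln(−L1)`), switching to the branch-point series in
`√(2(1 + ez))` for `e·z + 1 < 1e−3`, followed by vectorised Halley
iteration with step tolerance `1e−15·(1+|w|)`. Points with
`e·z + 1 < 1e−12` keep the series value (already at machine precision;
Halley's denominator degenerates there). The tests pin the solver
against an independent bisection of `w·eʷ = z` (1e−10) and against
`scipy.special.lambertw` (1e−13); the defining-equation residual is
below 1e−12 relative across the domain. The truncated expansion itself
is exposed (`approx_race_time`) for the logarithmic rescaled form
`τ(δ) = δ − υ(δ)`; it tracks the exact solution to better than 0.4% for
arguments in `[−0.1, 0)` and warns beyond.

Branch tie-breaks: at `T = t_c` / `d = d_c` the long branch is
evaluated; both branches agree there analytically, so this only avoids a
duplicated code path.

## Parameter estimation

The objective is the sum of squared *relative* time deviations
`Σ((T_model − T_obs)/T_obs)²`. Whether deviations are taken in percent
or fraction units does not move the argmin; reports carry both scales.
Minimisation uses Nelder–Mead over log-transformed parameters
(positivity for free), with box bounds `t_c ∈ [2, 40]` min,
`v_m ∈ [150, 700]` m/min, `γ ∈ [1e−3, 0.5]` enforced by penalty;
model-domain failures inside a candidate step also return a penalty so
the simplex keeps moving. Because `t_c` and `v_m` are strongly
correlated, the fit is multi-started on a
`t_c ∈ {4,6,9,13,20} × γ_l ∈ {0.04,0.055,0.08} × γ_s ∈ {0.06,0.10,0.15}`
grid (45 starts, 800 evaluations each), with `v_m` initialised from the
observed velocity of the result raced closest to six minutes; the best
start is polished twice with `fatol = 1e−17`, `xatol = 1e−12` (log
scale). The procedure is deterministic; a seed field exists on
`FitOptions` for API symmetry with the synthetic generator. A fit needs
at least four results; when all distances end up on one side of the
fitted `d_c` the report carries a "branch undetermined" warning because
the exponent of the empty branch has nothing to constrain it.

On noiseless synthetic sets the optimum is recovered to ~1e−12 relative;
the tests assert 0.1%. Refitting the thirteen embedded
record sets reproduces their published mean absolute errors to within
±0.005 percentage points, and the published parameter values evaluate to
within 0.3% of the refit optima's objective — they are near-optimal for
this objective.

## Synthetic data

`generate_race_set` draws `T_j = T(d_j)·(1 + ε_j)` with
`ε ~ N(0, noise_sd/100)`, seeded. The noise is multiplicative because
the objective is relative; 0.5% is a realistic day-to-day spread for
well-paced races, and 0 gives exact model times for identifiability
checks. What the generator does *not* emulate: distance specialisation
(personal bests being sharper at favoured distances), fitness drift
across the years over which personal bests accumulate, weather/course
effects correlated across distances, and the granularity of hand-timed
results. Passing recovery tests therefore demonstrate identifiability
under well-behaved errors, not robustness to structured real-world bias.
The seeded Monte-Carlo recovery study uses 24 replicates of 8 log-spaced
distances at 0.5% noise — enough for a 3-sigma test on the mean of the
fitted `gamma_l` at sub-1% precision — and asserts the mean is within
three standard errors of truth.

## Reference-table reproduction and its tolerances

The source tables are embedded digit-for-digit (13 record sets, 18
individual athletes, and six pace-sensitivity grids for three reference
runners, plus the external single-parameter reference paces displayed
alongside but never computed). `reproduce_tables` / `runpower tables`
recompute every reproducible cell:

- per-distance model times from the printed parameters: 0.1% relative
  (the printed parameters are rounded to two decimals; observed worst
  deviation 0.026%);
- refitted mean |error| per record set: 0.03 percentage points;
- pace grids: 0.2 s/km for the VDOT-40 runner, whose caption parameters
  are effectively exact; 0.25 s/km for the VDOT-60/80 grids, whose
  caption `gamma_l` is printed to only three decimals — the rounding
  propagates to ~0.22 s/km in long-distance cells, which is visible
  because the columns with exactly specified overrides (e.g.
  `gamma_l = 0.04`) agree to better than 0.01 s/km.

Two quirks of the source data are flagged rather than forced:

- the male-record threshold intensity quoted as 87.08% is not
  reproducible from the printed male-record parameters, which give
  87.89%; the female value (90.41%) does reproduce. The tests assert the
  discrepancy.
- of the two sub-2-hour marathon scenarios computed from the printed
  men's record parameters, the endurance scenario (`E_l → 7.49`)
  reproduces the quoted time to 0.14%, while the crossover-velocity
  scenario (`v_m → 418.7` m/min) lands at 1:59:42.6 against a quoted
  1:59:58 (0.21%) — inconsistent with the same parameters that reproduce
  the baseline marathon model time to 3e−5. No admissible reading of the
  printed values closes that gap.

Pace-table semantics: the "time t_c (I-pace)" row is a *fixed-duration*
query at the base profile's `t_c`. Under endurance variants its pace is
unchanged (the log term vanishes at `T = t_c`); under `t_c` variants it
shifts, because the queried duration stays put while the variant's
crossover moves — this is the only reading consistent with the embedded
sensitivity grids. Distance rows use the closed-form distance equation;
"5min"/"60min" rows are duration queries; all race-pace rows are at
intensity 1. Sensitivity variants perturb exactly one parameter;
scaling `t_c` rescales `d_c = v_m·t_c` with it. Invalid cells (domain
failures) are marked, not raised, so a table always renders.

## Degenerate inputs and guards

- `gamma` below 1e−3 is rejected at profile validation (`exp(1/γ)`
  overflows; the model is meaningless there anyway).
- Durations below one minute trigger a warning: oxygen-uptake kinetics
  dominate there and are outside the model.
- Race results implying velocities outside (50, 800) m/min are accepted
  with a warning.
- Distance queries whose Lambert argument leaves `[−1/e, 0)` raise a
  domain error (the distance is outside the model's validity for that
  profile); inside the fit they are penalised instead.

## Known limitations

- No uncertainty quantification on fitted parameters beyond the
  Monte-Carlo recovery study; `t_c`–`v_m` correlation makes their
  marginal values less certain than the endurance exponents.
- Personal-best sets usually span years of changing fitness; the model
  fits a single static profile.
- The sharp crossover is an idealisation; behaviour within a few percent
  of `t_c`/`d_c` should not be over-interpreted.
- Absolute energetics (W/kg, oxygen uptake) are annotations only; the
  package neither calibrates nor validates them against spirometry.
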