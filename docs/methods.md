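# Methods

## Decision problem and model structure

The package evaluates consolidation immunotherapy against placebo in
limited-stage small-cell lung cancer after concurrent chemoradiotherapy.
Patients start progression-free (PFS), may progress (PD) and die; the model
is a three-state cohort model on monthly cycles with a 120-cycle (10-year)
horizon, long enough that ~95% of deaths occur within it on the synthetic
preset (reported as a diagnostic, never enforced).

Although the source framing is a Markov model, only OS and PFS curves are
available as evidence, so the primary realization is **partitioned
survival**: occupancy is read directly off the curves,
`pfs(t) = min(S_PFS(t), S_OS(t))`, `death(t) = 1 − S_OS(t)`, `pd(t)` the
remainder. The clamp handles extrapolated curves that cross. A secondary
`transition` mode converts the same curves into per-cycle probabilities
(death hazard from OS applied to both alive states, progression hazard from
the PFS exit rate net of death) and iterates the state vector; it exists as
a structural sensitivity and coincides with the primary mode exactly when
progressors and non-progressors share the death hazard.

## Survival reconstruction and extrapolation

Digitized KM coordinates plus number-at-risk tables are inverted into
pseudo individual-patient data: within each inter-reading interval, event
counts at each digitized point are chosen to match the KM step ratios
(integer rounding with a carried residual so cumulative counts track the
curve), and the censor count is iterated until the implied number at risk
matches the next reading; censored subjects are spread uniformly over the
interval. Without a usable at-risk table the fallback assumes censoring
only at the administrative tail and flags it in the output metadata. An
optional published total event count rescales per-interval events in a
second pass (tracking the digitized rather than the implied curve, since
the self-correcting ratio update would otherwise undo the rescaling). The
procedure is deterministic.

Eight parametric families are fitted to the pseudo-IPD by maximum
likelihood under right censoring (log-density for events, log-survival for
censored). Parameterizations follow the flexible-survival conventions and
are tabulated in the `survival_models` module docstring; the generalized
gamma uses the location/scale/shape (μ, σ, Q) form with the log-normal as
its Q→0 limit, and the Gompertz is implemented directly so that negative
shapes (survival plateau `exp(rate/shape)`) are admissible. Optimization is
multi-start L-BFGS on log-transformed positive parameters with a
Nelder-Mead polish; the exponential rate uses its closed form
(events / total follow-up) exactly. Model selection is lowest AIC, ties
broken by lower BIC, then fewer parameters. Extrapolation to the horizon
uses the fitted function as-is (no hazard blending), matching the
evidence-generation convention the model emulates.

Numerical notes: event times at the grid origin are nudged to 1e-6 months
before taking logs; survival evaluations are clipped to [0, 1]; quadrature
equivalence of S(t) and exp(−∫h) is tested to 1e-6 for every family.

## Costs, utilities, discounting

All amounts are USD; CNY-tagged config fields convert once at load at
7.11 CNY/USD. Per-cycle unit costs (drug $7,631.74; laboratory $134.36;
imaging $140.65; topotecan $72.17; carboplatin $87.94; etoposide $266.67;
best supportive care $327.46; palliative care $2,549.63) and utilities
(PFS 0.673, PD 0.473 per year) follow the published parameter table, with
±20% bounds on costs.

Accounting per cycle k, discounted by `(1 + r)^(−k/12)` with r = 0.05
(varied 0–8%):

- **PFS**: drug (intervention arm only, while within any treatment cap,
  optional 13/12 dosing-intensity factor, default off) plus laboratory and
  imaging in both arms.
- **PD**: progression entrants (approximated by the decline in PFS
  occupancy) receive the second-line mix — 66.2% platinum–etoposide
  rechallenge, 33.8% topotecan — for 6 cycles after progression (clipped to
  PD occupancy), then best supportive care. The 6-cycle first-line duration
  is a package choice; the evidence states the mix but not its duration.
- **Death**: palliative/terminal cost applied to the per-cycle increment of
  death occupancy, i.e. once per death. A per-cycle cost on the absorbing
  state would grow without bound, so the "per cycle" label on this item is
  interpreted as per terminal episode.
- **Adverse events**: grade-3+ events enter as a one-time cost and a
  one-time QALY decrement (incidence × disutility × 1 year) at cycle 1.
  Incidences are study inputs; the fixture sets each listed event to 5% in
  both arms, the inclusion floor for the AE list.
- QALYs accumulate occupancy × utility / 12 per cycle; life-years use
  utility 1. No half-cycle correction by default; an optional trapezoid
  correction averages adjacent occupancies.

Cost is linear and homogeneous in the unit costs and strictly increasing in
the drug price, which underwrites the value-based price inversion.

## Uncertainty analysis

One-way analysis re-runs the model with each parameter at its bounds,
all others at base, and sorts by ICER range; failures are recorded per row.
Probabilistic analysis treats each [low, high] as a 95% interval,
`se = (high − low)/3.92` (alternative rule `se = 0.2·base` available), and
moment-matches: Gamma (shape = base²/se², rate = base/se²) for costs, Beta
from mean/se for utilities and disutilities, and a Beta rescaled to
[0, 0.08] with mean 0.05 for the discount rate. Each parameter draws from
its own named substream of the master seed (CRC-32 of the parameter name
spawns the stream), so draws are reproducible, extending the draw count
preserves the prefix, and adding a parameter does not shuffle the others.
Survival-curve uncertainty is deliberately not re-sampled — the PSA varies
economic parameters around fixed fitted curves, a known limitation of this
class of analysis when only digitized curves are available.

CEAC reports the fraction of draws with positive incremental net benefit at
each WTP; EVPI is `E[max_s NMB_s] − max_s E[NMB_s]` per decision, which is
non-negative by Jensen's inequality. CE-plane quadrants are counted under
the explicit convention ΔQALY on x and Δcost on y (NE = costlier and more
effective).

## Scenarios, pricing, subgroups

Scenario transforms are pure (new parameter set, original untouched): a
price multiplier on the intervention drug only, utility overrides (the
stock alternative set is PFS 0.86 / PD 0.77), and a treatment-duration cap
(stock: 24 months, the trial's maximum). Value-based pricing solves
`ICER(price) = λ` by Brent's method on a user bracket (default tolerance
$0.01/cycle); the ICER is strictly increasing in price for a fixed positive
QALY gain, so a bracketed root is unique. The subgroup runner re-executes
the full economics per subgroup from hazard-ratio adjustments
(`S → S^hr`), replacement survival arrays, or parameter overrides;
subgroups with incomplete survival inputs are skipped with a logged reason.

## Synthetic data generator

The generator emulates the evidence chain, not any particular dataset:
ground-truth event times from any of the eight families, independent
exponential dropout plus administrative censoring, and digitization
artefacts (grid sampling, probability rounding, additive jitter re-clamped
and re-monotonized, at-risk readings at fixed intervals). The two-arm
preset uses control OS Weibull(shape 1.2, median 33 months) and control PFS
Weibull(shape 0.85, median 9 months) — limited-stage SCLC scale — with a
proportional-hazards multiplier of 0.73 on the intervention arm (a
plausible immunotherapy effect size used purely as a fixture), 265 patients
per arm, dropout rate 0.005/month and administrative censoring at
38 months. What passing tests show is that the pipeline recovers known
truths under these idealized conditions: real digitized curves add
correlated digitization error, non-proportional hazards and informative
censoring that the generator does not emulate, so numerical agreement on
the preset does not certify accuracy on any real trial.

## Problem sizes and tolerances

Tests use n = 2,000 with ≈20% censoring for parameter recovery (relative
error < 15% per parameter, fixed seeds), n = 300 for the
digitize/reconstruct round trip (max KM discrepancy < 0.02), 1,000 PSA
draws for distributional summaries and 4,000 for the CEAC stability check
(±0.03). The acceptance script runs the whole pipeline at these sizes in a
few seconds.

## Known limitations

- Partitioned survival cannot separate death-from-PFS and death-from-PD;
  the chemotherapy sub-occupancy in PD is therefore an approximation based
  on PFS decline.
- No covariate adjustment, competing risks, cure or spline models, or
  time-varying utilities.
- PSA ignores survival-curve uncertainty (see above).
- The published per-arm net-benefit figures this model class typically
  reports are not always internally consistent with the printed
  costs/QALYs; the package reports identity-checked values only.
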