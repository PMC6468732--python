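# Methods

## Circuit model

The model tracks extracellular 20S proteasome (immuno `p_i`, standard
`p_s`), three osteopontin species (full-length `OPN_F`, thrombin-cleaved
`OPN_N`, `OPN_C`) and six fragment pools — one per (OPN species ×
proteasome isoform) — in serum. Units are nM and hours throughout; assay
values in ng/mL are converted with default molecular masses of 35 kDa
(OPN constructs) and 700 kDa (20S proteasome).

Assumptions worth stating explicitly:

* a single well-mixed serum compartment (no CSF/CNS compartmentalisation);
* proteasome release is shared between isoforms through the fraction
  `x_i` and inhibited by total OPN via `1/(1 + k_i·OPN_tot)`;
* OPN production is split `x_t : (1−x_t)/2 : (1−x_t)/2` across FL/N/C —
  the symmetric N/C split is a modelling choice, since only the FL
  fraction is defined by `x_t`;
* a relapse multiplies the OPN production rate `k_1` by γ with a linear
  two-week ramp, a two-week plateau, and an instantaneous return (the
  step-only variant is available via `ramp_duration = 0`); `x_t` is not
  altered during relapse;
* fragment pools are measured in "parent consumed" units, so in vitro
  substrate + fragment is exactly conserved.

Fixed constants `k_deg = k_deg3 = 2e-4 /h` and `k_1 = 1e-4 nM/h` are
package defaults, overridable on `CircuitParams`.

Integration uses LSODA (`scipy.integrate.solve_ivp`) at `rtol 1e-8`,
`atol 1e-10`, with negative excursions below `atol` clipped to zero. The
step size is capped at min(24 h, shortest schedule segment / 8) so the
solver cannot stride over the relapse window when starting from a steady
state. Steady states are found by `scipy.optimize.root` (hybr) on the
5-dimensional proteasome/OPN system (fragments follow in closed form); a
solution is accepted when the residual is below 1e-12 nM/h — far below
any meaningful drift at these rate scales — and a failed solve falls back
to ODE relaxation over `10/k_deg` hours followed by a second polish.

## Steady-state parameter identification

With both phases treated as (quasi-)steady states:

* `k_i = (p_rel − p_rem)/(p_rem·OPN_rem − p_rel·OPN_rel)`;
* `k_in = p_rem·k_deg·(1 + k_i·OPN_rem)`;
* `k_degX = production_X/OPN_X,rem − Σ_y kcut_X,y·p_y,rem/(KM_X,y + OPN_X,rem)`;
* `γ = OPN_F,rel·(Σ_y kcut_F,y·p_y,rel/(KM_F,y + OPN_F,rel) + k_degF)/(k_1·x_t)`.

Measured totals are apportioned by `x_t` / `x_i` as above. Negative
derived rates are inadmissible and raise (a patient behaving this way is
the "group B" pattern, where relapse OPN falls or proteasome rises).
Uncertainty is propagated by a patient-level bootstrap (resampling
patients with replacement, remission withdrawals averaged first); when
kinetic posterior draws are supplied, each bootstrap replicate is paired
with one, so digestion-kinetics uncertainty flows into the derived
parameters and locally inadmissible pairs are rejected and counted rather
than silently dropped.

## Digestion kinetics inference

In vitro digestion follows `dOPN/dt = −p·kcut·OPN/(KM + OPN)` with
constant enzyme. We use the exact integrated progress curve through the
Wright omega function rather than numerical integration; tests verify it
against `solve_ivp`. The likelihood is Gaussian on relative substrate
remaining with noise SD either fixed or (default) inferred under a
log-uniform prior on [1e-3, 1].

Priors are log-uniform: `kcut ∈ [1e-4, 1e2] /h`, `KM ∈ [10, 1e4] nM`.
The KM floor matters: progress curves from a single substrate
concentration constrain the initial velocity `p·kcut·OPN0/(KM + OPN0)`
tightly but `KM` itself only weakly, and a floor far below plausible
affinities lets prior volume in the fully saturated regime dominate the
posterior, which then extrapolates absurd consumption rates at serum OPN
concentrations four orders of magnitude below `OPN0`. Sub-10-nM Michaelis
constants are not credible for 20S degradation of a disordered substrate.

The sampler is a single-chain random-walk Metropolis–Hastings, authored
here: a Nelder–Mead polish of a first-order heuristic provides the start;
short pilots tune a global step scale toward ~30% acceptance; a second
pilot estimates the posterior covariance, and the production chain uses
multivariate normal proposals scaled by `2.38²/d`. Sampling happens in
`(log initial-rate, log KM, log σ)` coordinates — a unimodular transform
that straightens the kcut–KM ridge so the walk moves along it. Default
chain length is 50,000 with 10,000 burn-in; tests and the acceptance
script use 4,000–12,000 iterations with proportionate burn-in, which the
diagnostics (acceptance rate, cross-seed Kolmogorov–Smirnov distance)
show is sufficient at those problem sizes. Point estimates for
downstream extrapolation use the highest-posterior draw (MAP): on a ridge
the vector of marginal medians is not a parameter set the data support.
The kcut–KM ridge correlation at sparse designs is reported (and
asserted) rather than hidden.

## Chemotactic indices

Without proteasome the stimulus is constant, so
`ci_OPN = (percent − 100)/(OPN0·window)`. With proteasome, `OPN(t)` and
`F(t)` are integrated over the window (digestion starts at t = 0; the
window is [2, 22] h, reconstructed from the 2 h pre-incubation + 20 h
migration protocol and configurable), and
`ci_F = (percent − 100 − ci_OPN·∫OPN)/∫F`, evaluated per posterior
kinetic draw to yield index distributions. The control baseline of 100 is
subtracted so that a no-effect stimulus has index zero. Scenario grids
re-derive the circuit at each `(x_i, x_t)`, simulate a relapse episode
from the remission equilibrium, and compare total (and fragment-only)
chemotaxis at the relapse peak — the maximum inside the relapse window —
against the remission baseline; inadmissible grid cells are flagged, not
fatal. Cell types lacking immunoproteasome assays get standard-only
indices and chemotaxis.

## Severity modelling

MSSS ranks a query EDSS within its integer-year disease-duration bin with
the query included: `MSSS = 10 · midrank / (bin+1 size + 1)`, so an
all-tied bin scores exactly 5.0 and values stay strictly inside (0, 10).
ΔMSSS = MSSS_relapse − MSSS_remission (positive = worse relapse);
MSSS′ = ΔMSSS × MSSS_relapse. Patients are "group A" iff OPN strictly
rises and proteasome strictly falls from remission to relapse (ties are
group B). Each patient is simulated with `x_i = x_t = 0.5`; remission
features equal the measured (split) concentrations by construction, and
relapse features are read at the time of maximum total OPN inside the
relapse window. Group-B patients cannot be derived; they are flagged and
their features taken from measured concentrations with fragments at
quasi-steady state.

The severity model is an ordinary Gaussian linear model (rank-deficient
designs handled by least squares) with seeded k-fold cross-validation,
clamped to leave-one-out when n ≤ k; R² is computed on pooled
out-of-fold predictions (in-sample R² is reported as a secondary output,
since with six patients the distinction is large). Identical fold
assignments are reused across nested feature sets. Group B is never used
for fitting, only for out-of-group prediction. Cohort statistics use
`scipy.stats` (paired Wilcoxon on per-patient phase means of proteasome;
Pearson correlation of OPN vs 1/proteasome over all withdrawals) with a
seeded 1000-resample percentile bootstrap for the correlation CI.

## Synthetic data

The generator defines a self-consistent ground-truth world and emulates
each input table:

* **Serum scales.** `OPN_tot,rem = 0.05 nM`, proteasome `0.15 nM`
  (~105 ng/mL at 700 kDa), `k_i = 2 /nM`, `γ = 3`, `x_i = x_t = 0.5`.
  The published fixed constants are unit-free; combined with nM serum
  scales and in-vitro-calibrated kinetics they force serum OPN below a
  nM, or the derived clearances go negative. The chosen scales keep every
  group-A derivation admissible while preserving the qualitative
  orderings (inverse OPN–proteasome relation, proteasome drop of ~17% in
  relapse, ~3-fold OPN rise).
* **Cohort.** 16 patients, 3 of them group B (phase means swapped,
  marginals matched), 1–4 remission withdrawals each; patient-level
  log-normal effects on OPN production, proteasome release and relapse
  magnitude; within a withdrawal the proteasome level follows the
  release-inhibition relation of that withdrawal's OPN, which produces
  the pooled inverse correlation.
* **Digestion.** `kcut` 0.55–1.2 /h with immuno ≥ standard per substrate;
  `KM` 130–180 nM; enzyme 150 nM, substrate 250 nM, times 0–4 h, Gaussian
  noise SD 0.05, four replicates. The partially saturated design keeps
  both constants identifiable in principle; at five noisy time points the
  kcut–KM ridge is still present, which is why qualitative-ordering tests
  use a denser, lower-noise design.
* **Migration.** Expected percents forward-evaluated from true indices
  and kinetics; Gaussian noise SD 5 points, 8 replicates; control wells
  mean 87, SD 7.9 (n = 17). Immuno conditions are emitted for HUVECs
  only; lymphocytes and monocytes have standard-only assays, with
  monocytes given a higher OPN-FL index.
* **Severity.** Outcomes are linear combinations of the standardized
  proteasome + fragment features (OPN coefficients zero) plus Gaussian
  noise, clipped to admissible score ranges with the clipping fraction
  reported. A separate clinical table (EDSS, durations) exercises the
  MSSS ranking path against a generated reference population.

What passing tests on this world do **not** show: real serum
concentration scales (the cohort's marginals live in the data deposit,
not the text), Western-blot detection effects, fragment identity, any
spatial compartmentalisation, or the real cohort's R² values — those
depend on the patient data and are out of scope.

## Problem sizes

Defaults: bootstrap 1000 draws; MCMC 50,000/10,000; ensemble simulation
200 trajectories on a 400-point grid over 16 weeks; scenario grids 6×6
(11×11 in the grid-monotonicity check). The test suite and acceptance
script run the same machinery at 4,000–12,000 MCMC iterations, 50–100
bootstrap/ensemble draws and 50 synthetic patients for the
severity-recovery analyses; these sizes give stable results for every
quantity checked (coverage, recovery error, determinism) as the tests
themselves demonstrate.

## Known limitations

* The relapse "steady state" used by the γ derivation is a
  quasi-steady-state approximation; with `k_deg = 2e-4 /h` the proteasome
  pool relaxes over ~5,000 h, so a four-week episode never reaches the
  relapse equilibrium and γ derived from mid-relapse measurements
  underestimates the true multiplier (round-trip tests therefore read
  held-forcing equilibria).
* Single-concentration progress curves cannot fully separate `kcut` from
  `KM`; the serum extrapolation inherits that uncertainty, and a
  substantial fraction of kinetic-draw-paired bootstrap replicates can be
  rejected as inadmissible. The rejection fraction is part of the output.
* With six group-A patients the cross-validated R² of a 12-feature model
  is extremely noisy; recovery analyses use 50 synthetic patients.
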