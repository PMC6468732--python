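# opncircuit

Modelling the extracellular proteasome–osteopontin circuit in
relapsing–remitting multiple sclerosis (RRMS).

Serum osteopontin (OPN) — a pro-inflammatory cytokine that exists as
full-length OPN-FL and thrombin-cleaved OPN-N / OPN-C — is degraded in the
extracellular space by circulating 20S proteasomes (standard and
immuno-isoforms), producing fragments with chemotactic activities of their
own. OPN in turn inhibits proteasome release, closing a negative-feedback
loop that shapes the alternation of relapse and remission. `opncircuit`
implements that circuit end to end for researchers in systems biology and
neuroimmunology: ODE simulation of the serum dynamics, closed-form
parameter identification from paired remission/relapse measurements,
Bayesian inference of digestion kinetics, chemotactic-index estimation
from Boyden-chamber assays, and cross-validated linear modelling of
relapse severity. A synthetic-data generator emulates every input table,
so the whole analysis runs without patient data.

## The model

Eleven species (nM, time in hours): proteasome isoforms `p_i`, `p_s`;
OPN species `OPN_F`, `OPN_N`, `OPN_C`; six fragment pools `F_{x,y}`
(substrate × isoform). The core equations:

```
dp_i/dt   = k_in·X_i/(1 + k_i·OPN_tot) − k_deg·p_i          (p_s analogous with 1−X_i)
dOPN_F/dt = g(t)·k_1·X_t − OPN_F·Σ_y kcut_F,y·p_y/(KM_F,y + OPN_F) − k_degF·OPN_F
dF_xy/dt  = p_y·kcut_x,y·OPN_x/(KM_x,y + OPN_x) − k_deg3·F_xy
```

OPN-N and OPN-C are produced at `g(t)·k_1·(1−X_t)/2` each. During a
relapse the forcing `g(t)` ramps linearly from 1 to γ over two weeks,
holds for two weeks, and returns to 1. `X_i` is the immunoproteasome
fraction, `X_t` the OPN-FL fraction of production (inverse thrombin
activity). Fixed constants: `k_deg = k_deg3 = 2e-4 /h`, `k_1 = 1e-4 nM/h`.

Treating remission (and, quasi-statically, relapse) as steady states gives
closed forms for `k_i`, `k_in`, the clearances `k_degF/N/C` and γ from
paired serum measurements. Digestion kinetics `(kcut, KM)` per
(substrate, isoform) are inferred from in vitro time courses by
random-walk Metropolis–Hastings on the integrated Michaelis–Menten
progress curve. Chemotactic indices `ci` (relative migration per nM per
hour) come from solving

```
percent − 100 = ci_OPN·∫ OPN dt + ci_F·∫ F dt     over the 2–22 h window
```

per posterior kinetic draw. Total chemotaxis along a trajectory is
`C_tot(t) = Σ ci_x · x(t)` over the nine chemotactic species. Severity is
scored with the MSSS (EDSS decile-ranked within a disease-duration bin),
ΔMSSS = MSSS_relapse − MSSS_remission and MSSS′ = ΔMSSS · MSSS_relapse,
and regressed on simulated circuit features with a 10-fold
cross-validated Gaussian linear model.

## Worked example

```python
import numpy as np
from opncircuit import GeneratorConfig, equilibrium_state, simulate_circuit
from opncircuit import RelapseSchedule, derive_params

cfg = GeneratorConfig(seed=1)          # the default synthetic world
truth = cfg.true_params()

# forward: relapse equilibrium under the production multiplier gamma = 3
eq_rem = equilibrium_state(truth)
eq_rel = equilibrium_state(truth, forcing=truth.gamma, guess=eq_rem)
print(round(eq_rem.opn_tot, 4), round(eq_rel.opn_tot, 4))   # 0.05 0.1618
print(round(eq_rem.p_i + eq_rem.p_s, 4),
      round(eq_rel.p_i + eq_rel.p_s, 4))                    # 0.15 0.1247

# inverse: re-derive the circuit from those phase readouts
d = derive_params(eq_rem.opn_tot, eq_rem.p_i + eq_rem.p_s,
                  eq_rel.opn_tot, eq_rel.p_i + eq_rel.p_s, cfg.true_kinetics())
print(round(d.k_i, 3), round(d.gamma, 3))                   # 2.0 2.991
```

Serum OPN rises ~3.2-fold into relapse while total proteasome drops ~17%
(the feedback at work), and the closed-form inversion recovers the
generating `k_i = 2 /nM` and `γ = 3` to well under 1%.

The command-line pipeline runs every stage and writes tidy CSVs plus a
checksummed manifest:

```
opncircuit run-all --seed 1 --outdir run1
```

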