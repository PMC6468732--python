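"""Synthetic data emulating every input stream the pipeline consumes.

The generator produces a self-consistent world: a ground-truth circuit
(remission steady state + relapse equilibrium under the production
multiplier gamma), in vitro digestion curves drawn from the true
Michaelis-Menten kinetics, Boyden-chamber readouts forward-generated from
true chemotactic indices, a normative EDSS reference population, and
severity outcomes linearly planted on the circuit features.

Built-in qualitative structure mirrors the biology being modelled:

* serum OPN and extracellular proteasome are inversely related through the
  release-inhibition steady state p = k_in / (k_deg (1 + k_i OPN));
* the immunoproteasome degrades every OPN species at least as fast as the
  standard proteasome (kcut_immuno >= kcut_standard);
* fragment indices exceed the parent index for OPN-FL and OPN-C and are
  higher for immunoproteasome-generated fragments, while intact OPN-N is
  more chemotactic than its fragments;
* a configurable fraction of patients shows the inverted ("group B") phase
  ordering, with marginal distributions matched to group A.

Concentration scales are an internally consistent choice, not cohort
estimates: serum levels sit at the fraction of a nM that keeps the
fixed production/clearance constants (k_1 = 1e-4 nM/h, k_deg = 2e-4 /h)
compatible with the in-vitro-calibrated degradation kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import units
from .kinetics import ISOFORMS, SUBSTRATES, KineticParamSet, simulate_digestion
from .chemotaxis import DEFAULT_WINDOW, substrate_fragment_exposure
from .model import CircuitParams, equilibrium_state
from .steady_state import derive_kin, derive_opn_clearance, split_measurements

TRUE_KCUT = {("FL", "standard"): 0.60, ("N", "standard"): 0.80,
             ("C", "standard"): 0.55, ("FL", "immuno"): 1.20,
             ("N", "immuno"): 0.90, ("C", "immuno"): 1.10}
TRUE_KM = {("FL", "standard"): 180.0, ("N", "standard"): 160.0,
           ("C", "standard"): 170.0, ("FL", "immuno"): 140.0,
           ("N", "immuno"): 165.0, ("C", "immuno"): 130.0}

TRUE_CI = {
    "HUVEC": {
        "opn": {"FL": 0.15, "N": 0.40, "C": 0.15},
        "frag": {("FL", "standard"): 0.30, ("FL", "immuno"): 0.55,
                 ("N", "standard"): 0.20, ("N", "immuno"): 0.25,
                 ("C", "standard"): 0.28, ("C", "immuno"): 0.50},
    },
    "lymphocyte": {
        "opn": {"FL": 0.12, "N": 0.35, "C": 0.13},
        "frag": {("FL", "standard"): 0.25, ("FL", "immuno"): 0.48,
                 ("N", "standard"): 0.18, ("N", "immuno"): 0.22,
                 ("C", "standard"): 0.24, ("C", "immuno"): 0.45},
    },
    "monocyte": {
        "opn": {"FL": 0.30, "N": 0.38, "C": 0.15},
        "frag": {("FL", "standard"): 0.42, ("FL", "immuno"): 0.60,
                 ("N", "standard"): 0.17, ("N", "immuno"): 0.21,
                 ("C", "standard"): 0.26, ("C", "immuno"): 0.47},
    },
}

# coefficients planting the severity signal on proteasome + fragment
# features (standardized), leaving OPN features silent
TRUE_SEVERITY_COEF = {"prot_rem": -0.8, "prot_rel": -0.6,
                      "frag_s_rem": 0.5, "frag_s_rel": 0.7,
                      "frag_i_rem": 0.6, "frag_i_rel": 0.9}


@dataclass
class GeneratorConfig:
    seed: int = 0
    # cohort
    n_patients: int = 16
    group_b_fraction: float = 3.0 / 16.0
    opn_rem_nm: float = 0.05        # serum total OPN in remission, nM
    prot_rem_nm: float = 0.15       # serum proteasome in remission, nM
    k_i: float = 2.0                # 1/nM
    gamma: float = 3.0
    x_i: float = 0.5
    x_t: float = 0.5
    k_deg: float = 2e-4
    k_1: float = 1e-4
    k_deg3: float = 2e-4
    cohort_noise_sd: float = 0.10    # log-scale, OPN withdrawals
    prot_noise_sd: float = 0.08      # log-scale, proteasome given OPN
    opn_effect_sd: float = 0.25      # log-scale patient effect on k_1
    prot_effect_sd: float = 0.20     # log-scale patient effect on k_in
    gamma_effect_sd: float = 0.20    # log-scale patient effect on gamma
    min_withdrawals: int = 1
    max_withdrawals: int = 4
    # in vitro digestion
    digestion_times: tuple = (0.0, 0.5, 1.0, 2.0, 4.0)
    digestion_noise_sd: float = 0.05
    digestion_replicates: int = 4
    p_vitro_nm: float = 150.0
    opn0_vitro_nm: float = 250.0
    # migration
    migration_noise_sd: float = 5.0   # percent points
    migration_replicates: int = 8
    control_mean: float = 87.0
    control_sd: float = 7.9
    n_control: int = 17
    stimulus_nm: float = 10.0
    window: tuple = DEFAULT_WINDOW
    immuno_cell_types: tuple = ("HUVEC",)   # cell types with immuno assays
    # MSSS reference
    reference_max_duration: int = 30
    reference_bin_size: int = 30
    # severity
    severity_noise_sd: float = 0.15
    severity_coef: dict = field(default_factory=lambda: dict(TRUE_SEVERITY_COEF))

    def true_kinetics(self) -> KineticParamSet:
        return KineticParamSet(kcut=dict(TRUE_KCUT), km=dict(TRUE_KM))

    def true_params(self) -> CircuitParams:
        """Ground-truth circuit, self-consistent with the remission levels."""
        kin = self.true_kinetics()
        k_in = derive_kin(self.prot_rem_nm, self.opn_rem_nm, self.k_i, self.k_deg)
        opn_rem, p_i, p_s = split_measurements(
            self.opn_rem_nm, self.prot_rem_nm, self.x_i, self.x_t)
        clear = derive_opn_clearance(self.k_1, self.x_t, opn_rem, p_i, p_s, kin)
        return CircuitParams(
            k_in=k_in, k_i=self.k_i, gamma=self.gamma,
            k_deg_f=clear["FL"], k_deg_n=clear["N"], k_deg_c=clear["C"],
            x_i=self.x_i, x_t=self.x_t, kinetics=kin,
            k_deg=self.k_deg, k_1=self.k_1, k_deg3=self.k_deg3)

    def relapse_levels(self) -> tuple[float, float]:
        """(opn_tot, prot) at the relapse equilibrium under gamma."""
        eq = equilibrium_state(self.true_params(), forcing=self.gamma)
        return eq.opn_tot, eq.p_i + eq.p_s


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Cohort table (external units ng/mL) with 1-4 remission withdrawals.

    Patients differ by log-normal effects on OPN production (k_1),
    proteasome release (k_in) and relapse magnitude (gamma); their phase
    means are the corresponding circuit equilibria.  Within a withdrawal,
    the proteasome level follows the release-inhibition relation
    p = k_in / (k_deg (1 + k_i OPN)) of that withdrawal's OPN, so pooling
    all samples reproduces the inverse OPN-proteasome relation.
    Group-B patients have their OPN phase means swapped (inverted phase
    ordering, matched marginal distributions).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base = cfg.true_params()
    n_b = int(round(cfg.group_b_fraction * cfg.n_patients))
    rows = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:03d}"
        is_b = p < n_b
        k1_p = base.k_1 * float(np.exp(rng.normal(0.0, cfg.opn_effect_sd)))
        kin_p = base.k_in * float(np.exp(rng.normal(0.0, cfg.prot_effect_sd)))
        gamma_p = max(1.0 + 1e-9, cfg.gamma
                      * float(np.exp(rng.normal(0.0, cfg.gamma_effect_sd))))
        params_p = base.with_updates(k_1=k1_p, k_in=kin_p, gamma=gamma_p)
        eq_rem = equilibrium_state(params_p)
        eq_rel = equilibrium_state(params_p, forcing=gamma_p, guess=eq_rem)
        mean_rem, mean_rel = eq_rem.opn_tot, eq_rel.opn_tot
        if is_b:
            mean_rem, mean_rel = mean_rel, mean_rem

        def emit(phase, withdrawal, months, mean_opn):
            opn = mean_opn * float(np.exp(rng.normal(0.0, cfg.cohort_noise_sd)))
            prot = (kin_p / (cfg.k_deg * (1.0 + cfg.k_i * opn))
                    * float(np.exp(rng.normal(0.0, cfg.prot_noise_sd))))
            rows.append({"patient_id": pid, "phase": phase,
                         "withdrawal": withdrawal,
                         "months_from_relapse": months,
                         "opn_ng_ml": units.nm_to_ng_ml(opn, units.OPN_KDA),
                         "proteasome_ng_ml":
                             units.nm_to_ng_ml(prot, units.PROTEASOME_KDA)})

        n_wd = int(rng.integers(cfg.min_withdrawals, cfg.max_withdrawals + 1))
        for w in range(n_wd):
            emit("remission", w + 1, float(1 + 7 * rng.random()), mean_rem)
        emit("relapse", 1, 0.0, mean_rel)
    return pd.DataFrame(rows)


def generate_digestion(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Six digestion time courses (relative substrate remaining)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    kin = cfg.true_kinetics()
    times = np.asarray(cfg.digestion_times, dtype=float)
    rows = []
    for s in SUBSTRATES:
        for iso in ISOFORMS:
            kcut, km = kin.entry(s, iso)
            opn, _ = simulate_digestion(kcut, km, cfg.p_vitro_nm,
                                        cfg.opn0_vitro_nm, times)
            rel = opn / cfg.opn0_vitro_nm
            for r in range(cfg.digestion_replicates):
                noisy = np.clip(
                    rel + rng.normal(0.0, cfg.digestion_noise_sd, rel.size),
                    0.0, None)
                for t, v in zip(times, noisy):
                    rows.append({"substrate": s, "isoform": iso,
                                 "time_h": t, "replicate": r + 1,
                                 "relative_remaining": v,
                                 "proteasome_nM": cfg.p_vitro_nm,
                                 "opn0_nM": cfg.opn0_vitro_nm})
    return pd.DataFrame(rows)


def expected_percent(cfg: GeneratorConfig, cell_type: str, substrate: str,
                     isoform: str) -> float:
    """Noise-free percent-of-control for one assay condition."""
    ci = TRUE_CI[cell_type]
    t0, t1 = cfg.window
    if isoform == "none":
        return 100.0 + ci["opn"][substrate] * cfg.stimulus_nm * (t1 - t0)
    kcut, km = cfg.true_kinetics().entry(substrate, isoform)
    opn_int, frag_int = substrate_fragment_exposure(
        kcut, km, cfg.p_vitro_nm, cfg.stimulus_nm, cfg.window)
    return (100.0 + ci["opn"][substrate] * opn_int
            + ci["frag"][(substrate, isoform)] * frag_int)


def generate_migration(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Boyden-chamber readouts per (cell type, substrate, isoform)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    rows = []
    for ct in TRUE_CI:
        isoforms = ("none", "standard", "immuno") \
            if ct in cfg.immuno_cell_types else ("none", "standard")
        controls = rng.normal(cfg.control_mean, cfg.control_sd, cfg.n_control)
        for k, c in enumerate(controls):
            rows.append({"cell_type": ct, "substrate": "control",
                         "isoform": "none", "replicate": k + 1,
                         "percent_of_control": 100.0 * c / cfg.control_mean,
                         "stimulus_nM": 0.0, "proteasome_nM": 0.0})
        for s in SUBSTRATES:
            for iso in isoforms:
                mu = expected_percent(cfg, ct, s, iso)
                p_conc = 0.0 if iso == "none" else cfg.p_vitro_nm
                for r in range(cfg.migration_replicates):
                    val = max(mu + rng.normal(0.0, cfg.migration_noise_sd), 0.0)
                    rows.append({"cell_type": ct, "substrate": s,
                                 "isoform": iso, "replicate": r + 1,
                                 "percent_of_control": val,
                                 "stimulus_nM": cfg.stimulus_nm,
                                 "proteasome_nM": p_conc})
    return pd.DataFrame(rows)


def generate_msss_reference(cfg: GeneratorConfig,
                            seed: int | None = None) -> pd.DataFrame:
    """Normative (duration, EDSS) table; median EDSS increases with duration."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 3)
    rows = []
    for year in range(1, cfg.reference_max_duration + 1):
        raw = rng.normal(1.0 + 0.18 * year, 1.8, cfg.reference_bin_size)
        edss = np.clip(np.round(raw * 2.0) / 2.0, 0.0, 10.0)
        for e in edss:
            rows.append({"duration_years": year, "edss": e})
    return pd.DataFrame(rows)


def generate_clinical(cfg: GeneratorConfig, cohort: pd.DataFrame,
                      seed: int | None = None) -> pd.DataFrame:
    """EDSS/duration table for the cohort's patients (both phases)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 4)
    rows = []
    for pid in cohort["patient_id"].unique():
        dur_rel = float(rng.uniform(2.0, cfg.reference_max_duration - 2.0))
        e_rem = float(np.clip(np.round(rng.normal(2.5, 1.5) * 2) / 2, 0.0, 9.0))
        e_rel = float(np.clip(e_rem + np.round(rng.uniform(0.0, 4.0) * 2) / 2,
                              0.0, 10.0))
        rows.append({"patient_id": pid, "phase": "relapse",
                     "edss": e_rel, "duration_years": dur_rel})
        rows.append({"patient_id": pid, "phase": "remission",
                     "edss": e_rem, "duration_years": dur_rel + 0.25})
    return pd.DataFrame(rows)


def generate_severity(features: pd.DataFrame, cfg: GeneratorConfig,
                      seed: int | None = None) -> tuple[pd.DataFrame, float]:
    """Outcomes linearly planted on (standardized) circuit features.

    Returns the severity table and the fraction of clipped values.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 5)
    z = np.zeros(len(features))
    for name, coef in cfg.severity_coef.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            z += coef * (col - col.mean()) / sd
    zsd = z.std() if z.std() > 0 else 1.0
    z = z / zsd

    def noisy(scale, loc, lo, hi):
        raw = loc + scale * z + rng.normal(0.0, cfg.severity_noise_sd * abs(scale),
                                           z.size)
        return np.clip(raw, lo, hi), raw

    msss, raw1 = noisy(1.5, 5.0, 0.0, 10.0)
    delta, raw2 = noisy(1.2, 1.5, -10.0, 10.0)
    prime, raw3 = noisy(3.0, 7.0, -100.0, 100.0)
    clipped = float(np.mean([(msss != raw1).mean(), (delta != raw2).mean(),
                             (prime != raw3).mean()]))
    table = pd.DataFrame({"patient_id": features.index,
                          "msss_relapse": msss,
                          "delta_msss": delta,
                          "msss_prime": prime})
    return table, clipped


def truth_dict(cfg: GeneratorConfig) -> dict:
    """All ground-truth values, for truth.yaml."""
    params = cfg.true_params()
    opn_rel, prot_rel = cfg.relapse_levels()
    d = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "circuit_params": {
            "k_in": params.k_in, "k_i": params.k_i, "gamma": params.gamma,
            "k_deg_f": params.k_deg_f, "k_deg_n": params.k_deg_n,
            "k_deg_c": params.k_deg_c, "k_deg": params.k_deg,
            "k_1": params.k_1, "k_deg3": params.k_deg3,
            "x_i": params.x_i, "x_t": params.x_t},
        "kinetics": cfg.true_kinetics().to_dict(),
        "relapse_levels": {"opn_tot_nm": opn_rel, "prot_nm": prot_rel},
        "chemotactic_indices": {
            ct: {"opn": dict(v["opn"]),
                 "frag": {f"{s}_{i}": x for (s, i), x in v["frag"].items()}}
            for ct, v in TRUE_CI.items()},
    }
    return d
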