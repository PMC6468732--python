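"""Closed-form circuit parameters from remission/relapse serum measurements.

Assuming both disease phases sit at (quasi-)steady state, the cohort means
of serum OPN and extracellular proteasome pin down, in order:

* ``k_i``   — OPN-mediated inhibition of proteasome release, from the
  phase difference of proteasome levels;
* ``k_in``  — proteasome release rate, from the remission balance;
* ``k_deg_f/n/c`` — non-proteasomal OPN clearances, from the remission OPN
  balances given the Michaelis-Menten consumption by both isoforms;
* ``gamma`` — the relapse production multiplier, from the relapse OPN-FL
  balance.

Measured totals are apportioned to species by the assumed fractions:
OPN_tot -> (x_t, (1-x_t)/2, (1-x_t)/2) across FL/N/C and the proteasome
measurement -> (x_i, 1-x_i) across immuno/standard.

Uncertainty is propagated by bootstrap: patients are resampled with
replacement (the patient, not the withdrawal, is the resampling unit),
phase means recomputed, and the derivation repeated per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateMeasurementError, InadmissibleParameterError,
                     UndefinedGammaError)
from .kinetics import SUBSTRATES, KineticParamSet
from .model import CircuitParams

COHORT_COLUMNS = ("patient_id", "phase", "withdrawal",
                  "months_from_relapse", "opn_nm", "prot_nm")


def split_measurements(opn_tot: float, prot: float, x_i: float, x_t: float):
    """Apportion measured totals to model species."""
    opn = {"FL": opn_tot * x_t,
           "N": opn_tot * (1.0 - x_t) / 2.0,
           "C": opn_tot * (1.0 - x_t) / 2.0}
    return opn, prot * x_i, prot * (1.0 - x_i)


def derive_ki(p_rem, p_rel, opn_rem, opn_rel) -> float:
    """k_i = (p_rel - p_rem) / (p_rem*opn_rem - p_rel*opn_rel)."""
    if min(p_rem, p_rel, opn_rem, opn_rel) <= 0:
        raise ValueError("all measurements must be positive")
    denom = p_rem * opn_rem - p_rel * opn_rel
    if denom == 0.0:
        raise DegenerateMeasurementError("k_i denominator is zero")
    k_i = (p_rel - p_rem) / denom
    if k_i < 0:
        raise InadmissibleParameterError(
            f"derived k_i = {k_i:.4g} < 0: phase ordering inconsistent "
            "with OPN-mediated release inhibition (group-B pattern)")
    return k_i


def derive_kin(p_rem, opn_rem, k_i, k_deg) -> float:
    """k_in = p_rem * k_deg * (1 + k_i * OPN_tot,rem)."""
    if min(p_rem, opn_rem, k_i, k_deg) < 0:
        raise ValueError("inputs must be non-negative")
    return p_rem * k_deg * (1.0 + k_i * opn_rem)


def _consumption_per_opn(substrate, opn_level, p_i, p_s,
                         kinetics: KineticParamSet) -> float:
    """Proteasomal consumption rate per unit OPN at the given levels (1/h)."""
    kcut_i, km_i = kinetics.entry(substrate, "immuno")
    kcut_s, km_s = kinetics.entry(substrate, "standard")
    return (kcut_i * p_i / (km_i + opn_level)
            + kcut_s * p_s / (km_s + opn_level))


def derive_opn_clearance(k_1, x_t, opn_rem: dict, p_i_rem, p_s_rem,
                         kinetics: KineticParamSet) -> dict:
    """Non-proteasomal clearance per species from the remission balance.

    k_deg_X = production_X / OPN_X,rem - proteasomal consumption per unit.
    Species with zero production and zero remission level are skipped.
    """
    production = {"FL": k_1 * x_t,
                  "N": k_1 * (1.0 - x_t) / 2.0,
                  "C": k_1 * (1.0 - x_t) / 2.0}
    out = {}
    for s in SUBSTRATES:
        level = opn_rem[s]
        if level <= 0:
            if production[s] > 0:
                raise ValueError(f"remission level for {s} must be positive")
            continue
        if production[s] <= 0:
            raise InadmissibleParameterError(
                f"{s}: nonzero remission level with zero production")
        k = production[s] / level - _consumption_per_opn(
            s, level, p_i_rem, p_s_rem, kinetics)
        if k < 0:
            raise InadmissibleParameterError(
                f"{s}: production below proteasomal consumption "
                f"(derived clearance {k:.4g} < 0)")
        out[s] = k
    return out


def derive_gamma(opn_rel: dict, p_i_rel, p_s_rel, k_1, x_t,
                 kinetics: KineticParamSet, clearances: dict) -> float:
    """Relapse multiplier from the quasi-steady-state OPN-FL balance."""
    if x_t == 0:
        raise UndefinedGammaError("gamma undefined when x_t = 0")
    level = opn_rel["FL"]
    gamma = level * (_consumption_per_opn("FL", level, p_i_rel, p_s_rel, kinetics)
                     + clearances["FL"]) / (k_1 * x_t)
    if gamma < 1.0 - 1e-12:
        raise InadmissibleParameterError(
            f"derived gamma = {gamma:.4g} < 1: relapse production below "
            "remission production")
    return max(gamma, 1.0)


def derive_params(opn_rem_tot, prot_rem, opn_rel_tot, prot_rel,
                  kinetics: KineticParamSet, x_i=0.5, x_t=0.5,
                  k_deg=2e-4, k_1=1e-4, k_deg3=2e-4) -> CircuitParams:
    """Full closed-form derivation from phase-mean measurements (nM)."""
    k_i = derive_ki(prot_rem, prot_rel, opn_rem_tot, opn_rel_tot)
    k_in = derive_kin(prot_rem, opn_rem_tot, k_i, k_deg)
    opn_rem, p_i_rem, p_s_rem = split_measurements(opn_rem_tot, prot_rem, x_i, x_t)
    opn_rel, p_i_rel, p_s_rel = split_measurements(opn_rel_tot, prot_rel, x_i, x_t)
    clear = derive_opn_clearance(k_1, x_t, opn_rem, p_i_rem, p_s_rem, kinetics)
    gamma = derive_gamma(opn_rel, p_i_rel, p_s_rel, k_1, x_t, kinetics, clear)
    return CircuitParams(
        k_in=k_in, k_i=k_i, gamma=gamma,
        k_deg_f=clear.get("FL", 0.0), k_deg_n=clear.get("N", 0.0),
        k_deg_c=clear.get("C", 0.0),
        x_i=x_i, x_t=x_t, kinetics=kinetics,
        k_deg=k_deg, k_1=k_1, k_deg3=k_deg3)


def patient_phase_means(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, phase) mean concentrations; repeated remission
    withdrawals are averaged before any derivation."""
    return (cohort.groupby(["patient_id", "phase"], as_index=False)
            [["opn_nm", "prot_nm"]].mean())


@dataclass
class ParamEnsemble:
    """Bootstrap draws of circuit parameters with rejection bookkeeping."""

    draws: list = field(default_factory=list)        # CircuitParams
    provenance: list = field(default_factory=list)   # patient ids per draw
    rejected: list = field(default_factory=list)     # (draw index, reason)
    seed: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, p in enumerate(self.draws):
            rows.append({"draw": k, "k_in": p.k_in, "k_i": p.k_i,
                         "gamma": p.gamma, "k_deg_f": p.k_deg_f,
                         "k_deg_n": p.k_deg_n, "k_deg_c": p.k_deg_c,
                         "x_i": p.x_i, "x_t": p.x_t})
        return pd.DataFrame(rows)


def sample_parameter_distributions(cohort: pd.DataFrame,
                                   kinetics: KineticParamSet,
                                   n_draws: int = 1000, seed: int = 0,
                                   x_i: float = 0.5, x_t: float = 0.5,
                                   k_deg: float = 2e-4, k_1: float = 1e-4,
                                   k_deg3: float = 2e-4,
                                   kinetic_draws=None) -> ParamEnsemble:
    """Patient-level bootstrap of the closed-form derivations.

    When ``kinetic_draws`` (a sequence of KineticParamSet posterior draws)
    is given, each bootstrap replicate is paired with one of them in turn,
    propagating digestion-kinetics uncertainty into the derived parameters;
    otherwise the single ``kinetics`` point estimate is used throughout.
    """
    means = patient_phase_means(cohort)
    wide = means.pivot(index="patient_id", columns="phase",
                       values=["opn_nm", "prot_nm"]).dropna()
    patients = wide.index.to_numpy()
    if len(patients) < 2:
        raise ValueError("need >= 2 patients with both phases")
    rng = np.random.default_rng(seed)
    ens = ParamEnsemble(seed=seed)
    for k in range(n_draws):
        pick = rng.choice(patients, size=len(patients), replace=True)
        sub = wide.loc[pick]
        kin_k = (kinetic_draws[k % len(kinetic_draws)]
                 if kinetic_draws else kinetics)
        try:
            params = derive_params(
                sub[("opn_nm", "remission")].mean(),
                sub[("prot_nm", "remission")].mean(),
                sub[("opn_nm", "relapse")].mean(),
                sub[("prot_nm", "relapse")].mean(),
                kin_k, x_i=x_i, x_t=x_t,
                k_deg=k_deg, k_1=k_1, k_deg3=k_deg3)
        except (InadmissibleParameterError, DegenerateMeasurementError) as e:
            ens.rejected.append((k, str(e)))
            continue
        ens.draws.append(params)
        ens.provenance.append(list(pick))
    if not ens.draws:
        raise InadmissibleParameterError("every bootstrap draw was inadmissible")
    return ens
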