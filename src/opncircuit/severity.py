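"""MSSS severity scores, patient simulation, and the cross-validated
linear severity model.

The Multiple Sclerosis Severity Score (MSSS) ranks a patient's EDSS
against a normative population with the same (integer-year) disease
duration: the query is added to the duration bin, the average of its
lowest and highest rank (mid-rank under ties) is divided by
(augmented bin size + 1) and multiplied by 10, giving a value in (0, 10).

Relapse-worsening indices: dMSSS = MSSS_relapse - MSSS_remission (the
printed sign convention -(rem - rel)), and MSSS' = dMSSS * MSSS_relapse.

Each patient's circuit is derived from their own serum measurements
(assuming 50/50 isoform and OPN-FL splits), simulated through a relapse
episode, and the resulting per-phase concentrations feed a Gaussian linear
model of severity fitted with k-fold cross-validation; R^2 is computed on
pooled out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .errors import (InadmissibleParameterError, MissingReferenceError,
                     UndefinedR2Error)
from .kinetics import SUBSTRATES, KineticParamSet
from .model import RelapseSchedule, equilibrium_state, simulate_circuit
from .steady_state import derive_params, patient_phase_means

# the 12-feature set the best model uses: 6 quantities x 2 phases
BASE_QUANTITIES = ("opn_f", "opn_n", "opn_c", "prot", "frag_s", "frag_i")
PHASES = ("rem", "rel")

FEATURE_SETS = {
    "opn_only": [f"{q}_{ph}" for q in ("opn_f", "opn_n", "opn_c")
                 for ph in PHASES],
    "prot_frag": [f"{q}_{ph}" for q in ("prot", "frag_s", "frag_i")
                  for ph in PHASES],
    "opn_prot_frag": [f"{q}_{ph}" for q in BASE_QUANTITIES for ph in PHASES],
    "plus_chemotaxis": [f"{q}_{ph}" for q in BASE_QUANTITIES for ph in PHASES]
    + ["ctot_rem", "ctot_rel"],
    "isoform_resolved": [f"{q}_{ph}" for q in
                         ("opn_f", "opn_n", "opn_c", "p_i", "p_s",
                          "f_if", "f_in", "f_ic", "f_sf", "f_sn", "f_sc")
                         for ph in PHASES],
}


# ---------------------------------------------------------------------------
# MSSS

@dataclass
class MSSSReference:
    """Normative (disease duration, EDSS) assessments, binned by whole years."""

    table: pd.DataFrame  # columns: duration_years, edss

    def bin_values(self, duration_years: float) -> np.ndarray:
        year = int(np.floor(duration_years))
        vals = self.table.loc[
            self.table["duration_years"].astype(int) == year, "edss"
        ].to_numpy(dtype=float)
        if vals.size == 0:
            raise MissingReferenceError(
                f"no reference assessments for duration year {year}")
        return vals


def compute_msss(reference: MSSSReference, duration_years: float,
                 edss: float) -> float:
    """Decile-rank EDSS against the duration bin (query included).

    MSSS = 10 * mid-rank(query) / (augmented bin size + 1).
    """
    bin_vals = reference.bin_values(duration_years)
    aug = np.append(bin_vals, edss)
    lowest = np.sum(aug < edss) + 1
    highest = np.sum(aug <= edss)
    return 10.0 * (lowest + highest) / 2.0 / (aug.size + 1)


def severity_indices(msss_relapse: float, msss_remission: float):
    """(dMSSS, MSSS') from the two phase scores."""
    delta = msss_relapse - msss_remission
    return delta, delta * msss_relapse


def severity_table(clinical: pd.DataFrame,
                   reference: MSSSReference) -> pd.DataFrame:
    """Per-patient MSSS at both phases plus dMSSS and MSSS'.

    ``clinical`` columns: patient_id, phase, edss, duration_years.
    """
    rows = []
    for pid, grp in clinical.groupby("patient_id"):
        rec = {"patient_id": pid}
        for phase, key in (("relapse", "msss_relapse"),
                           ("remission", "msss_remission")):
            sel = grp[grp["phase"] == phase]
            if sel.empty:
                raise ValueError(f"patient {pid}: missing {phase} assessment")
            rec[key] = compute_msss(reference,
                                    float(sel["duration_years"].iloc[0]),
                                    float(sel["edss"].iloc[0]))
        rec["delta_msss"], rec["msss_prime"] = severity_indices(
            rec["msss_relapse"], rec["msss_remission"])
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient classification and simulation

def classify_patient_group(patient_records: pd.DataFrame) -> str:
    """'A' iff OPN rises and proteasome falls from remission to relapse
    (strict inequalities; remission withdrawals averaged)."""
    means = patient_records.groupby("phase")[["opn_nm", "prot_nm"]].mean()
    if not {"remission", "relapse"}.issubset(means.index):
        raise ValueError("patient needs both remission and relapse records")
    rem, rel = means.loc["remission"], means.loc["relapse"]
    if rel["opn_nm"] > rem["opn_nm"] and rel["prot_nm"] < rem["prot_nm"]:
        return "A"
    return "B"


def _quasi_steady_fragments(opn: dict, p_i: float, p_s: float,
                            kinetics: KineticParamSet, k_deg3: float) -> dict:
    out = {}
    for s in SUBSTRATES:
        for iso, p in (("immuno", p_i), ("standard", p_s)):
            kcut, km = kinetics.entry(s, iso)
            out[(s, iso)] = p * kcut * opn[s] / (km + opn[s]) / k_deg3
    return out


def _features_from_state(vec, ci_map=None, prefix="rem") -> dict:
    names = ("p_i", "p_s", "opn_f", "opn_n", "opn_c",
             "f_if", "f_in", "f_ic", "f_sf", "f_sn", "f_sc")
    d = {f"{n}_{prefix}": float(v) for n, v in zip(names, vec)}
    d[f"prot_{prefix}"] = d[f"p_i_{prefix}"] + d[f"p_s_{prefix}"]
    d[f"frag_i_{prefix}"] = sum(d[f"f_i{x}_{prefix}"] for x in "fnc")
    d[f"frag_s_{prefix}"] = sum(d[f"f_s{x}_{prefix}"] for x in "fnc")
    if ci_map is not None:
        d[f"ctot_{prefix}"] = float(sum(ci_map.get(n, 0.0) * v
                                        for n, v in zip(names, vec)))
    return d


def simulate_patient(patient_records: pd.DataFrame,
                     kinetics: KineticParamSet,
                     schedule: RelapseSchedule | None = None,
                     x_i: float = 0.5, x_t: float = 0.5,
                     ci_map: dict | None = None,
                     n_t: int = 400) -> dict:
    """Per-patient circuit features at remission baseline and relapse peak.

    Group-A patients get a full derivation + simulation; patients whose
    measurements do not support the derivation are flagged and their
    features are read off the measured concentrations, with fragments at
    quasi-steady state.  Returns a flat feature dict including ``group``
    and ``derivable``.
    """
    from .steady_state import split_measurements

    schedule = schedule or RelapseSchedule()
    group = classify_patient_group(patient_records)
    means = patient_records.groupby("phase")[["opn_nm", "prot_nm"]].mean()
    rem, rel = means.loc["remission"], means.loc["relapse"]

    features = {"group": group}
    try:
        params = derive_params(rem["opn_nm"], rem["prot_nm"],
                               rel["opn_nm"], rel["prot_nm"],
                               kinetics, x_i=x_i, x_t=x_t)
        init = equilibrium_state(params)
        t_grid = np.linspace(0.0, schedule.total_span, n_t)
        traj = simulate_circuit(params, init, schedule, t_grid)
        features["derivable"] = True
        features.update(_features_from_state(init.to_array(), ci_map, "rem"))
        window = (t_grid >= schedule.onset_time) & (t_grid <= schedule.end_time)
        peak = int(np.argmax(np.where(window, traj.opn_tot, -np.inf)))
        features.update(_features_from_state(traj.states[peak], ci_map, "rel"))
        features["_trajectory"] = traj
    except InadmissibleParameterError as e:
        features["derivable"] = False
        features["derivation_error"] = str(e)
        for phase, row in (("rem", rem), ("rel", rel)):
            opn, p_i, p_s = split_measurements(
                row["opn_nm"], row["prot_nm"], x_i, x_t)
            frag = _quasi_steady_fragments(opn, p_i, p_s, kinetics, 2e-4)
            vec = [p_i, p_s, opn["FL"], opn["N"], opn["C"],
                   frag[("FL", "immuno")], frag[("N", "immuno")],
                   frag[("C", "immuno")], frag[("FL", "standard")],
                   frag[("N", "standard")], frag[("C", "standard")]]
            features.update(_features_from_state(vec, ci_map, phase))
    return features


def simulate_cohort_patients(cohort: pd.DataFrame,
                             kinetics: KineticParamSet,
                             schedule: RelapseSchedule | None = None,
                             x_i: float = 0.5, x_t: float = 0.5,
                             ci_map: dict | None = None) -> pd.DataFrame:
    """Feature table: one row per patient with both phases measured."""
    rows = []
    for pid, grp in cohort.groupby("patient_id"):
        if set(grp["phase"]) < {"remission", "relapse"}:
            continue
        feats = simulate_patient(grp, kinetics, schedule, x_i, x_t, ci_map)
        feats.pop("_trajectory", None)
        feats["patient_id"] = pid
        rows.append(feats)
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# cross-validated linear severity model

@dataclass
class SeverityModelFit:
    outcome: str
    feature_names: list
    coefficients: pd.Series
    intercept: float
    cv_r2: float
    in_sample_r2: float
    folds: list = field(default_factory=list)
    model: LinearRegression | None = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"feature mismatch: missing {missing}")
        return self.model.predict(features[self.feature_names].to_numpy())


def make_folds(n: int, k_folds: int = 10, seed: int = 0) -> list:
    """Seeded fold assignment, clamped to leave-one-out for tiny n."""
    k = min(k_folds, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def _r2(y, yhat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedR2Error("outcome is constant")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_severity_glm(features: pd.DataFrame, outcome: pd.Series,
                     feature_names=None, k_folds: int = 10,
                     seed: int = 0, folds=None,
                     outcome_name: str = "severity") -> SeverityModelFit:
    """Gaussian linear model with k-fold CV; R^2 on pooled out-of-fold
    predictions (in-sample R^2 reported as a secondary output)."""
    if len(features) < 3:
        raise ValueError("need at least 3 patients")
    feature_names = list(feature_names or features.columns)
    X = features[feature_names].to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.var(y) == 0:
        raise UndefinedR2Error("outcome is constant")
    folds = folds or make_folds(len(y), k_folds, seed)
    y_oof = np.empty_like(y)
    for tr, te in folds:
        reg = LinearRegression().fit(X[tr], y[tr])
        y_oof[te] = reg.predict(X[te])
    full = LinearRegression().fit(X, y)
    return SeverityModelFit(
        outcome=outcome_name, feature_names=feature_names,
        coefficients=pd.Series(full.coef_, index=feature_names),
        intercept=float(full.intercept_),
        cv_r2=_r2(y, y_oof), in_sample_r2=_r2(y, full.predict(X)),
        folds=folds, model=full)


def evaluate_feature_sets(features: pd.DataFrame, outcomes: pd.DataFrame,
                          seed: int = 0, k_folds: int = 10,
                          feature_sets: dict | None = None) -> pd.DataFrame:
    """CV R^2 per (nested feature set x outcome), identical folds across sets."""
    feature_sets = feature_sets or {
        name: cols for name, cols in FEATURE_SETS.items()
        if all(c in features.columns for c in cols)}
    folds = make_folds(len(features), k_folds, seed)
    rows = []
    for set_name, cols in feature_sets.items():
        for outcome_name in outcomes.columns:
            fit = fit_severity_glm(features, outcomes[outcome_name],
                                   feature_names=cols, folds=folds,
                                   outcome_name=outcome_name)
            rows.append({"feature_set": set_name, "outcome": outcome_name,
                         "cv_r2": fit.cv_r2,
                         "in_sample_r2": fit.in_sample_r2})
    return pd.DataFrame(rows)


def apply_model_to_group_b(fit: SeverityModelFit, features_b: pd.DataFrame,
                           recorded: pd.Series | None = None) -> pd.DataFrame:
    """Out-of-group predictions for group-B patients (no refitting)."""
    if features_b.empty:
        return pd.DataFrame(columns=["predicted", "recorded", "residual"])
    pred = fit.predict(features_b)
    out = pd.DataFrame({"predicted": pred}, index=features_b.index)
    if recorded is not None:
        out["recorded"] = np.asarray(recorded, dtype=float)
        out["residual"] = out["recorded"] - out["predicted"]
    return out


# ---------------------------------------------------------------------------
# cohort statistics

@dataclass
class CohortStatistics:
    wilcoxon_p: float
    wilcoxon_statistic: float
    correlation: float
    boot_ci_low: float
    boot_ci_high: float
    n_patients: int
    n_boot: int


def cohort_statistics(cohort: pd.DataFrame, n_boot: int = 1000,
                      seed: int = 0) -> CohortStatistics:
    """Paired Wilcoxon on proteasome phase means; Pearson correlation of
    OPN vs 1/proteasome over all withdrawals, with a percentile bootstrap
    confidence interval (n_boot resamples of 100% of the rows)."""
    means = patient_phase_means(cohort)
    wide = means.pivot(index="patient_id", columns="phase",
                       values="prot_nm").dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 paired patients")
    diffs = wide["relapse"] - wide["remission"]
    if np.allclose(diffs, 0):
        w_stat, w_p = 0.0, 1.0
    else:
        res = stats.wilcoxon(wide["relapse"], wide["remission"])
        w_stat, w_p = float(res.statistic), float(res.pvalue)

    opn = cohort["opn_nm"].to_numpy(dtype=float)
    inv_prot = 1.0 / cohort["prot_nm"].to_numpy(dtype=float)
    if np.var(opn) == 0 or np.var(inv_prot) == 0:
        raise UndefinedR2Error("constant inputs: correlation undefined")
    r = float(stats.pearsonr(opn, inv_prot).statistic)

    rng = np.random.default_rng(seed)
    n = opn.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        o, ip = opn[idx], inv_prot[idx]
        if np.var(o) == 0 or np.var(ip) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.pearsonr(o, ip).statistic
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return CohortStatistics(
        wilcoxon_p=w_p, wilcoxon_statistic=w_stat, correlation=r,
        boot_ci_low=float(lo), boot_ci_high=float(hi),
        n_patients=len(wide), n_boot=n_boot)
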