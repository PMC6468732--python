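"""Chemotactic indices from Boyden-chamber migration and circuit chemotaxis.

A chemotactic index ``ci`` is the relative migration (percent of untreated
control, baseline 100 subtracted) elicited per nM of a substance per hour.
In the assay, cells migrate over a window (default 2-22 h after the OPN +
proteasome reaction starts; the first 2 h are pre-incubation):

* no proteasome:   net = ci_OPN * OPN0 * |window|
* with proteasome: net = ci_OPN * int_w OPN(t) dt + ci_F * int_w F(t) dt

where OPN(t), F(t) follow the Michaelis-Menten digestion of the respective
(substrate, isoform) kinetic parameters.  Solving the second relation for
``ci_F`` per posterior kinetic draw yields index distributions.

Total chemotaxis along a circuit trajectory is the ci-weighted sum over
all nine chemotactic species, with an exact decomposition into OPN-only,
standard-fragment and immuno-fragment contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .errors import (DegenerateMeasurementError, InadmissibleParameterError,
                     IntegrationError, SingularSystemError,
                     UndefinedIndexError)
from .kinetics import SUBSTRATES, KineticParamSet, mm_substrate
from .model import (OPN_OF_SUBSTRATE, SPECIES, RelapseSchedule, Trajectory,
                    equilibrium_state, simulate_circuit)
from .steady_state import derive_params

CELL_TYPES = ("HUVEC", "lymphocyte", "monocyte")
DEFAULT_WINDOW = (2.0, 22.0)

FRAGMENT_OF = {("FL", "immuno"): "f_if", ("N", "immuno"): "f_in",
               ("C", "immuno"): "f_ic", ("FL", "standard"): "f_sf",
               ("N", "standard"): "f_sn", ("C", "standard"): "f_sc"}


@dataclass
class ChemotacticIndexSet:
    """Per-cell-type indices; fragment entries are arrays (one value per
    posterior kinetic draw) or scalars for point estimates."""

    cell_type: str
    ci_opn: dict = field(default_factory=dict)   # substrate -> float
    ci_frag: dict = field(default_factory=dict)  # (substrate, isoform) -> array

    def species_map(self, reduce=np.median) -> dict:
        """Point map: circuit species name -> ci (fragments reduced)."""
        out = {}
        for s, v in self.ci_opn.items():
            out[OPN_OF_SUBSTRATE[s]] = float(v)
        for pair, v in self.ci_frag.items():
            if v is None:
                continue
            out[FRAGMENT_OF[pair]] = float(reduce(np.atleast_1d(v)))
        return out


def estimate_ci_unprocessed(percent, opn0: float,
                            window=DEFAULT_WINDOW) -> float:
    """Index of an intact OPN species from the no-proteasome assay."""
    if opn0 <= 0:
        raise UndefinedIndexError("stimulus concentration must be > 0")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    net = float(np.mean(percent)) - 100.0
    return net / (opn0 * (t1 - t0))


def substrate_fragment_exposure(kcut, km, p_conc, opn0,
                                window=DEFAULT_WINDOW) -> tuple[float, float]:
    """(int OPN dt, int F dt) over the migration window, digestion from t=0."""
    t0, t1 = window
    opn_int, _ = quad(lambda t: mm_substrate(kcut, km, p_conc, opn0, t),
                      t0, t1, limit=200)
    frag_int = opn0 * (t1 - t0) - opn_int
    return opn_int, frag_int


def ci_fragment_from_exposures(percent, ci_opn: float, opn_int: float,
                               frag_int: float) -> float:
    """Solve  net = ci_opn * int OPN dt + ci_F * int F dt  for ci_F."""
    if frag_int <= 0:
        raise SingularSystemError(
            "no fragment exposure over the window (kcut = 0?)")
    net = float(np.mean(percent)) - 100.0
    return (net - ci_opn * opn_int) / frag_int


def estimate_ci_fragments(percent, ci_opn: float, kcut, km, p_conc, opn0,
                          window=DEFAULT_WINDOW) -> float:
    """Fragment-pool index from an assay run with one proteasome isoform."""
    opn_int, frag_int = substrate_fragment_exposure(kcut, km, p_conc, opn0, window)
    return ci_fragment_from_exposures(percent, ci_opn, opn_int, frag_int)


def estimate_index_set(assays: pd.DataFrame, cell_type: str,
                       kinetic_draws: list[KineticParamSet],
                       window=DEFAULT_WINDOW) -> ChemotacticIndexSet:
    """All indices for one cell type from a tidy migration table.

    Expected columns: cell_type, substrate, isoform (none|standard|immuno),
    percent_of_control, stimulus_nM, proteasome_nM.  Missing isoform
    conditions leave the corresponding fragment indices as ``None``.
    """
    sub = assays[assays["cell_type"] == cell_type]
    if sub.empty:
        raise ValueError(f"no assays for cell type {cell_type!r}")
    out = ChemotacticIndexSet(cell_type=cell_type)
    for s in SUBSTRATES:
        none_rows = sub[(sub["substrate"] == s) & (sub["isoform"] == "none")]
        if none_rows.empty:
            raise ValueError(f"{cell_type}: missing no-proteasome assay for {s}")
        opn0 = float(none_rows["stimulus_nM"].iloc[0])
        out.ci_opn[s] = estimate_ci_unprocessed(
            none_rows["percent_of_control"].to_numpy(), opn0, window)
        for iso in ("standard", "immuno"):
            rows = sub[(sub["substrate"] == s) & (sub["isoform"] == iso)]
            if rows.empty:
                out.ci_frag[(s, iso)] = None
                continue
            opn0_iso = float(rows["stimulus_nM"].iloc[0])
            p_conc = float(rows["proteasome_nM"].iloc[0])
            percent = rows["percent_of_control"].to_numpy()
            vals = np.array([
                estimate_ci_fragments(
                    percent, out.ci_opn[s], *draw.entry(s, iso),
                    p_conc, opn0_iso, window)
                for draw in kinetic_draws])
            out.ci_frag[(s, iso)] = vals
    return out


def total_chemotaxis(trajectory: Trajectory, ci: ChemotacticIndexSet | dict,
                     reduce=np.median) -> dict:
    """ci-weighted chemotaxis along a trajectory, with exact decomposition.

    Returns arrays keyed ``total``, ``opn_only``, ``frag_standard``,
    ``frag_immuno``; the three components sum to ``total`` exactly.
    """
    cmap = ci if isinstance(ci, dict) else ci.species_map(reduce)
    w = np.array([cmap.get(name, 0.0) for name in SPECIES])
    opn_w, frag_i_w, frag_s_w = w.copy(), w.copy(), w.copy()
    opn_w[5:] = 0.0
    frag_i_w[:5] = 0.0
    frag_i_w[8:] = 0.0
    frag_s_w[:8] = 0.0
    opn_only = trajectory.states @ opn_w
    frag_immuno = trajectory.states @ frag_i_w
    frag_standard = trajectory.states @ frag_s_w
    # total assembled from the components so the decomposition is exact
    return {
        "total": opn_only + frag_standard + frag_immuno,
        "opn_only": opn_only,
        "frag_immuno": frag_immuno,
        "frag_standard": frag_standard,
    }


def _relapse_window_mask(t, schedule: RelapseSchedule):
    return (t >= schedule.onset_time) & (t <= schedule.end_time)


def scenario_grid(x_i_grid, x_t_grid, opn_rem_tot, prot_rem, opn_rel_tot,
                  prot_rel, kinetics: KineticParamSet,
                  ci: ChemotacticIndexSet | dict,
                  schedule: RelapseSchedule | None = None,
                  n_t: int = 400) -> pd.DataFrame:
    """Relapse-minus-remission chemotaxis surfaces over (x_i, x_t).

    At every grid point the circuit parameters are re-derived from the same
    cohort-level measurements under that isoform/thrombin split, the relapse
    episode is simulated from the remission equilibrium, and the change in
    total and fragment-only chemotaxis (relapse peak vs remission baseline)
    is recorded.  Inadmissible grid points are flagged (NaN), not fatal.
    """
    schedule = schedule or RelapseSchedule()
    t_grid = np.linspace(0.0, schedule.total_span, n_t)
    rows = []
    for x_i in np.asarray(x_i_grid, dtype=float):
        for x_t in np.asarray(x_t_grid, dtype=float):
            rec = {"x_i": x_i, "x_t": x_t, "admissible": True}
            try:
                params = derive_params(opn_rem_tot, prot_rem, opn_rel_tot,
                                       prot_rel, kinetics, x_i=x_i, x_t=x_t)
                init = equilibrium_state(params)
                traj = simulate_circuit(params, init, schedule, t_grid)
                ct = total_chemotaxis(traj, ci)
                mask = _relapse_window_mask(t_grid, schedule)
                frag = ct["frag_standard"] + ct["frag_immuno"]
                peak = int(np.argmax(np.where(mask, ct["total"], -np.inf)))
                rec["total_diff"] = float(ct["total"][peak] - ct["total"][0])
                rec["frag_diff"] = float(np.max(frag[mask]) - frag[0])
                denom = ct["total"][peak]
                rec["share_immuno"] = (float(ct["frag_immuno"][peak] / denom)
                                       if denom else np.nan)
                rec["share_standard"] = (float(ct["frag_standard"][peak] / denom)
                                         if denom else np.nan)
            except (InadmissibleParameterError, SingularSystemError,
                    DegenerateMeasurementError, IntegrationError, ValueError):
                rec.update(admissible=False, total_diff=np.nan,
                           frag_diff=np.nan, share_immuno=np.nan,
                           share_standard=np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)


def cell_type_comparison(assays: pd.DataFrame,
                         kinetic_draws: list[KineticParamSet],
                         params_by_ct=None,
                         trajectory: Trajectory | None = None,
                         window=DEFAULT_WINDOW) -> dict:
    """Index sets (and C_tot along a shared trajectory, if given) per cell type.

    Cell types lacking immunoproteasome assays get ``None`` immuno-fragment
    indices and a chemotaxis restricted to standard-only contributions.
    """
    if assays.empty:
        raise ValueError("empty assay table")
    out = {}
    for ct in assays["cell_type"].unique():
        idx = estimate_index_set(assays, ct, kinetic_draws, window)
        entry = {"indices": idx}
        if trajectory is not None:
            entry["chemotaxis"] = total_chemotaxis(trajectory, idx)
        out[ct] = entry
    return out
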