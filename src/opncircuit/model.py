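"""Extracellular proteasome-osteopontin circuit: state, parameters, ODEs.

The circuit tracks 11 species in serum (all nM, time in hours):

* ``p_i``, ``p_s`` — extracellular immuno- and standard 20S proteasome,
  released at a joint rate ``k_in`` (split by the isoform fraction ``x_i``),
  inhibited by total OPN through ``1/(1 + k_i * OPN_tot)``, cleared at
  ``k_deg``;
* ``opn_f``, ``opn_n``, ``opn_c`` — full-length and thrombin-cleaved
  osteopontin, produced at ``k_1`` (full-length fraction ``x_t``; the
  remainder split evenly between N and C), consumed by both proteasome
  isoforms with Michaelis-Menten kinetics, and cleared non-proteasomally at
  ``k_deg_f/n/c``;
* six fragment pools (one per substrate x isoform), each fed by its
  Michaelis-Menten flux and cleared at ``k_deg3``.

During a relapse the OPN production rate is multiplied by a factor that
ramps linearly from 1 to ``gamma`` over two weeks, stays at ``gamma`` for
two more weeks, then drops back to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import IntegrationError, InvalidScheduleError
from .kinetics import SUBSTRATES, KineticParamSet

SPECIES = ("p_i", "p_s", "opn_f", "opn_n", "opn_c",
           "f_if", "f_in", "f_ic", "f_sf", "f_sn", "f_sc")
OPN_OF_SUBSTRATE = {"FL": "opn_f", "N": "opn_n", "C": "opn_c"}
FRAGMENT_SPECIES = SPECIES[5:]

WEEK_H = 168.0

_IDX = {name: k for k, name in enumerate(SPECIES)}


@dataclass
class CircuitState:
    p_i: float = 0.0
    p_s: float = 0.0
    opn_f: float = 0.0
    opn_n: float = 0.0
    opn_c: float = 0.0
    f_if: float = 0.0
    f_in: float = 0.0
    f_ic: float = 0.0
    f_sf: float = 0.0
    f_sn: float = 0.0
    f_sc: float = 0.0

    def __post_init__(self):
        vec = self.to_array()
        if np.any(vec < 0) or not np.all(np.isfinite(vec)):
            raise ValueError("state fields must be finite and non-negative")

    @property
    def opn_tot(self) -> float:
        return self.opn_f + self.opn_n + self.opn_c

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "CircuitState":
        return cls(**{s: float(v) for s, v in zip(SPECIES, vec)})


@dataclass
class CircuitParams:
    """All rate constants of the circuit; defaults follow the fixed values
    k_deg = k_deg3 = 2e-4 /h and k_1 = 1e-4 nM/h used throughout."""

    k_in: float            # proteasome release, nM/h
    k_i: float             # OPN-mediated release inhibition, 1/nM
    gamma: float           # relapse multiplier on k_1
    k_deg_f: float         # non-proteasomal OPN clearances, 1/h
    k_deg_n: float
    k_deg_c: float
    x_i: float             # immunoproteasome fraction
    x_t: float             # OPN-FL fraction of production
    kinetics: KineticParamSet
    k_deg: float = 2e-4    # proteasome clearance, 1/h
    k_1: float = 1e-4      # OPN production, nM/h
    k_deg3: float = 2e-4   # fragment clearance, 1/h

    def __post_init__(self):
        rates = (self.k_in, self.k_i, self.k_deg, self.k_1,
                 self.k_deg_f, self.k_deg_n, self.k_deg_c, self.k_deg3)
        if any(r < 0 for r in rates):
            raise ValueError("all rate constants must be >= 0")
        if not (0.0 <= self.x_i <= 1.0 and 0.0 <= self.x_t <= 1.0):
            raise ValueError("x_i and x_t must lie in [0, 1]")
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")

    def production(self, substrate: str) -> float:
        """Baseline production rate (nM/h) of one OPN species."""
        if substrate == "FL":
            return self.k_1 * self.x_t
        return self.k_1 * (1.0 - self.x_t) / 2.0

    def clearance(self, substrate: str) -> float:
        return {"FL": self.k_deg_f, "N": self.k_deg_n, "C": self.k_deg_c}[substrate]

    def with_updates(self, **kw) -> "CircuitParams":
        return replace(self, **kw)


@dataclass
class RelapseSchedule:
    """Forcing window: linear ramp to gamma, plateau, instant return."""

    onset_time: float = 4 * WEEK_H
    ramp_duration: float = 2 * WEEK_H
    plateau_duration: float = 2 * WEEK_H
    total_span: float = 16 * WEEK_H

    def __post_init__(self):
        if min(self.ramp_duration, self.plateau_duration, self.total_span) < 0:
            raise InvalidScheduleError("durations must be non-negative")

    @property
    def plateau_start(self) -> float:
        return self.onset_time + self.ramp_duration

    @property
    def end_time(self) -> float:
        return self.plateau_start + self.plateau_duration


def relapse_forcing(t, schedule: RelapseSchedule, gamma: float):
    """Multiplier on the OPN production rate at time(s) ``t``.

    1 outside the relapse window, linear on the ramp, ``gamma`` on the
    plateau (plateau end excluded).
    """
    if gamma < 1.0:
        raise ValueError("gamma must be >= 1")
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    if schedule.ramp_duration > 0:
        on_ramp = (t >= schedule.onset_time) & (t < schedule.plateau_start)
        frac = (t - schedule.onset_time) / schedule.ramp_duration
        out = np.where(on_ramp, 1.0 + (gamma - 1.0) * frac, out)
    on_plateau = (t >= schedule.plateau_start) & (t < schedule.end_time)
    out = np.where(on_plateau, gamma, out)
    return float(out) if out.ndim == 0 else out


def _rhs(t, y, params: CircuitParams, schedule: RelapseSchedule | None,
         forcing_override: float | None = None):
    p_i, p_s = y[0], y[1]
    opn = {"FL": y[2], "N": y[3], "C": y[4]}
    opn_tot = y[2] + y[3] + y[4]

    if forcing_override is not None:
        g = forcing_override
    elif schedule is None:
        g = 1.0
    else:
        g = relapse_forcing(t, schedule, params.gamma)

    release = params.k_in / (1.0 + params.k_i * opn_tot)
    dy = np.empty(11)
    dy[0] = release * params.x_i - p_i * params.k_deg
    dy[1] = release * (1.0 - params.x_i) - p_s * params.k_deg

    kin = params.kinetics
    p_of = {"immuno": p_i, "standard": p_s}
    # Michaelis-Menten fluxes per (substrate, isoform)
    flux = {}
    for s in SUBSTRATES:
        for iso in ("immuno", "standard"):
            kcut, km = kin.entry(s, iso)
            flux[(s, iso)] = p_of[iso] * kcut * max(opn[s], 0.0) / (km + max(opn[s], 0.0))

    for j, s in enumerate(SUBSTRATES):
        dy[2 + j] = (g * params.production(s)
                     - flux[(s, "immuno")] - flux[(s, "standard")]
                     - params.clearance(s) * opn[s])

    for j, s in enumerate(SUBSTRATES):
        dy[5 + j] = flux[(s, "immuno")] - y[5 + j] * params.k_deg3
        dy[8 + j] = flux[(s, "standard")] - y[8 + j] * params.k_deg3
    return dy


def circuit_rhs(t: float, state: CircuitState, params: CircuitParams,
                schedule: RelapseSchedule | None = None) -> CircuitState:
    """Time derivative of every state field at time ``t`` (as a CircuitState
    carrier; values may be negative)."""
    dy = _rhs(t, state.to_array(), params, schedule)
    out = CircuitState.__new__(CircuitState)
    for s, v in zip(SPECIES, dy):
        object.__setattr__(out, s, float(v))
    return out


@dataclass
class Trajectory:
    """Numerical solution of the circuit on a time grid."""

    t: np.ndarray                 # h, strictly increasing
    states: np.ndarray            # (n_t, 11)
    params: CircuitParams
    schedule: RelapseSchedule | None
    rtol: float = 1e-8
    atol: float = 1e-10

    def series(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    @property
    def opn_tot(self) -> np.ndarray:
        return self.states[:, 2:5].sum(axis=1)

    @property
    def proteasome_tot(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    def to_frame(self, sample_id=0):
        import pandas as pd

        rows = []
        for j, s in enumerate(SPECIES):
            rows.append(pd.DataFrame({
                "time_h": self.t, "species": s,
                "value": self.states[:, j], "sample_id": sample_id}))
        return pd.concat(rows, ignore_index=True)


def simulate_circuit(params: CircuitParams, init: CircuitState,
                     schedule: RelapseSchedule | None, t_grid,
                     rtol: float = 1e-8, atol: float = 1e-10,
                     method: str = "LSODA",
                     max_step: float | None = None) -> Trajectory:
    """Integrate the circuit with a stiff-capable adaptive solver.

    The step size is capped (default: an eighth of the shortest nonzero
    schedule segment, at most 24 h) so the solver cannot stride across the
    time-dependent relapse forcing when starting from a steady state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if max_step is None:
        segs = [24.0]
        if schedule is not None:
            segs += [d / 8.0 for d in (schedule.ramp_duration,
                                       schedule.plateau_duration) if d > 0]
        max_step = min(segs)
    sol = solve_ivp(
        _rhs, (t_grid[0], t_grid[-1]), init.to_array(),
        t_eval=t_grid, args=(params, schedule), method=method,
        rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        raise IntegrationError(f"ODE solver failed: {sol.message}", t_fail=t_fail)
    states = sol.y.T.copy()
    # clip solver-tolerance-level negatives
    states[(states < 0) & (states > -atol)] = 0.0
    states[states < 0] = np.maximum(states[states < 0], 0.0)
    return Trajectory(t=t_grid, states=states, params=params,
                      schedule=schedule, rtol=rtol, atol=atol)


def equilibrium_state(params: CircuitParams, forcing: float = 1.0,
                      guess: CircuitState | None = None) -> CircuitState:
    """Steady state of the circuit under a constant production multiplier.

    Solves the 5-dimensional algebraic system for (p_i, p_s, OPN species);
    fragment pools follow in closed form.
    """
    if guess is None:
        p0 = params.k_in / max(params.k_deg, 1e-30)
        opn0 = [forcing * params.production(s) / max(params.clearance(s), 1e-12)
                for s in SUBSTRATES]
        y0 = np.array([p0 * params.x_i, p0 * (1 - params.x_i), *opn0])
    else:
        g = guess.to_array()
        y0 = g[:5]

    def resid(v):
        y = np.zeros(11)
        y[:5] = v
        return _rhs(0.0, y, params, None, forcing_override=forcing)[:5]

    # accept on residual size, not the solver flag: rates live on the scale
    # of k_1/k_in, so 1e-12 nM/h is far below any meaningful drift
    sol = root(resid, y0, method="hybr")
    if np.max(np.abs(resid(sol.x))) >= 1e-12 or np.any(sol.x < -1e-12):
        # relax towards the attractor first, then polish; rescues guesses
        # far from the equilibrium (e.g. near-zero clearances)
        relax = solve_ivp(
            lambda t, y: _rhs(t, y, params, None, forcing_override=forcing),
            (0.0, 10.0 / max(params.k_deg, 1e-6)),
            np.concatenate([np.clip(y0, 0.0, None), np.zeros(6)]),
            method="LSODA", rtol=1e-10, atol=1e-12)
        sol = root(resid, np.clip(relax.y[:5, -1], 0.0, None), method="hybr")
        if np.max(np.abs(resid(sol.x))) >= 1e-12 or np.any(sol.x < -1e-12):
            raise IntegrationError(
                f"equilibrium solve failed: {sol.message}")
    v = np.clip(sol.x, 0.0, None)
    y = np.zeros(11)
    y[:5] = v
    p_of = {"immuno": v[0], "standard": v[1]}
    opn = {"FL": v[2], "N": v[3], "C": v[4]}
    for j, s in enumerate(SUBSTRATES):
        for base, iso in ((5, "immuno"), (8, "standard")):
            kcut, km = params.kinetics.entry(s, iso)
            y[base + j] = (p_of[iso] * kcut * opn[s] / (km + opn[s])
                           / max(params.k_deg3, 1e-30))
    return CircuitState.from_array(y)


@dataclass
class EnsembleSummary:
    """Quantile envelope of an ensemble of trajectories."""

    t: np.ndarray
    quantiles: tuple
    envelope: dict = field(default_factory=dict)  # species -> (n_q, n_t)
    chemotaxis: np.ndarray | None = None          # (n_q, n_t) if ci given

    def median(self, species: str) -> np.ndarray:
        q = np.asarray(self.quantiles)
        j = int(np.argmin(np.abs(q - 0.5)))
        return self.envelope[species][j]


def simulate_ensemble(param_samples, init_samples, schedule, t_grid,
                      quantiles=(0.05, 0.5, 0.95), ci=None,
                      seed: int = 0) -> EnsembleSummary:
    """Simulate every (params, init) pair and summarize per-time quantiles.

    ``ci`` (optional) maps species name -> chemotactic index; when given the
    total-chemotaxis envelope is included.  Deterministic given the samples.
    """
    param_samples = list(param_samples)
    init_samples = list(init_samples)
    if not param_samples:
        raise ValueError("ensemble requires at least one parameter sample")
    if len(init_samples) == 1:
        init_samples = init_samples * len(param_samples)
    if len(init_samples) != len(param_samples):
        raise ValueError("param and init sample counts differ")

    t_grid = np.asarray(t_grid, dtype=float)
    stack = np.empty((len(param_samples), t_grid.size, 11))
    for k, (p, s0) in enumerate(zip(param_samples, init_samples)):
        stack[k] = simulate_circuit(p, s0, schedule, t_grid).states

    qs = np.asarray(quantiles, dtype=float)
    summary = EnsembleSummary(t=t_grid, quantiles=tuple(qs))
    for j, name in enumerate(SPECIES):
        summary.envelope[name] = np.quantile(stack[:, :, j], qs, axis=0)
    if ci is not None:
        weights = np.array([ci.get(name, 0.0) for name in SPECIES])
        ctot = stack @ weights
        summary.chemotaxis = np.quantile(ctot, qs, axis=0)
    return summary
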