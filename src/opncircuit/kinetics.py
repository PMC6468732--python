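"""In vitro osteopontin digestion kinetics and Bayesian inference.

Purified 20S proteasome (standard or immuno isoform) degrades each OPN
species (full-length, thrombin N-/C-terminal fragments) following simple
Michaelis-Menten kinetics:

    dOPN/dt = -p * kcut * OPN / (KM + OPN)
    dF/dt   = +p * kcut * OPN / (KM + OPN)

with constant enzyme concentration ``p`` over the 0-4 h time course and
exact mass conservation OPN(t) + F(t) = OPN(0).  ``kcut`` is the turnover
number (1/h) and ``KM`` the Michaelis constant (nM).

The integrated progress curve has the closed form

    OPN(t) = KM * omega( ln(OPN0/KM) + OPN0/KM - p*kcut*t/KM )

where omega is the Wright omega function (omega(z) solves w + ln w = z),
which we evaluate with :func:`scipy.special.wrightomega`.  Posteriors for
(kcut, KM) and the observation noise are drawn with a random-walk
Metropolis-Hastings sampler in log-parameter space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import wrightomega

from .errors import OpnCircuitError

SUBSTRATES = ("FL", "N", "C")
ISOFORMS = ("standard", "immuno")
PAIRS = tuple((s, i) for s in SUBSTRATES for i in ISOFORMS)

# Log-uniform prior bounds (natural log space).  The KM floor excludes
# sub-10-nM Michaelis constants: affinities that tight are implausible for
# 20S degradation of a disordered substrate, and prior volume down there
# otherwise dominates the weakly identified saturated regime.
KCUT_BOUNDS = (1e-4, 1e2)
KM_BOUNDS = (10.0, 1e4)
SIGMA_BOUNDS = (1e-3, 1.0)


@dataclass
class KineticParamSet:
    """kcut (1/h) and KM (nM) for every (substrate, isoform) pair."""

    kcut: dict
    km: dict

    def __post_init__(self):
        for pair in PAIRS:
            if pair not in self.kcut or pair not in self.km:
                raise ValueError(f"missing kinetic entry for {pair}")
            if self.kcut[pair] < 0:
                raise ValueError(f"kcut{pair} must be >= 0")
            if self.km[pair] <= 0:
                raise ValueError(f"KM{pair} must be > 0")

    def entry(self, substrate: str, isoform: str) -> tuple[float, float]:
        return self.kcut[(substrate, isoform)], self.km[(substrate, isoform)]

    def to_dict(self) -> dict:
        out = {}
        for (s, i), v in self.kcut.items():
            out[f"kcut_{s}_{i}"] = float(v)
        for (s, i), v in self.km.items():
            out[f"km_{s}_{i}"] = float(v)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParamSet":
        kcut, km = {}, {}
        for s in SUBSTRATES:
            for i in ISOFORMS:
                kcut[(s, i)] = float(d[f"kcut_{s}_{i}"])
                km[(s, i)] = float(d[f"km_{s}_{i}"])
        return cls(kcut=kcut, km=km)


@dataclass
class DigestionTimeCourse:
    """Replicate measurements of relative substrate remaining in vitro."""

    substrate: str
    isoform: str
    p_conc: float          # enzyme concentration, nM (constant)
    opn0: float            # initial substrate, nM
    times: np.ndarray      # h, increasing from 0
    observations: np.ndarray  # shape (n_rep, n_times), relative remaining

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.observations = np.atleast_2d(np.asarray(self.observations, dtype=float))
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.opn0 <= 0:
            raise ValueError("initial substrate must be positive")


def mm_substrate(kcut: float, km: float, p_conc: float, opn0: float, t):
    """Substrate concentration OPN(t) from the integrated rate law."""
    t = np.asarray(t, dtype=float)
    if p_conc * kcut == 0.0:
        return np.full_like(t, opn0)
    z = math.log(opn0 / km) + opn0 / km - p_conc * kcut * t / km
    out = km * wrightomega(z).real
    # the identity omega(ln x + x) = x holds only to rounding; pin t = 0
    return np.where(t == 0.0, opn0, out)


def simulate_digestion(kcut, km, p_conc, opn0, t_grid):
    """Substrate and fragment concentrations over an in vitro digestion.

    Returns ``(opn, frag)`` with exact conservation opn + frag = opn0.
    """
    opn = mm_substrate(kcut, km, p_conc, opn0, t_grid)
    return opn, opn0 - opn


def log_likelihood(kcut, km, sigma, data: DigestionTimeCourse) -> float:
    """Gaussian log-likelihood of relative substrate observations."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if data.observations.size == 0:
        return 0.0
    model = mm_substrate(kcut, km, data.p_conc, data.opn0, data.times) / data.opn0
    if not np.all(np.isfinite(model)):
        return -np.inf
    resid = data.observations - model[None, :]
    n = resid.size
    return float(-0.5 * np.sum(resid**2) / sigma**2
                 - n * math.log(sigma) - 0.5 * n * math.log(2 * math.pi))


@dataclass
class PosteriorChains:
    """Raw MCMC output for one (substrate, isoform) inference."""

    param_names: tuple
    samples: np.ndarray       # (n_kept, d) in natural space
    log_posterior: np.ndarray
    acceptance_rate: float
    burn_in: int
    seed: int

    def after_burn_in(self) -> np.ndarray:
        return self.samples[self.burn_in:]

    def summary(self) -> dict:
        post = self.after_burn_in()
        out = {}
        for j, name in enumerate(self.param_names):
            col = post[:, j]
            out[name] = {
                "median": float(np.median(col)),
                "ci_low": float(np.quantile(col, 0.025)),
                "ci_high": float(np.quantile(col, 0.975)),
            }
        return out

    def map_estimate(self) -> dict:
        idx = int(np.argmax(self.log_posterior))
        return dict(zip(self.param_names, self.samples[idx]))


def metropolis_hastings(log_target, init, n_iter, proposal_scales, seed=0):
    """Random-walk Metropolis-Hastings.

    ``log_target`` is evaluated at points in the caller's parameter space
    (here: log-parameters).  ``proposal_scales`` is either a per-dimension
    step size (diagonal proposal) or a full proposal covariance matrix
    (2-D array), which lets the walk follow parameter ridges.
    Deterministic given ``seed``.  Returns (chain including init,
    log-target trace, acceptance rate).
    """
    init = np.asarray(init, dtype=float)
    proposal_scales = np.asarray(proposal_scales, dtype=float)
    if proposal_scales.ndim == 2:
        chol = np.linalg.cholesky(proposal_scales)
        def step(z):
            return chol @ z
    else:
        scales = np.broadcast_to(proposal_scales, init.shape)
        def step(z):
            return scales * z
    lp = log_target(init)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero target density")
    rng = np.random.default_rng(seed)
    chain = np.empty((n_iter + 1, init.size))
    trace = np.empty(n_iter + 1)
    chain[0], trace[0] = init, lp
    x, n_acc = init.copy(), 0
    for k in range(1, n_iter + 1):
        prop = x + step(rng.standard_normal(init.size))
        lp_prop = log_target(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_acc += 1
        chain[k], trace[k] = x, lp
    acc = n_acc / max(n_iter, 1)
    return chain, trace, acc


@dataclass
class MCMCConfig:
    n_iter: int = 50_000
    burn_in: int = 10_000
    seed: int = 0
    sigma_fixed: float | None = None   # None -> infer sigma
    initial_scale: float = 0.25
    adapt_rounds: int = 4
    adapt_length: int = 400
    target_acceptance: float = 0.30


def _log_prior_log_space(theta, infer_sigma):
    """Log-uniform priors -> uniform (constant) in log space within bounds."""
    lo = [math.log(KCUT_BOUNDS[0]), math.log(KM_BOUNDS[0])]
    hi = [math.log(KCUT_BOUNDS[1]), math.log(KM_BOUNDS[1])]
    if infer_sigma:
        lo.append(math.log(SIGMA_BOUNDS[0]))
        hi.append(math.log(SIGMA_BOUNDS[1]))
    if np.any(theta < lo) or np.any(theta > hi):
        return -np.inf
    return 0.0


def _make_log_posterior(data: DigestionTimeCourse, sigma_fixed):
    infer_sigma = sigma_fixed is None

    def log_post(theta):
        prior = _log_prior_log_space(theta, infer_sigma)
        if not np.isfinite(prior):
            return -np.inf
        kcut, km = math.exp(theta[0]), math.exp(theta[1])
        sigma = math.exp(theta[2]) if infer_sigma else sigma_fixed
        return prior + log_likelihood(kcut, km, sigma, data)

    return log_post


def _sampling_transform(opn0: float):
    """Map log-parameters to the sampling frame and back.

    Progress-curve data pin down the initial velocity ~ kcut/(KM + OPN0)
    much better than kcut or KM alone; sampling (log rate, log KM) turns
    the curved kcut-KM ridge into independent axes.  The map is unimodular
    (Jacobian 1), so the flat log-space prior needs no correction.
    """

    def to_sampling(theta):
        out = np.array(theta, dtype=float)
        out[0] = theta[0] - math.log(math.exp(theta[1]) + opn0)
        return out

    def from_sampling(phi):
        out = np.array(phi, dtype=float)
        out[0] = phi[0] + math.log(math.exp(phi[1]) + opn0)
        return out

    return to_sampling, from_sampling


def _initial_guess(data: DigestionTimeCourse, sigma_fixed) -> np.ndarray:
    """Crude first-order estimate refined by a Nelder-Mead polish."""
    mean_obs = np.clip(data.observations.mean(axis=0), 1e-6, None)
    pos = data.times > 0
    if np.any(pos):
        rates = -np.log(mean_obs[pos]) / data.times[pos]
        lam = float(np.clip(np.median(rates), 1e-6, None))
    else:
        lam = 0.1
    km0 = max(data.opn0, KM_BOUNDS[0] * 10)
    kcut0 = np.clip(lam * (km0 + data.opn0) / max(data.p_conc, 1e-12),
                    KCUT_BOUNDS[0] * 10, KCUT_BOUNDS[1] / 10)
    theta = [math.log(kcut0), math.log(km0)]
    if sigma_fixed is None:
        theta.append(math.log(0.05))
    log_post = _make_log_posterior(data, sigma_fixed)
    res = minimize(lambda th: -log_post(th), theta, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    return res.x if np.isfinite(res.fun) else np.asarray(theta)


def run_inference(data: DigestionTimeCourse, config: MCMCConfig) -> PosteriorChains:
    """MH inference for a single (substrate, isoform) time course."""
    infer_sigma = config.sigma_fixed is None
    names = ("kcut", "km") + (("sigma",) if infer_sigma else ())
    log_post_natural = _make_log_posterior(data, config.sigma_fixed)
    to_sampling, from_sampling = _sampling_transform(data.opn0)

    def log_post(phi):
        return log_post_natural(from_sampling(phi))

    init = to_sampling(_initial_guess(data, config.sigma_fixed))

    # pilot adaptation of a global proposal scale towards ~30% acceptance
    scale = config.initial_scale
    x = init
    for r in range(config.adapt_rounds):
        pilot, _, acc = metropolis_hastings(
            log_post, x, config.adapt_length, scale,
            seed=config.seed * 1009 + r + 1)
        x = pilot[-1]
        if acc > 0:
            scale *= math.exp(acc - config.target_acceptance)
        else:
            scale *= 0.3
    # second pilot estimates the posterior covariance so the final walk can
    # move along the kcut-KM ridge rather than across it
    pilot, _, _ = metropolis_hastings(
        log_post, x, max(config.adapt_length * 4, 1000), scale,
        seed=config.seed * 1009 + config.adapt_rounds + 1)
    cov = np.cov(pilot[len(pilot) // 2:].T)
    cov = np.atleast_2d(cov) + 1e-8 * np.eye(init.size)
    proposal = (2.38**2 / init.size) * cov
    chain, trace, acc = metropolis_hastings(
        log_post, pilot[-1], config.n_iter, proposal, seed=config.seed)
    chain = np.apply_along_axis(from_sampling, 1, chain)
    if not (0.05 <= acc <= 0.8):
        warnings.warn(
            f"{data.substrate}/{data.isoform}: acceptance rate {acc:.3f} "
            "outside [0.05, 0.8] after adaptation", RuntimeWarning)
    return PosteriorChains(
        param_names=names,
        samples=np.exp(chain),
        log_posterior=trace,
        acceptance_rate=acc,
        burn_in=min(config.burn_in, config.n_iter // 2),
        seed=config.seed,
    )


@dataclass
class KineticsPosterior:
    """Posterior chains for all six (substrate, isoform) digestions."""

    chains: dict = field(default_factory=dict)  # (substrate, isoform) -> PosteriorChains

    def summary_table(self):
        import pandas as pd

        rows = []
        for (s, i), ch in self.chains.items():
            for name, stats in ch.summary().items():
                rows.append({"substrate": s, "isoform": i, "parameter": name,
                             "acceptance_rate": ch.acceptance_rate, **stats})
        return pd.DataFrame(rows)

    def median_paramset(self) -> KineticParamSet:
        kcut, km = {}, {}
        for pair, ch in self.chains.items():
            s = ch.summary()
            kcut[pair] = s["kcut"]["median"]
            km[pair] = s["km"]["median"]
        return KineticParamSet(kcut=kcut, km=km)

    def map_paramset(self) -> KineticParamSet:
        """Highest-log-posterior draw per pair; preferred point estimate for
        downstream extrapolation (marginal medians can sit off the best-fit
        ridge when KM is weakly identified)."""
        kcut, km = {}, {}
        for pair, ch in self.chains.items():
            m = ch.map_estimate()
            kcut[pair], km[pair] = m["kcut"], m["km"]
        return KineticParamSet(kcut=kcut, km=km)

    def draw_paramsets(self, n: int, seed: int = 0) -> list[KineticParamSet]:
        """Joint draws: one post-burn-in sample per pair, independently."""
        rng = np.random.default_rng(seed)
        draws = []
        post = {pair: ch.after_burn_in() for pair, ch in self.chains.items()}
        for _ in range(n):
            kcut, km = {}, {}
            for pair, samples in post.items():
                row = samples[rng.integers(len(samples))]
                kcut[pair], km[pair] = row[0], row[1]
            draws.append(KineticParamSet(kcut=kcut, km=km))
        return draws


def infer_kinetics(datasets: list[DigestionTimeCourse],
                   config: MCMCConfig | None = None) -> KineticsPosterior:
    """Run MH inference for every digestion time course supplied."""
    config = config or MCMCConfig()
    posterior = KineticsPosterior()
    for k, data in enumerate(datasets):
        if data.times.size < 3:
            raise OpnCircuitError(
                f"{data.substrate}/{data.isoform}: need >= 3 time points")
        sub_cfg = MCMCConfig(**{**config.__dict__,
                                "seed": config.seed * 613 + k})
        posterior.chains[(data.substrate, data.isoform)] = run_inference(data, sub_cfg)
    return posterior
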