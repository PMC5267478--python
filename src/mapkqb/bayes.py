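"""Prior, likelihood, posterior, adaptive-Metropolis MCMC and PPDs.

The posterior over the twelve cascade constants combines a scale-free prior
(log-uniform over [1e-4, 1e4] for all rates and feedback strengths, uniform
over [1, 8] for the Hill exponent ``g``, log-uniform over [0.5, 100] min for
the input half-decay time ``K``) with two likelihood blocks:

* time courses: the observed activities are normalized to the 5-minute
  reference and compared to the normalized model prediction on the log
  scale with a Gaussian of standard deviation ``sigma_log`` (default 0.2).
  The density is defined on log-values without the 1/y Jacobian, so zero
  residual contributes the zero-deviation density and the block is invariant
  under joint rescaling of data and prediction.
* global response coefficients: Gaussian in R-space against the simulated
  GRCs with the empirical per-cell standard deviation floored at 0.05
  (``grc_model="gauss"``); a delta-method alternative propagates the
  log-normal concentration noise through the R transform
  (``grc_model="delta"``).

Sampling uses an adaptive Metropolis random walk on log-parameters with
empirical covariance adaptation and Robbins-Monro scale tuning.  Failed ODE
solves map to log-density -inf, never to exceptions, so chains cannot crash
mid-run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (Condition, OBSERVABLE_SPECIES, PARAM_NAMES, ParamVec,
                    normalize, simulate)
from .mra import GRCTable

__all__ = ["PriorSpec", "Dataset", "PosteriorSample",
           "log_prior", "loglik_timecourse", "loglik_grc", "log_posterior",
           "adaptive_metropolis", "mcmc_sample", "posterior_predict",
           "DEFAULT_PRIOR"]

_LOG2PI = np.log(2.0 * np.pi)

#: ODE tolerances used inside the likelihood: integration error at this level
#: is orders of magnitude below the sigma_log = 0.2 observation noise.
INFERENCE_ODE_TOL = (1e-6, 1e-9)


@dataclass(frozen=True)
class PriorSpec:
    """Independent box prior; log-uniform components are flat on the log scale."""

    rate_bounds: tuple = (1e-4, 1e4)       # rates and feedback strengths
    g_bounds: tuple = (1.0, 8.0)           # uniform on the natural scale
    K_bounds: tuple = (0.5, 100.0)         # log-uniform, minutes

    def bounds_for(self, name: str) -> tuple:
        if name == "g":
            return self.g_bounds
        if name == "K":
            return self.K_bounds
        return self.rate_bounds

    def lower(self) -> np.ndarray:
        return np.array([self.bounds_for(n)[0] for n in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds_for(n)[1] for n in PARAM_NAMES])


DEFAULT_PRIOR = PriorSpec()


@dataclass
class Dataset:
    """Calibration data: normalized time courses plus GRC tables.

    ``timecourse`` columns: growth_factor, time_min, species, value (all
    values strictly positive; log-normal support).  ``grc`` follows the tidy
    GRC schema.  ``sigma_log`` is the common log-scale standard deviation of
    the time-course block.
    """

    timecourse: pd.DataFrame
    grc: pd.DataFrame
    sigma_log: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma_log <= 0.0:
            raise ValueError("sigma_log must be > 0")
        if len(self.timecourse) and (self.timecourse["value"] <= 0.0).any():
            raise ValueError("time-course values must be strictly positive")

    def grc_tables(self):
        for (gf, t), block in self.grc.groupby(["growth_factor", "t_min"]):
            yield GRCTable.from_frame(block.reset_index(drop=True))

    # -- cached numpy views used by the likelihood hot path ----------------
    def _timecourse_arrays(self, t_ref: float = 5.0):
        """Per growth factor: (sim grid, time index, species index, log values)."""
        key = ("_tc_arrays", t_ref)
        if key not in self.__dict__:
            out = {}
            for gf, block in self.timecourse.groupby("growth_factor"):
                t_grid = np.unique(np.concatenate(
                    [block["time_min"].to_numpy(float), [t_ref]]))
                i_t = np.searchsorted(t_grid, block["time_min"].to_numpy(float))
                i_sp = np.array([OBSERVABLE_SPECIES.index(sp)
                                 for sp in block["species"]])
                logv = np.log(block["value"].to_numpy(float))
                out[gf] = (t_grid, i_t, i_sp, logv)
            self.__dict__[key] = out
        return self.__dict__[key]

    def _grc_arrays(self):
        """Per growth factor: (eval times, R means, sds, replicate counts)."""
        if "_grc_cache" not in self.__dict__:
            out = {}
            for gf, block in self.grc.groupby("growth_factor"):
                tables = [GRCTable.from_frame(b.reset_index(drop=True))
                          for _, b in block.groupby("t_min")]
                out[gf] = (np.array([tb.t_eval for tb in tables]),
                           np.stack([tb.R for tb in tables]),
                           np.stack([tb.sd for tb in tables]),
                           np.array([tb.n_replicates for tb in tables]))
            self.__dict__["_grc_cache"] = out
        return self.__dict__["_grc_cache"]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.timecourse.to_csv(directory / "timecourse.csv", index=False)
        self.grc.to_csv(directory / "grc.csv", index=False)
        (directory / "meta.json").write_text(json.dumps({"sigma_log": self.sigma_log}))

    @classmethod
    def load(cls, directory) -> "Dataset":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        return cls(timecourse=pd.read_csv(directory / "timecourse.csv"),
                   grc=pd.read_csv(directory / "grc.csv"),
                   sigma_log=float(meta["sigma_log"]))


def log_prior(theta: ParamVec, prior: PriorSpec = DEFAULT_PRIOR) -> float:
    """Log prior density on the sampling (log-parameter) scale.

    Flat inside the support (so any two interior points have equal density
    for the log-uniform components) and -inf outside.
    """
    arr = theta.to_array()
    lo, hi = prior.lower(), prior.upper()
    if np.any(arr < lo) or np.any(arr > hi):
        return -np.inf
    return 0.0


def loglik_timecourse(theta: ParamVec, data: Dataset, t_ref: float = 5.0,
                      method: str = "auto",
                      ode_tol: tuple = INFERENCE_ODE_TOL) -> float:
    """Gaussian log-density on log observations vs normalized predictions."""
    sigma = data.sigma_log
    total = 0.0
    const = -0.5 * _LOG2PI - np.log(sigma)
    for gf, (t_grid, i_t, i_sp, logv) in data._timecourse_arrays(t_ref).items():
        cond = Condition.for_growth_factor(gf)
        try:
            traj = simulate(theta, cond, t_grid, method=method,
                            rtol=ode_tol[0], atol=ode_tol[1])
            z = normalize(traj, t_ref)
        except Exception:
            return -np.inf
        pred = z[i_t, i_sp]
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0.0):
            return -np.inf
        r = (logv - np.log(pred)) / sigma
        total += logv.size * const - 0.5 * float(r @ r)
    return float(total)


def _delta_sd(R_sim: float, sigma: float, n_replicates: int) -> float:
    """Delta-method sd of R under log-normal concentration noise.

    The replicate-level ratio rho = v_s/v_c has log-sd sigma*sqrt(2); with
    R = 2(rho - 1)/(rho + 1), dR/dlog(rho) = 4 rho/(1 + rho)^2.  The table
    reports a mean over replicates, so the sd shrinks by sqrt(n).
    """
    rho = (2.0 + R_sim) / (2.0 - R_sim)
    sd = 4.0 * rho / (1.0 + rho) ** 2 * sigma * np.sqrt(2.0)
    if n_replicates > 1:
        sd /= np.sqrt(n_replicates)
    return max(sd, 1e-6)


def loglik_grc(theta: ParamVec, data: Dataset, grc_model: str = "gauss",
               sd_floor: float = 0.05, method: str = "auto",
               ode_tol: tuple = INFERENCE_ODE_TOL) -> float:
    """Gaussian log-density of observed GRC means given simulated GRCs.

    Evaluation times of the same growth factor share one control and one
    silenced simulation each, which keeps a posterior evaluation at eight
    ODE solves.
    """
    if grc_model not in ("gauss", "delta"):
        raise ValueError(f"unknown grc_model {grc_model!r}")
    from .mra import SILENCING_FACTORS
    total = 0.0
    for gf, (t_evals, R_obs, SD_obs, n_reps) in data._grc_arrays().items():
        cond_c = Condition.for_growth_factor(gf)
        t_grid = np.unique(t_evals)
        i_t = np.searchsorted(t_grid, t_evals)
        try:
            v_c = simulate(theta, cond_c, t_grid, method=method,
                           rtol=ode_tol[0], atol=ode_tol[1]).observables()[i_t]
            if np.any(v_c <= 0.0):
                return -np.inf
            R_sim = np.empty_like(R_obs)
            for j, factor in enumerate(SILENCING_FACTORS):
                v_s = simulate(theta, cond_c.with_silencing(j, factor),
                               t_grid, method=method,
                               rtol=ode_tol[0], atol=ode_tol[1]).observables()[i_t]
                R_sim[:, :, j] = 2.0 * (v_s - v_c) / (v_s + v_c)
        except Exception:
            return -np.inf
        if grc_model == "gauss":
            sd = np.maximum(SD_obs, sd_floor)
        else:
            rho = (2.0 + R_sim) / (2.0 - R_sim)
            sd = 4.0 * rho / (1.0 + rho) ** 2 * data.sigma_log * np.sqrt(2.0)
            sd /= np.sqrt(np.maximum(n_reps, 1))[:, None, None]
            sd = np.maximum(sd, 1e-6)
        r = (R_obs - R_sim) / sd
        total += float(np.sum(-0.5 * _LOG2PI - np.log(sd) - 0.5 * r * r))
    return float(total)


def log_posterior(theta: ParamVec, data: Dataset,
                  prior: PriorSpec = DEFAULT_PRIOR,
                  grc_model: str = "gauss", method: str = "auto",
                  ode_tol: tuple = INFERENCE_ODE_TOL) -> float:
    """Unnormalized log posterior; -inf propagates, never raises."""
    lp = log_prior(theta, prior)
    if not np.isfinite(lp):
        return -np.inf
    try:
        lt = loglik_timecourse(theta, data, method=method, ode_tol=ode_tol)
        if not np.isfinite(lt):
            return -np.inf
        lg = loglik_grc(theta, data, grc_model=grc_model, method=method,
                        ode_tol=ode_tol)
    except Exception:
        return -np.inf
    return float(lp + lt + lg)


@dataclass
class PosteriorSample:
    """Retained MCMC draws (one ParamVec per row) with chain metadata."""

    draws: np.ndarray            # (n, 12) on the natural scale
    log_post: np.ndarray
    acceptance_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != len(PARAM_NAMES):
            raise ValueError("draws must be (n, 12)")
        if len(self.draws) < 1:
            raise ValueError("at least one draw required")

    def __len__(self) -> int:
        return len(self.draws)

    def iter_params(self):
        for row in self.draws:
            yield ParamVec.from_array(row)

    def param(self, i: int) -> ParamVec:
        return ParamVec.from_array(self.draws[i])

    def credible_interval(self, name: str, level: float = 0.95):
        j = PARAM_NAMES.index(name)
        a = (1.0 - level) / 2.0
        return tuple(np.quantile(self.draws[:, j], [a, 1.0 - a]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(PARAM_NAMES))
        df.insert(0, "draw_id", np.arange(len(df)))
        df["log_posterior"] = self.log_post
        return df

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "posterior.csv", index=False)
        meta = dict(self.meta)
        meta["acceptance_rate"] = self.acceptance_rate
        (directory / "chain_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorSample":
        directory = Path(directory)
        df = pd.read_csv(directory / "posterior.csv")
        meta = json.loads((directory / "chain_meta.json").read_text())
        acc = meta.pop("acceptance_rate")
        return cls(draws=df[list(PARAM_NAMES)].to_numpy(),
                   log_post=df["log_posterior"].to_numpy(),
                   acceptance_rate=float(acc), meta=meta)


def adaptive_metropolis(log_target, eta0: np.ndarray, n_steps: int,
                        rng: np.random.Generator,
                        target_acceptance: float = 0.28):
    """Adaptive Metropolis random walk on an arbitrary unnormalized target.

    Haario-style proposal-covariance adaptation from the running chain
    covariance (scaled by 2.38^2/d) combined with Robbins-Monro tuning of a
    global step scale towards ``target_acceptance``.  Returns
    ``(chain, log_targets, acceptance_rate)``.  The walk is invariant under
    adding any constant to ``log_target`` and raises if every proposal was
    rejected.
    """
    eta = np.asarray(eta0, dtype=float).copy()
    d = eta.size
    lp = log_target(eta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log target")
    lam = (2.38 ** 2) / d
    log_scale = 0.0
    chol = np.linalg.cholesky(np.eye(d) * 0.01)
    mean = eta.copy()
    m2 = np.zeros((d, d))
    n_adapt_start = 200
    eps = 1e-8 * np.eye(d)

    chain = np.empty((n_steps, d))
    lps = np.empty(n_steps)
    n_accept = 0
    for step in range(n_steps):
        prop = eta + np.exp(0.5 * log_scale) * np.sqrt(lam) \
            * (chol @ rng.standard_normal(d))
        lp_prop = log_target(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            eta, lp = prop, lp_prop
            n_accept += 1
            accepted = 1.0
        else:
            accepted = 0.0
        chain[step] = eta
        lps[step] = lp
        # running covariance (Welford)
        delta = eta - mean
        mean += delta / (step + 1)
        m2 += np.outer(delta, eta - mean)
        if step >= n_adapt_start and step % 50 == 0:
            try:
                chol = np.linalg.cholesky(m2 / step + eps)
            except np.linalg.LinAlgError:
                pass
        log_scale += (accepted - target_acceptance) * 2.0 / np.sqrt(step + 1)

    if n_accept == 0:
        raise RuntimeError("all proposals rejected; chain did not move")
    return chain, lps, n_accept / n_steps


def _default_init(data, prior, rng, n_candidates, log_post_fn):
    """Starting point: best random candidate refined by a short local search.

    Draws ``n_candidates`` points from a moderate sub-box of the prior,
    keeps the best, then polishes it with a derivative-free Nelder-Mead run
    on the log-parameter scale so the chain starts on the posterior ridge
    rather than in a flat tail.
    """
    from scipy.optimize import minimize

    lo = np.maximum(prior.lower(), [1e-2] * 10 + [prior.g_bounds[0], 1.0])
    hi = np.minimum(prior.upper(), [1e2] * 10 + [prior.g_bounds[1], 100.0])
    cands = []
    for _ in range(n_candidates):
        eta = rng.uniform(np.log(lo), np.log(hi))
        theta = ParamVec.from_array(np.exp(eta))
        lp = log_post_fn(theta)
        if np.isfinite(lp):
            cands.append((lp, theta))
    if not cands:
        raise RuntimeError("could not find a finite-posterior starting point")
    cands.sort(key=lambda c: -c[0])

    def neg(eta):
        try:
            return -log_post_fn(ParamVec.from_array(np.exp(eta)))
        except ValueError:
            return np.inf

    # polish several leading candidates: single restarts can strand the
    # chain in a poorly fitting local mode of this multimodal posterior
    best_lp, best = cands[0]
    for lp0, theta0 in cands[:5]:
        res = minimize(neg, np.log(theta0.to_array()), method="Nelder-Mead",
                       options={"maxfev": 1500, "xatol": 1e-3, "fatol": 1e-3})
        if np.isfinite(res.fun) and -res.fun > best_lp:
            best_lp, best = -res.fun, ParamVec.from_array(np.exp(res.x))
    return best


def mcmc_sample(data: Dataset, n_steps: int, seed: int,
                init: ParamVec | None = None,
                prior: PriorSpec = DEFAULT_PRIOR,
                burn_in: float = 0.5, n_retain: int = 2000,
                target_acceptance: float = 0.28,
                grc_model: str = "gauss", method: str = "auto",
                n_init_candidates: int = 200) -> PosteriorSample:
    """Adaptive Metropolis on log-parameters.

    The chain walks in ``eta = log(theta)``; the uniform-in-``g`` prior
    contributes a ``+log(g)`` change-of-variables term (the log-uniform
    components need none).  The proposal covariance is adapted to the
    empirical chain covariance (scaled by 2.38^2/d) and the global scale is
    tuned by Robbins-Monro towards ``target_acceptance``.  Fully reproducible
    given ``seed``; raises if every proposal was rejected.
    """
    if n_steps < 10:
        raise ValueError("n_steps too small")
    rng = np.random.default_rng(seed)
    d = len(PARAM_NAMES)
    g_idx = PARAM_NAMES.index("g")

    def log_target(eta: np.ndarray) -> float:
        arr = np.exp(eta)
        if not np.all(np.isfinite(arr)):
            return -np.inf
        try:
            theta = ParamVec.from_array(arr)
        except ValueError:
            return -np.inf
        lp = log_posterior(theta, data, prior=prior, grc_model=grc_model,
                           method=method)
        if not np.isfinite(lp):
            return -np.inf
        return lp + eta[g_idx]

    if init is None:
        init = _default_init(
            data, prior, rng, n_init_candidates,
            lambda th: log_posterior(th, data, prior=prior,
                                     grc_model=grc_model, method=method))
    eta = np.log(init.to_array())
    chain, lps, acceptance = adaptive_metropolis(
        log_target, eta, n_steps, rng, target_acceptance=target_acceptance)

    start = int(burn_in * n_steps)
    kept = chain[start:]
    kept_lp = lps[start:]
    if len(kept) > n_retain:
        idx = np.linspace(0, len(kept) - 1, n_retain).astype(int)
        kept = kept[idx]
        kept_lp = kept_lp[idx]
    return PosteriorSample(
        draws=np.exp(kept), log_post=kept_lp, acceptance_rate=acceptance,
        meta={"seed": int(seed), "n_steps": int(n_steps),
              "burn_in": float(burn_in), "n_retained": int(len(kept)),
              "grc_model": grc_model,
              "init": ParamVec.from_array(np.round(init.to_array(), 12)).to_dict()})


def posterior_predict(samples: PosteriorSample, scenario: Condition,
                      t_grid, quantiles=(0.025, 0.5, 0.975),
                      sigma_log: float = 0.2, seed: int = 0,
                      t_ref: float = 5.0, species: str = "ppERK",
                      with_noise: bool = True, normalize_to_ref: bool = True,
                      method: str = "auto"):
    """Monte-Carlo posterior predictive bands for one observable.

    Every draw is pushed through simulate, normalization to the ``t_ref``
    anchor of the requested species (skipped when ``normalize_to_ref`` is
    false) and, when ``with_noise`` is set, the log-normal observation
    model.  Failed simulations and degenerate anchors are dropped and
    counted.  Returns ``(band, n_failed)`` where ``band`` is a DataFrame
    with one row per time point: the requested quantiles and the predictive
    mean.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    sim_grid = np.unique(np.concatenate([t_grid, [t_ref]]))
    i_sp = OBSERVABLE_SPECIES.index(species)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for theta in samples.iter_params():
        try:
            traj = simulate(theta, scenario, sim_grid, method=method)
        except Exception:
            n_failed += 1
            continue
        z = traj.observables()[:, i_sp]
        if normalize_to_ref:
            ref = z[int(np.argmin(np.abs(sim_grid - t_ref)))]
            if ref <= 0.0:
                n_failed += 1
                continue
            z = z / ref
        vals = np.interp(t_grid, sim_grid, z)
        if with_noise:
            vals = vals * np.exp(sigma_log * rng.standard_normal(t_grid.size))
        rows.append(vals)
    if not rows:
        raise RuntimeError("every posterior draw failed to simulate")
    arr = np.vstack(rows)
    out = {"time_min": t_grid, "mean": arr.mean(axis=0)}
    for q in quantiles:
        out[f"q{q:g}"] = np.quantile(arr, q, axis=0)
    return pd.DataFrame(out), n_failed
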