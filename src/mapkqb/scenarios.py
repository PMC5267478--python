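"""Validation scenarios: perturbation experiments run over a posterior sample.

Each scenario treats the retained posterior draws as a heterogeneous cell
population and reports posterior-predictive summaries.  All scenarios are
pure functions of (samples, configuration) and reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .bayes import PosteriorSample, posterior_predict
from .model import Condition, simulate

__all__ = ["dose_response", "mek_inhibition", "feedback_removal",
           "signal_termination", "is_bimodal"]


def is_bimodal(values: np.ndarray, bic_margin: float = 10.0,
               min_weight: float = 0.10, min_separation: float = 1.0,
               seed: int = 0) -> bool:
    """Bimodality flag for a population of positive responses.

    A two-component Gaussian mixture on log-values must beat the
    single-component fit by ``bic_margin`` BIC points, with both components
    carrying at least ``min_weight`` of the mass and means separated by at
    least ``min_separation`` log units.  Populations of fewer than 10
    positive values are never flagged.
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0.0]
    if v.size < 10 or np.ptp(np.log(v)) < 1e-12:
        return False
    x = np.log(v)
    n = x.size
    # 1-component BIC
    var1 = x.var()
    if var1 <= 0.0:
        return False
    ll1 = -0.5 * n * (np.log(2.0 * np.pi * var1) + 1.0)
    bic1 = 2.0 * np.log(n) - 2.0 * ll1
    # 2-component fit via a small deterministic EM
    rng = np.random.default_rng(seed)
    mu = np.quantile(x, [0.25, 0.75])
    sd = np.full(2, x.std() / 2.0 + 1e-6)
    w = np.array([0.5, 0.5])
    for _ in range(200):
        logp = (np.log(w)[None, :]
                - 0.5 * np.log(2.0 * np.pi * sd[None, :] ** 2)
                - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2)
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        resp = p / p.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0) + 1e-12
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, 1e-3)
    logp = (np.log(w)[None, :]
            - 0.5 * np.log(2.0 * np.pi * sd[None, :] ** 2)
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2)
    m = logp.max(axis=1)
    ll2 = float(np.sum(m + np.log(np.exp(logp - m[:, None]).sum(axis=1))))
    bic2 = 5.0 * np.log(n) - 2.0 * ll2
    return (bic1 - bic2 > bic_margin and w.min() >= min_weight
            and abs(mu[1] - mu[0]) >= min_separation)


def _population_values(samples, cond, t_eval, species_col=3, method="auto"):
    t_grid = np.array(sorted({0.0, 5.0, float(t_eval)}))
    i_t = int(np.argmin(np.abs(t_grid - t_eval)))
    vals = []
    n_failed = 0
    for theta in samples.iter_params():
        try:
            traj = simulate(theta, cond, t_grid, method=method)
        except Exception:
            n_failed += 1
            continue
        vals.append(traj.states[i_t, species_col])
    return np.array(vals), n_failed


def dose_response(samples: PosteriorSample, growth_factor: str,
                  ku_grid, t_eval: float | None = None,
                  bic_margin: float = 10.0):
    """ppERK population response across input doses with a bimodality flag.

    The dose enters through ``ku`` (multiplying the input amplitude); the
    readout time defaults to 5 min for EGF and 60 min for NGF.  Returns a
    tidy per-(dose, draw) table and a per-dose summary with mean, median and
    the bimodality flag.  Dose units are arbitrary: without a receptor model
    the comparison to measured dose responses is qualitative.
    """
    gf = growth_factor.upper()
    if t_eval is None:
        t_eval = 5.0 if gf == "EGF" else 60.0
    rows = []
    summary = []
    for ku in ku_grid:
        if ku < 0.0:
            raise ValueError("doses must be non-negative")
        cond = Condition.for_growth_factor(gf, ku=float(ku))
        if ku == 0.0:
            vals = np.zeros(len(samples))
            n_failed = 0
        else:
            vals, n_failed = _population_values(samples, cond, t_eval)
        for i, v in enumerate(vals):
            rows.append((gf, float(ku), t_eval, i, v))
        flag = is_bimodal(vals, bic_margin=bic_margin) if len(vals) > 1 else False
        summary.append((gf, float(ku), t_eval, float(np.mean(vals)),
                        float(np.median(vals)), flag, n_failed))
    per_draw = pd.DataFrame(rows, columns=["growth_factor", "ku", "t_eval",
                                           "draw_id", "ppERK"])
    summary = pd.DataFrame(summary, columns=["growth_factor", "ku", "t_eval",
                                             "mean", "median", "bimodal",
                                             "n_failed"])
    return per_draw, summary


def mek_inhibition(samples: PosteriorSample, t_grid, seed: int = 0):
    """pRaf predictive bands, NGF control versus complete MEK inhibition.

    Setting the MEK phosphorylation rate to zero severs the feedback from
    ppERK back to Raf, so the inhibited pRaf simply tracks the transient
    input, while downstream ppMEK/pERK/ppERK stay identically zero.
    """
    control = Condition.ngf_control()
    inhibited = replace(control, mek_inhibited=True)
    band_c, nf_c = posterior_predict(samples, control, t_grid, species="pRaf",
                                     seed=seed, normalize_to_ref=False)
    band_i, nf_i = posterior_predict(samples, inhibited, t_grid, species="pRaf",
                                     seed=seed, normalize_to_ref=False)
    return {"control": band_c, "mek_inhibited": band_i,
            "n_failed": {"control": nf_c, "mek_inhibited": nf_i}}


def feedback_removal(samples: PosteriorSample, t_grid, seed: int = 0):
    """ppERK predictive bands, NGF control versus feedback deletion.

    Emulates pharmacological feedback breaking by forcing both feedback
    strengths to zero, which abolishes the sustained branch of the response.
    """
    control = Condition.ngf_control()
    removed = replace(control, feedback_removed=True)
    band_c, nf_c = posterior_predict(samples, control, t_grid, species="ppERK",
                                     seed=seed, normalize_to_ref=False)
    band_r, nf_r = posterior_predict(samples, removed, t_grid, species="ppERK",
                                     seed=seed, normalize_to_ref=False)
    return {"control": band_c, "feedback_removed": band_r,
            "n_failed": {"control": nf_c, "feedback_removed": nf_r}}


def signal_termination(samples: PosteriorSample, growth_factor: str,
                       t_off_list, t_report, seed: int = 0):
    """ppERK predictive bands under abrupt input termination.

    Mimics neutralizing antibodies / receptor inhibitors added at each
    ``t_off``; ``None`` in the list denotes the untreated control.  Bands
    are reported on ``t_report``.
    """
    gf = growth_factor.upper()
    out = {}
    n_failed = {}
    t_report = np.asarray(t_report, dtype=float)
    for t_off in t_off_list:
        key = "control" if t_off is None else f"t_off={t_off:g}"
        cond = Condition.for_growth_factor(gf, t_off=t_off)
        if t_off is not None and t_off <= 0.0:
            zero = pd.DataFrame({"time_min": t_report,
                                 "mean": np.zeros(t_report.size)})
            out[key] = zero
            n_failed[key] = 0
            continue
        band, nf = posterior_predict(samples, cond, t_report, species="ppERK",
                                     seed=seed, normalize_to_ref=False)
        out[key] = band
        n_failed[key] = nf
    out["n_failed"] = n_failed
    return out
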