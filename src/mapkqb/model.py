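"""Rescaled four-state ODE model of the Raf/MEK/ERK cascade.

The model describes the three-tiered MAPK phosphorylation cascade in PC-12
cells in terms of fractions of total protein: ``x1`` = pRaf, ``x2`` = ppMEK
(double phosphorylation treated as a single processive step), ``x3`` = pERK
and ``x4`` = ppERK (two distributive steps).  Conservation of total protein
confines the state to ``x1 <= s1``, ``x2 <= s2``, ``x3 + x4 <= s3``, where the
silencing factors ``s_i`` give the fraction of total protein remaining after
RNA interference.

A transient input ``u(t)`` stands in for all receptor-level events: it jumps
to ``ku`` at stimulation and decays sigmoidally with half-decay time ``K``,
mirroring the fast deactivation of Ras.  The growth-factor context enters
through feedback switches: under EGF an effective negative feedback from
ppERK enhances pRaf dephosphorylation, under NGF a sigmoidal positive
feedback from ppERK drives Raf phosphorylation.  At ``u=0`` with no positive
feedback input the origin is a steady state (no basal activity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from ._rk45 import integrate_cascade

__all__ = [
    "PARAM_NAMES", "SPECIES", "OBSERVABLE_SPECIES", "OBSERVABLE_COLUMNS",
    "ParamVec", "Condition", "Trajectory",
    "SimulationError", "DegenerateNormalizationError",
    "input_signal", "hill", "rhs", "rhs_at_input", "simulate", "normalize",
]

#: order of the twelve inferred constants in every flat representation
PARAM_NAMES = ("k1p", "k2p", "k3p", "k4p", "k1m", "k2m", "k3m", "k4m",
               "kFn", "kFp", "g", "K")

#: state-variable species names (x1..x4)
SPECIES = ("pRaf", "ppMEK", "pERK", "ppERK")

#: the measured (active) species and the state columns they map to
OBSERVABLE_SPECIES = ("pRaf", "ppMEK", "ppERK")
OBSERVABLE_COLUMNS = (0, 1, 3)


class SimulationError(RuntimeError):
    """ODE integration failed; the message carries the offending parameters."""


class DegenerateNormalizationError(ValueError):
    """An observable is zero at the normalization anchor."""


@dataclass(frozen=True)
class ParamVec:
    """The twelve inferred model constants.

    Rates are per minute (``k1p`` per minute per unit input, ``k3p``, ``k4p``,
    ``k2p`` per minute per protein fraction); ``kFn``/``kFp`` are the negative
    and positive feedback strengths, ``g`` the Hill exponent of the positive
    feedback (dimensionless, >= 1) and ``K`` the half-decay time of the input
    in minutes.
    """

    k1p: float
    k2p: float
    k3p: float
    k4p: float
    k1m: float
    k2m: float
    k3m: float
    k4m: float
    kFn: float
    kFp: float
    g: float
    K: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("parameters must be finite")
        if np.any(arr <= 0.0):
            raise ValueError("all parameters must be strictly positive")
        if self.g < 1.0:
            raise ValueError("Hill exponent g must be >= 1")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "ParamVec":
        arr = np.asarray(list(arr), dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} entries, got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ParamVec":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ParamVec":
        return cls.from_dict(json.loads(s))

    def scaled(self, name: str, factor: float) -> "ParamVec":
        """Return a copy with one parameter multiplied by ``factor``."""
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class Condition:
    """Experimental context: feedback switches, silencing, input scaling.

    ``fp`` activates the positive feedback (NGF context), ``fn`` the negative
    feedback (EGF context); they are mutually exclusive.  ``s`` holds the
    silencing factors (remaining total-protein fractions) for Raf, MEK, ERK.
    ``ku`` scales the input amplitude (dose multiplier on ``k1p * u(t)``),
    ``mek_inhibited`` forces the MEK phosphorylation rate to zero,
    ``feedback_removed`` forces both feedback strengths to zero and ``t_off``
    terminates the input abruptly at the given time (minutes).
    """

    fp: bool = False
    fn: bool = False
    s: tuple = (1.0, 1.0, 1.0)
    ku: float = 1.0
    mek_inhibited: bool = False
    feedback_removed: bool = False
    t_off: float | None = None

    def __post_init__(self) -> None:
        if self.fp and self.fn:
            raise ValueError("fp and fn must not both be active")
        # RNAi silencing uses s in (0, 1]; values above 1 are admitted so the
        # same field can represent raised total-protein content in
        # sensitivity analyses of cell-to-cell variability.
        if len(self.s) != 3 or any(si <= 0.0 for si in self.s):
            raise ValueError("protein-content factors must be positive")
        if self.ku < 0.0:
            raise ValueError("ku must be >= 0")
        if self.t_off is not None and self.t_off < 0.0:
            raise ValueError("t_off must be >= 0")
        object.__setattr__(self, "s", tuple(float(si) for si in self.s))

    @classmethod
    def ngf_control(cls, **kw) -> "Condition":
        return cls(fp=True, fn=False, **kw)

    @classmethod
    def egf_control(cls, **kw) -> "Condition":
        return cls(fp=False, fn=True, **kw)

    @classmethod
    def for_growth_factor(cls, growth_factor: str, **kw) -> "Condition":
        gf = growth_factor.upper()
        if gf == "NGF":
            return cls.ngf_control(**kw)
        if gf == "EGF":
            return cls.egf_control(**kw)
        raise ValueError(f"unknown growth factor {growth_factor!r}")

    @property
    def growth_factor(self) -> str:
        return "NGF" if self.fp else "EGF"

    def with_silencing(self, index: int, factor: float) -> "Condition":
        """Condition with protein ``index`` (0 Raf, 1 MEK, 2 ERK) silenced."""
        s = list(self.s)
        s[index] = factor
        return replace(self, s=tuple(s))


def input_signal(t, K: float, ku: float = 1.0,
                 t_off: float | None = None):
    """Transient input ``u(t) = ku * (1 - t^3/(t^3 + K^3))`` for ``t >= 0``.

    Zero before stimulation and from ``t_off`` onward (abrupt signal
    termination, e.g. neutralizing antibodies).  ``K`` is the half-decay
    time: ``u(K) = ku / 2``.
    """
    if K <= 0.0:
        raise ValueError("input half-decay time K must be > 0")
    if ku < 0.0:
        raise ValueError("ku must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    t3 = np.where(t_arr > 0.0, t_arr, 0.0) ** 3
    u = ku * (1.0 - t3 / (t3 + K ** 3))
    u = np.where(t_arr < 0.0, 0.0, u)
    if t_off is not None:
        u = np.where(t_arr >= t_off, 0.0, u)
    return u if u.ndim else float(u)


def hill(y, g: float):
    """Sigmoidal positive-feedback activation ``h(y) = y^g / (1 + y^g)``.

    Half-saturation is fixed at 1 on the rescaled concentration scale;
    ``h(0) = 0`` preserves the trivial steady state at the origin.
    """
    y_arr = np.asarray(y, dtype=float)
    yg = np.where(y_arr > 0.0, y_arr, 0.0) ** g
    out = yg / (1.0 + yg)
    return out if out.ndim else float(out)


def _effective(theta: ParamVec, cond: Condition):
    """(k1p_eff incl. dose, k2p_eff, kFn_eff, kFp_eff) under the condition."""
    k2p = 0.0 if cond.mek_inhibited else theta.k2p
    if cond.feedback_removed:
        return theta.k1p, k2p, 0.0, 0.0
    return theta.k1p, k2p, theta.kFn, theta.kFp


def rhs_at_input(x, u: float, theta: ParamVec, cond: Condition) -> np.ndarray:
    """Cascade vector field at a fixed input level ``u`` (dose included)."""
    x1, x2, x3, x4 = x
    s1, s2, s3 = cond.s
    k1p, k2p, kFn, kFp = _effective(theta, cond)
    h = hill(x4, theta.g) if cond.fp else 0.0
    a = k1p * u + (kFp * h if cond.fp else 0.0)
    b = theta.k1m + (kFn * x4 if cond.fn else 0.0)
    return np.array([
        a * (s1 - x1) - b * x1,
        k2p * x1 * (s2 - x2) - theta.k2m * x2,
        theta.k3p * x2 * (s3 - x3 - x4) - theta.k3m * x3
        - theta.k4p * x2 * x3 + theta.k4m * x4,
        theta.k4p * x2 * x3 - theta.k4m * x4,
    ])


def rhs(x, t: float, theta: ParamVec, cond: Condition) -> np.ndarray:
    """Time-dependent vector field; the input follows ``input_signal``."""
    u = input_signal(t, theta.K, cond.ku, cond.t_off)
    return rhs_at_input(x, u, theta, cond)


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: strictly increasing times and 4-state rows."""

    times: np.ndarray
    states: np.ndarray
    condition: Condition
    theta: ParamVec

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or y.shape != (t.size, 4):
            raise ValueError("times must be 1-D and states (n, 4)")
        if np.any(np.diff(t) <= 0.0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    def index_of(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"time {t} min not on the trajectory grid")
        return i

    def value(self, species: str, t: float) -> float:
        col = SPECIES.index(species)
        return float(self.states[self.index_of(t), col])

    def observables(self) -> np.ndarray:
        """(n, 3) array of the measured species pRaf, ppMEK, ppERK."""
        return self.states[:, list(OBSERVABLE_COLUMNS)]

    def to_frame(self, condition_id: str = "cond",
                 t_ref: float = 5.0) -> pd.DataFrame:
        """Tidy export: condition_id, time_min, species, value, normalized_value."""
        rows = []
        try:
            iref = self.index_of(t_ref)
        except KeyError:
            iref = None
        for col, sp in enumerate(SPECIES):
            vals = self.states[:, col]
            ref = self.states[iref, col] if iref is not None else np.nan
            norm = vals / ref if (iref is not None and ref > 0.0) else np.full_like(vals, np.nan)
            for t, v, z in zip(self.times, vals, norm):
                rows.append((condition_id, t, sp, v, z))
        return pd.DataFrame(rows, columns=["condition_id", "time_min",
                                           "species", "value",
                                           "normalized_value"])


def _stiffness_scale(theta: ParamVec, cond: Condition) -> float:
    """Crude upper bound on the Jacobian scale (1/min) used to pick a solver."""
    k1p, k2p, kFn, kFp = _effective(theta, cond)
    return max(k1p * cond.ku + kFp + theta.k1m + kFn,
               k2p + theta.k2m,
               theta.k3p + theta.k3m + theta.k4p + theta.k4m)


def _simulate_lsoda(theta, cond, t_all, x0, rtol, atol):
    # plain-float closure: attribute lookups are hoisted out of the callback
    k1p, k2p, kFn, kFp = _effective(theta, cond)
    k1m, k2m, k3p, k3m, k4p, k4m = (theta.k1m, theta.k2m, theta.k3p,
                                    theta.k3m, theta.k4p, theta.k4m)
    g, K3 = theta.g, theta.K ** 3
    s1, s2, s3 = cond.s
    ku, fp, fn = cond.ku, cond.fp, cond.fn
    t_off = cond.t_off if cond.t_off is not None else np.inf

    def f(x, t):
        x1, x2, x3, x4 = x
        if t < 0.0 or t >= t_off:
            u = 0.0
        else:
            t3 = t * t * t
            u = ku * (1.0 - t3 / (t3 + K3))
        h = 0.0
        if fp and x4 > 0.0:
            yg = x4 ** g
            h = yg / (1.0 + yg)
        a = k1p * u + (kFp * h if fp else 0.0)
        b = k1m + (kFn * x4 if fn else 0.0)
        return (a * (s1 - x1) - b * x1,
                k2p * x1 * (s2 - x2) - k2m * x2,
                k3p * x2 * (s3 - x3 - x4) - k3m * x3 - k4p * x2 * x3 + k4m * x4,
                k4p * x2 * x3 - k4m * x4)

    segments = [t_all]
    if cond.t_off is not None and t_all[0] < cond.t_off < t_all[-1]:
        # split at the discontinuity; LSODA steps must not straddle it
        left = t_all[t_all < cond.t_off]
        right = t_all[t_all >= cond.t_off]
        ys = []
        t_left = np.concatenate([left, [cond.t_off]])
        y = odeint(f, x0, t_left, rtol=rtol, atol=atol, mxstep=500000)
        ys.append(y[:-1])
        t_right = np.concatenate([[cond.t_off], right])
        y2 = odeint(f, y[-1], t_right, rtol=rtol, atol=atol, mxstep=500000)
        ys.append(y2[1:])
        return np.vstack(ys)
    y = odeint(f, x0, segments[0], rtol=rtol, atol=atol, mxstep=500000)
    return y


def simulate(theta: ParamVec, cond: Condition, t_grid: Sequence[float],
             x0: Sequence[float] | None = None, method: str = "auto",
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the cascade from rest over ``t_grid`` (minutes).

    ``method`` is ``"rk45"`` (compiled adaptive Dormand-Prince),
    ``"lsoda"`` (scipy's stiff-switching integrator) or ``"auto"`` (the
    default): a cheap bound on the Jacobian scale routes stiff parameter
    sets, for which an explicit solver would be stability-limited, to
    LSODA and everything else to the fast compiled kernel.  Deterministic
    given its inputs.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0.0):
        raise ValueError("t_grid must be strictly increasing")
    x0 = np.zeros(4) if x0 is None else np.asarray(x0, dtype=float)

    prepend = t_grid[0] > 0.0
    t_all = np.concatenate([[0.0], t_grid]) if prepend else t_grid
    if t_all[0] < 0.0:
        raise ValueError("t_grid must start at or after t = 0")

    if method == "auto":
        # explicit steps needed ~ scale * horizon / 3; cap at ~2e4
        method = "rk45" if _stiffness_scale(theta, cond) * t_all[-1] < 1.2e5 \
            else "lsoda"

    if method == "rk45":
        th_arr = theta.to_array()
        if cond.feedback_removed:
            th_arr[PARAM_NAMES.index("kFn")] = 0.0
            th_arr[PARAM_NAMES.index("kFp")] = 0.0
        y, status = integrate_cascade(
            t_all, x0, th_arr, cond.fp, cond.fn,
            cond.mek_inhibited, cond.s, cond.ku, cond.t_off, rtol, atol)
        if status != 0:
            raise SimulationError(
                f"integration failed (status {status}) for theta={theta.to_dict()}")
    elif method == "lsoda":
        y = _simulate_lsoda(theta, cond, t_all, x0, rtol, atol)
        if not np.all(np.isfinite(y)):
            raise SimulationError(
                f"LSODA produced non-finite values for theta={theta.to_dict()}")
    else:
        raise ValueError(f"unknown method {method!r}")

    if prepend:
        y = y[1:]
    return Trajectory(times=t_grid, states=y, condition=cond, theta=theta)


def normalize(traj: Trajectory, t_ref: float = 5.0) -> np.ndarray:
    """Observables divided by their value at ``t_ref`` (default 5 min).

    Returns an ``(n, 3)`` array ``z`` with columns (pRaf, ppMEK, ppERK);
    ``z[:, i]`` equals 1 exactly at ``t_ref``.  Raises
    :class:`DegenerateNormalizationError` if any observable is non-positive
    at the anchor.
    """
    iref = traj.index_of(t_ref)
    obs = traj.observables()
    ref = obs[iref]
    if np.any(ref <= 0.0):
        bad = [sp for sp, r in zip(OBSERVABLE_SPECIES, ref) if r <= 0.0]
        raise DegenerateNormalizationError(
            f"observable(s) {bad} are zero at t_ref={t_ref} min")
    return obs / ref
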