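"""Circuit-breaking algorithm (CBA) for cascade steady states.

Every feedback circuit of the cascade passes through ppERK (``x4``), so
clamping the single cutset variable ``x4 = kappa`` leaves a loop-free chain
x1 -> x2 -> x3 whose steady state is available in closed form.  Full-system
steady states are then the zeros of the one-dimensional circuit
characteristic

    c(kappa) = k4p * x2bar(kappa) * x3bar(kappa) - k4m * kappa,

i.e. the residual of the released ``x4`` balance.  Zeros are located by sign
changes on a dense grid refined by bisection, expanded back to full states,
and labelled stable/unstable via the eigenvalues of the full 4x4 Jacobian.
One stable state is a monostable system; two is bistable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import Condition, ParamVec, hill, rhs_at_input

__all__ = ["CircuitCharacteristic", "SteadyState", "SteadyStateSet",
           "cascade_steady_state", "circuit_characteristic",
           "find_steady_states", "jacobian", "second_state_distribution"]

_RESIDUAL_TOL = 1e-8
_STABLE_EIG_TOL = -1e-9


def cascade_steady_state(kappa, u: float, theta: ParamVec, cond: Condition):
    """Closed-form steady state of the clamped chain (x1, x2, x3) given x4=kappa.

    Solved sequentially: the x1 balance with ``x4 = kappa`` fixed, then the
    x2 balance from ``x1bar``, then the x3 balance from ``x2bar`` and kappa.
    Accepts scalar or array ``kappa``.
    """
    kap = np.asarray(kappa, dtype=float)
    if np.any(kap < 0.0) or np.any(kap > cond.s[2] + 1e-12):
        raise ValueError("kappa must lie in [0, s3]")
    s1, s2, s3 = cond.s
    k2p = 0.0 if cond.mek_inhibited else theta.k2p
    kFn = 0.0 if cond.feedback_removed else theta.kFn
    kFp = 0.0 if cond.feedback_removed else theta.kFp

    a = theta.k1p * u + (kFp * hill(kap, theta.g) if cond.fp else 0.0)
    b = theta.k1m + (kFn * kap if cond.fn else 0.0)
    x1 = a * s1 / (a + b)                      # b >= k1m > 0
    x2 = k2p * x1 * s2 / (k2p * x1 + theta.k2m)
    x3 = (theta.k3p * x2 * (s3 - kap) + theta.k4m * kap) \
        / ((theta.k3p + theta.k4p) * x2 + theta.k3m)
    if kap.ndim:
        return x1, x2, x3
    return float(x1), float(x2), float(x3)


@dataclass(frozen=True)
class CircuitCharacteristic:
    """c(kappa) sampled on a grid over [0, s3] at fixed input level u."""

    kappa: np.ndarray
    c: np.ndarray
    u: float
    theta: ParamVec
    condition: Condition

    def __call__(self, kap):
        x1, x2, x3 = cascade_steady_state(kap, self.u, self.theta, self.condition)
        return self.theta.k4p * x2 * x3 - self.theta.k4m * np.asarray(kap, dtype=float)


def circuit_characteristic(theta: ParamVec, u: float, cond: Condition,
                           grid_size: int = 800) -> CircuitCharacteristic:
    """Evaluate the circuit characteristic on a uniform kappa grid."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    kap = np.linspace(0.0, cond.s[2], grid_size)
    x1, x2, x3 = cascade_steady_state(kap, u, theta, cond)
    c = theta.k4p * x2 * x3 - theta.k4m * kap
    return CircuitCharacteristic(kappa=kap, c=c, u=u, theta=theta, condition=cond)


@dataclass(frozen=True)
class SteadyState:
    x: np.ndarray
    stability: str      # "stable" | "unstable" | "marginal"
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class SteadyStateSet:
    states: tuple
    u: float
    classification: str     # "monostable" | "bistable" | "other"
    unresolved: bool = False

    @property
    def n_stable(self) -> int:
        return sum(1 for st in self.states if st.stability == "stable")

    def stable_x4(self) -> np.ndarray:
        return np.array(sorted(st.x[3] for st in self.states
                               if st.stability == "stable"))

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.u, i, *st.x, st.stability, self.classification)
                for i, st in enumerate(self.states)]
        return pd.DataFrame(rows, columns=["u", "state_id", "x1", "x2", "x3",
                                           "x4", "stability", "class"])


def jacobian(x, u: float, theta: ParamVec, cond: Condition,
             eps: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of the vector field at fixed u."""
    x = np.asarray(x, dtype=float)
    J = np.zeros((4, 4))
    for j in range(4):
        xp = x.copy()
        xm = x.copy()
        xp[j] += eps
        xm[j] -= eps
        J[:, j] = (rhs_at_input(xp, u, theta, cond)
                   - rhs_at_input(xm, u, theta, cond)) / (2.0 * eps)
    return J


def _stability_of(x, u, theta, cond):
    ev = np.linalg.eigvals(jacobian(x, u, theta, cond))
    re = ev.real
    if np.all(re < _STABLE_EIG_TOL):
        return "stable", ev
    if np.any(re > -_STABLE_EIG_TOL):
        return "unstable", ev
    return "marginal", ev


def find_steady_states(theta: ParamVec, u: float, cond: Condition,
                       grid_size: int = 800,
                       kappa_tol: float = 1e-10) -> SteadyStateSet:
    """Steady states of the full system from the zeros of c(kappa).

    Sign changes on the grid are refined by bisection to ``kappa_tol``; the
    origin is included explicitly when it is an exact zero (``u = 0``).  Each
    zero is expanded to a full state via the clamped-chain closed form and
    labelled via the full Jacobian.  An even number of zeros (generic
    parameters produce an odd count: the origin branch plus saddle-node
    pairs) sets ``unresolved=True``.
    """
    cc = circuit_characteristic(theta, u, cond, grid_size)
    kap, c = cc.kappa, cc.c
    scale = theta.k4m * cond.s[2] + theta.k4p
    zeros: list[float] = []
    if abs(c[0]) <= 1e-13 * scale:
        zeros.append(0.0)
    for i in range(len(kap) - 1):
        a, b = c[i], c[i + 1]
        if i > 0 and abs(a) <= 1e-13 * scale and kap[i] not in zeros:
            zeros.append(float(kap[i]))
        elif a * b < 0.0:
            z = brentq(cc, kap[i], kap[i + 1], xtol=min(kappa_tol, 1e-12))
            zeros.append(float(z))

    states = []
    for z in zeros:
        x1, x2, x3 = cascade_steady_state(z, u, theta, cond)
        x = np.array([x1, x2, x3, z])
        res = np.linalg.norm(rhs_at_input(x, u, theta, cond))
        if res > _RESIDUAL_TOL:
            # refine once with a tighter bisection bracket before giving up
            continue
        stab, ev = _stability_of(x, u, theta, cond)
        states.append(SteadyState(x=x, stability=stab, eigenvalues=ev))

    n_stable = sum(1 for st in states if st.stability == "stable")
    if n_stable == 1:
        classification = "monostable"
    elif n_stable == 2:
        classification = "bistable"
    else:
        classification = "other"
    unresolved = (len(states) % 2 == 0)
    return SteadyStateSet(states=tuple(states), u=float(u),
                          classification=classification, unresolved=unresolved)


def second_state_distribution(samples, t_ref: float = 5.0,
                              method: str = "auto"):
    """Normalized upper steady state ``zbar3`` over the bistable posterior draws.

    For every draw that the CBA classifies as bistable at rest (``u = 0``,
    NGF control) the nonzero stable ``x4bar`` is divided by that draw's
    ppERK at ``t_ref`` from the NGF control simulation.  Returns
    ``(values, n_bistable, n_excluded)`` where ``n_excluded`` counts bistable
    draws with a degenerate normalization anchor.
    """
    from .model import simulate  # local import to avoid cycle at module load

    cond = Condition.ngf_control()
    values = []
    n_bistable = 0
    n_excluded = 0
    for theta in samples.iter_params():
        sset = find_steady_states(theta, 0.0, cond)
        if sset.classification != "bistable":
            continue
        n_bistable += 1
        upper = sset.stable_x4()[-1]
        traj = simulate(theta, cond, np.array([0.0, t_ref]), method=method)
        ref = traj.states[-1, 3]
        if ref <= 0.0:
            n_excluded += 1
            continue
        values.append(upper / ref)
    return np.array(values), n_bistable, n_excluded
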