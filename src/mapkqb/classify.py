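"""Trajectory classification and quasi-bistability diagnostics.

A posterior draw simulated under the NGF control condition is classified from
its ppERK activity relative to the 5-minute reference:

* class 1 (bistable):        ppERK(60)/ppERK(5) > 0.2 and ppERK(600)/ppERK(5) >= 0.1
* class 2 (quasi-bistable):  ppERK(60)/ppERK(5) > 0.2 and ppERK(600)/ppERK(5) < 0.1
* class 3 (monostable):      ppERK(60)/ppERK(5) <= 0.2

Quasi-bistable draws are monostable at rest yet linger for hours near the
location of a vanished upper steady state.  The module quantifies the two
delay mechanisms: the time at which the decaying input crosses the
saddle-node bifurcation (the system becomes monostable) and the much later
switching time at which the trajectory finally collapses; between the two
the vector-field norm is nearly zero (the slow-region plateau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cba import find_steady_states
from .model import (Condition, PARAM_NAMES, ParamVec, Trajectory,
                    normalize, rhs, simulate)

__all__ = [
    "CLASS_BISTABLE", "CLASS_QUASI_BISTABLE", "CLASS_MONOSTABLE",
    "ClassLabel", "BifurcationDiagram",
    "classify_ratios", "classify_trajectory", "population_classify",
    "switching_time", "vector_field_norm", "bifurcation_sweep",
    "time_of_monostability", "oat_sensitivity", "silencing_sensitivity",
    "min_switch_filter", "default_classification_grid",
]

CLASS_BISTABLE = "class1_bistable"
CLASS_QUASI_BISTABLE = "class2_quasi_bistable"
CLASS_MONOSTABLE = "class3_monostable"

_R60_THRESHOLD = 0.2
_R600_THRESHOLD = 0.1
_SWITCH_THRESHOLD = 0.1


@dataclass(frozen=True)
class ClassLabel:
    label: str
    r60: float
    r600: float
    t_switch: float | None = None


@dataclass(frozen=True)
class BifurcationDiagram:
    """Steady-state branches (x4bar, stability) over an input grid."""

    u: np.ndarray
    branches: tuple          # per-u tuple of (x4bar, stability) pairs
    u_snb: tuple             # saddle-node input levels, ascending
    theta: ParamVec
    condition: Condition

    def n_stable(self) -> np.ndarray:
        return np.array([sum(1 for _, stab in b if stab == "stable")
                         for b in self.branches])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, b in zip(self.u, self.branches):
            for k, (x4, stab) in enumerate(b):
                rows.append((u, k, x4, stab))
        return pd.DataFrame(rows, columns=["u", "branch_id", "x4bar", "stability"])


def classify_ratios(r60: float, r600: float) -> str:
    """The printed decision rule on the two ppERK ratios (boundaries exact)."""
    if not (np.isfinite(r60) and np.isfinite(r600)):
        raise ValueError("ratios must be finite")
    if r60 > _R60_THRESHOLD:
        return CLASS_BISTABLE if r600 >= _R600_THRESHOLD else CLASS_QUASI_BISTABLE
    return CLASS_MONOSTABLE


def classify_trajectory(traj: Trajectory, with_switching_time: bool = False) -> ClassLabel:
    """Classify an NGF-control trajectory covering t = 5, 60 and 600 min."""
    ref = traj.value("ppERK", 5.0)
    if ref <= 0.0:
        raise ValueError("ppERK(5 min) is zero; classification degenerate")
    r60 = traj.value("ppERK", 60.0) / ref
    r600 = traj.value("ppERK", 600.0) / ref
    label = classify_ratios(r60, r600)
    t_sw = None
    if with_switching_time and label != CLASS_MONOSTABLE:
        t_sw = switching_time(traj)
    return ClassLabel(label=label, r60=r60, r600=r600, t_switch=t_sw)


def default_classification_grid(t_end: float = 650.0, dt: float = 0.5) -> np.ndarray:
    """Dense grid through t_end that contains the anchors 5, 60 and 600 min."""
    g = np.arange(0.0, t_end + dt / 2, dt)
    return np.unique(np.concatenate([g, [5.0, 60.0, 600.0]]))


def switching_time(traj: Trajectory, threshold: float = _SWITCH_THRESHOLD,
                   t_ref: float = 5.0) -> float | None:
    """First time after t_ref at which normalized ppERK stays below threshold.

    ``None`` if the trajectory never settles below the threshold (bistable
    memory).  If the tail re-crosses the threshold the last downward crossing
    is returned with a warning.
    """
    z3 = normalize(traj, t_ref)[:, 2]
    t = traj.times
    after = t > t_ref
    below = (z3 < threshold) & after
    if not below.any():
        return None
    # last index that is at-or-above threshold among times > t_ref
    above_idx = np.where(after & (z3 >= threshold))[0]
    first_below = np.where(below)[0][0]
    if above_idx.size and above_idx[-1] > first_below:
        warnings.warn("non-monotone tail: returning the last downward crossing")
        return float(t[above_idx[-1] + 1]) if above_idx[-1] + 1 < t.size else None
    return float(t[first_below])


def vector_field_norm(traj: Trajectory, theta: ParamVec | None = None,
                      cond: Condition | None = None) -> np.ndarray:
    """Euclidean norm of the vector field evaluated along the trajectory."""
    theta = traj.theta if theta is None else theta
    cond = traj.condition if cond is None else cond
    return np.array([np.linalg.norm(rhs(x, t, theta, cond))
                     for t, x in zip(traj.times, traj.states)])


def population_classify(samples, cond: Condition | None = None,
                        t_grid: np.ndarray | None = None,
                        method: str = "auto"):
    """Classify every posterior draw under the NGF control condition.

    Returns ``(fractions, per_draw)``: a dict of class fractions (over the
    draws that simulated successfully; failures are counted under
    ``"failed"``) and a tidy per-draw table with the ratios, the label, the
    switching time and the CBA classification at rest.
    """
    cond = Condition.ngf_control() if cond is None else cond
    t_grid = default_classification_grid() if t_grid is None else t_grid
    rows = []
    n_failed = 0
    for i, theta in enumerate(samples.iter_params()):
        try:
            traj = simulate(theta, cond, t_grid, method=method)
            lab = classify_trajectory(traj, with_switching_time=True)
            cba_class = find_steady_states(theta, 0.0, cond).classification
        except Exception:
            n_failed += 1
            continue
        rows.append((i, lab.r60, lab.r600, lab.label, lab.t_switch, cba_class))
    per_draw = pd.DataFrame(rows, columns=["draw_id", "r60", "r600", "label",
                                           "t_switch", "cba_class"])
    n_ok = len(per_draw)
    fractions = {lab: (float((per_draw["label"] == lab).sum()) / n_ok if n_ok else np.nan)
                 for lab in (CLASS_BISTABLE, CLASS_QUASI_BISTABLE, CLASS_MONOSTABLE)}
    fractions["failed"] = n_failed
    return fractions, per_draw


def bifurcation_sweep(theta: ParamVec, cond: Condition, u_grid: np.ndarray,
                      snb_tol: float = 1e-8) -> BifurcationDiagram:
    """Steady-state branches over an input grid with saddle-node bisection.

    The input ``u`` is treated as a static bifurcation parameter.  Wherever
    the number of stable states changes between adjacent grid points the
    saddle-node location is refined by bisection to ``|du| < snb_tol``.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    if np.any(np.diff(u_grid) <= 0.0):
        raise ValueError("u_grid must be strictly increasing")
    branch_list = []
    nst = []
    for u in u_grid:
        sset = find_steady_states(theta, u, cond)
        branch_list.append(tuple((st.x[3], st.stability) for st in sset.states))
        nst.append(sset.n_stable)
    nst = np.array(nst)
    snbs = []
    for i in range(len(u_grid) - 1):
        if nst[i] != nst[i + 1]:
            lo, hi = u_grid[i], u_grid[i + 1]
            n_lo = nst[i]
            while hi - lo > snb_tol:
                mid = 0.5 * (lo + hi)
                n_mid = find_steady_states(theta, mid, cond).n_stable
                if n_mid == n_lo:
                    lo = mid
                else:
                    hi = mid
            snbs.append(0.5 * (lo + hi))
    return BifurcationDiagram(u=u_grid, branches=tuple(branch_list),
                              u_snb=tuple(snbs), theta=theta, condition=cond)


def time_of_monostability(theta: ParamVec, cond: Condition,
                          u_snb: float | None = None,
                          u_grid: np.ndarray | None = None) -> float | None:
    """Time at which the decaying input crosses the saddle-node level.

    Solves ``u(t) = u_SNB`` in closed form for the sigmoidal input.  Returns
    ``None`` when the system is bistable at rest (no saddle-node destroys the
    upper state as the input decays) or when no saddle-node exists.
    """
    if find_steady_states(theta, 0.0, cond).classification == "bistable":
        return None
    if u_snb is None:
        if u_grid is None:
            u_grid = np.concatenate([[0.0], np.geomspace(1e-4, max(cond.ku, 1e-4), 60)])
        diagram = bifurcation_sweep(theta, cond, u_grid)
        if not diagram.u_snb:
            return None
        u_snb = min(diagram.u_snb)
    ku = cond.ku
    if ku <= 0.0 or u_snb >= ku:
        return 0.0
    if u_snb <= 0.0:
        return None
    # u(t) = ku (1 - t^3/(t^3+K^3))  =>  t = K ((ku - u)/u)^(1/3)
    return float(theta.K * ((ku - u_snb) / u_snb) ** (1.0 / 3.0))


def oat_sensitivity(theta_map: ParamVec, factors=(0.5, 2.0 / 3.0, 1.0, 1.5, 2.0),
                    cond: Condition | None = None,
                    t_grid: np.ndarray | None = None) -> pd.DataFrame:
    """One-at-a-time sensitivity of both classifications around a reference fit.

    Each parameter is multiplied individually by each factor; the trajectory
    class (NGF control) and the CBA class at rest are recorded.  The
    rest-state classification is structurally independent of ``k1p`` and
    ``K`` because the input is zero there.
    """
    cond = Condition.ngf_control() if cond is None else cond
    t_grid = default_classification_grid() if t_grid is None else t_grid
    rows = []
    for name in PARAM_NAMES:
        for f in factors:
            theta = theta_map.scaled(name, f)
            try:
                lab = classify_trajectory(simulate(theta, cond, t_grid)).label
            except Exception:
                lab = "failed"
            cba_class = find_steady_states(theta, 0.0, cond).classification
            rows.append((name, f, lab, cba_class))
    return pd.DataFrame(rows, columns=["parameter", "factor", "traj_class",
                                       "cba_class_u0"])


def silencing_sensitivity(samples, s_index: int, s_grid,
                          t_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Class fractions as one total-protein level is scaled about nominal 1.

    Emulates cell-to-cell variation in total Raf/MEK/ERK content by scaling
    ``s[s_index]`` over ``s_grid`` (values above 1 are represented by scaling
    the conservation bound directly) and re-running the population
    classification.
    """
    rows = []
    for sv in s_grid:
        cond = _condition_with_total(Condition.ngf_control(), s_index, sv)
        fractions, _ = population_classify(samples, cond=cond, t_grid=t_grid)
        rows.append((sv, fractions[CLASS_BISTABLE], fractions[CLASS_QUASI_BISTABLE],
                     fractions[CLASS_MONOSTABLE], fractions["failed"]))
    return pd.DataFrame(rows, columns=["s_value", "frac_bistable",
                                       "frac_quasi_bistable", "frac_monostable",
                                       "n_failed"])


def _condition_with_total(cond: Condition, index: int, value: float) -> Condition:
    """Condition with one conservation total set to ``value`` (may exceed 1)."""
    if value <= 0.0:
        raise ValueError("total-protein scale must be positive")
    s = list(cond.s)
    s[index] = value
    return replace(cond, s=tuple(s))


def min_switch_filter(per_draw: pd.DataFrame, t_min_list=(0.0, 120.0, 180.0)) -> pd.DataFrame:
    """Bistable : quasi-bistable ratio after imposing minimal switching times.

    Retains draws whose switching time is at least ``t_min`` (or absent,
    i.e. never switching).  Draws that switch earlier than the imposed
    minimum are filtered out, which can only raise the ratio.
    """
    rows = []
    for t_min in t_min_list:
        keep = per_draw["t_switch"].isna() | (per_draw["t_switch"] >= t_min)
        sub = per_draw[keep]
        n1 = int((sub["label"] == CLASS_BISTABLE).sum())
        n2 = int((sub["label"] == CLASS_QUASI_BISTABLE).sum())
        ratio = n1 / n2 if n2 else np.inf
        rows.append((t_min, n1, n2, ratio))
    return pd.DataFrame(rows, columns=["t_min", "n_bistable",
                                       "n_quasi_bistable", "ratio"])
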