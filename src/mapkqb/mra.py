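"""Modular response analysis: global response coefficients (GRCs).

A GRC quantifies how readout ``i`` responds to silencing of protein ``j``:
``R = 2 (v_s - v_c) / (v_s + v_c)``, the symmetrized relative change between
the silenced (``v_s``) and control (``v_c``) activities.  It is bounded in
(-2, 2) for positive concentrations and inverts to the fold change
``v_s / v_c = (2 + R) / (2 - R)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Condition, ParamVec, Trajectory, simulate

__all__ = ["PROTEINS", "SILENCING_FACTORS", "GRC_TIMES", "GRCTable",
           "response_coefficient", "ratio_from_R", "simulated_grc"]

PROTEINS = ("Raf", "MEK", "ERK")

#: remaining total-protein fractions under RNAi of Raf, MEK, ERK
SILENCING_FACTORS = (0.72, 0.70, 0.65)

#: evaluation times (min) at which GRCs are computed per growth factor
GRC_TIMES = {"EGF": (5.0,), "NGF": (5.0, 15.0)}


def response_coefficient(v_perturbed, v_control):
    """GRC from a silenced/control activity pair: ``2 (v_s - v_c)/(v_s + v_c)``."""
    v_s = np.asarray(v_perturbed, dtype=float)
    v_c = np.asarray(v_control, dtype=float)
    if np.any(v_c < 0.0) or np.any(v_s < 0.0):
        raise ValueError("activities must be non-negative")
    if np.any(v_s + v_c == 0.0):
        raise ValueError("response coefficient undefined when both activities are 0")
    out = 2.0 * (v_s - v_c) / (v_s + v_c)
    return out if out.ndim else float(out)


def ratio_from_R(R):
    """Fold change ``v_s / v_c = (2 + R) / (2 - R)``; requires ``R < 2``."""
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr >= 2.0):
        raise ValueError("R must be < 2")
    out = (2.0 + R_arr) / (2.0 - R_arr)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GRCTable:
    """3x3 GRC matrix: readout (pRaf, ppMEK, ppERK) x silenced protein.

    ``R[i, j]`` is the response of readout ``i`` to silencing of protein
    ``j``; ``sd`` holds per-cell standard deviations (zeros for noiseless
    simulated tables).
    """

    R: np.ndarray
    sd: np.ndarray
    growth_factor: str
    t_eval: float
    n_replicates: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if R.shape != (3, 3) or sd.shape != (3, 3):
            raise ValueError("R and sd must be 3x3")
        if np.any(sd < 0.0):
            raise ValueError("sd must be non-negative")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "sd", sd)

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV schema: growth_factor, t_min, readout, silenced, R_mean, R_sd, n_replicates."""
        rows = []
        for i, readout in enumerate(PROTEINS):
            for j, silenced in enumerate(PROTEINS):
                rows.append((self.growth_factor, self.t_eval, readout,
                             silenced, self.R[i, j], self.sd[i, j],
                             self.n_replicates))
        return pd.DataFrame(rows, columns=["growth_factor", "t_min", "readout",
                                           "silenced", "R_mean", "R_sd",
                                           "n_replicates"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GRCTable":
        gf = df["growth_factor"].iloc[0]
        t = float(df["t_min"].iloc[0])
        R = np.zeros((3, 3))
        sd = np.zeros((3, 3))
        for _, row in df.iterrows():
            i = PROTEINS.index(row["readout"])
            j = PROTEINS.index(row["silenced"])
            R[i, j] = row["R_mean"]
            sd[i, j] = row["R_sd"]
        return cls(R=R, sd=sd, growth_factor=gf, t_eval=t,
                   n_replicates=int(df["n_replicates"].iloc[0]))


def _observables_at(traj: Trajectory, t_eval: float) -> np.ndarray:
    return traj.observables()[traj.index_of(t_eval)]


def simulated_grc(theta: ParamVec, growth_factor: str, t_eval: float,
                  silencing_factors=SILENCING_FACTORS,
                  method: str = "auto") -> GRCTable:
    """Noiseless GRC table from model trajectories under one-at-a-time silencing.

    Column ``j`` compares the trajectory with protein ``j`` silenced (factor
    ``silencing_factors[j]``) against the control trajectory, both evaluated
    at ``t_eval`` minutes after stimulation on the measured species
    (pRaf, ppMEK, ppERK).  The stated evaluation time stands in for a steady
    state, following the experimental convention.
    """
    control = Condition.for_growth_factor(growth_factor)
    t_grid = np.array(sorted({t_eval, 5.0}))
    v_c = _observables_at(simulate(theta, control, t_grid, method=method), t_eval)
    if np.any(v_c <= 0.0):
        raise ValueError(
            f"control observable is zero at t={t_eval} min; GRC degenerate")
    R = np.zeros((3, 3))
    for j, factor in enumerate(silencing_factors):
        cond_j = control.with_silencing(j, factor)
        v_s = _observables_at(simulate(theta, cond_j, t_grid, method=method), t_eval)
        R[:, j] = response_coefficient(v_s, v_c)
    return GRCTable(R=R, sd=np.zeros((3, 3)), growth_factor=growth_factor.upper(),
                    t_eval=float(t_eval), n_replicates=0)
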