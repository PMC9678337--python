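"""Two-compartment gLV dynamics with conjugative gene transfer.

Each taxon ``i`` is split into a susceptible (gene-free) population ``X_s,i``
and a resistant (gene-bearing) population ``X_r,i``.  Both compartments share
the taxon's ecology — self-inhibition and interactions act on partner TOTAL
abundances — but resistant cells pay a growth cost ``c`` and are killed at the
reduced rate ``beta_r * D`` under a stressor dose ``D``.  The gene moves by
mass action: susceptible cells of taxon ``i`` acquire it from resistant cells
of taxon ``j`` at rate ``Gamma[i, j] * X_s,i * X_r,j``.

    dX_s,i/dt = X_s,i * (r_i - s_i (X_s,i + X_r,i) + sum_j a_ij (X_s,j + X_r,j))
                - sum_j Gamma_ij X_s,i X_r,j - beta_s D X_s,i  [+ delta X_r,i]
    dX_r,i/dt = X_r,i * (r_i - c - s_i (X_s,i + X_r,i) + sum_j a_ij (X_s,j + X_r,j))
                + sum_j Gamma_ij X_s,i X_r,j - beta_r D X_r,i  - delta X_r,i

Segregation loss (rate ``delta``, default 0) either returns plasmid-free
segregants to the susceptible compartment or removes them, depending on
``params.segregation_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .community import Community, ModelParams

__all__ = ["State", "Trajectory", "IntegrationError", "rhs", "integrate"]


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge; never silently swallowed."""


@dataclass
class State:
    """Abundances of the 2N populations at one instant."""

    X_s: np.ndarray
    X_r: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.X_s = np.asarray(self.X_s, dtype=float)
        self.X_r = np.asarray(self.X_r, dtype=float)
        if self.X_s.shape != self.X_r.shape:
            raise ValueError("X_s and X_r must have the same length")

    @property
    def total(self) -> np.ndarray:
        return self.X_s + self.X_r

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.X_s, self.X_r])

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float = 0.0) -> "State":
        N = y.size // 2
        return cls(X_s=y[:N].copy(), X_r=y[N:].copy(), t=t)


@dataclass
class Trajectory:
    """Time-stamped solution: arrays of shape (T, N) per compartment."""

    times: np.ndarray
    X_s: np.ndarray
    X_r: np.ndarray
    D_profile: list  # list of (t_start, t_end, dose)

    @property
    def total(self) -> np.ndarray:
        return self.X_s + self.X_r

    def state_at(self, index: int) -> State:
        return State(self.X_s[index], self.X_r[index], t=float(self.times[index]))

    def concat(self, other: "Trajectory") -> "Trajectory":
        """Join a subsequent phase, dropping its duplicated first sample."""
        if not np.isclose(other.times[0], self.times[-1]):
            raise ValueError("trajectories are not contiguous in time")
        return Trajectory(
            times=np.concatenate([self.times, other.times[1:]]),
            X_s=np.vstack([self.X_s, other.X_s[1:]]),
            X_r=np.vstack([self.X_r, other.X_r[1:]]),
            D_profile=self.D_profile + other.D_profile,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: one row per (time, taxon, compartment)."""
        T, N = self.X_s.shape
        frames = []
        for name, arr in (("susceptible", self.X_s), ("resistant", self.X_r)):
            df = pd.DataFrame(arr, columns=range(N))
            df["time"] = self.times
            df = df.melt(id_vars="time", var_name="taxon", value_name="abundance")
            df["compartment"] = name
            frames.append(df)
        return pd.concat(frames, ignore_index=True)[
            ["time", "taxon", "compartment", "abundance"]
        ]


def rhs(
    state: State,
    D: float,
    community: Community,
    params: ModelParams,
) -> State:
    """Time derivative of a :class:`State` under stressor dose ``D``."""
    y = state.to_vector()
    dy = _rhs_vec(state.t, y, D, community, params)
    return State.from_vector(dy, t=state.t)


def _rhs_vec(
    t: float,
    y: np.ndarray,
    D: float,
    community: Community,
    params: ModelParams,
) -> np.ndarray:
    N = community.N
    if y.size != 2 * N:
        raise ValueError(f"state has {y.size} entries, expected {2 * N}")
    Xs = y[:N]
    Xr = y[N:]
    total = Xs + Xr
    # shared per-capita growth: r - s*own_total + interactions on partner totals
    g = community.r_vec - community.s_vec * total + community.A @ total
    transfer = Xs * (community.Gamma @ Xr)
    dXs = Xs * g - transfer - params.beta_s * D * Xs
    dXr = Xr * (g - community.c) + transfer - params.beta_r * D * Xr
    if params.delta > 0.0:
        seg = params.delta * Xr
        dXr = dXr - seg
        if params.segregation_mode == "return":
            dXs = dXs + seg
    return np.concatenate([dXs, dXr])


def _jac_vec(
    t: float,
    y: np.ndarray,
    D: float,
    community: Community,
    params: ModelParams,
) -> np.ndarray:
    """Analytic Jacobian of :func:`_rhs_vec` (speeds up stiff steps)."""
    N = community.N
    Xs, Xr = y[:N], y[N:]
    total = Xs + Xr
    A, s, G = community.A, community.s_vec, community.Gamma
    g = community.r_vec - s * total + A @ total
    M = A - np.diag(s)  # d g_i / d X_j for either compartment of j
    GXr = G @ Xr

    dfs_dXs = np.diag(g - GXr - params.beta_s * D) + Xs[:, None] * M
    dfs_dXr = Xs[:, None] * M - np.diag(Xs) @ G
    dfr_dXs = Xr[:, None] * M + np.diag(GXr)
    dfr_dXr = (
        np.diag(g - community.c - params.beta_r * D)
        + Xr[:, None] * M
        + np.diag(Xs) @ G
    )
    if params.delta > 0.0:
        dfr_dXr = dfr_dXr - params.delta * np.eye(N)
        if params.segregation_mode == "return":
            dfs_dXr = dfs_dXr + params.delta * np.eye(N)
    return np.block([[dfs_dXs, dfs_dXr], [dfr_dXs, dfr_dXr]])


def integrate(
    community: Community,
    initial: State,
    span: tuple[float, float],
    D: float,
    params: ModelParams,
    report_times: Optional[Sequence[float]] = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over one constant-dose phase.

    Abundances are clipped to zero (they can only go numerically negative by
    integrator error of order ``atol``); the extinction floor is applied by
    the protocol layer at phase boundaries, not here.
    """
    t0, t1 = float(span[0]), float(span[1])
    if not t1 > t0:
        raise ValueError("span must be a nonempty forward time interval")
    y0 = initial.to_vector()
    if np.any(y0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    if report_times is None:
        t_eval = np.array([t0, t1])
    else:
        t_eval = np.asarray(report_times, dtype=float)
    sol = solve_ivp(
        _rhs_vec,
        (t0, t1),
        y0,
        method=method,
        t_eval=t_eval,
        args=(D, community, params),
        rtol=params.rtol,
        atol=params.atol,
        jac=_jac_vec if method in ("LSODA", "BDF", "Radau") else None,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed on [{t0}, {t1}] at D={D}: {sol.message}")
    Y = np.clip(sol.y.T, 0.0, None)
    N = community.N
    return Trajectory(
        times=sol.t.copy(),
        X_s=Y[:, :N],
        X_r=Y[:, N:],
        D_profile=[(t0, t1, D)],
    )
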