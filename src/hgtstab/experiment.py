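"""The four-scenario perturbation protocol.

Each community is assayed under a 2x2 design: the focal taxon does or does
not carry the resistance gene (R vs S), and the adjustment phase does or does
not include low-level stressor exposure (exposed vs naive).  Every scenario
follows the same three phases:

1. adjustment for ``t_adjust`` at dose ``D_prior`` (exposed) or 0 (naive),
   starting all taxa at equal abundance ``x0``;
2. perturbation at dose ``D_perturb`` for ``t_perturb``;
3. (optional) recovery at dose 0 for ``t_recover``, retained for the
   return-time stability metric.

Abundance snapshots immediately before (``A_before``) and after (``A_after``)
the perturbation window feed the stability metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .community import Community, ModelParams
from .dynamics import IntegrationError, State, Trajectory, integrate

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "SCENARIO_LABELS",
    "initial_state",
    "run_scenario",
    "run_quartet",
]

SCENARIO_LABELS = ("S-naive", "S-exposed", "R-naive", "R-exposed")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the 2x2 (resistance gene, prior exposure) design."""

    has_resistance: bool
    prior_exposure: bool

    @property
    def label(self) -> str:
        return ("R" if self.has_resistance else "S") + (
            "-exposed" if self.prior_exposure else "-naive"
        )

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        if label not in SCENARIO_LABELS:
            raise ValueError(f"unknown scenario label {label!r}")
        res, exp = label.split("-")
        return cls(has_resistance=(res == "R"), prior_exposure=(exp == "exposed"))


@dataclass
class ScenarioResult:
    """Observations from one scenario run on one community."""

    spec: ScenarioSpec
    A_before: np.ndarray  # per-taxon total abundance at end of adjustment
    A_after: np.ndarray  # per-taxon total abundance at end of perturbation
    resistance_freq_before: np.ndarray  # X_r / total, NaN below floor
    resistance_freq_after: np.ndarray
    state_after: State  # full compartment state at end of perturbation
    trajectory: Optional[Trajectory] = None
    recovery: Optional[Trajectory] = None

    @property
    def label(self) -> str:
        return self.spec.label

    def background_resistance_freq_before(self, community: Community) -> float:
        """Abundance-weighted resistance frequency over background taxa."""
        idx = community.background
        tot = float(self.A_before[idx].sum())
        if tot <= 0.0:
            return float("nan")
        # reconstruct X_r from frequency * total; NaN freq means total ~ 0
        freq = np.nan_to_num(self.resistance_freq_before[idx], nan=0.0)
        return float((freq * self.A_before[idx]).sum() / tot)


def initial_state(
    community: Community, spec: ScenarioSpec, params: ModelParams
) -> State:
    """All taxa start at equal total abundance ``x0``.

    In R-scenarios a fraction ``initial_resistant_fraction`` (default all) of
    the focal taxon's abundance is placed in its resistant compartment; every
    other taxon starts fully susceptible.
    """
    N = community.N
    X_s = np.full(N, params.x0)
    X_r = np.zeros(N)
    if spec.has_resistance:
        f = params.initial_resistant_fraction
        X_r[community.focal] = params.x0 * f
        X_s[community.focal] = params.x0 * (1.0 - f)
    return State(X_s=X_s, X_r=X_r, t=0.0)


def _apply_floor(state: State, floor: float) -> State:
    """Zero out numerically extinct populations at a phase boundary."""
    X_s = np.where(state.X_s < floor, 0.0, state.X_s)
    X_r = np.where(state.X_r < floor, 0.0, state.X_r)
    return State(X_s=X_s, X_r=X_r, t=state.t)


def _freq(state: State, floor: float) -> np.ndarray:
    total = state.total
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total >= floor, state.X_r / np.where(total > 0, total, 1.0), np.nan)
    return f


def run_scenario(
    community: Community,
    spec: ScenarioSpec,
    params: ModelParams,
    keep_trajectory: bool = False,
    include_recovery: bool = False,
    n_report: int = 201,
) -> ScenarioResult:
    """Run one scenario: adjust, perturb, optionally recover."""
    try:
        state0 = initial_state(community, spec, params)
        D_adjust = params.D_prior if spec.prior_exposure else 0.0

        t1 = params.t_adjust
        t2 = params.t_adjust + params.t_perturb
        rt = (
            np.linspace(0.0, t1, n_report)
            if keep_trajectory
            else None
        )
        adj = integrate(community, state0, (0.0, t1), D_adjust, params, report_times=rt)
        state_before = _apply_floor(adj.state_at(-1), params.extinction_floor)
        A_before = state_before.total
        freq_before = _freq(state_before, params.extinction_floor)

        rt = np.linspace(t1, t2, n_report) if keep_trajectory else None
        pert = integrate(
            community, state_before, (t1, t2), params.D_perturb, params, report_times=rt
        )
        state_after = _apply_floor(pert.state_at(-1), params.extinction_floor)
        A_after = state_after.total
        freq_after = _freq(state_after, params.extinction_floor)

        trajectory = adj.concat(pert) if keep_trajectory else None
        recovery = None
        if include_recovery and params.t_recover > 0:
            t3 = t2 + params.t_recover
            rec_times = np.linspace(t2, t3, max(n_report, 501))
            recovery = integrate(
                community, state_after, (t2, t3), 0.0, params, report_times=rec_times
            )
            if keep_trajectory and trajectory is not None:
                trajectory = trajectory.concat(recovery)
    except IntegrationError as err:
        raise IntegrationError(f"scenario {spec.label}: {err}") from err

    return ScenarioResult(
        spec=spec,
        A_before=A_before,
        A_after=A_after,
        resistance_freq_before=freq_before,
        resistance_freq_after=freq_after,
        state_after=state_after,
        trajectory=trajectory,
        recovery=recovery,
    )


def run_quartet(
    community: Community,
    params: ModelParams,
    keep_trajectories: bool = False,
    include_recovery: bool = False,
) -> dict[str, ScenarioResult]:
    """Run all four scenarios on the same community (paired design)."""
    results: dict[str, ScenarioResult] = {}
    for label in SCENARIO_LABELS:
        spec = ScenarioSpec.from_label(label)
        results[label] = run_scenario(
            community,
            spec,
            params,
            keep_trajectory=keep_trajectories,
            include_recovery=include_recovery,
        )
    return results
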