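"""Stability and robustness metrics for perturbation experiments.

The core metric is the per-taxon stability
``Stability_i = min(0, log10(A_after_i / A_before_i))`` — the capped log
fold change across the perturbation window.  Community *Robustness* is the
mean of per-taxon stabilities over a taxon subset: the whole community, the
background (all but the focal taxon), or the focal taxon alone.  The two
headline contrasts are paired within a community:

* ``dR`` — robustness(R-naive) - robustness(S-naive): the effect of the
  resistance gene's initial presence;
* ``dE`` — robustness(R-exposed) - robustness(R-naive): the effect of prior
  low-level stressor exposure, given the gene is present.

The susceptible-pair exposure contrast (S-exposed - S-naive) is reported
alongside as ``dEs``.  Two supplementary metrics are provided: Bray–Curtis
dissimilarity between pre- and post-perturbation composition, and the time
for the community to return to its pre-perturbation state.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .community import Community, ModelParams
from .experiment import ScenarioResult
from .dynamics import Trajectory

__all__ = [
    "StabilityReport",
    "DeltaMetrics",
    "stability_per_taxon",
    "robustness",
    "delta_metrics",
    "bray_curtis",
    "return_time",
    "SCOPES",
    "quartet_reports",
]

SCOPES = ("whole", "background", "focal")


@dataclass
class StabilityReport:
    """Per-taxon stabilities and aggregate robustness for one scenario."""

    per_taxon: np.ndarray  # NaN where A_before was below the floor
    whole: float
    background: float
    focal: float
    bray_curtis: float
    return_time: Optional[float] = None
    n_missing: int = 0
    label: Optional[str] = None
    community_id: Optional[int] = None

    def scope(self, name: str) -> float:
        if name not in SCOPES:
            raise ValueError(f"unknown scope {name!r}")
        return getattr(self, name)


@dataclass
class DeltaMetrics:
    """Paired robustness contrasts for one community's quartet."""

    dR_whole: float
    dR_background: float
    dR_focal: float
    dE_whole: float
    dE_background: float
    dE_focal: float
    dEs_whole: float
    dEs_background: float
    dEs_focal: float
    community_id: Optional[int] = None

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "community_id"
        }


def stability_per_taxon(
    A_before: np.ndarray,
    A_after: np.ndarray,
    floor: float = 1e-9,
) -> np.ndarray:
    """Capped log10 fold change per taxon.

    Gains are capped at 0 so only losses count against stability.  A taxon
    already extinct before the perturbation (below ``floor``) is recorded as
    NaN (missing).  A taxon driven extinct by the perturbation receives the
    finite value ``log10(floor / A_before)`` instead of -inf, keeping means
    defined while remaining monotone in severity.
    """
    A_before = np.asarray(A_before, dtype=float)
    A_after = np.asarray(A_after, dtype=float)
    if A_before.shape != A_after.shape:
        raise ValueError("A_before and A_after must have the same length")
    if np.any(A_before < 0) or np.any(A_after < 0):
        raise ValueError("abundances must be nonnegative")
    out = np.full(A_before.shape, np.nan)
    alive_before = A_before >= floor
    extinct_after = alive_before & (A_after < floor)
    ok = alive_before & ~extinct_after
    with np.errstate(divide="ignore"):
        out[ok] = np.minimum(0.0, np.log10(A_after[ok] / A_before[ok]))
    out[extinct_after] = np.log10(floor / A_before[extinct_after])
    return out


def robustness(per_taxon: np.ndarray, subset: Optional[Sequence[int]] = None) -> float:
    """Mean stability over a taxon subset, ignoring missing (NaN) entries."""
    per_taxon = np.asarray(per_taxon, dtype=float)
    vals = per_taxon if subset is None else per_taxon[np.asarray(subset, dtype=int)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no non-missing taxa in subset")
    return float(vals.mean())


def bray_curtis(A_before: np.ndarray, A_after: np.ndarray) -> float:
    """Bray–Curtis dissimilarity ``sum|b - a| / sum(b + a)`` on abundances."""
    b = np.asarray(A_before, dtype=float)
    a = np.asarray(A_after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("vectors must have the same length")
    if np.any(b < 0) or np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    if b.sum() + a.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(_sp_braycurtis(b, a))


def return_time(
    trajectory: Trajectory,
    reference: np.ndarray,
    tol: float = 0.05,
    floor: float = 1e-9,
) -> Optional[float]:
    """Time after the perturbation at which the community has recovered.

    Recovery means every non-extinct taxon's total abundance is within
    relative tolerance ``tol`` of its pre-perturbation reference, and stays
    within it for the rest of the horizon.  Returns None if never achieved
    (including when a reference taxon has gone extinct with no recovery).
    """
    reference = np.asarray(reference, dtype=float)
    alive = reference >= floor
    if not alive.any():
        return None
    total = trajectory.total[:, alive]
    ref = reference[alive]
    within = np.all(np.abs(total - ref) <= tol * ref, axis=1)
    # first index from which `within` holds through the end of the horizon
    ok_from = np.flip(np.logical_and.accumulate(np.flip(within)))
    idx = np.nonzero(ok_from)[0]
    if idx.size == 0:
        return None
    return float(trajectory.times[idx[0]] - trajectory.times[0])


def scenario_report(
    result: ScenarioResult,
    community: Community,
    params: ModelParams,
    recovery_tol: float = 0.05,
) -> StabilityReport:
    """Compute the full stability report for one scenario result."""
    floor = params.extinction_floor
    per = stability_per_taxon(result.A_before, result.A_after, floor=floor)
    bg = community.background
    rt = None
    if result.recovery is not None:
        rt = return_time(result.recovery, result.A_before, tol=recovery_tol, floor=floor)
    return StabilityReport(
        per_taxon=per,
        whole=robustness(per),
        background=robustness(per, bg),
        focal=robustness(per, [community.focal]),
        bray_curtis=bray_curtis(result.A_before, result.A_after),
        return_time=rt,
        n_missing=int(np.isnan(per).sum()),
        label=result.label,
        community_id=community.seed_entropy,
    )


def quartet_reports(
    quartet: dict[str, ScenarioResult],
    community: Community,
    params: ModelParams,
) -> dict[str, StabilityReport]:
    return {
        label: scenario_report(res, community, params)
        for label, res in quartet.items()
    }


def delta_metrics(reports: dict[str, StabilityReport]) -> DeltaMetrics:
    """Paired robustness contrasts from the four scenario reports."""
    needed = {"S-naive", "S-exposed", "R-naive", "R-exposed"}
    if set(reports) != needed:
        raise ValueError(f"expected reports keyed by {sorted(needed)}")
    ids = {r.community_id for r in reports.values()}
    if len(ids) > 1:
        raise ValueError("reports come from different communities")
    vals = {}
    for scope in SCOPES:
        vals[f"dR_{scope}"] = reports["R-naive"].scope(scope) - reports["S-naive"].scope(scope)
        vals[f"dE_{scope}"] = reports["R-exposed"].scope(scope) - reports["R-naive"].scope(scope)
        vals[f"dEs_{scope}"] = reports["S-exposed"].scope(scope) - reports["S-naive"].scope(scope)
    return DeltaMetrics(community_id=ids.pop(), **vals)
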