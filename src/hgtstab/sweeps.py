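"""Ensemble sweeps over gene mobility and community interaction structure.

A *mobility sweep* runs the four-scenario protocol on an ensemble of
communities at each mean conjugation rate on a (log-spaced) grid, producing
the ensemble mean and s.d. of each paired contrast (dR, dE, dEs) at each
scope, plus the mean background resistance frequency immediately before the
perturbation.  A *positivity-by-mobility sweep* repeats this over a grid of
interaction-positivity values, producing heatmap-shaped output.

By default the same community ensemble is reused across all mobility values
of a sweep (common random numbers): only the mean conjugation rate is
rescaled, reusing each community's stored per-pair noise.  This pairs cells
along the mobility axis and sharpens the curves; set ``paired=False`` to
draw an independent ensemble per cell instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .community import Community, ModelParams, generate_ensemble
from .experiment import run_quartet
from .metrics import SCOPES, DeltaMetrics, delta_metrics, quartet_reports

__all__ = [
    "SweepResult",
    "sweep_mobility",
    "sweep_positivity_by_mobility",
    "aggregate_cell",
    "DELTA_METRICS",
    "FREQ_METRICS",
]

DELTA_METRICS = tuple(
    f"{base}_{scope}" for base in ("dR", "dE", "dEs") for scope in SCOPES
)
FREQ_METRICS = ("freq_bg_naive", "freq_bg_exposed")


@dataclass
class SweepResult:
    """Aggregated sweep output.

    ``cell_stats`` is tidy: one row per (positivity, gamma_bar, metric) with
    columns mean, sd, n, n_missing.  ``records`` holds the underlying
    per-community values, one row per (positivity, gamma_bar, community).
    """

    gamma_grid: np.ndarray
    pm_grid: Optional[np.ndarray]
    n_per_cell: int
    seed: Optional[int]
    paired: bool
    cell_stats: pd.DataFrame
    records: pd.DataFrame

    def cell(self, metric: str, gamma_bar: float, positivity: Optional[float] = None) -> pd.Series:
        df = self.cell_stats
        m = (df["metric"] == metric) & np.isclose(df["gamma_bar"], gamma_bar)
        if positivity is not None:
            m &= np.isclose(df["positivity"], positivity)
        hit = df[m]
        if len(hit) != 1:
            raise KeyError(f"expected one cell, found {len(hit)}")
        return hit.iloc[0]

    def curve(self, metric: str, positivity: Optional[float] = None) -> pd.DataFrame:
        """Mean ± sd of one metric along the mobility grid."""
        df = self.cell_stats[self.cell_stats["metric"] == metric]
        if positivity is not None:
            df = df[np.isclose(df["positivity"], positivity)]
        return df.sort_values("gamma_bar").reset_index(drop=True)

    def grid(self, metric: str) -> pd.DataFrame:
        """Heatmap pivot (positivity rows x gamma columns) of cell means."""
        if self.pm_grid is None:
            raise ValueError("not a positivity sweep")
        df = self.cell_stats[self.cell_stats["metric"] == metric]
        return df.pivot(index="positivity", columns="gamma_bar", values="mean")

    def to_json(self) -> str:
        return json.dumps(
            {
                "gamma_grid": self.gamma_grid.tolist(),
                "pm_grid": None if self.pm_grid is None else self.pm_grid.tolist(),
                "n_per_cell": self.n_per_cell,
                "seed": self.seed,
                "paired": self.paired,
                "cell_stats": self.cell_stats.to_dict(orient="list"),
                "records": self.records.to_dict(orient="list"),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SweepResult":
        d = json.loads(text)
        return cls(
            gamma_grid=np.asarray(d["gamma_grid"], dtype=float),
            pm_grid=None if d["pm_grid"] is None else np.asarray(d["pm_grid"], dtype=float),
            n_per_cell=d["n_per_cell"],
            seed=d["seed"],
            paired=d["paired"],
            cell_stats=pd.DataFrame(d["cell_stats"]),
            records=pd.DataFrame(d["records"]),
        )


def aggregate_cell(
    deltas: Sequence[DeltaMetrics],
    freqs: Optional[Sequence[dict]] = None,
) -> dict[str, dict]:
    """Mean / sample s.d. / counts per metric over one grid cell."""
    if len(deltas) == 0:
        raise ValueError("empty cell")
    out: dict[str, dict] = {}
    for name in DELTA_METRICS:
        vals = np.array([getattr(d, name) for d in deltas], dtype=float)
        out[name] = _stats(vals)
    if freqs is not None:
        for name in FREQ_METRICS:
            vals = np.array([f[name] for f in freqs], dtype=float)
            out[name] = _stats(vals)
    return out


def _stats(vals: np.ndarray) -> dict:
    ok = vals[~np.isnan(vals)]
    return {
        "mean": float(ok.mean()) if ok.size else float("nan"),
        "sd": float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
        "n": int(ok.size),
        "n_missing": int(np.isnan(vals).sum()),
    }


def _community_rows(
    community: Community,
    gamma_grid: np.ndarray,
    params: ModelParams,
    positivity: float,
    community_index: int,
) -> list[dict]:
    """Run the quartet at every mobility value for one community."""
    rows = []
    for gb in gamma_grid:
        comm = community.with_gamma_bar(float(gb))
        quartet = run_quartet(comm, params)
        reports = quartet_reports(quartet, comm, params)
        dm = delta_metrics(reports)
        row = {
            "positivity": positivity,
            "gamma_bar": float(gb),
            "community": community_index,
            "focal": comm.focal,
            "freq_bg_naive": quartet["R-naive"].background_resistance_freq_before(comm),
            "freq_bg_exposed": quartet["R-exposed"].background_resistance_freq_before(comm),
        }
        row.update(dm.as_dict())
        for label, rep in reports.items():
            row[f"bray_{label}"] = rep.bray_curtis
            row[f"robustness_whole_{label}"] = rep.whole
        rows.append(row)
    return rows


def _aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    stats = []
    metrics = list(DELTA_METRICS) + list(FREQ_METRICS)
    for (pm, gb), grp in records.groupby(["positivity", "gamma_bar"], sort=True):
        for name in metrics:
            vals = grp[name].to_numpy(dtype=float)
            st = _stats(vals)
            stats.append({"positivity": pm, "gamma_bar": gb, "metric": name, **st})
    return pd.DataFrame(stats)


def sweep_mobility(
    params: ModelParams,
    gamma_grid: Sequence[float],
    n_communities: int,
    seed: int,
    paired: bool = True,
    n_jobs: int = 1,
    _positivity: Optional[float] = None,
    _seed_seq: Optional[np.random.SeedSequence] = None,
) -> SweepResult:
    """Sweep mean gene mobility at fixed community structure."""
    gamma_grid = np.asarray(sorted(gamma_grid), dtype=float)
    if np.any(gamma_grid < 0):
        raise ValueError("gamma grid must be nonnegative")
    pm = params.positivity if _positivity is None else _positivity
    seq = np.random.SeedSequence(seed) if _seed_seq is None else _seed_seq

    jobs = []
    if paired:
        ensemble = generate_ensemble(params, n_communities, seq)
        for i, comm in enumerate(ensemble):
            jobs.append((comm, gamma_grid, i))
    else:
        for g_idx, (gb, child) in enumerate(zip(gamma_grid, seq.spawn(len(gamma_grid)))):
            ensemble = generate_ensemble(params.replace(gamma_bar=float(gb)), n_communities, child)
            for i, comm in enumerate(ensemble):
                jobs.append((comm, np.array([gb]), i))

    chunks = Parallel(n_jobs=n_jobs)(
        delayed(_community_rows)(comm, grid, params, pm, idx)
        for comm, grid, idx in jobs
    )
    records = pd.DataFrame([row for chunk in chunks for row in chunk])
    records = records.sort_values(
        ["positivity", "gamma_bar", "community"], kind="mergesort"
    ).reset_index(drop=True)
    return SweepResult(
        gamma_grid=gamma_grid,
        pm_grid=None,
        n_per_cell=n_communities,
        seed=seed if _seed_seq is None else None,
        paired=paired,
        cell_stats=_aggregate_records(records),
        records=records,
    )


def sweep_positivity_by_mobility(
    params: ModelParams,
    pm_grid: Sequence[float],
    gamma_grid: Sequence[float],
    n_communities: int,
    seed: int,
    paired: bool = True,
    n_jobs: int = 1,
) -> SweepResult:
    """Full factorial sweep over interaction positivity and gene mobility."""
    pm_grid = np.asarray(sorted(pm_grid), dtype=float)
    if np.any(pm_grid < 0) or np.any(pm_grid > 1):
        raise ValueError("positivity grid must lie in [0, 1]")
    seq = np.random.SeedSequence(seed)
    parts = []
    for pm, child in zip(pm_grid, seq.spawn(len(pm_grid))):
        sub = sweep_mobility(
            params.replace(positivity=float(pm)),
            gamma_grid,
            n_communities,
            seed=seed,
            paired=paired,
            n_jobs=n_jobs,
            _positivity=float(pm),
            _seed_seq=child,
        )
        parts.append(sub.records)
    records = pd.concat(parts, ignore_index=True)
    return SweepResult(
        gamma_grid=np.asarray(sorted(gamma_grid), dtype=float),
        pm_grid=pm_grid,
        n_per_cell=n_communities,
        seed=seed,
        paired=paired,
        cell_stats=_aggregate_records(records),
        records=records,
    )
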