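"""Random community generation for the two-compartment gLV-HGT model.

A community is a random ecological interaction network of ``N`` taxa plus a
conjugation-rate matrix describing how fast a plasmid-borne resistance gene
moves between taxa.  Interaction presence, sign and magnitude follow the
classic random-matrix construction: each ordered off-diagonal term ``a_ij``
is present with probability ``C`` (connectance), positive with probability
``positivity`` and its magnitude is drawn from a half-normal distribution.
Intrinsic growth rates are then calibrated so the plasmid-free, stressor-free
system has an equilibrium with every abundance at 1, and only communities for
which that equilibrium is linearly asymptotically stable are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "Community",
    "sample_interactions",
    "calibrate_growth_rates",
    "check_linear_stability",
    "sample_conjugation_matrix",
    "generate_ensemble",
    "EnsembleRejectionError",
]


class EnsembleRejectionError(RuntimeError):
    """Raised when the stability rejection sampler exceeds its attempt cap."""


@dataclass(frozen=True)
class ModelParams:
    """Model and protocol parameters.

    Ecological parameters
    ---------------------
    N : taxon count.
    C : connectance — probability that any ordered off-diagonal interaction
        term is nonzero.
    sigma : scale of the half-normal distribution of interaction magnitudes
        (the standard deviation of the parent normal).
    s : self-inhibition coefficient, identical across taxa.
    positivity : fraction of present interaction terms that are positive
        (0 = purely competitive, 1 = purely cooperative).

    Evolutionary parameters
    -----------------------
    c : growth-rate cost of carrying the resistance gene.
    gamma_bar : mean per-cell conjugation rate.
    gamma_rel_sd : relative s.d. of per-pair conjugation noise; the noise term
        eps_ij ~ Normal(0, (gamma_rel_sd * gamma_bar)^2).
    delta : segregation-loss rate (plasmid-bearing cells reverting to
        plasmid-free); 0 disables segregation loss.
    segregation_mode : "return" sends the delta flux back to the susceptible
        compartment; "loss" removes it outright.

    Stressor parameters
    -------------------
    beta_s, beta_r : kill susceptibility of susceptible / resistant cells.
    D_perturb : stressor dose during the perturbation window.
    D_prior : stressor dose during the adjustment phase when the community
        has prior low-level exposure.

    Protocol constants
    ------------------
    t_adjust, t_perturb, t_recover : phase durations in model time units.
    x0 : initial total abundance per taxon at the start of adjustment.
    initial_resistant_fraction : fraction of the focal taxon's initial
        abundance placed in the resistant compartment in R-scenarios.
    extinction_floor : abundances below this are treated as extinct at phase
        boundaries and in the metrics.
    rtol, atol : integrator tolerances.
    max_attempts : cap on rejection-sampling attempts per community.
    """

    N: int = 10
    C: float = 0.7
    sigma: float = 0.015
    s: float = 0.1
    positivity: float = 0.5
    c: float = 0.005
    gamma_bar: float = 0.5e-3
    gamma_rel_sd: float = 0.1
    delta: float = 0.0
    segregation_mode: str = "return"
    beta_s: float = 1.0
    beta_r: float = 0.1
    D_perturb: float = 0.1
    D_prior: float = 0.01
    t_adjust: float = 500.0
    t_perturb: float = 25.0
    t_recover: float = 500.0
    x0: float = 0.1
    initial_resistant_fraction: float = 1.0
    extinction_floor: float = 1e-9
    rtol: float = 1e-8
    atol: float = 1e-10
    max_attempts: int = 1000
    pairwise_presence: bool = False

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        for name in ("C", "positivity", "initial_resistant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "sigma", "s", "c", "gamma_bar", "gamma_rel_sd", "delta",
            "beta_s", "beta_r", "D_perturb", "D_prior",
            "t_adjust", "t_perturb", "t_recover", "x0",
            "extinction_floor", "rtol", "atol",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.beta_r > self.beta_s:
            raise ValueError("beta_r must not exceed beta_s")
        if self.segregation_mode not in ("return", "loss"):
            raise ValueError("segregation_mode must be 'return' or 'loss'")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    @property
    def gamma_noise_sd(self) -> float:
        """Absolute s.d. of the conjugation noise term eps_ij."""
        return self.gamma_rel_sd * self.gamma_bar

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Community:
    """One sampled ecological network plus its gene-mobility structure.

    ``A[i, j]`` is the per-capita effect of taxon ``j`` on taxon ``i`` (zero
    diagonal; self-inhibition lives in ``s_vec``).  ``Gamma[i, j]`` is the
    per-cell conjugation rate from donor taxon ``j`` into recipient ``i``.
    ``gamma_noise`` stores the standard-normal draws behind ``Gamma`` so the
    same community can be re-equipped with a plasmid of different mean
    mobility (common random numbers across a mobility sweep).
    """

    A: np.ndarray
    s_vec: np.ndarray
    r_vec: np.ndarray
    Gamma: np.ndarray
    c: float
    focal: int
    gamma_bar: float = 0.0
    gamma_rel_sd: float = 0.0
    gamma_noise: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    seed_entropy: Optional[int] = None
    n_rejected: int = 0

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def background(self) -> np.ndarray:
        """Indices of all taxa except the focal one."""
        return np.array([i for i in range(self.N) if i != self.focal])

    def with_gamma_bar(self, gamma_bar: float) -> "Community":
        """Re-equip the community with a plasmid of different mean mobility.

        Reuses the stored per-pair noise draws, so Gamma scales exactly with
        the new mean rate (truncation at zero is re-applied).
        """
        if self.gamma_noise is None:
            raise ValueError("community carries no stored conjugation noise")
        Gamma = gamma_bar * np.clip(1.0 + self.gamma_rel_sd * self.gamma_noise, 0.0, None)
        if self.mask is not None:
            Gamma = Gamma * self.mask
        return replace(self, Gamma=Gamma, gamma_bar=gamma_bar)

    def to_json(self) -> str:
        d = {
            "A": self.A.tolist(),
            "s_vec": self.s_vec.tolist(),
            "r_vec": self.r_vec.tolist(),
            "Gamma": self.Gamma.tolist(),
            "c": self.c,
            "focal": int(self.focal),
            "gamma_bar": self.gamma_bar,
            "gamma_rel_sd": self.gamma_rel_sd,
            "gamma_noise": None if self.gamma_noise is None else self.gamma_noise.tolist(),
            "mask": None if self.mask is None else self.mask.tolist(),
            "seed_entropy": self.seed_entropy,
            "n_rejected": self.n_rejected,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "Community":
        d = json.loads(text)
        arr = lambda x: None if x is None else np.asarray(x, dtype=float)
        return cls(
            A=arr(d["A"]),
            s_vec=arr(d["s_vec"]),
            r_vec=arr(d["r_vec"]),
            Gamma=arr(d["Gamma"]),
            c=d["c"],
            focal=d["focal"],
            gamma_bar=d["gamma_bar"],
            gamma_rel_sd=d["gamma_rel_sd"],
            gamma_noise=arr(d["gamma_noise"]),
            mask=arr(d["mask"]),
            seed_entropy=d["seed_entropy"],
            n_rejected=d["n_rejected"],
        )


def sample_interactions(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Draw a signed random interaction matrix.

    Each ordered off-diagonal entry is nonzero with probability ``params.C``;
    nonzero magnitudes are half-normal with scale ``params.sigma``; each
    nonzero entry is positive with probability ``params.positivity``.  With
    ``pairwise_presence`` the presence indicator is shared by (i, j) and
    (j, i) while signs and magnitudes stay independent per ordered entry.
    """
    N = params.N
    if params.pairwise_presence:
        upper = rng.random((N, N)) < params.C
        present = np.triu(upper, 1)
        present = present | present.T
    else:
        present = rng.random((N, N)) < params.C
    magnitude = np.abs(rng.normal(0.0, params.sigma, size=(N, N)))
    sign = np.where(rng.random((N, N)) < params.positivity, 1.0, -1.0)
    A = present * sign * magnitude
    np.fill_diagonal(A, 0.0)
    return A


def calibrate_growth_rates(A: np.ndarray, s) -> np.ndarray:
    """Growth rates placing the plasmid-free equilibrium at all-ones.

    Substituting X_j = 1 into the growth equation and requiring a zero
    derivative gives ``r_i = s_i - sum_j a_ij``.  Cooperative communities
    therefore trade intrinsic growth for growth via partners, which damps
    explosive dynamics.
    """
    A = np.asarray(A, dtype=float)
    s_vec = np.broadcast_to(np.asarray(s, dtype=float), (A.shape[0],))
    return s_vec - A.sum(axis=1)


def check_linear_stability(community: Community) -> bool:
    """Linear asymptotic stability of the all-ones plasmid-free equilibrium.

    At the calibrated fixed point the Jacobian of the gLV system reduces to
    ``A - diag(s)``; stability requires every eigenvalue to have a strictly
    negative real part.
    """
    J = community.A - np.diag(community.s_vec)
    return bool(np.all(np.linalg.eigvals(J).real < 0.0))


def sample_conjugation_matrix(
    params: ModelParams,
    rng: np.random.Generator,
    mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the conjugation-rate matrix Gamma and its underlying noise.

    ``Gamma[i, j] = gamma_bar + eps_ij`` with ``eps_ij`` independent normal
    noise of s.d. ``gamma_rel_sd * gamma_bar``; negative draws are truncated
    to zero.  An optional binary mask zeroes forbidden donor->recipient pairs
    (e.g. transfer restricted to close relatives).

    Returns ``(Gamma, z)`` where ``z`` holds the standard-normal draws, kept
    so the same community can be rescaled to another mean mobility.
    """
    N = params.N
    z = rng.standard_normal((N, N))
    Gamma = np.clip(params.gamma_bar * (1.0 + params.gamma_rel_sd * z), 0.0, None)
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if mask.shape != (N, N):
            raise ValueError(f"mask must be {N}x{N}")
        Gamma = Gamma * mask
    return Gamma, z


def generate_community(
    params: ModelParams,
    rng: np.random.Generator,
    mask: Optional[np.ndarray] = None,
    seed_entropy: Optional[int] = None,
) -> Community:
    """Rejection-sample one calibrated, linearly stable community."""
    s_vec = np.full(params.N, params.s)
    for attempt in range(params.max_attempts):
        A = sample_interactions(params, rng)
        r_vec = calibrate_growth_rates(A, s_vec)
        Gamma, z = sample_conjugation_matrix(params, rng, mask=mask)
        focal = int(rng.integers(params.N))
        comm = Community(
            A=A, s_vec=s_vec, r_vec=r_vec, Gamma=Gamma, c=params.c,
            focal=focal, gamma_bar=params.gamma_bar,
            gamma_rel_sd=params.gamma_rel_sd, gamma_noise=z,
            mask=None if mask is None else np.asarray(mask, dtype=float),
            seed_entropy=seed_entropy, n_rejected=attempt,
        )
        if check_linear_stability(comm):
            return comm
    raise EnsembleRejectionError(
        f"no linearly stable community found in {params.max_attempts} draws; "
        "parameter regime likely infeasible"
    )


def generate_ensemble(
    params: ModelParams,
    n_communities: int,
    rng: "np.random.Generator | int | np.random.SeedSequence",
    mask: Optional[np.ndarray] = None,
) -> list[Community]:
    """Generate an ensemble of stable communities.

    Each community is drawn from its own deterministic substream of the
    supplied seed, so ensembles are reproducible and order-independent under
    parallel execution.
    """
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    if isinstance(rng, np.random.Generator):
        seq = rng.bit_generator.seed_seq  # type: ignore[attr-defined]
    elif isinstance(rng, np.random.SeedSequence):
        seq = rng
    else:
        seq = np.random.SeedSequence(rng)
    children = seq.spawn(n_communities)
    out = []
    for i, child in enumerate(children):
        sub = np.random.default_rng(child)
        entropy = int(child.generate_state(1, dtype=np.uint32)[0])
        out.append(generate_community(params, sub, mask=mask, seed_entropy=entropy))
    return out
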