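# Methods

## Model

`hgtstab` simulates deterministic continuous-time dynamics of an
`N`-taxon community in which every taxon is split into a plasmid-free
(susceptible) and a plasmid-bearing (resistant) population. The ecology is
generalized Lotka–Volterra: per-capita growth of either compartment of
taxon `i` is `r_i − s_i·T_i + Σ_j a_ij·T_j`, where `T_k = Xs_k + Xr_k` is
the *total* abundance of taxon `k` — a partner's resistant cells compete
or cooperate exactly like its susceptible cells. On top of the ecology:

* resistant cells grow at `r_i − c` (plasmid carriage cost);
* the gene transfers by mass action, susceptible cells of taxon `i`
  acquiring it from resistant cells of any taxon `j` at rate
  `γ_ij · Xs_i · Xr_j` (within-taxon transfer included, `j = i`);
* a stressor at dose `D` kills susceptible cells at rate `β_s·D` and
  resistant cells at `β_r·D` (resistance is protective but not absolute);
* optionally, segregation loss converts resistant cells to susceptible at
  rate `δ` (`segregation_mode="return"`), or removes them outright
  (`"loss"`) — the interpretation of segregants is genuinely open, so both
  forms are provided; the default `δ = 0` disables the process entirely.

The model is deterministic; all randomness lives in community
construction. There is no demographic noise, no de novo mutation, no
multi-plasmid competition.

## Community construction

Each ordered off-diagonal interaction `a_ij` is independently nonzero with
probability `C`, positive with probability `positivity` (P_m), with
magnitude drawn half-normal with scale `sigma`. Presence and sign are
sampled per ordered element, so `a_ij` and `a_ji` are independent; a
`pairwise_presence` switch shares the presence indicator across the pair
for users who prefer the unordered reading. `sigma` is interpreted as the
scale of the half-normal's parent normal, so the mean interaction
magnitude is `sigma·sqrt(2/π)`.

Growth rates are calibrated as `r_i = s_i − Σ_j a_ij`, which places an
equilibrium of the plasmid-free, stressor-free system at all-ones and
builds in a trade-off: taxa receiving cooperative support have lower
intrinsic growth. A community is accepted only if that equilibrium is
linearly asymptotically stable (all eigenvalues of `A − diag(s)` have
negative real part); unstable draws are rejected whole and redrawn, up to
`max_attempts = 1000` per community, preserving the stated interaction
statistics among accepted communities. Conjugation rates are
`γ_ij = γ̄(1 + 0.1·z_ij)` with `z_ij` standard normal, truncated at zero —
algebraically identical to `γ̄ + ε_ij` with `ε_ij ~ N(0, (0.1 γ̄)²)`.
Storing `z` lets a sweep re-equip the same community with a plasmid of any
mean mobility exactly (common random numbers; see Sweeps). An optional
binary mask zeroes donor→recipient pairs to emulate host-range or spatial
constraints on conjugation.

Ensembles are seeded through `numpy.random.SeedSequence.spawn`, one
substream per community, so a single top-level seed reproduces every
matrix bitwise and communities can be processed in any order or in
parallel.

## Perturbation protocol

Every community is assayed under a 2×2 design — focal taxon carries the
gene or not (R/S), adjustment with or without low-level stressor
(exposed/naive) — using the same three-phase schedule with piecewise-
constant dose and state handoff between phases:

1. **adjustment**, `t_adjust = 500` time units at `D = 0.01` (exposed) or
   `0` (naive), from equal per-taxon abundance `x0 = 0.1` (well below the
   equilibrium at 1, so the phase performs genuine assembly);
2. **perturbation**, `t_perturb = 25` at `D = 0.1`;
3. optional **recovery**, `t_recover = 500` at `D = 0`, retained only for
   the return-time metric.

In R-scenarios the focal taxon starts entirely resistant
(`initial_resistant_fraction = 1`, configurable), mirroring a clonal
introduction. Per-taxon totals are recorded at exactly `t_adjust`
(`A_before`) and `t_adjust + t_perturb` (`A_after`), together with
resistance frequencies `Xr/(Xs+Xr)`; background-community frequency is
abundance-weighted. Populations below the extinction floor (`1e-9`,
orders of magnitude under any dynamical scale) are zeroed at phase
boundaries so numerically extinct populations cannot revive.

## Stability metrics

`Stability_i = min(0, log10(A_after_i / A_before_i))` — gains are capped
at zero so only losses count. Robustness is the mean over a scope: whole
community, background (all but focal), or focal alone; the whole-community
value decomposes exactly as `((N−1)·background + focal)/N`. Taxa extinct
before the perturbation are recorded missing and excluded from means (the
exclusion count is reported); taxa driven extinct *by* the perturbation
score the finite `log10(floor/A_before)` rather than −∞, keeping means
defined and monotone in severity.

The paired contrasts per community are `dR = R-naive − S-naive` (effect of
the gene's initial presence) and `dE = R-exposed − R-naive` (effect of
prior exposure, gene present — the contrast that remains meaningful as a
function of gene mobility). The susceptible-pair exposure contrast `dEs =
S-exposed − S-naive` is computed alongside. Supplementary metrics:
Bray–Curtis dissimilarity between `A_before` and `A_after` (computed on
absolute abundances, since the model tracks them; callers can renormalize
if they want the compositional variant) and return time — the first time
in the recovery phase at which every non-extinct taxon is within 5%
(configurable) of its pre-perturbation abundance and stays there for the
rest of the horizon.

## Sweeps

`sweep_mobility` runs the quartet on an ensemble at each mean mobility of
a log-spaced grid; `sweep_positivity_by_mobility` adds a positivity axis
for heatmaps. By default the *same* ensemble is reused across all mobility
values of a sweep, with only `γ̄` rescaled through the stored noise —
common random numbers that pair cells along the mobility axis and sharpen
the curves; `paired=False` draws an independent ensemble per cell instead
(both modes exist because either design is defensible for the published
heatmaps). Cells aggregate to mean and sample s.d. (ddof = 1) per metric,
with missing-value counts. Communities are embarrassingly parallel
(`n_jobs` via joblib); results are invariant to worker count because all
randomness is fixed at ensemble generation.

Default desk grids are 11–21 mobility points over `[1e-6, 1e-2]` and
ensembles of 30–100 communities; the full 101-point grids and 100-repeat
ensembles used for publication-scale figures are plain configuration.

## Numerical choices

Integration uses `scipy.integrate.solve_ivp` with LSODA and an analytic
Jacobian, `rtol = 1e-8`, `atol = 1e-10`; halving the tolerances changes
reported abundances by far less than 0.1% (tested). On 1–2 taxon systems
the adaptive solution matches a fixed-step classical RK4 reference at step
`1e-3` to within `1e-6` relative error. Solver failures raise, carrying
the scenario label. Abundances are clipped at zero on output (integrator
error of order `atol` can make them infinitesimally negative); the
extinction floor is applied only at phase boundaries.

## What the generator emulates — and what it does not

The synthetic ensembles reproduce the *statistical* structure of diverse
microbiomes — random sign-mixed interactions at fixed connectance, taxa of
equal carrying capacity, a single costly mobile gene — under which the
qualitative results hold: a resistance gene raises whole-community
robustness at any mobility; the background benefits only at high mobility
or after prior exposure (strongest at intermediate mobility); low-mobility
genes *destabilize* the background of purely competitive communities via
the focal taxon's escape from competitive release, and prior exposure can
slightly destabilize a competitive focal taxon at intermediate mobility.
Real communities differ in ways the model deliberately omits: uneven
abundances and richness, saturating (non-gLV) functional responses,
phylogenetically structured transfer (only a user-supplied mask here),
environmental fluctuation, and evolutionary routes to resistance other
than conjugation. Passing tests therefore validate the mechanism, not
quantitative predictions for any particular real microbiome.

One scale note: the focal-taxon exposure penalty in competitive
communities (`dE_focal < 0`) is confined to a narrow intermediate-mobility
band (γ̄ ≈ 3×10⁻⁴–10⁻³ at the default parameters); coarse decade-spaced
grids straddle it, which is why the dedicated competitive sweep scans
`[1e-5, 1e-3]` and reports the minimizing mobility.

## Known limitations

* The gLV form can, in principle, produce unbounded trajectories for
  extreme parameter choices; the stability-filtered ensembles at the
  default interaction scale do not exhibit this, but user-supplied
  communities are not screened.
* Return time is reported relative to the discrete reporting grid of the
  recovery phase (resolution `t_recover/500` by default).
* The rejection sampler conditions the ensemble on local stability of the
  all-ones equilibrium; at parameter regimes where most draws are unstable
  (strong, dense mutualism) the accepted communities are a biased subset
  of the raw interaction distribution, and generation aborts with an
  explicit error beyond `max_attempts`.
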