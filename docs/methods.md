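# Methods

## Model

`camnoise` treats the free-calcium content of a small, well-mixed voxel as a
stochastic process shaped by reversible buffer binding and, optionally,
diffusive exchange with constant-concentration surroundings:

    Ca + B_j <-> CaB_j        (on-rate k+_j, off-rate k-_j),   j = 1..M
    Ca       <-> exterior     (hop rate c_d = D/L^2, constant-pool influx)

Units are fixed package-wide: concentrations in uM, time in ms, volume in fl
(= um^3), so a 1 uM species in 1 fl has 602.214076 molecules (Avogadro's
number x 1e-21). Bimolecular copy-number rates are c+ = k+/(602.214076 V);
monomolecular rates are unchanged by the volume. This conversion makes the
copy-number propensity c+ X Y numerically equal to the deterministic flux
k+ x y, which is what lets closed-form results derived in concentration
units (e.g. the autocorrelation time) be compared directly against
simulated copy-number series. The voxel is assumed cubic, L = V^(1/3).

At equilibrium the bound fraction of each buffer is Z_j = B_T,j /
(1 + K_D,j / x), with K_D = k-/k+ always derived from the rate pair and
never stored, so a rounded table value can never drift out of consistency
with the rates.

## Excess buffer approximation and the OU surrogate

With the free buffer pinned at its equilibrium value (valid far from buffer
saturation, i.e. small K_D/B_T), calcium kinetics linearize:
dx/dt = -K1 x + K2 with K1 = k+ y_eq + k-, K2 = k- x_T, giving
mono-exponential relaxation with time constant 1/K1. The same reduction of
the chemical Langevin equation yields an Ornstein-Uhlenbeck-like process
whose stationary parameters are evaluated at equilibrium:

    mu    = X_eq                                          (counts)
    tau   = 1 / (sum_j (k+_j y_eq,j + k-_j) + c_d)        (ms)
    sigma = sqrt(sum_j (c+_j X Y_j + c-_j Z_j) + 2 c_d X) (counts ms^-1/2)
    Var   = sigma^2 tau / 2

tau is volume-independent; sigma grows as sqrt(V). Buffer and diffusion
contributions are combined additively in tau's denominator — each channel
adds its rate to the linearized drift — even though the single-mechanism
formulas are usually quoted separately. mu is evaluated through the general
stationary expression (off-rates times available calcium over total
relaxation rate) and collapses algebraically to X_eq in every system class;
the identity is exercised as a property test rather than assumed.

Note on one reference value: for the CaM system with D = 0.2 um^2/ms the
formula gives tau = 0.366 ms at V = 0.125 fl (0.468 ms at 1 fl). Literature
figures sometimes quote 0.190 ms for this configuration without stating the
voxel size; no volume consistent with c_d = D/L^2 reproduces it, so no test
relies on that number.

## Engines

* **SSA** — Gillespie's direct method over the binding/unbinding channels
  plus, with diffusion, efflux (c_d X) and constant-pool influx at the fixed
  real-valued rate c_d X_eq. Initial copy numbers are the equilibrium
  values rounded half-to-even (free calcium overridable for perturbation
  studies). Jump paths are linearly interpolated onto a uniform grid
  (default dt = 0.01 ms) before statistical processing; a zero-order-hold
  mode exists for master-equation comparisons where the exact path measure
  matters.
* **CLE** — Euler-Maruyama, one Gaussian increment per reaction channel
  with variance propensity x dt, signed by stoichiometry and shared by all
  species the channel touches (equivalent to, and cheaper than, separate
  Wiener terms per species). Propensity arguments are clamped at zero
  inside square roots, species at zero after each step; clamp counts are
  recorded in `meta['n_clamped']` and logged, keeping the impact of the
  Gaussian approximation near zero copy numbers auditable.
* **CLE-EBA** — the reduced equation with free buffer pinned. For one
  buffer it is the scalar SDE dX = -(C1+c_d)(X - X_eq) dt + sigma_t dW with
  sigma_t^2 = c+ X Y_eq + c- Z + c_d (X + X_eq) and Z = X_T - X (X_T the
  equilibrium total, so the drift's fixed point is exactly X_eq);
  `freeze_sigma=True` pins sigma_t at its equilibrium value, making the
  engine literally an Euler OU integrator — a reduction the tests verify
  numerically against `oup_simulate` with a shared seed. For M > 1 each
  bound pool keeps its own reduced dynamics with channel noise shared with
  X.
* **OUP** — dX = -(X - mu)/tau dt + sigma dW, by Euler-Maruyama (default,
  matching the other engines' step) or the exact AR(1) discretization
  (unbiased at any step). Both recursions are evaluated as linear filters,
  so million-step paths are effectively free.

Every engine takes one integer seed feeding a single named NumPy
generator; identical seeds give identical paths within this implementation
(not across RNG algorithms).

## Estimators

* ACF: mean-removed, biased (1/N) sample autocorrelation (positive
  semidefinite by construction), normalized at lag zero.
* tau-hat from equilibrium noise: OLS line through log(ACF) over the
  contiguous initial lags above 0.05, tau = -1/slope. Chosen over ACF
  integration because every process in scope is mono-exponential by
  construction and the log fit ignores the noisy tail. The estimator's
  single-run spread scales like tau sqrt(tau/T) and it carries a
  noticeable upward finite-sample bias below ~5 x 10^3 correlation times
  per window, so scenario runners use >= 10^4 tau windows and average over
  seeds.
* tau-hat from relaxation: OLS on log|X_t - x_eq| over the initial window
  where the deviation exceeds 10% of its starting value, wrong-side points
  dropped. Relaxations are fitted per trajectory and tau-hat averaged over
  n = 10 runs, not fitted to the averaged trace. Engines that conserve
  total calcium (SSA, CLE) relax to the equilibrium of the *perturbed*
  totals; that value (from the bracketed root solve) is used as the fit
  asymptote, while the reduced/OU engines relax to the unperturbed mean.
* CME oracle: for a single closed buffer the conservation laws collapse
  the state onto X alone, a finite birth-death chain (integer totals by
  half-even rounding) whose stationary law is the null space of the
  tridiagonal generator. Capacity is capped at 200 total calcium ions /
  2000 buffer molecules. Tests cross-check it against the independent
  detailed-balance product form and against sojourn-weighted SSA occupancy.

## Double-well driver

V(X) = -a/2 X^2 + b/4 X^4 with a = b = 1 by default (minima +/-1, barrier
1/4 — the canonical normalization of the colored-noise literature), first
order Euler at dt = 0.01 ms, driven additively: X_{k+1} = X_k +
(aX_k - bX_k^3) dt + xi_k. The supplied noise samples enter directly as
increments (scaling them by sqrt(dt) recovers the white-noise limit), and
their mean is removed inside the integrator to respect the potential's
symmetry. Defaults for the driving OU noise, where the source conditions
are unstated, were fixed once: sigma = 0.6, t_end = 2000 ms per seed. At
tau = 0.01 ms the drive is effectively white with diffusion ~0.09, giving
a Kramers hopping time of tens of ms — frequent, noise-timed transitions.
At tau = 0.75 ms the persistent increments dominate the restoring force,
so the state tracks the noise sign with long two-state residences and
overshoots the minima; coupling is therefore quantified by the Pearson
correlation and the L1 distance between the joint (noise, state) mass and
the product of its marginals, not by point values of the trajectory. A
`match_variance` option rescales sigma by 1/sqrt(tau) for
equal-stationary-variance comparisons; the tau-ordering of the coupling
persists either way.

## Synthetic study conditions

No external data exists; all inputs are the shipped kinetics table
(calmodulin, troponin C, parvalbumin, EGTA, Fluo-4, OGB-5N with their
literature on/off rates and total concentrations) plus scenario defaults:
resting calcium 0.1 uM, voxels of 0.125 or 1.0 fl, D = 0.2 um^2/ms when
diffusion is on, perturbations from 1.0 uM, dt = 0.01 ms. The generator
therefore emulates a homogeneous, well-mixed voxel with a single binding
site per buffer and no channel fluxes, pH/Mg competition, buffer
diffusion, or spatial gradients — passing tests say nothing about those
effects in real microdomains. The table's CV column is carried as metadata
only; no definition (or reference volume) is available to recompute it.

## Problem sizes and numerical choices

Test and scenario run lengths are chosen to keep estimator error a few
times smaller than the asserted tolerances: relaxation fits use ~8 tau
horizons and 10 seeds; equilibrium tau recovery uses 5 x 10^3 - 10^4 ms
windows; the master-equation comparison uses a ~17-ion synthetic system
(B_T = 5 uM, k+ = 1 uM^-1 ms^-1, k- = 1 ms^-1, V = 0.05 fl, 0.1 uM
calcium) run for > 10^6 events; the OU engine checks use 10^6 exact steps.
Euler discretization at dt = 0.01 ms biases rates by ~K1 dt/2 (up to ~12%
for the fastest dyes with the Euler OU engine), which stays inside the 15%
agreement band used for cross-engine identities. Root solves bracket on
[0, x_T] (the mapped function is strictly increasing, so the bracket is
guaranteed); equilibrium relations are evaluated in the x/(x + K_D) form
that is well-defined at x = 0.

## Known limitations

* The Langevin engines' zero-clamping slightly inflates the stationary
  mean when the mean copy number is O(1-10) (visible at V <= 0.125 fl);
  the clamp counter makes this measurable.
* tau-hat estimators assume mono-exponential decorrelation; strongly
  separated multi-buffer timescales produce a biexponential ACF that the
  head fit summarizes by its fast component mixture.
* The constant-pool diffusion model keeps the exterior at equilibrium;
  there is no spatial resolution, channel gating, or buffer transport.
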