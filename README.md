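# camnoise

Stochastic simulation and analysis of calcium concentration fluctuations in
buffered femtoliter microdomains.

At resting conditions (~100 nM free Ca2+) a 1 fl voxel holds only ~60
calcium ions, so the local concentration a channel, enzyme or sensor
actually sees is intrinsically noisy. `camnoise` models that noise for a
voxel containing one or more calcium buffers (calmodulin, troponin C,
parvalbumin, EGTA, Fluo-4, OGB-5N, or custom kinetics) and optional
diffusive exchange with the surroundings. The central result it implements:
free-calcium noise is a *colored* (exponentially autocorrelated) process
whose parameters follow in closed form from the buffer kinetics via the
excess buffer approximation,

    mu    = X_eq,
    tau   = 1 / ( Σ_j (k+_j ỹ_j + k-_j) + c_d ),
    sigma = sqrt( Σ_j (c+_j X̃ Ỹ_j + c-_j Z̃_j) + 2 c_d X̃ ),

with stationary variance σ²τ/2 — an Ornstein-Uhlenbeck surrogate that can
replace a full stochastic simulation inside larger signaling models.

The package provides:

* **Four consistent engines** (`camnoise.simulate`): exact Gillespie SSA,
  chemical Langevin equation, its excess-buffer reduction, and the OU
  surrogate (Euler or exact discretization).
* **Closed-form noise parameters** (`camnoise.noise_theory`) and the
  chemistry/units layer (`camnoise.chemistry`) with a shipped buffer
  kinetics table.
* **Estimators** (`camnoise.analyze`): sample ACF, autocorrelation-time
  and relaxation fits, summary statistics, and an exact master-equation
  stationary solver for small systems.
* **A colored-noise-driven double well** (`camnoise.bistable`)
  demonstrating that noise *color*, not amplitude, controls how strongly a
  bistable target couples to calcium noise.
* **Scenario runners and a CLI** (`camnoise.experiments`, `camnoise`
  command) that regenerate the canonical figure/table datasets as TSV.

## Worked example

```python
import camnoise as cn

# calcium-calmodulin microdomain: 0.125 fl, 100 nM resting calcium
system = cn.make_system(cn.buffer_from_table("CaM"), volume=0.125, ca_eq=0.1)

p = cn.noise_params(system)
print(f"mu = {p.mu:.2f} counts, tau = {p.tau:.3f} ms, "
      f"sigma = {p.sigma:.3f}, Var = {p.variance:.2f}")

path = cn.ssa_simulate(system, t_end=10_000.0, seed=42)   # exact jump path
traj = cn.resample_path(path, dt=0.01).component("X")
st = cn.summary_stats(traj)
print(f"simulated: mean = {st.mean:.2f}, var = {st.sd**2:.2f}, "
      f"tau_hat = {st.tau_hat:.3f} ms")
```

prints

```
mu = 7.53 counts, tau = 0.516 ms, sigma = 5.348, Var = 7.38
simulated: mean = 7.54, var = 7.15, tau_hat = 0.525 ms
```

i.e. the voxel holds 7.5 free ions on average, fluctuations decorrelate in
about half a millisecond, and a single exact 10-second trajectory
reproduces the closed-form mean, variance and noise color within a few
percent. Adding a second buffer or diffusion shortens tau (e.g. CaM+EGTA
0.483 ms, CaM+Fluo-4 0.044 ms) and raises sigma — faster reaction channels
decorrelate the signal.

From the shell:

```sh
camnoise theory system.yaml
camnoise simulate --engine ssa --config system.yaml --t-end 1000 --seed 1 --out traj.tsv
camnoise analyze traj.tsv
camnoise bistable --tau 0.75 --t-end 2000 --seed 1 --out dw
camnoise reproduce fig3 --out results/fig3
```

where `system.yaml` is e.g.

```yaml
buffers: [CaM]
volume_fl: 0.125
ca_eq_uM: 0.1
```

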