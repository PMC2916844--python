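# ringmaps

Continuous-attractor ring networks that store **two correlated spatial maps**
or a **morph sequence** between two uncorrelated maps: the exact five-variable
mean-field reduction, the phase diagram of its solutions (homogeneous /
single ring / double ring / cylinder / amplitude-unstable), linear stability
analysis, a finite-N microscopic rate-network simulator, and the stimulation
protocols built on top of them (tuning curves, dynamical pattern separation,
a delayed shortest-path discrimination task, and slow-morph remapping with an
activity-correlation readout).

## Model in one paragraph

Each of N threshold-linear rate neurons carries an angle on map A and on
map B, built from a middle-map angle `theta` and a bounded offset `phi`
(`theta_{A,B} = theta ± d·phi`, `phi ~ U[-pi/2, pi/2]`); `d ∈ [0,1]`
interpolates from identical (`d=0`) to independent (`d=1`) maps.  The
coupling is the sum of one cosine harmonic per stored map minus uniform
inhibition, so the population dynamics closes exactly on five moments —
equivalently the order parameters (amplitude, bump size, map preference
`mu`, bump angle `psi0`, bump offset `x_phi`).  Depending on the coupling
strength and `d` the stable bump is a *single ring* (localized only on the
middle map), a *double ring* (localized in map A **or** B, `mu = ±|mu|`), or
a *cylinder* state localized in both maps at once with a marginal offset
direction — the regime responsible for unreliable static coding, dynamical
pattern separation under moving inputs, and the memory effect used by the
discrimination task.

## Layout

| module                | contents                                                                  |
|-----------------------|---------------------------------------------------------------------------|
| `ringmaps.geometry`   | correlated-map sampling, inverse transform, morph sequences, circular utilities |
| `ringmaps.meanfield`  | reduced dynamics (moments/order parameters), steady profiles, integrators, coupling kernels, field simulator |
| `ringmaps.phase`      | fixed-point solver, closed-form boundaries, regime classification, scans  |
| `ringmaps.stability`  | homogeneous 2-condition analysis, localized linearization, marginal modes |
| `ringmaps.network`    | finite-N coupling construction (dense or exact low-rank), RK45/Euler–Maruyama simulation, order-parameter estimation |
| `ringmaps.protocols`  | tuning curves, pattern separation, shortest-path task, slow morph         |
| `ringmaps.config` / `ringmaps.cli` | YAML configs, fixtures, manifests, command-line entry points |
| `ringmaps.presets`    | versioned parameter presets used by the protocols                          |
| `ringmaps.validation` | the acceptance-level experiments (shared by tests and the report script)  |

## CLI

All subcommands read a YAML config and write CSV outputs plus a
`manifest.json` (config hash, seed, code version); nonzero exit on solver
failure.

```sh
ringmaps fixtures --out fixtures/            # seeded configs, one per regime
ringmaps phase-scan  --config fixtures/single_ring.yaml --out out/ --nd 21 --nj 21
ringmaps simulate-mf --config fixtures/cylinder.yaml    --out out/
ringmaps simulate-net --config fixtures/double_ring.yaml --out out/
ringmaps tuning      --config fixtures/single_ring.yaml --out out/
ringmaps separation  --config fixtures/cylinder.yaml    --out out/
ringmaps discriminate --config fixtures/cylinder.yaml   --out out/ --n-trials 50
ringmaps morph       --config fixtures/cylinder.yaml    --out out/ --mode two_maps
```

## Notes on numerics

- Quadrature: trapezoid on a regular `(theta, phi)` product grid
  (256×129 default; protocol code uses 128×65 where convergence allows —
  pinned by resolution-doubling tests).
- Deterministic integration: adaptive RK45 (rtol 1e-6 / atol 1e-8); noisy
  runs: fixed-step Euler–Maruyama, `dt = tau/100`, noise in the input
  current only.
- Amplitude divergence is reported as an event on the trajectory (mean
  field) or a `SimulationError` carrying the last valid state (network),
  never swallowed.
- The N×N coupling is exactly low rank (2 vectors per stored map); above
  5000 neurons the product is evaluated implicitly with identical results.
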