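# aimforce

Analysis toolkit for the force-regulated activation of von Willebrand
factor (VWF): single-molecule force spectroscopy of the autoinhibitory
module (AIM) that shields the platelet-binding A1 domain, and bio-layer
interferometry (BLI) of A1 binding its receptor.

VWF only captures platelets where flow is strong enough to unfold the
AIM — a discontinuous module formed by the sequences flanking A1.  This
package implements the quantitative machinery that turns raw
optical-tweezer and biosensor measurements into that statement:

* **Worm-like chain (WLC) elasticity** — `F(x)·Lp/kBT = ¼(1−x/Lc)⁻² − ¼
  + x/Lc` — fitted to rupture (force, extension) data to read off the
  contour length `Lc` released by an unfolding event and hence the
  number of residues involved (26.6 nm ↔ ~67 residues at
  0.4 nm/residue).
* **Bell–Evans rupture kinetics** — `k_u(f) = k_u0·exp(f·γ_u/kBT)` —
  with the rupture-force density at constant loading rate `R_f`, its
  mode `f* = (kBT/γ_u)·ln(γ_u R_f/(k_u0 kBT))`, exact inverse-CDF
  sampling, and recovery of `(k_u0, γ_u)` from the `f*` vs `ln R_f`
  regression.  Transition-state stabilization between conditions is
  `ΔG₁₂ = kBT·ln(k₁/k₂)`.
* **Trace analysis** — rip detection in force-extension traces,
  measurement of unfolding extensions (force re-establishment
  definition), classification of pull cycles (cooperative whole-module
  unfolding vs sequential or partial sub-module events), refolding
  detection in relaxation traces, and force-binned Gaussian extension
  histograms — orchestrated into a reproducible pipeline.
* **Synthetic experiments** — a Monte-Carlo forward model of the
  tweezer assay (effective-spring tether, exact Bell–Evans rupture
  draws, WLC extension jumps, Gaussian force noise) with presets
  carrying the published parameters of all ten measured
  construct/additive conditions, plus a two-affinity-state BLI
  sensorgram generator.  Every analysis stage is testable against
  ground truth without any external data.
* **Two-site binding kinetics** — global multi-start fitting of the
  heterogeneous-ligand (two independent affinity states) model across a
  concentration series, and steady-state hyperbola fits with confidence
  intervals on the apparent K_D.

Fitting operations are scikit-learn-style estimators
(`WormLikeChainModel`, `BellEvansModel`, `TwoSiteBindingModel`,
`HyperbolicSteadyState`: `fit`/`predict`, `get_params`, fitted
attributes with trailing underscores), with plain functions (`fit_wlc`,
`fit_bell_evans`, `global_fit`, `steady_state_fit`, …) wrapping them.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate a realistic pulling experiment on the full AIM-A1 construct
(80 tethers cycled three times at each of 50–500 nm/s, σ = 0.3 pN force
noise — about a minute) and run the complete analysis:

```python
import aimforce as af

presets = af.published_presets()
cfg = af.SimulationConfig(construct=presets["AIM-A1"], n_tethers=80, seed=7)
experiment = af.simulate_experiment(cfg)
report = af.run_pipeline(experiment.traces, af.PipelineConfig())

g = report["groups"]["AIM-A1"]
wlc, be = g["wlc"], g["bell_evans"]
print(f"events detected: {g['n_events']} in {g['n_pull_traces']} pulls")
print(f"contour length:  {wlc['contour_length_nm']:.2f} +/- {wlc['stderr_contour_length_nm']:.2f} nm"
      f"  (~{wlc['n_residues']} residues)")
print(f"persistence len: {wlc['persistence_length_nm']:.2f} +/- {wlc['stderr_persistence_length_nm']:.2f} nm")
print(f"unstressed rate: {be['unstressed_rate_per_s']:.3f} /s   barrier position: {be['barrier_position_nm']:.2f} nm")
print(f"cycle classes:   {g['class_counts']}")
print(f"refolding seen:  {g['refolding']['frequency']:.1%} of relaxations")
print(f"nanobody stabilization: {af.delta_g(0.074, 0.0061).summary()}")
```

prints

```
events detected: 1228 in 1200 pulls
contour length:  26.81 +/- 0.01 nm  (~67 residues)
persistence len: 0.58 +/- 0.00 nm
unstressed rate: 0.097 /s   barrier position: 1.03 nm
cycle classes:   {'single_long': 1021, 'two_short': 45, 'single_short': 117, 'no_event': 17, 'unclassified': 0}
refolding seen:  8.5% of relaxations
nanobody stabilization: 2.5 kBT
```

The pipeline recovers the generating mechanics: the fitted 26.8 nm
contour length (~67 residues — both AIM flanks, i.e. cooperative
unfolding of the whole module, not of A1 itself), the Bell–Evans
parameters near the generating (0.074 /s, 1.10 nm), the dominance of
single long rips over one or two short ones, and a refolding frequency
near the configured 9.6%.  The last line is the activation-energy gain
conferred by the stabilizing nanobody, computed from the two measured
unstressed unfolding rates.

The same stages are scriptable from the shell:

```bash
aimforce simulate-traces --preset AIM-A1 --seed 7 --out scratch/sim
aimforce analyze-traces --manifest scratch/sim/manifest.json --out scratch/out
aimforce simulate-bli --seed 7 --fit --out scratch/bli
```

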