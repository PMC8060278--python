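# Methods

This note documents the models implemented in `aimforce`, the choices
behind their defaults, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Scientific setting

Von Willebrand factor (VWF) initiates platelet adhesion when its A1
domain binds the platelet receptor GPIbα.  In circulating VWF the A1
domain is shielded by an autoinhibitory module (AIM) formed by the
sequences flanking A1 on both sides; tensile force unfolds the AIM and
exposes A1.  Two experiment classes quantify this switch:

* **Optical-tweezer force ramps** on single tethered AIM-A1 molecules:
  repeated pull–relax cycles at constant pulling speed produce
  force-extension traces in which AIM unfolding appears as a rip — an
  abrupt extension gain with a force drop.  Rip statistics over a ladder
  of loading rates yield the module's mechanical fingerprint.
* **Bio-layer interferometry (BLI)** sensorgrams of A1 fragments binding
  immobilized GPIbα ligand-binding domain, analyzed with a two-affinity-
  state ("heterogeneous ligand") model because A1 populates a
  high-affinity and a low-affinity conformation.

## Worm-like chain elasticity

The unfolded polypeptide released by a rip is modeled with the WLC
interpolation formula

    F(x)·Lp/kBT = 1/4·(1 − x/Lc)^−2 − 1/4 + x/Lc

with contour length `Lc` (nm) and persistence length `Lp` (nm).
Fitting (`WormLikeChainModel`) is unweighted nonlinear least squares with
extension as predictor and force as response; parameter uncertainties are
the standard errors of the fit.  Defaults: initialization
`Lc = 1.2·max(x)`, `Lp = 0.5 nm`; box bounds `Lp ∈ [0.05, 5] nm`,
`Lc ∈ [1, 200] nm` — stable for rip-sized (10–30 nm) data.  The numerical
inverse uses safeguarded bisection on `[0, Lc(1 − 1e−9)]` to 1e−9 nm.

Contour-length increments convert to residue counts at 0.4 nm/residue
(round half-up), the standard backbone spacing; no folded-state
end-to-end correction is subtracted by default (the conversion is a plain
quotient and callers may pre-subtract one).  Temperature defaults to
298 K (kBT = 4.114 pN·nm).

## Bell–Evans rupture kinetics

Force tilts the unfolding barrier, giving
`k_u(f) = k_u0·exp(f·γ_u/kBT)`.  Under a constant loading rate `R_f` the
rupture-force density (normalized over force by the 1/R_f factor, which
leaves the mode unchanged) is

    p(f) = (k_u0/R_f)·exp(fγ_u/kBT)·exp{(k_u0·kBT/(γ_u·R_f))·[1 − exp(fγ_u/kBT)]}

with mode `f* = (kBT/γ_u)·ln(γ_u·R_f/(k_u0·kBT))`.  Sampling uses the
exact inverse survival function.  `(k_u0, γ_u)` are recovered by
unweighted linear regression of `f*` on `ln R_f` (`BellEvansModel`):
`γ_u = kBT/slope`, `k_u0 = (γ_u/kBT)·exp(−intercept/slope)`; standard
errors propagate from the coefficient covariance by the delta method
(first-order, hence approximate for `k_u0`).

### Estimating f* from rupture-force histograms

`extract_most_probable_force` implements the histogram convention:
fixed-width bins anchored at zero force, `f*` = center of the tallest bin
± half the bin width, ties resolved toward the lower-force bin (default
width 2 pN).

The pipeline defaults to a refinement, `gaussian_peak_force`: a Gaussian
fitted to the histogram bins reaching ≥30% of the tallest bin, whose mean
is taken as `f*`.  Two facts motivate this.  First, the tallest-bin
center is a poor estimator of a smooth density's mode: adjacent bins near
the peak hold nearly equal probability mass, so the tallest bin flips
between neighbors with probability that decays very slowly with sample
size (~1 pN rms error at 200–300 events per rate, at any practical bin
width), enough to corrupt the regression slope badly for constructs with
narrow rupture-force distributions (large `γ_u`).  Second, the
rupture-force density has the same shape at every loading rate — only its
location moves and its scale is fixed at `kBT/γ_u` — so the small,
shape-dependent offset between the Gaussian mean and the true mode is
identical across loading rates and cancels exactly from the slope; it
shifts only the intercept, biasing `k_u0` by a modest constant factor
(~e^0.15).  The f* histogram bin width defaults to 1 pN in the pipeline;
the raw tallest-bin procedure remains available
(`PipelineConfig.fstar_method = "tallest_bin"`).

Transition-state energy differences between two conditions are
`ΔG12 = kBT·ln(k1/k2)`, reported in kBT units (2 significant figures in
summaries).

## Trace analysis

**Rip detection.**  The force channel is median-filtered (window
5 samples).  A candidate rip is a force drop ≥ 0.2 pN together with an
extension gain ≥ 2 nm, both measured across a one-window lag; consecutive
candidates merge into one event located at the largest single-step
extension gain (the extension jump is the sharpest signature of a rip),
and events within 20 ms of the previous one are discarded.  The unfolding
force is the median of the raw force over the window ending at the
rupture sample, which no post-rip sample contaminates.  The low force
threshold is deliberate: with an effective tether stiffness of
0.1 pN/nm, a sub-module rip releasing ~7 nm of chain at 8 pN drops the
force by only ~0.7 pN, and rips at 4–5 pN by ~0.4 pN; requiring the
coincident extension jump is what keeps the false-positive rate at zero
on rupture-free ramps.  On real instrument data with a noisy extension
channel both thresholds would need re-tuning (they are configuration
fields, `DetectionConfig`).

**Unfolding extension** is the extension at the first post-rupture sample
whose smoothed force re-attains the unfolding force, minus the extension
at rupture — the operational definition used experimentally.  Events
whose force is never re-established (rupture too close to the ramp's end)
are flagged and excluded from WLC data but still counted.

**Cycle classification.**  An event is *long* when its unfolding
extension exceeds the WLC extension, at the event's force, of a boundary
contour length midway between the whole-module (26.6 nm) and sub-module
(~13 nm) increments (defaults: `Lc = 19.85 nm`, `Lp = 0.66 nm`).  A
model-informed boundary adapts to rupture force, unlike a fixed
nanometer cutoff.  Cycles map to: one long rip → `single_long`
(cooperative unfolding of the whole module); two short rips →
`two_short`; one short rip → `single_short`; none → `no_event`; anything
else → `unclassified` (reported, never forced into a category).

**Refolding** during relaxation is a reverse rip: extension drop ≥ 2 nm
with a force rise ≥ 0.05 pN across the same lag.

**Extension–force binning.**  Events are binned by force (2 pN default);
each bin's extension histogram is fitted with a Gaussian, reported as
peak ± FWHM/√n; bins with fewer than 5 events fall back to the sample
mean/SD and are flagged.

**Pipeline.**  Per construct/condition group, fits use one event
population: the most frequent eventful class, which is the construct's
characteristic unfolding event (whole-module rips for AIM-A1, the single
short rip for the truncations).  The WLC is fitted to pooled raw
(force, extension) rupture points by default; fitting the binned
most-probable pairs instead is a configuration switch
(`wlc_source = "binned"`), since either reading of the original
procedure is plausible.  Per-event loading rates default to the nominal
`pulling_speed × effective_stiffness` from trace metadata; a local
pre-rupture force-slope estimator is available
(`loading_rate_method = "local_slope"`).  Reports are deterministic given
inputs and configuration.

## Synthetic pulling experiments

The generator forward-models the tether as the controlled trap–pipette
separation `z` ramping at the pulling speed, with the handle plus all
still-folded structure lumped into one effective linear spring
(default 0.1 pN/nm, so the 50–500 nm/s speeds give loading rates of
5–50 pN/s).  At each sample the force solves the quasi-static balance
`z = F/κ + Σ x_WLC,i(F)` over the unfolded units — exactly linear
(`F = κz`) before the first rupture, and inverted on a dense force grid
(~0.008 pN spacing) afterwards.  The recorded extension channel is the
unfolded-chain extension `z − F/κ`; Gaussian noise (default σ = 0.3 pN at
1 kHz) is added to the force channel only, so detection thresholds
against extension noise are not exercised (see limitations).

Rupture forces are exact inverse-CDF draws from the Bell–Evans density at
the nominal loading rate; units rupture in order of drawn force, as a
ramp would reach them.  A drawn force at or below the hold force means
the unit is already unfolded at the ramp's start (no detectable rip,
recorded in truth); one above the force ceiling stays folded.  At a
rupture the extension jumps by the WLC extension of the released contour
length at the prevailing force and the force relaxes along the balance,
re-establishing the rupture force a short ramp later — reproducing the
measurement definition exactly.

Each pull cycle draws a construct state: cooperative (whole module, one
rip consuming the full increment, whole-module kinetics), two sequential
sub-module rips (per-sub-unit kinetics), one pre-unfolded sub-module
(one rip), or no event; defaults for the full construct are
(0.85, 0.05, 0.10), read from the observed class shares (~80–90% single
large event, ~5% two smaller, 5–15% one smaller).  Pull cycles are
i.i.d.: the module is taken to have refolded by the next pull whether or
not a refolding transition was visible, consistent with unfolding
recurring in subsequent pulls even when refolding was not apparent.
Visible refolding during relaxation is a Bernoulli event (default
p = 0.096 for the full construct; 0.045/0.031 for the truncations) that
recollapses the whole unfolded chain at a force drawn uniformly from
1.5–3 pN; no mechanistic refolding kinetics are modeled (only that
refolding is slow and requires sustained low force is known).

Tethers are pulled repeatedly: by default each tether contributes three
cycles at each of the five speeds (15 cycles/tether; with the default 80
tethers, ~250–350 analyzable events per loading rate).  Repeated cycling
matches how tethered molecules are actually used, and the event counts it
produces are what make the histogram-based f* statistic stable (see
above); with single cycles per speed the mode estimator's sampling error
dominates the loading-rate regression.

Simulation presets carry the published (Lc, Lp, k_u0, γ_u) for all ten
measured construct/additive conditions as ground truth.  The full AIM-A1
construct (and its 6G1-bound variant, whose truncation counterparts were
also measured) carries sub-units for the partial states; conditions
without published sub-unit rows are single-unit constructs.

Reproducibility: one root seed; each tether gets a child stream spawned
in tether order (`numpy` `SeedSequence.spawn`), so output is
byte-identical across reruns and stable under parallel generation.

## Two-site binding kinetics

Sensorgrams are sums of two independent 1:1 Langmuir components (high-
and low-affinity ligand states; interconversion deliberately not modeled
— the states are frozen on the assay timescale without force):
association `R_i(t) = Req_i(1 − e^{−(kon_i·C + koff_i)t})` with
`Req_i = Rmax_i·C/(C + KD_i)`, dissociation `R_i(t0)·e^{−koff_i·t}`.
Input sensorgrams are assumed reference-subtracted; per-curve baseline
offsets are off by default and `Rmax` is shared across the dilution
series (global), with both choices configurable.

The global fit shares all six parameters across curves and runs ≥10
starts (a deterministic log-spaced design plus seeded jitter) of bounded
least squares in log10-rate space (`kon ∈ [1e2, 1e8] /M/s`,
`koff ∈ [1e-5, 1] /s`), keeping the best objective; two-site fits are
notoriously multimodal, hence the multi-start.  Components are relabeled
by KD after fitting; standard errors come from the Jacobian at the
optimum (delta method back to linear rate space); a rank-deficient
Jacobian raises an identifiability warning.

Steady-state plateaus (mean over the last 5% of association) are fitted
with the hyperbola `Req = Bmax·C/(KD_app + C)`; the 95% CI on `KD_app`
uses the parameter covariance with a t-distribution on n−2 degrees of
freedom.

The default simulated truth — kon' = 3e5 /M/s, koff' = 2e-3 /s
(KD' ≈ 6.7 nM) against kon = 5e4 /M/s, koff = 5e-2 /s (KD = 1 µM), Rmax
0.8/1.2 response units, 1 µM → 15.6 nM two-fold dilution, 300 s + 300 s
phases, noise 1% of total Rmax — is a realistic nM-versus-µM two-state
split; the instrument data behind the published affinities are not
available in machine-readable form, so recovery is always measured
against this synthetic truth, never against the published KD values.

## Problem sizes

Recovery runs use 80 tethers × 15 cycles over the five speeds per
construct (three constructs), 1000 cycles at 200 nm/s for class/refolding
statistics, 10⁴ draws for distributional checks, 7-curve sensorgram sets
at 1 Hz, and 200 replicates for CI coverage.

## Known limitations

* The event detector's defaults are tuned to the simulator's noise model
  (noiseless extension channel, white 0.3 pN force noise at 1 kHz); real
  traces have correlated noise, drift and a noisy extension channel, and
  would need re-tuned thresholds and possibly drift correction, which is
  out of scope.
* Passing recovery tests on simulated data shows the pipeline inverts its
  own forward model under realistic noise — not that the simplified
  tether mechanics (single effective spring, no series-WLC handle, no
  bead/trap hydrodynamics) reproduce real instrument traces.
* The Bell–Evans picture (single sharp barrier, force-independent γ_u,
  ν = 1) is assumed throughout; free-energy-surface variants are not
  implemented.
* `k_u0` from the f*-regression inherits both the delta-method
  approximation and the constant peak-offset factor of the Gaussian-peak
  f* estimator; its recovery is order-of-magnitude by nature (the
  published uncertainties on unstressed rates are themselves ~30–50%).
* The residue bookkeeping of the flanking sequences is left to the
  caller (`nm_per_residue` and any folded-core correction are
  configuration), since published residue spans are ambiguous at the
  ±3-residue level.
* Relaxation traces serve refolding statistics only; no refolding
  kinetics, force-dependent or otherwise, are modeled.
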