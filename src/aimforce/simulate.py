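"""Monte-Carlo generators for force-ramp trace and biosensor experiments.

The trace generator forward-models an optical-tweezer force-ramp
experiment on a multi-state unfoldable construct held through a
handle.  The handle plus everything still folded is a single effective
linear spring of stiffness ``kappa`` (pN/nm), so the nominal loading rate
is R_f = kappa * pulling_speed.  The controlled trap-pipette separation
``z`` ramps at the pulling speed, and at every sample the force solves the
quasi-static balance

    z = F/kappa + sum_i x_WLC(F; dLc_i, Lp_i)      (sum over unfolded units),

which before any rupture reduces to the linear handle model F = kappa*z.
Rupture forces are drawn exactly from the Bell-Evans rupture-force
distribution at the nominal loading rate (inverse-CDF sampling); at a
rupture the recorded extension channel (the unfolded-chain extension
z - F/kappa) jumps and the force relaxes, producing the rip signature the
analysis pipeline detects.  Gaussian noise is added to the force channel
only.

Each pull cycle independently draws one of the construct's states:
cooperative (the whole module unfolds in one rip), two_sequential (both
sub-units rip independently), one_prefolded (a single sub-unit rip), or
no event.  Relaxation traces optionally contain a visible refolding
transition (Bernoulli per relaxation); pull cycles are i.i.d. because the
module is taken to have refolded by the next pull whether or not the
transition was visible.

Published whole-module and sub-module (contour length, persistence
length, unstressed rate, barrier position) values for every measured
construct/additive condition are bundled as simulation presets, and a
two-affinity-state sensorgram generator produces biosensor data for the
binding-kinetics module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binding import Sensorgram, SensorgramSet, TwoSiteParams, predict_sensorgram
from .exceptions import ValidationError
from .kinetics import BellEvansParams, LoadingCondition, sample_rupture_force
from .polymer import WLCParams, wlc_extension
from .thermal import ThermalContext, ROOM_TEMPERATURE
from .traces import ForceExtensionTrace


@dataclass(frozen=True)
class UnfoldableUnit:
    """One unfoldable structural unit: kinetics plus released contour length."""

    name: str
    kinetics: BellEvansParams
    delta_lc: float      # contour-length increment on unfolding, nm
    unfolded_lp: float   # persistence length of the released chain, nm

    def __post_init__(self) -> None:
        if not (self.delta_lc > 0 and self.unfolded_lp > 0):
            raise ValidationError("delta_lc and unfolded_lp must be > 0")

    @property
    def wlc(self) -> WLCParams:
        return WLCParams(self.delta_lc, self.unfolded_lp)


@dataclass(frozen=True)
class ConstructSpec:
    """A simulated molecule.

    ``units[0]`` is the whole module (used by the cooperative state);
    ``units[1:]`` are the independent sub-units used by the two_sequential
    and one_prefolded states.  Single-unit constructs use ``units[0]``
    for every eventful state.
    ``state_probabilities`` = (p_cooperative, p_two_sequential,
    p_one_prefolded); any remainder is the no-event probability.
    """

    name: str
    units: Tuple[UnfoldableUnit, ...]
    state_probabilities: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    refold_probability: float = 0.0
    handle_stiffness: float = 0.1   # pN/nm

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise ValidationError("a construct needs at least one unfoldable unit")
        p = self.state_probabilities
        if any(x < 0 for x in p) or sum(p) > 1.0 + 1e-12:
            raise ValidationError("state probabilities must be >= 0 and sum <= 1")
        if not (0.0 <= self.refold_probability <= 1.0):
            raise ValidationError("refold_probability must be in [0, 1]")
        if not self.handle_stiffness > 0:
            raise ValidationError("handle_stiffness must be > 0")

    @property
    def sub_units(self) -> Tuple[UnfoldableUnit, ...]:
        return self.units[1:] if len(self.units) > 1 else self.units


def _unit(name, lc, lp, k0, gu) -> UnfoldableUnit:
    return UnfoldableUnit(name=name, kinetics=BellEvansParams(k0, gu),
                          delta_lc=lc, unfolded_lp=lp)


def published_presets() -> Dict[str, ConstructSpec]:
    """Simulation presets carrying the published single-molecule parameters.

    Keys are construct/additive condition names; values hold the measured
    (L_c, L_p, k_u0, gamma_u) as ground truth.  The full AIM-A1 construct
    (and its 6G1 condition, whose truncation counterparts were also
    measured) carries sub-units for the sequential/partial states; all
    other conditions are single-unit constructs.
    """
    aim = _unit("AIM", 26.6, 0.60, 0.074, 1.10)
    naim = _unit("NAIM", 12.9, 0.78, 0.154, 1.22)
    caim = _unit("CAIM", 13.1, 0.72, 0.093, 2.34)
    aim_6g1 = _unit("AIM+6G1", 14.6, 0.76, 0.10, 1.48)
    naim_6g1 = _unit("NAIM+6G1", 14.2, 0.95, 0.247, 1.17)
    caim_6g1 = _unit("CAIM+6G1", 13.0, 1.08, 0.096, 3.38)
    multi = dict(state_probabilities=(0.85, 0.05, 0.10))
    presets = {
        "AIM-A1": ConstructSpec("AIM-A1", (aim, naim, caim),
                                refold_probability=0.096, **multi),
        "NAIM-A1": ConstructSpec("NAIM-A1", (naim,), refold_probability=0.045),
        "A1-CAIM": ConstructSpec("A1-CAIM", (caim,), refold_probability=0.031),
        "AIM-A1 H1268D": ConstructSpec(
            "AIM-A1 H1268D", (_unit("AIM(H1268D)", 17.7, 0.67, 0.288, 0.84),)),
        "AIM-A1 R1341Q": ConstructSpec(
            "AIM-A1 R1341Q", (_unit("AIM(R1341Q)", 14.5, 1.32, 0.27, 1.15),)),
        "AIM-A1 with 6G1": ConstructSpec(
            "AIM-A1 with 6G1", (aim_6g1, naim_6g1, caim_6g1), **multi),
        "NAIM-A1 with 6G1": ConstructSpec("NAIM-A1 with 6G1", (naim_6g1,)),
        "A1-CAIM with 6G1": ConstructSpec("A1-CAIM with 6G1", (caim_6g1,)),
        "AIM-A1 with CR1": ConstructSpec(
            "AIM-A1 with CR1", (_unit("AIM+CR1", 27.9, 0.37, 0.133, 0.94),)),
        "AIM-A1 with VHH81": ConstructSpec(
            "AIM-A1 with VHH81", (_unit("AIM+VHH81", 25.3, 0.56, 0.0061, 1.47),)),
    }
    return presets


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated pulling experiment."""

    construct: ConstructSpec
    pulling_speeds: Tuple[float, ...] = (50.0, 100.0, 200.0, 400.0, 500.0)
    n_tethers: int = 80
    #: cycles per tether; None = REPEATS_PER_SPEED passes over the speed list,
    #: emulating the repeated pull-relax cycling each tether undergoes
    cycles_per_tether: Optional[int] = None
    noise_sigma: float = 0.3      # pN, force channel
    sampling_rate: float = 1000.0  # Hz
    max_force: float = 30.0       # pN
    hold_force: float = 1.0       # pN
    refold_force_range: Tuple[float, float] = (1.5, 3.0)  # pN
    include_relaxation: bool = True
    temperature: float = ROOM_TEMPERATURE.temperature
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.pulling_speeds):
            raise ValidationError("pulling speeds must be > 0")
        if self.n_tethers <= 0:
            raise ValidationError("n_tethers must be > 0")
        if not 0 < self.hold_force < self.max_force:
            raise ValidationError("need 0 < hold_force < max_force")


@dataclass
class SimulatedExperiment:
    """Traces plus ground-truth tables from one simulated experiment."""

    traces: List[ForceExtensionTrace]
    events_truth: pd.DataFrame   # tether, cycle, unit, rupture force/index, dLc, jump
    cycles_truth: pd.DataFrame   # tether, cycle, speed, drawn state, n events
    refolds_truth: pd.DataFrame  # tether, cycle, refolded flag
    config: SimulationConfig


STATES = ("cooperative", "two_sequential", "one_prefolded", "no_event")

#: Default passes over the speed list per tether.  Tethers are pulled
#: repeatedly; three cycles at each speed gives a few hundred events per
#: loading rate, enough for the histogram-mode rupture-force statistic to
#: be stable at its 2 pN bin width.
REPEATS_PER_SPEED = 3


def draw_cycle_state(spec: ConstructSpec, rng: np.random.Generator) -> str:
    pc, p2, p1 = spec.state_probabilities
    r = rng.random()
    if r < pc:
        return "cooperative"
    if r < pc + p2:
        return "two_sequential"
    if r < pc + p2 + p1:
        return "one_prefolded"
    return "no_event"


def _units_for_state(spec: ConstructSpec, state: str,
                     rng: np.random.Generator) -> List[UnfoldableUnit]:
    if state == "no_event":
        return []
    if state == "cooperative" or len(spec.units) == 1:
        return [spec.units[0]]
    if state == "two_sequential":
        return list(spec.sub_units)
    # one_prefolded: one sub-unit remains folded at the start of the pull
    return [spec.sub_units[int(rng.integers(len(spec.sub_units)))]]


def _uniform_open(rng: np.random.Generator) -> float:
    """Uniform deviate strictly inside (0, 1)."""
    return float(np.clip(rng.random(), 1e-15, 1.0 - 1e-16))


def _chain_extension(units: Sequence[UnfoldableUnit], f, ctx) -> np.ndarray:
    """Summed WLC extension of the unfolded chains at force(s) f."""
    fa = np.asarray(f, dtype=float)
    total = np.zeros_like(fa)
    for u in units:
        total += wlc_extension(u.wlc, fa, ctx)
    return total


def _solve_force(z: np.ndarray, units: Sequence[UnfoldableUnit], kappa: float,
                 ctx: ThermalContext, f_max: float) -> np.ndarray:
    """Force from the balance z = F/kappa + X(F), monotone in z.

    With no unfolded chain the balance is exactly linear (F = kappa*z);
    otherwise z(F) is tabulated on a dense force grid and inverted by
    interpolation (grid spacing ~0.01 pN keeps the interpolation error
    orders of magnitude below the force noise).
    """
    if len(units) == 0:
        return kappa * z
    fgrid = np.linspace(0.0, max(f_max * 1.05, kappa * float(np.max(z))), 4096)
    zgrid = fgrid / kappa + _chain_extension(units, fgrid, ctx)
    return np.interp(z, zgrid, fgrid)


def simulate_pull(spec: ConstructSpec, speed: float, state: str,
                  rng: np.random.Generator,
                  cfg: SimulationConfig,
                  tether_id: str = "t0", cycle: int = 0,
                  ) -> Tuple[ForceExtensionTrace, List[dict], List[UnfoldableUnit]]:
    """Simulate one pulling cycle.

    Returns the trace, the ground-truth event list (one dict per unit that
    was due to unfold, including those whose drawn rupture force exceeded
    ``max_force`` and therefore produced no event), and the list of units
    unfolded at the end of the pull (input for the paired relaxation).
    """
    if state not in STATES:
        raise ValidationError(f"unknown cycle state {state!r}")
    ctx = ThermalContext(cfg.temperature)
    kappa = spec.handle_stiffness
    rf = kappa * speed
    load = LoadingCondition(rf, pulling_speed=speed, effective_stiffness=kappa)
    drawn = []
    for u in _units_for_state(spec, state, rng):
        f_u = sample_rupture_force(u.kinetics, load, ctx, _uniform_open(rng))
        drawn.append((u, f_u))
    drawn.sort(key=lambda t: t[1])  # a ramp reaches lower rupture forces first
    active = [(u, f) for u, f in drawn if cfg.hold_force < f < cfg.max_force]
    # a drawn rupture force at or below the hold force means the unit is
    # already unfolded when the ramp starts: no detectable rip
    pre_unfolded = [u for u, f in drawn if f <= cfg.hold_force]

    z0 = cfg.hold_force / kappa + float(
        _chain_extension(pre_unfolded, cfg.hold_force, ctx))
    ruptured: List[UnfoldableUnit] = list(pre_unfolded)
    boundaries = []
    for k, (u, f_u) in enumerate(active):
        chain = pre_unfolded + [uu for uu, _ in active[:k]]
        boundaries.append(f_u / kappa + float(_chain_extension(chain, f_u, ctx)))
        ruptured.append(u)
    z_end = cfg.max_force / kappa + float(_chain_extension(ruptured, cfg.max_force, ctx))
    n = int(np.floor((z_end - z0) / speed * cfg.sampling_rate)) + 1
    t = np.arange(n) / cfg.sampling_rate
    z = z0 + speed * t

    force = np.empty(n)
    seg_edges = [0] + [int(np.searchsorted(z, zb, side="left")) for zb in boundaries] + [n]
    truth: List[dict] = []
    for k in range(len(seg_edges) - 1):
        i0, i1 = seg_edges[k], seg_edges[k + 1]
        chain = pre_unfolded + [u for u, _ in active[:k]]
        if i1 > i0:
            force[i0:i1] = _solve_force(z[i0:i1], chain, kappa, ctx, cfg.max_force)
    for k, (u, f_u) in enumerate(active):
        truth.append({
            "tether_id": tether_id, "cycle": cycle, "unit": u.name,
            "rupture_force_pN": f_u,
            "rupture_index": max(seg_edges[k + 1] - 1, 0),
            "delta_lc_nm": u.delta_lc,
            "extension_jump_nm": float(wlc_extension(u.wlc, f_u, ctx)),
            "ruptured": True,
            "loading_rate_pNs": rf,
        })
    for u, f_u in drawn:
        if not cfg.hold_force < f_u < cfg.max_force:
            truth.append({
                "tether_id": tether_id, "cycle": cycle, "unit": u.name,
                "rupture_force_pN": f_u, "rupture_index": -1,
                "delta_lc_nm": u.delta_lc, "extension_jump_nm": np.nan,
                "ruptured": False, "loading_rate_pNs": rf,
            })
    extension = z - force / kappa
    noisy = force + rng.normal(0.0, cfg.noise_sigma, n) if cfg.noise_sigma > 0 else force
    trace = ForceExtensionTrace(
        time=t, force=noisy, extension=extension, direction="pull",
        pulling_speed=speed, tether_id=tether_id, cycle=cycle,
        sampling_rate=cfg.sampling_rate, construct=spec.name,
        effective_stiffness=kappa,
    )
    return trace, truth, ruptured


def simulate_relaxation(spec: ConstructSpec, speed: float,
                        unfolded_units: Sequence[UnfoldableUnit],
                        refold: bool, rng: np.random.Generator,
                        cfg: SimulationConfig,
                        tether_id: str = "t0", cycle: int = 0,
                        ) -> Tuple[ForceExtensionTrace, bool]:
    """Simulate the relaxation half-cycle back down to the hold force.

    If ``refold`` and any units are unfolded, the whole unfolded chain
    recollapses at a force drawn uniformly from ``refold_force_range``,
    producing a reverse rip (extension drop, force blip up).  Returns the
    trace and whether a refolding transition is actually present.
    """
    ctx = ThermalContext(cfg.temperature)
    kappa = spec.handle_stiffness
    units = list(unfolded_units)
    z_start = cfg.max_force / kappa + float(_chain_extension(units, cfg.max_force, ctx))
    z0 = cfg.hold_force / kappa
    n = int(np.floor((z_start - z0) / speed * cfg.sampling_rate)) + 1
    t = np.arange(n) / cfg.sampling_rate
    z = z_start - speed * t

    has_refold = bool(refold and units)
    if has_refold:
        f_refold = float(rng.uniform(*cfg.refold_force_range))
        z_star = f_refold / kappa + float(_chain_extension(units, f_refold, ctx))
        i_star = int(np.searchsorted(-z, -z_star, side="left"))  # z is decreasing
        force = np.empty(n)
        force[:i_star] = _solve_force(z[:i_star], units, kappa, ctx, cfg.max_force)
        force[i_star:] = kappa * z[i_star:]
    else:
        force = _solve_force(z, units, kappa, ctx, cfg.max_force)
    extension = z - force / kappa
    noisy = force + rng.normal(0.0, cfg.noise_sigma, n) if cfg.noise_sigma > 0 else force
    trace = ForceExtensionTrace(
        time=t, force=noisy, extension=extension, direction="relax",
        pulling_speed=speed, tether_id=tether_id, cycle=cycle,
        sampling_rate=cfg.sampling_rate, construct=spec.name,
        effective_stiffness=kappa,
    )
    return trace, has_refold


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Simulate a full experiment: n_tethers, each pulled over the speed list.

    Reproducible from ``cfg.seed``: each tether gets its own child RNG
    stream (spawned in tether order from the root seed), so the output is
    byte-identical across reruns and independent of how tethers might be
    generated in parallel.
    """
    spec = cfg.construct
    n_cycles = cfg.cycles_per_tether or REPEATS_PER_SPEED * len(cfg.pulling_speeds)
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_tethers)
    traces: List[ForceExtensionTrace] = []
    events_rows: List[dict] = []
    cycle_rows: List[dict] = []
    refold_rows: List[dict] = []
    for ti in range(cfg.n_tethers):
        rng = np.random.default_rng(streams[ti])
        tether_id = f"t{ti:04d}"
        for c in range(n_cycles):
            speed = cfg.pulling_speeds[c % len(cfg.pulling_speeds)]
            state = draw_cycle_state(spec, rng)
            trace, truth, unfolded = simulate_pull(
                spec, speed, state, rng, cfg, tether_id=tether_id, cycle=c)
            traces.append(trace)
            events_rows.extend(truth)
            cycle_rows.append({
                "tether_id": tether_id, "cycle": c, "pulling_speed_nm_s": speed,
                "state": state,
                "n_events": sum(1 for r in truth if r["ruptured"]),
            })
            if cfg.include_relaxation:
                want_refold = rng.random() < spec.refold_probability
                relax, refolded = simulate_relaxation(
                    spec, speed, unfolded, want_refold, rng, cfg,
                    tether_id=tether_id, cycle=c)
                traces.append(relax)
                refold_rows.append({
                    "tether_id": tether_id, "cycle": c, "refolded": refolded,
                })
    return SimulatedExperiment(
        traces=traces,
        events_truth=pd.DataFrame(events_rows),
        cycles_truth=pd.DataFrame(cycle_rows),
        refolds_truth=pd.DataFrame(refold_rows),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Biosensor (BLI) sensorgram generation
# ---------------------------------------------------------------------------

#: Default two-affinity-state ground truth: a high-affinity state in the nM
#: range and a low-affinity state in the uM range, with comparable surface
#: capacities.  Chosen once as a realistic, well-separated pair; all
#: recovery tests measure against these values.
DEFAULT_TWO_SITE = TwoSiteParams(
    kon_high=3e5, koff_high=2e-3,   # KD' ~ 6.7 nM
    kon_low=5e4, koff_low=5e-2,     # KD  ~ 1.0 uM
    rmax_high=0.8, rmax_low=1.2,
)

#: Default analyte dilution: 1 uM down to 15.6 nM, two-fold, 7 concentrations.
DEFAULT_CONCENTRATIONS = tuple(1e-6 / 2 ** k for k in range(7))


def simulate_sensorgrams(params: TwoSiteParams = DEFAULT_TWO_SITE,
                         concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
                         t_assoc: float = 300.0, t_dissoc: float = 300.0,
                         noise_sigma: Optional[float] = None,
                         sampling_interval: float = 1.0,
                         rng: Optional[np.random.Generator] = None,
                         seed: Optional[int] = None) -> SensorgramSet:
    """Generate a two-site sensorgram series with Gaussian response noise.

    ``noise_sigma`` defaults to 1% of the total surface capacity
    (rmax_high + rmax_low); pass 0 for noiseless curves.  Truth parameters
    ride along on the returned set.
    """
    if any(c <= 0 for c in concentrations):
        raise ValidationError("concentrations must be > 0 M")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValidationError("phase durations must be > 0 s")
    if rng is None:
        rng = np.random.default_rng(seed)
    if noise_sigma is None:
        noise_sigma = 0.01 * (params.rmax_high + params.rmax_low)
    time = np.arange(0.0, t_assoc + t_dissoc + sampling_interval / 2,
                     sampling_interval)
    curves = []
    for conc in concentrations:
        curve = Sensorgram(concentration=float(conc), time=time,
                           response=np.zeros_like(time), t_association_end=t_assoc)
        clean = predict_sensorgram(params, curve)
        noisy = clean + rng.normal(0.0, noise_sigma, clean.size) if noise_sigma > 0 else clean
        curve.response = noisy
        curves.append(curve)
    return SensorgramSet(curves=curves, truth=params)
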