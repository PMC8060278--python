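"""End-to-end analysis pipeline: traces in, mechanics/kinetics tables out.

Per (construct, condition) group the pipeline detects rips, measures
unfolding extensions, classifies cycles, counts refolding transitions in
relaxation traces, bins extensions by force, fits the worm-like chain to
the rupture (force, extension) data, extracts most probable rupture forces
per loading rate, and fits the Bell-Evans model to f* vs ln(R_f).  Output
is a plain-dict report (JSON-serializable, deterministic given inputs and
configuration); failures in one stage or group are reported in place
without aborting the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .exceptions import AimforceError, MeasurementError, ValidationError
from .kinetics import (extract_most_probable_force, fit_bell_evans,
                       gaussian_peak_force)
from .polymer import NM_PER_RESIDUE, contour_to_residues, fit_wlc
from .thermal import ThermalContext, ROOM_TEMPERATURE
from .traces import (ClassifyConfig, DetectionConfig, ForceExtensionTrace,
                     RefoldingSummary, UnfoldingEvent, bin_extensions_by_force,
                     classify_cycle, detect_events, detect_refolding,
                     local_loading_rate, measure_unfolding_extension)

CLASS_LABELS = ("single_long", "two_short", "single_short", "no_event", "unclassified")


@dataclass(frozen=True)
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    force_bin_width: float = 2.0          # pN, extension-vs-force binning
    #: bin width of the rupture-force histograms behind f*.  Narrower than
    #: the extension bins: the rupture-force distribution is only a few
    #: kBT/gamma_u wide, and a 2 pN grid quantizes f* coarsely enough to
    #: bias the f*-vs-ln(R_f) slope for high-gamma_u constructs.
    fstar_bin_width: float = 1.0
    #: f* estimator: 'gaussian_peak' (Gaussian fitted to the histogram
    #: peak; stable) or 'tallest_bin' (raw tallest-bin center).
    fstar_method: str = "gaussian_peak"
    min_events_per_rate: int = 5
    temperature: float = ROOM_TEMPERATURE.temperature
    default_stiffness: float = 0.1        # pN/nm when trace metadata lacks one
    wlc_source: str = "pooled"            # 'pooled' raw points or 'binned' peaks
    loading_rate_method: str = "nominal"  # 'nominal' or 'local_slope'
    nm_per_residue: float = NM_PER_RESIDUE
    wlc_class: Optional[str] = None       # event class fitted; None = modal class


def _event_loading_rate(trace: ForceExtensionTrace, event: UnfoldingEvent,
                        cfg: PipelineConfig) -> float:
    if cfg.loading_rate_method == "local_slope":
        return local_loading_rate(trace, event, cfg=cfg.detection)
    rate = trace.nominal_loading_rate
    if rate is None:
        rate = trace.pulling_speed * cfg.default_stiffness
    return rate


def analyze_group(traces: Sequence[ForceExtensionTrace],
                  cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Analyze one construct/condition group of traces; returns a report dict."""
    pulls = [t for t in traces if t.direction == "pull"]
    relaxes = [t for t in traces if t.direction == "relax"]
    events: List[UnfoldingEvent] = []
    event_classes: List[str] = []
    cycle_labels: List[str] = []
    event_rows: List[dict] = []
    n_unmeasurable = 0
    for trace in pulls:
        try:
            evs = detect_events(trace, cfg.detection)
        except ValidationError as exc:
            cycle_labels.append("unclassified")
            event_rows.append({"tether_id": trace.tether_id, "cycle": trace.cycle,
                               "error": str(exc)})
            continue
        measured: List[UnfoldingEvent] = []
        for ev in evs:
            ev.loading_rate = _event_loading_rate(trace, ev, cfg)
            try:
                ev.unfolding_extension = measure_unfolding_extension(
                    trace, ev, cfg.detection)
                measured.append(ev)
            except MeasurementError:
                n_unmeasurable += 1  # excluded from WLC data, still counted
        cls = classify_cycle(measured, cfg.classify)
        cycle_labels.append(cls.label)
        events.extend(measured)
        event_classes.extend([cls.label] * len(measured))
        for ev in measured:
            event_rows.append({
                "tether_id": ev.tether_id, "cycle": ev.cycle,
                "loading_rate_pNs": ev.loading_rate,
                "unfolding_force_pN": ev.unfolding_force,
                "unfolding_extension_nm": ev.unfolding_extension,
                "class": cls.label,
            })

    counts = {lab: cycle_labels.count(lab) for lab in CLASS_LABELS}
    n_cycles = len(cycle_labels)
    proportions = {lab: (counts[lab] / n_cycles if n_cycles else float("nan"))
                   for lab in CLASS_LABELS}

    n_refold = sum(bool(detect_refolding(t, cfg.detection)) for t in relaxes)
    refolding = RefoldingSummary(len(relaxes), n_refold)

    report: dict = {
        "n_pull_traces": len(pulls),
        "n_relax_traces": len(relaxes),
        "n_events": len(events),
        "n_unmeasurable_events": n_unmeasurable,
        "class_counts": counts,
        "class_proportions": proportions,
        "refolding": {
            "n_relaxation_traces": refolding.n_relaxation_traces,
            "n_refolding_observed": refolding.n_refolding_observed,
            "frequency": refolding.frequency,
        },
        "events": event_rows,
    }

    # Mechanics and kinetics are fitted on one event population: the
    # requested class, or the most common eventful class (the construct's
    # characteristic unfolding event).
    fit_class = cfg.wlc_class
    if fit_class is None:
        eventful = {k: v for k, v in counts.items()
                    if k in ("single_long", "single_short", "two_short") and v > 0}
        fit_class = max(eventful, key=eventful.get) if eventful else None
    report["fitted_class"] = fit_class
    fit_events = [ev for ev, c in zip(events, event_classes) if c == fit_class]

    try:
        if not fit_events:
            raise ValidationError("no events available for WLC fitting")
        bins = bin_extensions_by_force(fit_events, cfg.force_bin_width)
        report["extension_bins"] = [
            {"force_bin_center_pN": b.force_bin_center,
             "peak_extension_nm": b.peak_extension, "fwhm_nm": b.fwhm,
             "count": b.count, "uncertainty_nm": b.uncertainty,
             "low_count": b.low_count}
            for b in bins
        ]
        ctx = ThermalContext(cfg.temperature)
        if cfg.wlc_source == "binned":
            pts = [(b.force_bin_center, b.peak_extension) for b in bins
                   if not b.low_count]
        else:
            pts = [(ev.unfolding_force, ev.unfolding_extension) for ev in fit_events]
        wlc = fit_wlc(pts, ctx)
        report["wlc"] = wlc.to_dict()
        report["wlc"]["n_residues"] = contour_to_residues(
            wlc.params.contour_length, cfg.nm_per_residue)
    except AimforceError as exc:
        report["wlc_error"] = str(exc)

    try:
        by_rate: Dict[float, List[float]] = {}
        for ev in fit_events:
            by_rate.setdefault(round(ev.loading_rate, 6), []).append(ev.unfolding_force)
        fstar_fn = (gaussian_peak_force if cfg.fstar_method == "gaussian_peak"
                    else extract_most_probable_force)
        mpfs = [fstar_fn(forces, cfg.fstar_bin_width, loading_rate=rate,
                         min_events=cfg.min_events_per_rate)
                for rate, forces in sorted(by_rate.items())
                if len(forces) >= cfg.min_events_per_rate]
        report["most_probable_forces"] = [
            {"loading_rate_pNs": m.loading_rate, "f_star_pN": m.f_star,
             "uncertainty_pN": m.uncertainty, "n_events": m.n_events}
            for m in mpfs
        ]
        ctx = ThermalContext(cfg.temperature)
        be = fit_bell_evans(mpfs, ctx)
        report["bell_evans"] = be.to_dict()
    except AimforceError as exc:
        report["bell_evans_error"] = str(exc)

    return report


def run_pipeline(traces: Sequence[ForceExtensionTrace],
                 cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Run the full analysis, one report section per (construct, condition).

    Deterministic: groups are processed and emitted in sorted key order.
    An empty input yields an empty report with a warning flag rather than
    an error.
    """
    groups: Dict[str, List[ForceExtensionTrace]] = {}
    for t in traces:
        key = " | ".join(x for x in (t.construct or "unknown", t.condition) if x)
        groups.setdefault(key, []).append(t)
    report: dict = {"groups": {}, "n_traces": len(list(traces))}
    if not groups:
        report["warning"] = "no input traces"
        return report
    for key in sorted(groups):
        try:
            report["groups"][key] = analyze_group(groups[key], cfg)
        except AimforceError as exc:  # isolate per-condition failures
            report["groups"][key] = {"error": str(exc)}
    return report
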