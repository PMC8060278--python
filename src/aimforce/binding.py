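"""Two-affinity-state ("heterogeneous ligand") biosensor binding kinetics.

Sensorgrams of an analyte binding an immobilized ligand that exists in two
non-interconverting affinity states are modeled as the sum of two
independent 1:1 Langmuir components:

    association:  R_i(t) = Req_i * (1 - exp(-(kon_i*C + koff_i) * t)),
                  Req_i  = Rmax_i * C / (C + KD_i),   KD_i = koff_i / kon_i
    dissociation: R_i(t) = R_i(t0) * exp(-koff_i * t)

Interconversion between the states is deliberately not modeled (the states
are frozen on the assay timescale in the absence of force).  The module
provides the forward model, a multi-start global fit sharing all rate
constants and Rmax values across a concentration series, and the
steady-state hyperbola fit  Req(C) = Bmax*C/(KD_app + C)  with a
t-distribution 95% confidence interval on the apparent KD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DomainError, FitError, ValidationError

KON_BOUNDS = (1e2, 1e8)   # 1/(M*s)
KOFF_BOUNDS = (1e-5, 1.0)  # 1/s


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant KD = k_off / k_on (M)."""
    if not (k_on > 0 and k_off > 0):
        raise DomainError("rate constants must be > 0")
    return k_off / k_on


@dataclass(frozen=True)
class TwoSiteParams:
    """Kinetic parameters of the two affinity states.

    The 'high' component is the higher-affinity state (KD_high <= KD_low);
    construction enforces the labeling convention.
    """

    kon_high: float   # 1/(M*s)
    koff_high: float  # 1/s
    kon_low: float
    koff_low: float
    rmax_high: float  # response units
    rmax_low: float

    def __post_init__(self) -> None:
        for name in ("kon_high", "koff_high", "kon_low", "koff_low"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.rmax_high < 0 or self.rmax_low < 0:
            raise ValidationError("Rmax values must be >= 0")
        if self.kd_high > self.kd_low * (1 + 1e-12):
            raise ValidationError(
                "labeling convention violated: KD_high must be <= KD_low "
                f"({self.kd_high:.3g} > {self.kd_low:.3g} M)"
            )

    @property
    def kd_high(self) -> float:
        return self.koff_high / self.kon_high

    @property
    def kd_low(self) -> float:
        return self.koff_low / self.kon_low

    @staticmethod
    def ordered(kon1, koff1, kon2, koff2, rmax1, rmax2) -> "TwoSiteParams":
        """Build with components sorted so the higher-affinity one is 'high'."""
        if koff1 / kon1 <= koff2 / kon2:
            return TwoSiteParams(kon1, koff1, kon2, koff2, rmax1, rmax2)
        return TwoSiteParams(kon2, koff2, kon1, koff1, rmax2, rmax1)

    def to_dict(self) -> dict:
        return {
            "kon_high_per_M_s": self.kon_high, "koff_high_per_s": self.koff_high,
            "kon_low_per_M_s": self.kon_low, "koff_low_per_s": self.koff_low,
            "rmax_high": self.rmax_high, "rmax_low": self.rmax_low,
            "kd_high_M": self.kd_high, "kd_low_M": self.kd_low,
        }


@dataclass
class Sensorgram:
    """One response curve: association then dissociation on a common time axis."""

    concentration: float      # M
    time: np.ndarray          # s, from 0 at association start
    response: np.ndarray
    t_association_end: float  # s; dissociation runs from here to time[-1]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if not self.concentration > 0:
            raise ValidationError("analyte concentration must be > 0 M")
        if self.time.size != self.response.size:
            raise ValidationError("time and response must align")


@dataclass
class SensorgramSet:
    """Curves across an analyte dilution series, plus optional truth metadata."""

    curves: List[Sensorgram]
    truth: Optional[TwoSiteParams] = None

    def __post_init__(self) -> None:
        concs = [c.concentration for c in self.curves]
        if len(set(concs)) != len(concs):
            raise ValidationError("concentrations must be distinct")


@dataclass(frozen=True)
class SteadyStateFit:
    b_max: float
    kd_app: float            # M
    ci95_kd: Tuple[float, float]  # M
    stderr_b_max: float
    stderr_kd: float


def _component_response(kon, koff, rmax, C, t, t_assoc):
    """Response of one 1:1 component over a joint assoc+dissoc time axis."""
    t = np.asarray(t, dtype=float)
    kobs = kon * C + koff
    req = rmax * C / (C + koff / kon)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def two_site_response(params: TwoSiteParams, concentration: float, t, phase: str,
                      initial_state: Tuple[float, float] = (0.0, 0.0)):
    """Forward model for one phase, per-component initial responses given.

    ``phase`` is 'association' (analyte at ``concentration``) or
    'dissociation' (analyte-free buffer); ``t`` counts from the phase start.
    """
    if not concentration > 0:
        raise DomainError("concentration must be > 0 M")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    comps = ((params.kon_high, params.koff_high, params.rmax_high, initial_state[0]),
             (params.kon_low, params.koff_low, params.rmax_low, initial_state[1]))
    total = np.zeros_like(t)
    if phase == "association":
        for kon, koff, rmax, r0 in comps:
            kobs = kon * concentration + koff
            req = rmax * concentration / (concentration + koff / kon)
            total += req + (r0 - req) * np.exp(-kobs * t)
    elif phase == "dissociation":
        for kon, koff, _rmax, r0 in comps:
            total += r0 * np.exp(-koff * t)
    else:
        raise ValidationError(f"unknown phase {phase!r}")
    return total if total.ndim else float(total)


def component_states(params: TwoSiteParams, concentration: float,
                     t_assoc: float) -> Tuple[float, float]:
    """Per-component responses at the end of an association phase started empty."""
    out = []
    for kon, koff, rmax in ((params.kon_high, params.koff_high, params.rmax_high),
                            (params.kon_low, params.koff_low, params.rmax_low)):
        kobs = kon * concentration + koff
        req = rmax * concentration / (concentration + koff / kon)
        out.append(req * (1.0 - math.exp(-kobs * t_assoc)))
    return tuple(out)


def predict_sensorgram(params: TwoSiteParams, curve: Sensorgram) -> np.ndarray:
    """Model response on a curve's own time axis (both phases)."""
    hi = _component_response(params.kon_high, params.koff_high, params.rmax_high,
                             curve.concentration, curve.time, curve.t_association_end)
    lo = _component_response(params.kon_low, params.koff_low, params.rmax_low,
                             curve.concentration, curve.time, curve.t_association_end)
    return hi + lo


class TwoSiteBindingModel(BaseEstimator):
    """Global multi-start fit of the two-site model across a dilution series.

    All four rate constants and both Rmax values are shared across curves.
    Rates are optimized in log10 space inside box bounds; ``n_starts``
    initializations (a deterministic log-spaced design plus seeded jitter)
    are run and the best objective kept.  Standard errors come from the
    Jacobian at the optimum; a rank-deficient Jacobian raises an
    identifiability warning.

    Attributes: params_, stderr_, cost_, residuals_, n_starts_converged_.
    """

    def __init__(self, n_starts: int = 10,
                 kon_bounds=KON_BOUNDS, koff_bounds=KOFF_BOUNDS,
                 random_state: int = 0):
        self.n_starts = n_starts
        self.kon_bounds = kon_bounds
        self.koff_bounds = koff_bounds
        self.random_state = random_state

    def _residuals(self, theta, data: SensorgramSet):
        kon1, koff1, kon2, koff2 = 10.0 ** theta[:4]
        rmax1, rmax2 = theta[4], theta[5]
        res = []
        for curve in data.curves:
            model = (_component_response(kon1, koff1, rmax1, curve.concentration,
                                         curve.time, curve.t_association_end)
                     + _component_response(kon2, koff2, rmax2, curve.concentration,
                                           curve.time, curve.t_association_end))
            res.append(model - curve.response)
        return np.concatenate(res)

    def _starts(self, rmax_scale: float) -> List[np.ndarray]:
        lk_on = np.log10(self.kon_bounds)
        lk_off = np.log10(self.koff_bounds)
        base = []
        # deterministic design: fast/slow pairs bracketing the box
        for kon1 in np.linspace(lk_on[0] + 1, lk_on[1] - 1, 2):
            for koff1 in np.linspace(lk_off[0] + 1, lk_off[1] - 1, 2):
                base.append([kon1 + 1, koff1 - 1, kon1, koff1,
                             0.6 * rmax_scale, 0.6 * rmax_scale])
        rng = np.random.default_rng(self.random_state)
        while len(base) < self.n_starts:
            base.append([
                rng.uniform(lk_on[0] + 0.5, lk_on[1] - 0.5),
                rng.uniform(lk_off[0] + 0.5, lk_off[1] - 0.5),
                rng.uniform(lk_on[0] + 0.5, lk_on[1] - 0.5),
                rng.uniform(lk_off[0] + 0.5, lk_off[1] - 0.5),
                rng.uniform(0.2, 1.5) * rmax_scale,
                rng.uniform(0.2, 1.5) * rmax_scale,
            ])
        return [np.asarray(b, dtype=float) for b in base[: self.n_starts]]

    def fit(self, data: SensorgramSet, init: Optional[TwoSiteParams] = None):
        if len(data.curves) < 3:
            raise ValidationError("need >= 3 concentrations for a global fit")
        for curve in data.curves:
            if curve.t_association_end >= curve.time[-1]:
                raise ValidationError("each curve needs both phases")
        rmax_scale = max(float(np.max(c.response)) for c in data.curves)
        rmax_scale = max(rmax_scale, 1e-6)
        lo = [math.log10(self.kon_bounds[0]), math.log10(self.koff_bounds[0])] * 2 + [0.0, 0.0]
        hi = [math.log10(self.kon_bounds[1]), math.log10(self.koff_bounds[1])] * 2 + \
             [5.0 * rmax_scale, 5.0 * rmax_scale]
        starts = self._starts(rmax_scale)
        if init is not None:
            starts.insert(0, np.array([
                math.log10(init.kon_high), math.log10(init.koff_high),
                math.log10(init.kon_low), math.log10(init.koff_low),
                init.rmax_high, init.rmax_low,
            ]))
        best = None
        n_ok = 0
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            try:
                sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                                    args=(data,), method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if not sol.success:
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("no multi-start initialization converged")
        theta = best.x
        self.params_ = TwoSiteParams.ordered(
            10.0 ** theta[0], 10.0 ** theta[1],
            10.0 ** theta[2], 10.0 ** theta[3],
            theta[4], theta[5],
        )
        # stderr from the Jacobian at the optimum (linear approximation)
        J = best.jac
        n_res = sum(c.response.size for c in data.curves)
        dof = max(n_res - theta.size, 1)
        s2 = 2.0 * best.cost / dof
        JtJ = J.T @ J
        rank = np.linalg.matrix_rank(JtJ)
        if rank < theta.size:
            warnings.warn("rank-deficient Jacobian: parameters not all identifiable",
                          stacklevel=2)
            cov = s2 * np.linalg.pinv(JtJ)
        else:
            cov = s2 * np.linalg.inv(JtJ)
        err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        ln10 = math.log(10.0)
        # delta method back from log10-rate space; keep the fitted (unordered) labels
        stderr_lin = {
            "kon1": 10.0 ** theta[0] * ln10 * err[0],
            "koff1": 10.0 ** theta[1] * ln10 * err[1],
            "kon2": 10.0 ** theta[2] * ln10 * err[2],
            "koff2": 10.0 ** theta[3] * ln10 * err[3],
            "rmax1": err[4], "rmax2": err[5],
        }
        self.stderr_ = stderr_lin
        self.cost_ = float(best.cost)
        self.residuals_ = [
            predict_sensorgram(self.params_, c) - c.response for c in data.curves
        ]
        self.n_starts_converged_ = n_ok
        return self


def global_fit(data: SensorgramSet, init: Optional[TwoSiteParams] = None,
               n_starts: int = 10, random_state: int = 0) -> TwoSiteBindingModel:
    """Fit the shared two-site model to a sensorgram set; returns the estimator."""
    return TwoSiteBindingModel(n_starts=n_starts, random_state=random_state).fit(
        data, init=init)


class HyperbolicSteadyState(BaseEstimator, RegressorMixin):
    """Steady-state hyperbola fit Req(C) = Bmax*C/(KD_app + C).

    fit(X, y) takes concentrations (M) and plateau responses.  The 95%
    confidence interval on KD_app uses the parameter covariance with a
    t-distribution on n-2 degrees of freedom.

    Attributes: b_max_, kd_app_, ci95_kd_, stderr_b_max_, stderr_kd_.
    """

    def fit(self, X, y):
        C = np.asarray(X, dtype=float).reshape(-1)
        req = np.asarray(y, dtype=float).reshape(-1)
        if C.size != req.size:
            raise ValidationError("concentration and response arrays must match")
        if C.size < 4:
            raise ValidationError("need >= 4 steady-state points")
        if np.any(C <= 0):
            raise ValidationError("concentrations must be > 0 M")
        p0 = [float(np.max(req)) or 1.0, float(np.median(C))]
        try:
            popt, pcov = curve_fit(lambda c, bmax, kd: bmax * c / (kd + c),
                                   C, req, p0=p0, bounds=([0, 0], [np.inf, np.inf]),
                                   maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"steady-state fit did not converge: {exc}") from exc
        if popt[1] > np.max(C):
            warnings.warn(
                "apparent KD exceeds the highest concentration: all points in the "
                "near-linear regime, KD estimate unreliable", stacklevel=2)
        perr = np.sqrt(np.diag(pcov))
        tcrit = stats.t.ppf(0.975, df=C.size - 2)
        self.b_max_ = float(popt[0])
        self.kd_app_ = float(popt[1])
        self.stderr_b_max_ = float(perr[0])
        self.stderr_kd_ = float(perr[1])
        self.ci95_kd_ = (self.kd_app_ - tcrit * self.stderr_kd_,
                         self.kd_app_ + tcrit * self.stderr_kd_)
        return self

    def predict(self, X):
        C = np.asarray(X, dtype=float).reshape(-1)
        return self.b_max_ * C / (self.kd_app_ + C)


def steady_state_fit(points: Sequence[tuple]) -> SteadyStateFit:
    """Hyperbola fit of (concentration M, plateau response) points."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("points must be (concentration, response) pairs")
    est = HyperbolicSteadyState().fit(arr[:, 0], arr[:, 1])
    return SteadyStateFit(
        b_max=est.b_max_, kd_app=est.kd_app_, ci95_kd=est.ci95_kd_,
        stderr_b_max=est.stderr_b_max_, stderr_kd=est.stderr_kd_,
    )


def steady_state_points(data: SensorgramSet, tail_fraction: float = 0.05):
    """(C, Req) pairs from the mean response over the last fraction of association."""
    pts = []
    for curve in data.curves:
        mask = (curve.time <= curve.t_association_end) & \
               (curve.time >= curve.t_association_end * (1.0 - tail_fraction))
        pts.append((curve.concentration, float(np.mean(curve.response[mask]))))
    return pts
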