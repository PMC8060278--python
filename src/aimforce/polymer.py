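"""Worm-like chain (WLC) polymer elasticity.

The interpolation form of the WLC force-extension relation,

    F(x) * L_p / (k_B T) = 1/4 * (1 - x/L_c)^-2 - 1/4 + x/L_c,

relates the tension ``F`` on an unstructured polypeptide to its end-to-end
distance ``x`` through the contour length ``L_c`` (fully stretched length,
nm) and persistence length ``L_p`` (bending stiffness scale, nm).  The
module provides the forward model, its numerical inverse, nonlinear
least-squares fitting of rupture (force, extension) data in scikit-learn
estimator form, and the conversion from a fitted contour-length increment
to the number of residues released by an unfolding event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DomainError, FitError, ValidationError
from .thermal import ThermalContext, ROOM_TEMPERATURE

#: Contour length gained per unfolded residue (nm/residue). Not a measured
#: constant of this dataset but the standard crystallographic backbone
#: spacing used to translate contour-length increments into residue counts.
NM_PER_RESIDUE = 0.4

# Fit box constraints; stable for rip-sized (10-30 nm) polypeptide data.
LP_BOUNDS = (0.05, 5.0)
LC_BOUNDS = (1.0, 200.0)

_EDGE = 1.0 - 1e-9  # fractional-extension guard against the 1/(1-x/Lc)^2 pole


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: contour length and persistence length (nm)."""

    contour_length: float
    persistence_length: float

    def __post_init__(self) -> None:
        if not (self.contour_length > 0 and self.persistence_length > 0):
            raise ValidationError(
                "contour_length and persistence_length must be > 0, got "
                f"({self.contour_length}, {self.persistence_length})"
            )


@dataclass(frozen=True)
class WLCFitResult:
    """Fitted WLC parameters with standard errors of the fit."""

    params: WLCParams
    stderr_contour_length: float
    stderr_persistence_length: float
    n_points: int
    residual_rms: float  # rms force residual, pN

    def to_dict(self) -> dict:
        return {
            "contour_length_nm": self.params.contour_length,
            "persistence_length_nm": self.params.persistence_length,
            "stderr_contour_length_nm": self.stderr_contour_length,
            "stderr_persistence_length_nm": self.stderr_persistence_length,
            "n_points": self.n_points,
            "residual_rms_pN": self.residual_rms,
        }


def _wlc_force_raw(x: np.ndarray, lc: float, lp: float, kbt: float) -> np.ndarray:
    """Interpolation formula with the pole softly clipped (for optimizer safety)."""
    r = np.minimum(np.asarray(x, dtype=float) / lc, _EDGE)
    return (kbt / lp) * (0.25 / (1.0 - r) ** 2 - 0.25 + r)


def wlc_force(params: WLCParams, x, ctx: ThermalContext = ROOM_TEMPERATURE):
    """Tension (pN) of a worm-like chain at end-to-end distance ``x`` (nm).

    Vectorized over ``x``. Valid for 0 <= x < L_c; the force diverges as the
    chain approaches full extension.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa >= params.contour_length):
        raise DomainError(
            f"extension must satisfy 0 <= x < L_c = {params.contour_length} nm"
        )
    out = _wlc_force_raw(xa, params.contour_length, params.persistence_length,
                         ctx.thermal_energy)
    return out if out.ndim else float(out)


def wlc_extension(params: WLCParams, f, ctx: ThermalContext = ROOM_TEMPERATURE):
    """Numerical inverse of :func:`wlc_force`: extension (nm) at force ``f`` (pN).

    Safeguarded bisection on [0, L_c*(1-1e-9)] to an absolute tolerance of
    1e-9 nm; vectorized over ``f``.
    """
    fa = np.asarray(f, dtype=float)
    if np.any(fa < 0):
        raise DomainError("force must be >= 0 pN")
    lo = np.zeros_like(fa, dtype=float)
    hi = np.full_like(fa, params.contour_length * _EDGE, dtype=float)
    # ~68 halvings brings any bracket of width <= 200 nm below 1e-9 nm.
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        too_low = _wlc_force_raw(mid, params.contour_length,
                                 params.persistence_length,
                                 ctx.thermal_energy) < fa
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    out = 0.5 * (lo + hi)
    out = np.where(fa == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def contour_to_residues(contour_length: float, nm_per_residue: float = NM_PER_RESIDUE) -> int:
    """Number of residues corresponding to a contour-length increment.

    Round-half-up of ``L_c / nm_per_residue``.  No folded-state end-to-end
    correction is subtracted (configurable upstream by adjusting ``contour_length``
    before the call).
    """
    if not (contour_length > 0 and nm_per_residue > 0):
        raise ValidationError("contour_length and nm_per_residue must be > 0")
    return int(math.floor(contour_length / nm_per_residue + 0.5))


class WormLikeChainModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares WLC fit: extension (nm) -> force (pN).

    Parameters
    ----------
    temperature : float, K
    init : WLCParams or None
        Starting point.  Default: L_c = 1.2 * max(extension) and L_p = 0.5 nm.
    lc_bounds, lp_bounds : (low, high)
        Box constraints on the two parameters.

    Attributes
    ----------
    contour_length_, persistence_length_ : fitted parameters (nm)
    stderr_contour_length_, stderr_persistence_length_ : standard errors (nm)
    n_points_ : number of fitted points
    residual_rms_ : rms force residual (pN); unweighted least squares
    """

    def __init__(self, temperature: float = ROOM_TEMPERATURE.temperature,
                 init: Optional[WLCParams] = None,
                 lc_bounds=LC_BOUNDS, lp_bounds=LP_BOUNDS):
        self.temperature = temperature
        self.init = init
        self.lc_bounds = lc_bounds
        self.lp_bounds = lp_bounds

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        f = np.asarray(y, dtype=float).reshape(-1)
        if x.size != f.size:
            raise ValidationError("extension and force arrays must be the same length")
        if x.size < 3:
            raise ValidationError(f"need >= 3 points to fit a 2-parameter WLC, got {x.size}")
        if np.any(f <= 0):
            raise ValidationError("forces must be > 0 pN for WLC fitting")
        if np.ptp(x) == 0.0:
            raise ValidationError("degenerate data: all extensions identical")
        ctx = ThermalContext(self.temperature)
        if self.init is not None:
            p0 = [self.init.contour_length, self.init.persistence_length]
        else:
            p0 = [1.2 * float(np.max(x)), 0.5]
        p0[0] = float(np.clip(p0[0], *self.lc_bounds))
        p0[1] = float(np.clip(p0[1], *self.lp_bounds))
        try:
            popt, pcov = curve_fit(
                lambda xx, lc, lp: _wlc_force_raw(xx, lc, lp, ctx.thermal_energy),
                x, f, p0=p0,
                bounds=([self.lc_bounds[0], self.lp_bounds[0]],
                        [self.lc_bounds[1], self.lp_bounds[1]]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - hard to trigger deterministically
            raise FitError(f"WLC fit did not converge: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        resid = f - _wlc_force_raw(x, *popt, ctx.thermal_energy)
        self.contour_length_ = float(popt[0])
        self.persistence_length_ = float(popt[1])
        self.stderr_contour_length_ = float(perr[0])
        self.stderr_persistence_length_ = float(perr[1])
        self.n_points_ = int(x.size)
        self.residual_rms_ = float(np.sqrt(np.mean(resid ** 2)))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        ctx = ThermalContext(self.temperature)
        return _wlc_force_raw(x, self.contour_length_, self.persistence_length_,
                              ctx.thermal_energy)

    def result_(self) -> WLCFitResult:
        return WLCFitResult(
            params=WLCParams(self.contour_length_, self.persistence_length_),
            stderr_contour_length=self.stderr_contour_length_,
            stderr_persistence_length=self.stderr_persistence_length_,
            n_points=self.n_points_,
            residual_rms=self.residual_rms_,
        )


def fit_wlc(points: Sequence[tuple], ctx: ThermalContext = ROOM_TEMPERATURE,
            init: Optional[WLCParams] = None) -> WLCFitResult:
    """Fit the WLC model to (force pN, extension nm) pairs.

    Extension is the predictor and force the response; residuals are in
    force, unweighted.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("points must be an iterable of (force, extension) pairs")
    est = WormLikeChainModel(temperature=ctx.temperature, init=init)
    est.fit(arr[:, 1], arr[:, 0])
    return est.result_()
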