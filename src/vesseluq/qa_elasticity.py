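"""Elastic-modulus estimation from flow--area (QA) curves.

A single imaging plane yields, over one cardiac cycle, the lumen
cross-sectional area ``A(t)`` and the through-plane volumetric flow
``Q(t)``.  During the reflection-free early-systolic upstroke the QA loop
is approximately linear and its slope is the local pulse wave velocity,

    PWV = dQ/dA |_{early systole}.

The wall elastic modulus then follows from the chi-corrected stiffness
formula

    E = 3 * chi * rho * PWV^2 * (1 + A0 / WCSA),

where ``A0`` is the diastolic lumen area, ``WCSA`` the wall cross-sectional
area (annulus between inner and outer wall contours), ``rho`` the blood
density, and ``chi = gamma / RAC`` a dimensionless correction built from
the relative area change ``RAC`` over the cycle and a factor ``gamma``
that depends on diastolic area, flow and internal pressure.  The internal
form of ``gamma`` is deliberately *not* fixed here: it is a user-supplied
scalar or callable, with a default that makes ``chi = 1`` and thus reduces
the formula to its uncorrected form.

All quantities are strict SI (m, s, kg, Pa); megapascals appear only in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .errors import (
    DegenerateFitError,
    DegenerateInputError,
    NonPhysicalSlopeError,
    WindowTooSmallError,
    ZeroDeformationError,
)

__all__ = [
    "QACurveSet",
    "EarlySystoleWindow",
    "PWVEstimate",
    "VesselGeometry",
    "ElasticityEstimate",
    "detect_early_systole",
    "fit_pwv",
    "compute_rac",
    "compute_chi",
    "estimate_elastic_modulus",
    "pwv_from_modulus",
    "estimate_from_curves",
]

BLOOD_DENSITY = 1060.0  # kg/m^3, whole blood


@dataclass(frozen=True)
class QACurveSet:
    """Sampled flow--area curves over one cardiac cycle.

    ``time`` is strictly increasing within ``[0, period]``; sampling need
    not be uniform.  Flow in m^3/s, area in m^2.
    """

    time: np.ndarray
    flow: np.ndarray
    area: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if not (len(t) == len(q) == len(a)):
            raise ValueError("time, flow and area must have equal length")
        if len(t) < 8:
            raise ValueError("need at least 8 samples per cycle")
        if not self.period > 0:
            raise ValueError("period must be > 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if t[0] < 0 or t[-1] > self.period + 1e-12:
            raise ValueError("time samples must lie within [0, period]")
        if np.any(a <= 0):
            raise ValueError("all area samples must be > 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", q)
        object.__setattr__(self, "area", a)

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class EarlySystoleWindow:
    """Inclusive index range on the early-systolic flow upstroke."""

    start_index: int
    end_index: int
    method: str = "manual"

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError("require 0 <= start_index < end_index")
        if self.n_samples < 3:
            raise ValueError("window must contain at least 3 samples")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)


@dataclass(frozen=True)
class PWVEstimate:
    """Pulse wave velocity from a linear QA-loop fit, with goodness of fit."""

    pwv: float
    r_squared: float
    window: EarlySystoleWindow
    intercept: float = 0.0


@dataclass(frozen=True)
class VesselGeometry:
    """Diastolic lumen area ``A0`` and wall cross-sectional area, both m^2."""

    lumen_area_diastole: float
    wall_cross_sectional_area: float

    def __post_init__(self) -> None:
        if not (self.lumen_area_diastole > 0 and self.wall_cross_sectional_area > 0):
            raise ValueError("areas must be > 0")

    @property
    def area_ratio(self) -> float:
        """``A0 / WCSA``, the lumen-to-wall area ratio entering the formula."""
        return self.lumen_area_diastole / self.wall_cross_sectional_area


@dataclass(frozen=True)
class ElasticityEstimate:
    """Elastic modulus with the intermediate quantities that produced it."""

    elastic_modulus: float
    chi: float
    gamma: float
    rac: float
    pwv: float
    blood_density: float

    def __post_init__(self) -> None:
        if self.elastic_modulus <= 0 or self.chi <= 0 or self.blood_density <= 0:
            raise ValueError("elastic_modulus, chi and blood_density must be > 0")
        if not (0 < self.rac < 1):
            raise ValueError("rac must lie in (0, 1)")
        if abs(self.chi * self.rac - self.gamma) > 1e-9 * max(abs(self.gamma), 1e-30):
            raise ValueError("inconsistent chi, rac, gamma (chi*rac must equal gamma)")


def detect_early_systole(
    curves: QACurveSet,
    low_fraction: float = 0.15,
    high_fraction: float = 0.85,
) -> EarlySystoleWindow:
    """Locate the early-systolic window on the first rising limb of flow.

    The window is the contiguous index run on the upstroke leading to the
    systolic peak where flow lies between ``low_fraction`` and
    ``high_fraction`` of the peak value.  Fractional thresholds are used
    because no universal frame rule exists; both bounds are overridable, and
    an explicit :class:`EarlySystoleWindow` may be passed downstream instead.
    """
    if not (0 <= low_fraction < high_fraction <= 1):
        raise ValueError("require 0 <= low_fraction < high_fraction <= 1")
    q = curves.flow
    peak = int(np.argmax(q))
    qmax = q[peak]
    qmin = float(np.min(q))
    if qmax - qmin <= 0 or peak == 0:
        raise DegenerateInputError("flow has no rising limb (constant or decreasing)")
    # walk back from the peak to the start of its rising limb
    rise_start = peak
    while rise_start > 0 and q[rise_start - 1] < q[rise_start]:
        rise_start -= 1
    lo = qmin + low_fraction * (qmax - qmin)
    hi = qmin + high_fraction * (qmax - qmin)
    idx = [i for i in range(rise_start, peak + 1) if lo <= q[i] <= hi]
    if len(idx) < 3:
        raise WindowTooSmallError(
            f"only {len(idx)} samples qualify in ({low_fraction}, {high_fraction}) "
            "of peak flow; widen the fractions or supply an explicit window"
        )
    # contiguous run ending closest to the peak
    start, end = idx[0], idx[0]
    best = (start, end)
    for i in idx[1:]:
        if i == end + 1:
            end = i
        else:
            start, end = i, i
        if end - start >= best[1] - best[0]:
            best = (start, end)
    if best[1] - best[0] + 1 < 3:
        raise WindowTooSmallError("no contiguous upstroke run of >= 3 samples")
    return EarlySystoleWindow(best[0], best[1], method=f"fractions({low_fraction},{high_fraction})")


def fit_pwv(curves: QACurveSet, window: EarlySystoleWindow) -> PWVEstimate:
    """Ordinary least-squares slope of Q on A over the window samples.

    The slope is the pulse wave velocity in m/s; ``r_squared`` reports the
    goodness of the same linear fit.  A non-positive slope signals a wrong
    window or corrupted data and raises rather than returning nonsense.
    """
    if window.end_index >= len(curves):
        raise ValueError("window exceeds curve length")
    sl = window.slice()
    a = curves.area[sl]
    q = curves.flow[sl]
    var_a = np.var(a)
    if var_a == 0:
        raise DegenerateFitError("zero area variance in window")
    cov = np.mean((a - a.mean()) * (q - q.mean()))
    slope = cov / var_a
    intercept = q.mean() - slope * a.mean()
    if slope <= 0:
        raise NonPhysicalSlopeError(
            f"fitted dQ/dA = {slope:.3g} <= 0; check the window or the data"
        )
    resid = q - (slope * a + intercept)
    ss_tot = np.sum((q - q.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return PWVEstimate(pwv=float(slope), r_squared=float(min(max(r2, 0.0), 1.0)),
                       window=window, intercept=float(intercept))


def compute_rac(curves: QACurveSet, denominator: str = "max") -> float:
    """Relative area change over the cycle, ``(Amax - Amin) / denom``.

    ``denominator`` selects the normalization convention: ``"max"`` (default),
    ``"min"``, or ``"mean"``.  The default keeps RAC in (0, 1) by
    construction.
    """
    a = curves.area
    amax, amin = float(np.max(a)), float(np.min(a))
    if amax == amin:
        raise ZeroDeformationError("area is constant; RAC undefined")
    denoms = {"max": amax, "min": amin, "mean": float(np.mean(a))}
    try:
        denom = denoms[denominator]
    except KeyError:
        raise ValueError(f"unknown denominator convention {denominator!r}") from None
    return (amax - amin) / denom


def compute_chi(gamma: float, rac: float) -> float:
    """Correction factor ``chi = gamma / RAC``."""
    if rac <= 0:
        raise ValueError("rac must be > 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return gamma / rac


def estimate_elastic_modulus(
    pwv: Union[PWVEstimate, float],
    geometry: VesselGeometry,
    blood_density: float = BLOOD_DENSITY,
    chi: float = 1.0,
    *,
    rac: float | None = None,
) -> Union[float, ElasticityEstimate]:
    """Elastic modulus ``E = 3 chi rho PWV^2 (1 + A0/WCSA)`` in Pa.

    If ``rac`` is provided, a full :class:`ElasticityEstimate` (with
    ``gamma = chi * rac``) is returned; otherwise the bare modulus.
    """
    v = pwv.pwv if isinstance(pwv, PWVEstimate) else float(pwv)
    if v <= 0 or blood_density <= 0 or chi <= 0:
        raise ValueError("pwv, blood_density and chi must be > 0")
    e = 3.0 * chi * blood_density * v**2 * (1.0 + geometry.area_ratio)
    if rac is None:
        return e
    return ElasticityEstimate(
        elastic_modulus=e, chi=chi, gamma=chi * rac, rac=rac, pwv=v,
        blood_density=blood_density,
    )


def pwv_from_modulus(
    elastic_modulus: float,
    geometry: VesselGeometry,
    blood_density: float = BLOOD_DENSITY,
    chi: float = 1.0,
) -> float:
    """Algebraic inverse of :func:`estimate_elastic_modulus`.

    ``PWV = sqrt(E / (3 chi rho (1 + A0/WCSA)))`` -- the wave speed a wall
    of modulus ``E`` implies for this geometry.
    """
    if elastic_modulus <= 0 or blood_density <= 0 or chi <= 0:
        raise ValueError("elastic_modulus, blood_density and chi must be > 0")
    return float(
        np.sqrt(elastic_modulus / (3.0 * chi * blood_density * (1.0 + geometry.area_ratio)))
    )


GammaLike = Union[float, Callable[[QACurveSet], float], None]


def _resolve_gamma(gamma: GammaLike, curves: QACurveSet, rac: float) -> float:
    """Resolve the user-supplied gamma convention.

    ``None`` chooses ``gamma = rac`` so that ``chi = 1`` (uncorrected
    formulation); a callable receives the curve set.
    """
    if gamma is None:
        return rac
    if callable(gamma):
        return float(gamma(curves))
    return float(gamma)


def estimate_from_curves(
    curves: QACurveSet,
    geometry: VesselGeometry,
    blood_density: float = BLOOD_DENSITY,
    gamma: GammaLike = None,
    *,
    low_fraction: float = 0.15,
    high_fraction: float = 0.85,
    window: EarlySystoleWindow | None = None,
    rac_denominator: str = "max",
) -> tuple[ElasticityEstimate, PWVEstimate]:
    """Full estimation chain: window detection, PWV fit, chi, modulus."""
    if window is None:
        window = detect_early_systole(curves, low_fraction, high_fraction)
    pwv = fit_pwv(curves, window)
    rac = compute_rac(curves, denominator=rac_denominator)
    g = _resolve_gamma(gamma, curves, rac)
    chi = compute_chi(g, rac)
    est = estimate_elastic_modulus(pwv, geometry, blood_density, chi, rac=rac)
    return est, pwv
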