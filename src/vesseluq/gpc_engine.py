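"""Non-intrusive generalized Polynomial Chaos for one uniform parameter.

The uncertain input is a single scalar (here: an elastic modulus) with a
uniform distribution on ``[center*(1-h), center*(1+h)]``.  Uniform inputs
pair with Legendre polynomials, so the machinery below is the classical
Legendre chaos on the standard coordinate ``zeta in [-1, 1]`` with
probability weight ``eta(zeta) = 1/2``:

* a Gauss--Legendre quadrature rule supplies the parameter values at which
  the deterministic model must be run (one run per node);
* spectral projection turns the model outputs at the nodes into expansion
  coefficients ``a_r``, independently for every output sample (time index,
  cross-section, quantity);
* the truncated series is a cheap surrogate that yields moments, sampled
  probability densities, and a coefficient-decay convergence diagnostic.

With the ``eta = 1/2`` normalization the Legendre basis satisfies
``<P_r, P_r> = 1/(2r+1)``, hence the projection constant ``(2r+1)`` and the
variance formula ``sum_r a_r^2/(2r+1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

from .errors import ConvergenceWarning

__all__ = [
    "UniformParameter",
    "QuadratureRule",
    "GPCExpansion",
    "StochasticSummary",
    "gauss_legendre_rule",
    "parameter_values_from_rule",
    "legendre_eval",
    "project",
    "evaluate_surrogate",
    "moments",
    "estimate_pdf",
    "convergence_ratios",
]

#: default warning threshold on max |a_n / a_0| (coefficient-decay check)
DEFAULT_DECAY_THRESHOLD = 0.1


@dataclass(frozen=True)
class UniformParameter:
    """Uniformly distributed scalar parameter, e.g. an elastic modulus in Pa.

    ``halfwidth_fraction`` is the relative half-width of the support: the
    parameter lives on ``[center*(1-h), center*(1+h)]``.  The default 0.23
    covers a roughly +/-20% estimation error with margin.
    """

    center: float
    halfwidth_fraction: float = 0.23

    def __post_init__(self) -> None:
        if not (self.center > 0):
            raise ValueError("center must be > 0")
        if not (0 <= self.halfwidth_fraction < 1):
            raise ValueError("halfwidth_fraction must lie in [0, 1)")

    @property
    def support_low(self) -> float:
        return self.center * (1.0 - self.halfwidth_fraction)

    @property
    def support_high(self) -> float:
        return self.center * (1.0 + self.halfwidth_fraction)

    def value_from_zeta(self, zeta):
        """Affine map from the standard coordinate in [-1, 1] to the support."""
        return self.center * (1.0 + self.halfwidth_fraction * np.asarray(zeta, float))


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss--Legendre rule on [-1, 1] with weights under ``eta = 1/2``.

    ``nodes`` are stored in ascending order; ``weights`` sum to 1 so they act
    as a discrete probability measure.
    """

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.nodes)


def gauss_legendre_rule(n_points: int) -> QuadratureRule:
    """Build the ``n_points``-point Gauss--Legendre rule on [-1, 1].

    Nodes are the roots of the degree-``n_points`` Legendre polynomial;
    weights are the standard Gauss--Legendre weights rescaled by 1/2 so that
    they sum to one (probability normalization).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    nodes, weights = npleg.leggauss(n_points)
    return QuadratureRule(nodes=nodes, weights=weights / 2.0)


def parameter_values_from_rule(
    rule: QuadratureRule, parameter: UniformParameter
) -> np.ndarray:
    """Map quadrature nodes onto parameter values, largest first.

    The descending order matches the conventional labelling x1 > x2 > ... of
    the deterministic runs.
    """
    values = parameter.value_from_zeta(rule.nodes)
    return values[::-1].copy()


def legendre_eval(r: int, zeta, *, extrapolate: bool = False):
    """Evaluate the degree-``r`` Legendre polynomial at ``zeta``.

    ``zeta`` outside [-1, 1] raises unless ``extrapolate`` is set, in which
    case a warning is emitted (the surrogate is only meaningful on the
    support of the uncertain parameter).
    """
    if r < 0:
        raise ValueError("degree r must be >= 0")
    z = np.asarray(zeta, dtype=float)
    if np.any(np.abs(z) > 1.0 + 1e-12):
        if not extrapolate:
            raise ValueError("zeta outside [-1, 1]; pass extrapolate=True to override")
        warnings.warn("evaluating Legendre basis outside [-1, 1]", stacklevel=2)
    coef = np.zeros(r + 1)
    coef[r] = 1.0
    out = npleg.legval(z, coef)
    return float(out) if np.isscalar(zeta) else out


@dataclass(frozen=True)
class GPCExpansion:
    """Legendre-chaos coefficients ``a_r`` for one or many output samples.

    ``coefficients`` has shape ``(order+1,) + sample_shape``; a scalar model
    has ``sample_shape == ()``, a time series ``(n_t,)``.
    """

    coefficients: np.ndarray
    basis: str = "legendre"

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim < 1:
            raise ValueError("coefficients must have at least one axis (degree)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", c)

    @property
    def order(self) -> int:
        return self.coefficients.shape[0] - 1

    @property
    def sample_shape(self) -> tuple:
        return self.coefficients.shape[1:]


def project(model_outputs, rule: QuadratureRule, order: int) -> GPCExpansion:
    """Spectral projection of model outputs evaluated at the quadrature nodes.

    ``model_outputs`` has shape ``(rule.n_points,) + sample_shape``, with the
    first axis aligned to ``rule.nodes`` (ascending zeta).  The discrete
    projection reads ``a_r = (2r+1) * sum_q w_q X(zeta_q) P_r(zeta_q)``,
    applied independently to every trailing sample.
    """
    X = np.asarray(model_outputs, dtype=float)
    if X.shape[0] != rule.n_points:
        raise ValueError(
            f"model_outputs first axis ({X.shape[0]}) must equal "
            f"rule.n_points ({rule.n_points})"
        )
    if rule.n_points < order + 1:
        raise ValueError("need at least order+1 quadrature points")
    # V[q, r] = P_r(zeta_q)
    V = npleg.legvander(rule.nodes, order)
    scale = 2.0 * np.arange(order + 1) + 1.0
    flat = X.reshape(rule.n_points, -1)
    coeffs = scale[:, None] * (V * rule.weights[:, None]).T @ flat
    return GPCExpansion(coefficients=coeffs.reshape((order + 1,) + X.shape[1:]))


def evaluate_surrogate(expansion: GPCExpansion, zeta, *, extrapolate: bool = False):
    """Evaluate the truncated series ``sum_r a_r P_r(zeta)``.

    For an expansion over a time series and array-valued ``zeta`` the result
    has shape ``sample_shape + zeta.shape``.
    """
    z = np.asarray(zeta, dtype=float)
    if np.any(np.abs(z) > 1.0 + 1e-12):
        if not extrapolate:
            raise ValueError("zeta outside [-1, 1]; pass extrapolate=True to override")
        warnings.warn("evaluating surrogate outside [-1, 1]", stacklevel=2)
    out = npleg.legval(z, expansion.coefficients)
    return float(out) if (np.isscalar(zeta) and expansion.sample_shape == ()) else out


def moments(expansion: GPCExpansion):
    """Mean and standard deviation per sample, from the coefficients alone.

    ``mean = a_0``; ``var = sum_{r>=1} a_r^2 / (2r+1)`` under the uniform
    input density.
    """
    c = expansion.coefficients
    mean = c[0].copy()
    r = np.arange(1, expansion.order + 1)
    if len(r):
        var = np.tensordot(1.0 / (2.0 * r + 1.0), c[1:] ** 2, axes=(0, 0))
    else:
        var = np.zeros_like(mean)
    return mean, np.sqrt(var)


@dataclass
class StochasticSummary:
    """Time-resolved stochastic description of one output quantity.

    ``pdf`` holds the estimated density on a shared value axis
    (``bin_centers``), one column per time instant, each column normalized to
    unit integral.  ``point_mass`` flags instants where the surrogate is
    (numerically) constant and the density degenerates to a single bin.
    """

    time: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    bin_centers: np.ndarray
    pdf: np.ndarray
    point_mass: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.point_mass is None:
            self.point_mass = np.zeros(np.shape(self.mean), dtype=bool)


# width below which a value axis is treated as degenerate (relative to scale)
_DEGENERATE_REL_WIDTH = 1e-12


def estimate_pdf(
    expansion: GPCExpansion,
    n_samples: int = 100_000,
    seed: int = 0,
    n_bins: int = 64,
    *,
    time: np.ndarray | None = None,
    chunk: int = 20_000,
):
    """Monte-Carlo density of the surrogate output, per time instant.

    Draws ``zeta ~ Uniform[-1, 1]`` with the given seed, pushes the samples
    through the truncated expansion, and histograms the values on ``n_bins``
    over the observed range (a shared value axis across time, so the result
    is directly plottable as a density surface).  Sampling is favoured over
    an analytic change of variables because cubic surrogates may be
    non-monotone on the support, making the analytic density multi-branch.

    Returns a :class:`StochasticSummary` whose mean/std come from the
    coefficients (exact under the expansion), not from the samples.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    c = expansion.coefficients
    if c.ndim == 1:
        c = c[:, None]
        squeeze = True
    else:
        squeeze = False
    n_t = int(np.prod(c.shape[1:]))
    c2 = c.reshape(c.shape[0], n_t)

    # value-axis range from a dense deterministic sweep of the surrogate
    zg = np.linspace(-1.0, 1.0, 513)
    sweep = npleg.legval(zg, c2)          # (n_t, 513)
    lo_t, hi_t = sweep.min(axis=1), sweep.max(axis=1)
    lo, hi = float(lo_t.min()), float(hi_t.max())
    scale = max(abs(lo), abs(hi), 1.0e-300)
    if hi - lo <= _DEGENERATE_REL_WIDTH * scale:
        # constant surrogate everywhere: single-bin point mass
        centers = np.array([0.5 * (lo + hi)])
        pdf = np.full((1, n_t), np.inf)
        mean, std = moments(expansion)
        summ = StochasticSummary(
            time=np.arange(n_t) if time is None else time,
            mean=mean.reshape(-1) if not squeeze else mean,
            std=std.reshape(-1) if not squeeze else std,
            bin_centers=centers,
            pdf=pdf[:, 0] if squeeze else pdf,
            point_mass=np.ones(n_t, dtype=bool),
        )
        return summ

    edges = np.linspace(lo, hi, n_bins + 1)
    width = edges[1] - edges[0]
    counts = np.zeros((n_bins, n_t))
    rng = np.random.default_rng(seed)
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        zeta = rng.uniform(-1.0, 1.0, size=m)
        vals = npleg.legval(zeta, c2)     # (n_t, m)
        idx = np.clip(((vals - lo) / width).astype(np.int64), 0, n_bins - 1)
        flat = (idx + n_bins * np.arange(n_t)[:, None]).ravel()
        counts += np.bincount(flat, minlength=n_bins * n_t).reshape(n_t, n_bins).T

    pdf = counts / (n_samples * width)
    # per-instant degenerate columns: all mass in one bin
    point_mass = (hi_t - lo_t) <= _DEGENERATE_REL_WIDTH * scale
    mean, std = moments(expansion)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return StochasticSummary(
        time=np.arange(n_t) if time is None else np.asarray(time),
        mean=mean.reshape(n_t) if not squeeze else mean,
        std=std.reshape(n_t) if not squeeze else std,
        bin_centers=centers,
        pdf=pdf[:, 0] if squeeze else pdf,
        point_mass=point_mass,
    )


def convergence_ratios(
    expansion: GPCExpansion,
    *,
    threshold: float = DEFAULT_DECAY_THRESHOLD,
    warn: bool = False,
    a0_floor: float = 0.05,
):
    """Coefficient-decay diagnostic ``|a_r / a_0|`` for r = 1..n.

    Samples where ``a_0`` vanishes -- or, for multi-sample expansions, where
    ``|a_0|`` falls below ``a0_floor`` times the stream's largest ``|a_0|``
    -- are flagged (NaN in the returned ratios) and excluded from the
    summary maximum: a signed quantity such as flow crosses zero within the
    cycle, and a ratio normalized by a near-zero mean is not a truncation
    diagnostic.  If ``warn`` is set, a :class:`ConvergenceWarning` is
    emitted when the highest-order summary ratio exceeds ``threshold``,
    signalling that the truncation order may be too low for the model.

    Returns ``(ratios, max_per_order)`` where ``ratios`` has shape
    ``(order,) + sample_shape``.
    """
    c = expansion.coefficients
    a0 = c[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.abs(c[1:]) / np.abs(a0)
    scale = np.max(np.abs(a0)) if np.ndim(a0) else np.abs(a0)
    negligible = np.abs(a0) <= a0_floor * scale if np.ndim(a0) else (a0 == 0)
    ratios = np.where(negligible, np.nan, ratios)
    if ratios.ndim > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            max_per_order = np.nanmax(ratios.reshape(ratios.shape[0], -1), axis=1)
    else:
        max_per_order = ratios.copy()
    max_per_order = np.where(np.isnan(max_per_order), 0.0, max_per_order)
    if warn and len(max_per_order) and max_per_order[-1] > threshold:
        warnings.warn(
            f"gPC truncation may be insufficient: max |a_n/a_0| = "
            f"{max_per_order[-1]:.3g} exceeds {threshold}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return ratios, max_per_order
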