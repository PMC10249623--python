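"""Variable phase ratio headspace (VPR-HS) models and nonlinear fits.

Two closed-vial designs are covered, both of which vary phase volumes
across vials that receive the same spike and read out a headspace GC/MS
peak area (PA):

* **modified** — vials hold water + hexadecane with total liquid volume
  V_tot fixed; under mass balance, response linearity, and no sorption
  to third phases the peak area follows

      PA = alpha * m / (V_tot + (K_Hxd/w - 1) * V_Hxd)

  so K_Hxd/w is identified from the PA-vs-V_Hxd curve.  The instrument
  response factor alpha and the spike m are not separable and are fitted
  as one nuisance scale parameter ``scale = alpha * m``.
* **standard** — vials hold water only; the gas volume is the vial
  volume minus the water volume and

      PA = alpha * m / (V_gas + V_water / K_aw)

  identifies K_aw directly.

Fits are unweighted least squares on raw peak areas, parameterized in
log10 K so the search is unconstrained and stable over the many orders
of magnitude K spans.  Confidence intervals come from a seeded residual
bootstrap, since replicate-free series offer no other route.  A
residual diagnostic flags series whose shape departs systematically
from the model — the signature of sorptive losses that violate the
mass-balance assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import Quantity
from .exceptions import (
    ConvergenceError,
    InvalidGeometryError,
    InvalidInputError,
    UnderDeterminedError,
)

#: Convergence tolerance on relative parameter change.
XTOL = 1e-10
#: Iteration cap for the trust-region solver.
MAX_ITER = 500
#: Default number of residual-bootstrap resamples.
DEFAULT_BOOTSTRAP = 999

# Residual-diagnostic thresholds: flag only when misfit clearly exceeds
# numerical noise AND trends significantly with the varied volume.
_DIAG_MIN_REL_RESID = 0.01
_DIAG_CORR_P = 0.05


@dataclass
class HeadspaceSeries:
    """One VPR-HS experiment: (volume, peak area) pairs across vials.

    ``kind`` is ``"modified"`` (points are hexadecane volume vs PA, with
    ``v_tot`` the fixed total liquid volume) or ``"standard"`` (points
    are water volume vs PA, with ``vial_volume`` fixing the gas volume
    as vial_volume - v_water).
    """

    compound: str
    points: Sequence[Tuple[float, float]]
    kind: str = "modified"
    v_tot: float = 20.0
    vial_volume: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("modified", "standard"):
            raise InvalidInputError(f"unknown series kind {self.kind!r}")
        pts = [(float(v), float(pa)) for v, pa in self.points]
        if any(pa <= 0 for _, pa in pts):
            raise InvalidInputError("peak areas must be positive")
        if self.kind == "modified":
            if any(not 0 <= v <= self.v_tot for v, _ in pts):
                raise InvalidInputError(
                    "hexadecane volumes must lie in [0, v_tot]"
                )
        else:
            if self.vial_volume is None:
                raise InvalidGeometryError(
                    "standard series needs the vial volume"
                )
            if any(not 0 <= v < self.vial_volume for v, _ in pts):
                raise InvalidInputError(
                    "water volumes must lie in [0, vial_volume)"
                )
        if len({v for v, _ in pts}) < 2:
            raise UnderDeterminedError(
                "need >=2 distinct volumes to identify K"
            )
        self.points = pts

    @property
    def volumes(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    @property
    def peak_areas(self) -> np.ndarray:
        return np.array([pa for _, pa in self.points])


@dataclass
class VprhsFit:
    """Result of a VPR-HS least-squares fit."""

    log_k: float
    scale: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    n_iter: int = 0
    quantity: Quantity = Quantity.HXD_W
    systematic_residuals: bool = False


def modified_vprhs_predict(
    scale: float, log_k: float, v_tot: float, v_hxd
):
    """Peak area for the water+hexadecane design: scale/(V_tot+(K-1)V_Hxd).

    At K = 1 the liquid composition is irrelevant and PA = scale/V_tot;
    at V_Hxd = 0 the vial is pure water regardless of K.
    """
    if v_tot <= 0:
        raise InvalidInputError("v_tot must be positive")
    v = np.asarray(v_hxd, dtype=float)
    if np.any(v < 0) or np.any(v > v_tot):
        raise InvalidInputError("v_hxd must lie in [0, v_tot]")
    k = 10.0 ** log_k
    denom = v_tot + (k - 1.0) * v
    if np.any(denom <= 0):
        raise InvalidInputError("non-physical denominator (K < 1, large v_hxd)")
    out = scale / denom
    return float(out) if np.isscalar(v_hxd) else out


def standard_vprhs_predict(
    scale: float, log_kaw: float, v_gas, v_water
):
    """Peak area for the water-only design: scale/(V_gas + V_water/K_aw)."""
    vg = np.asarray(v_gas, dtype=float)
    vw = np.asarray(v_water, dtype=float)
    if np.any(vg <= 0):
        raise InvalidGeometryError("gas volume must be positive")
    if np.any(vw < 0):
        raise InvalidInputError("water volume must be non-negative")
    out = scale / (vg + vw / 10.0 ** log_kaw)
    scalar = np.isscalar(v_gas) and np.isscalar(v_water)
    return float(out) if scalar else out


def _initial_modified(series: HeadspaceSeries) -> Tuple[float, float]:
    """Starting values from the two-point identity PA(0)/PA(V_tot) = K.

    For arbitrary endpoints (v1, PA1), (v2, PA2) the exact two-point
    solution is K = 1 + V_tot (PA2 - PA1) / (PA1 v1 - PA2 v2), which
    reduces to PA(0)/PA(V_tot) when v1 = 0, v2 = V_tot.
    """
    pts = sorted(series.points)
    (v1, pa1), (v2, pa2) = pts[0], pts[-1]
    denom = pa1 * v1 - pa2 * v2
    k0 = 1.0
    if denom != 0:
        k0 = 1.0 + series.v_tot * (pa2 - pa1) / denom
    k0 = max(k0, 1e-3)
    log_k0 = math.log10(k0)
    scale0 = pa1 * (series.v_tot + (k0 - 1.0) * v1)
    return max(scale0, 1e-300), log_k0


def _initial_standard(series: HeadspaceSeries) -> Tuple[float, float]:
    """Two-point closed-form start for the standard design."""
    pts = sorted(series.points)
    (v1, pa1), (v2, pa2) = pts[0], pts[-1]
    vial = series.vial_volume
    g1, g2 = vial - v1, vial - v2
    # PA1 (g1 + v1/K) = PA2 (g2 + v2/K)  =>  1/K = (PA2 g2 - PA1 g1)/(PA1 v1 - PA2 v2)
    denom = pa1 * v1 - pa2 * v2
    inv_k = (pa2 * g2 - pa1 * g1) / denom if denom != 0 else 1.0
    k0 = 1.0 / inv_k if inv_k > 0 else 1.0
    log_k0 = math.log10(max(k0, 1e-12))
    scale0 = pa1 * (g1 + v1 / k0)
    return max(scale0, 1e-300), log_k0


def _predict(series: HeadspaceSeries, scale: float, log_k: float) -> np.ndarray:
    if series.kind == "modified":
        return modified_vprhs_predict(scale, log_k, series.v_tot, series.volumes)
    v_gas = series.vial_volume - series.volumes
    return standard_vprhs_predict(scale, log_k, v_gas, series.volumes)


def _lsq(series: HeadspaceSeries, x0: Tuple[float, float]):
    pa = series.peak_areas

    def resid(theta):
        log_scale, log_k = theta
        return _predict(series, 10.0 ** log_scale, log_k) - pa

    # Internally the scale is also log10 so both parameters are
    # unconstrained and comparably scaled.
    t0 = np.array([math.log10(x0[0]), x0[1]])
    return least_squares(resid, t0, xtol=XTOL, ftol=1e-14, gtol=1e-14,
                         max_nfev=MAX_ITER)


def _diagnose(series: HeadspaceSeries, predicted: np.ndarray,
              residuals: np.ndarray) -> bool:
    """Flag residuals that are both large and volume-correlated.

    Sorptive mass loss (glass wall, septum, air/water interface)
    distorts the PA-vs-volume curve into a shape outside the model
    family, leaving residuals that trend with the varied volume rather
    than scattering.  The flag requires the volume-residual Pearson
    correlation to be significant (two-sided p < 0.05), so plain
    measurement noise on a handful of vials rarely triggers it.
    """
    rel = residuals / predicted
    if np.max(np.abs(rel)) < _DIAG_MIN_REL_RESID:
        return False
    v = series.volumes
    if rel.size < 4 or np.std(rel) == 0 or np.std(v) == 0:
        return False
    from scipy import stats

    res = stats.pearsonr(v, rel)
    return res.pvalue < _DIAG_CORR_P


def _bootstrap_ci(series: HeadspaceSeries, fit_scale: float, fit_logk: float,
                  residuals: np.ndarray, seed: int, n_boot: int,
                  confidence: float) -> Tuple[float, float]:
    """Residual-bootstrap CI on log K.

    Measurement noise on peak areas is multiplicative, so *relative*
    residuals (residual / prediction) are the exchangeable quantity:
    they are centered, inflated by sqrt(n/(n-2)) to undo the shrinkage a
    2-parameter fit imposes, resampled with replacement onto the fitted
    curve, and refitted.  The interval is the symmetric bootstrap
    interval log_k +/- q, with q the ``confidence`` quantile of
    |log_k* - log_k| — better calibrated than the percentile interval
    at the few design points a VPR-HS series offers.
    """
    rng = np.random.default_rng(seed)
    predicted = _predict(series, fit_scale, fit_logk)
    rel = residuals / predicted
    n = rel.size
    rel = (rel - rel.mean()) * math.sqrt(n / (n - 2))
    x0 = (fit_scale, fit_logk)  # warm start: resampled fits start near optimum
    draws = np.empty(n_boot)
    for b in range(n_boot):
        pa_star = predicted * (1.0 + rng.choice(rel, size=n, replace=True))
        pa_star = np.maximum(pa_star, 1e-12 * predicted)
        star = HeadspaceSeries.__new__(HeadspaceSeries)
        star.compound = series.compound
        star.kind = series.kind
        star.v_tot = series.v_tot
        star.vial_volume = series.vial_volume
        star.points = list(zip(series.volumes, pa_star))
        draws[b] = _lsq(star, x0).x[1]
    half = float(np.quantile(np.abs(draws - fit_logk), confidence))
    return fit_logk - half, fit_logk + half


def _fit(series: HeadspaceSeries, seed: int, n_bootstrap: int,
         confidence: float, quantity: Quantity) -> VprhsFit:
    x0 = (_initial_modified(series) if series.kind == "modified"
          else _initial_standard(series))
    res = _lsq(series, x0)
    scale = 10.0 ** res.x[0]
    log_k = float(res.x[1])
    predicted = _predict(series, scale, log_k)
    residuals = series.peak_areas - predicted
    fit = VprhsFit(
        log_k=log_k,
        scale=scale,
        residuals=residuals,
        converged=res.status > 0,
        n_iter=int(res.nfev),
        quantity=quantity,
        systematic_residuals=_diagnose(series, predicted, residuals),
    )
    if not fit.converged:
        raise ConvergenceError(
            f"VPR-HS fit did not converge in {MAX_ITER} evaluations", fit=fit
        )
    if n_bootstrap > 0 and len(series.points) > 2:
        fit.ci_low, fit.ci_high = _bootstrap_ci(
            series, scale, log_k, residuals, seed, n_bootstrap, confidence
        )
    else:
        fit.ci_low, fit.ci_high = log_k, log_k
    return fit


def fit_modified_vprhs(
    series: HeadspaceSeries,
    seed: int = 0,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    confidence: float = 0.95,
) -> VprhsFit:
    """Fit (scale, log K_Hxd/w) to a water+hexadecane VPR-HS series.

    Initialization uses the exact two-point solution through the extreme
    volumes (the PA(0)/PA(V_tot) = K identity when endpoints exist), so
    noise-free series converge to machine precision in a few steps.
    """
    if series.kind != "modified":
        raise InvalidInputError("series kind must be 'modified'")
    return _fit(series, seed, n_bootstrap, confidence, Quantity.HXD_W)


def fit_standard_vprhs(
    series: HeadspaceSeries,
    seed: int = 0,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    confidence: float = 0.95,
) -> VprhsFit:
    """Fit (scale, log K_aw) to a water-only VPR-HS series."""
    if series.kind != "standard":
        raise InvalidInputError("series kind must be 'standard'")
    return _fit(series, seed, n_bootstrap, confidence, Quantity.AW)


def grid_search_fit(
    series: HeadspaceSeries,
    log_k_grid: np.ndarray,
) -> Tuple[float, float]:
    """Brute-force (log_k, scale) by 1-D grid over log_k.

    For fixed K the model is linear in the scale, whose least-squares
    optimum is closed-form: scale* = sum(PA u) / sum(u^2) with
    u_i = 1/denominator_i.  Intended as an independent cross-check of
    the iterative fit on small series.
    """
    pa = series.peak_areas
    best = (np.inf, np.nan, np.nan)
    for log_k in np.asarray(log_k_grid, dtype=float):
        u = _predict(series, 1.0, log_k)
        scale = float(pa @ u / (u @ u))
        sse = float(np.sum((pa - scale * u) ** 2))
        if sse < best[0]:
            best = (sse, log_k, scale)
    return best[1], best[2]
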