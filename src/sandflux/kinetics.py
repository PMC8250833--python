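"""Instantaneous denitrification rates and saturating-kinetics fitting.

During an acetylene-block incubation every depth traces out its own
N2O-accumulation curve.  Differentiating that curve in time (central
differences) and adding the diffusive transport correction gives an
*instantaneous* denitrification rate at each (depth, time) sample.  The
apparent NOx concentration still present in the porewater at that moment is
reconstructed from the accumulated N2O, the 2:1 N:N2O stoichiometry, and a
correction factor for NOx lost to processes other than denitrification.
Pairing rates with apparent concentrations yields a rate-versus-substrate
cloud that is fitted with the Hill equation

    R(C) = V_max * C**n / (K_M**n + C**n)

or its n = 1 special case (Michaelis-Menten), compared via AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError, InsufficientDataError, ValidationError
from .profiles import Analyte, FitModel, KineticsFit, ProfileSeries, SedimentCore
from .rates import flux_divergence
from . import units

logger = logging.getLogger(__name__)

#: Points whose N2O exceeds this fraction of the per-depth maximum sit on the
#: flat tail of the accumulation curve and are excluded from fitting.
DEFAULT_CEILING_EXCLUSION = 0.95

#: Relative RSS floor used in the AIC so that numerically perfect fits do
#: not drive ln(RSS) to -inf (see docs/methods.md).
_AIC_RSS_FLOOR_REL = 1e-8


@dataclass
class InstantRatePoint:
    """One (rate, apparent substrate) sample for kinetics fitting."""

    depth_m: float
    time_h: float
    rate: float            # mmol N m^-3 sediment h^-1; may be negative (noise)
    apparent_nox: float    # umol L^-1, clipped to [0, nox_init]


def central_difference_rate(series: ProfileSeries, depth_m: float
                            ) -> list[tuple[float, float]]:
    """Tangent-line slope dC/dt at one depth for each interior time.

    For profile n the derivative is approximated by the central difference
    (C_(n+1) - C_(n-1)) / (t_(n+1) - t_(n-1)); the first and last profiles
    have no two-sided neighbour and are excluded.

    Raises
    ------
    InsufficientDataError  if fewer than 3 profiles.
    KeyError  if ``depth_m`` is not on the series' depth grid.
    """
    if len(series) < 3:
        raise InsufficientDataError("central differences need >= 3 profiles")
    depths = series.depths
    idx = np.nonzero(np.isclose(depths, depth_m, rtol=0, atol=1e-12))[0]
    if idx.size == 0:
        raise KeyError(f"depth {depth_m} m is not on the profile grid")
    i = int(idx[0])
    t = series.times
    c = series.concentration_matrix[:, i]
    out = []
    for n in range(1, len(t) - 1):
        dcdt = (c[n + 1] - c[n - 1]) / (t[n + 1] - t[n - 1])
        out.append((float(t[n]), float(dcdt)))
    return out


def correction_factor(n2o_max: float, nox_init: float,
                      exact: bool = False) -> float:
    """Factor accounting for NOx consumed by processes other than
    denitrification.

    Assumes (nearly) all the initial NOx pool was consumed by the end of the
    incubation, so any shortfall of 2*N2O_max below nox_init is attributed
    to a non-denitrification sink:

        f = 1 + (1 - 2*N2O_max / NOx_init)

    With ``exact=True`` the alternative exhaustion normalisation
    ``f = NOx_init / (2*N2O_max)`` is used instead (differs in the second
    order of the sink fraction).

    Raises
    ------
    DomainError  if ``nox_init <= 0`` (or, for the exact form, n2o_max <= 0).
    """
    if nox_init <= 0:
        raise DomainError("nox_init must be > 0")
    ratio = 2.0 * n2o_max / nox_init
    if ratio > 1.0:
        warnings.warn(
            f"2*N2O_max = {2 * n2o_max:.3g} exceeds nox_init = {nox_init:.3g}; "
            "capping ratio at 1 (sensor noise above the stoichiometric "
            "ceiling)", stacklevel=2)
        ratio = 1.0
    if exact:
        if n2o_max <= 0:
            raise DomainError("exact correction needs n2o_max > 0")
        return nox_init / (2.0 * min(n2o_max, nox_init / 2.0))
    return 1.0 + (1.0 - ratio)


def apparent_nox(n2o: "float | np.ndarray", nox_init: float,
                 f: float) -> "float | np.ndarray":
    """Apparent NOx remaining in porewater given accumulated N2O.

    NOx_app = NOx_init - 2 * N2O * f, clipped below at zero (clipping is
    logged); 2 accounts for denitrification stoichiometry and f for the
    non-denitrification sink.
    """
    raw = nox_init - 2.0 * np.asarray(n2o, dtype=float) * f
    n_clip = int(np.sum(raw < 0))
    if n_clip:
        logger.info("apparent_nox clipped %d value(s) below 0", n_clip)
    clipped = np.clip(raw, 0.0, None)
    return float(clipped) if np.isscalar(n2o) else clipped


def hill_rate(c: "float | np.ndarray", fit: KineticsFit) -> "float | np.ndarray":
    """Evaluate the fitted rate law at concentration ``c`` (umol L^-1)."""
    return _hill(np.asarray(c, dtype=float), fit.v_max, fit.k_m, fit.hill_n)


def _hill(c: np.ndarray, v_max: float, k_m: float, n: float) -> np.ndarray:
    c = np.clip(c, 0.0, None)
    cn = np.power(c, n)
    return v_max * cn / (np.power(k_m, n) + cn)


def saturating_concentration(fit: KineticsFit, fraction: float) -> float:
    """Concentration at which the rate reaches ``fraction`` of V_max.

    Closed form of the inverted Hill equation:
    C = K_M * (q / (1 - q))**(1/n).

    Raises
    ------
    DomainError  if ``fraction`` is not strictly between 0 and 1.
    """
    if not 0.0 < fraction < 1.0:
        raise DomainError("fraction must be in (0, 1)")
    return float(fit.k_m * (fraction / (1.0 - fraction)) ** (1.0 / fit.hill_n))


def _aic(rss: float, n: int, k: int, scale: float) -> float:
    floor = n * (_AIC_RSS_FLOOR_REL * max(scale, 1.0)) ** 2
    return n * np.log(max(rss, floor) / n) + 2 * k


def fit_kinetics(points: Sequence[InstantRatePoint],
                 model: FitModel = FitModel.HILL) -> KineticsFit:
    """Nonlinear least-squares fit of the rate-versus-substrate cloud.

    Multi-start initialisation (V_max from the observed maximum rate, K_M
    from concentration quantiles, n in {1, 2, 4}); the best residual sum of
    squares wins.  AIC = N ln(RSS/N) + 2k with k = 3 for Hill, 2 for
    Michaelis-Menten.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 points or concentration span below 3-fold.
    FitError
        No start converged.
    """
    pts = list(points)
    if len(pts) < 5:
        raise InsufficientDataError(
            f"kinetics fit needs >= 5 points, got {len(pts)}")
    c = np.array([p.apparent_nox for p in pts])
    r = np.array([p.rate for p in pts])
    c_pos = c[c > 0]
    if c_pos.size == 0 or c_pos.max() / c_pos.min() < 3.0:
        raise InsufficientDataError(
            "kinetics fit needs at least a 3-fold concentration range")

    model = FitModel(model)
    fix_n = model is FitModel.MICHAELIS_MENTEN
    r_max = max(float(r.max()), 1e-6)
    v0s = [r_max, 1.5 * r_max]
    k0s = [float(np.quantile(c_pos, 0.25)), float(np.quantile(c_pos, 0.50))]
    n0s = [1.0] if fix_n else [1.0, 2.0, 4.0]

    def residual(theta: np.ndarray) -> np.ndarray:
        v, k = theta[0], theta[1]
        n = 1.0 if fix_n else theta[2]
        return _hill(c, v, k, n) - r

    tiny = 1e-9
    if fix_n:
        lower, upper = [tiny, tiny], [np.inf, np.inf]
    else:
        lower, upper = [tiny, tiny, tiny], [np.inf, np.inf, np.inf]

    best = None
    for v0 in v0s:
        for k0 in k0s:
            for n0 in n0s:
                theta0 = [v0, k0] if fix_n else [v0, k0, n0]
                try:
                    sol = least_squares(residual, theta0, bounds=(lower, upper),
                                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
                except ValueError:
                    continue
                if not sol.success:
                    continue
                rss = float(np.sum(sol.fun ** 2))
                if best is None or rss < best[0]:
                    best = (rss, sol)
    if best is None:
        raise FitError(f"{model.value} fit did not converge from any start")
    rss, sol = best
    v, k = float(sol.x[0]), float(sol.x[1])
    n_hill = 1.0 if fix_n else float(sol.x[2])
    n_free = 2 if fix_n else 3
    aic = float(_aic(rss, len(pts), n_free, scale=r_max))

    # parameter SEs from the Gauss-Newton covariance (J^T J)^-1 * s^2
    ses = [None] * sol.x.size
    dof = len(pts) - n_free
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * rss / dof
            ses = list(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
        except np.linalg.LinAlgError:
            pass
    return KineticsFit(v_max=v, k_m=k, hill_n=n_hill, model=model, rss=rss,
                       aic=aic, n_points=len(pts),
                       v_max_se=ses[0], k_m_se=ses[1],
                       hill_n_se=None if fix_n else ses[2])


def compare_models(points: Sequence[InstantRatePoint]
                   ) -> dict[FitModel, KineticsFit]:
    """Fit both rate laws on the same cloud.

    The Hill fit is additionally seeded with the Michaelis-Menten optimum
    (n = 1), which guarantees RSS(Hill) <= RSS(MM) up to solver tolerance
    since MM is nested within Hill.
    """
    mm = fit_kinetics(points, FitModel.MICHAELIS_MENTEN)
    hill = fit_kinetics(points, FitModel.HILL)
    # polish the Hill fit from the MM solution to enforce nesting
    c = np.array([p.apparent_nox for p in points])
    r = np.array([p.rate for p in points])

    def residual(theta: np.ndarray) -> np.ndarray:
        return _hill(c, theta[0], theta[1], theta[2]) - r

    sol = least_squares(residual, [mm.v_max, mm.k_m, 1.0],
                        bounds=([1e-9] * 3, [np.inf] * 3),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    rss = float(np.sum(sol.fun ** 2))
    if sol.success and rss < hill.rss:
        r_max = max(float(r.max()), 1e-6)
        hill = KineticsFit(v_max=float(sol.x[0]), k_m=float(sol.x[1]),
                           hill_n=float(sol.x[2]), model=FitModel.HILL,
                           rss=rss, aic=float(_aic(rss, len(c), 3, r_max)),
                           n_points=len(c))
    return {FitModel.HILL: hill, FitModel.MICHAELIS_MENTEN: mm}


def instantaneous_rate_cloud(series: ProfileSeries, core: SedimentCore,
                             depth_range: tuple[float, float],
                             nox_init: float = units.DEFAULT_NOX_INIT,
                             ceiling_exclusion: float | None =
                             DEFAULT_CEILING_EXCLUSION,
                             exact_correction: bool = False
                             ) -> list[InstantRatePoint]:
    """Rate-versus-apparent-NOx samples over a depth window.

    For every grid depth inside ``depth_range`` (m, inclusive) and every
    interior time, the instantaneous N-based rate is

        rate = 2 * (dC/dt_central + (J_out - J_in)/dz)

    and the apparent NOx comes from the accumulated N2O with the per-depth
    correction factor.  Points on the flat tail of the accumulation curve
    (N2O above ``ceiling_exclusion`` of the per-depth maximum) are dropped;
    pass None to keep them.  Negative rates are retained so that noise
    stays symmetric around the fitted curve.
    """
    if series.analyte is not Analyte.N2O:
        raise ValidationError("rate cloud needs N2O profiles")
    if len(series) < 3:
        raise InsufficientDataError("rate cloud needs >= 3 profiles")
    lo, hi = depth_range
    sediment = [p.sediment_only() for p in series.profiles]
    depths = sediment[0].depths
    n_z = depths.size
    # divergence at interior depths, per profile
    divergence = np.vstack([flux_divergence(p, core) for p in sediment])
    conc = np.vstack([p.concentrations for p in sediment])
    times = series.times

    points: list[InstantRatePoint] = []
    for i in range(1, n_z - 1):
        z = depths[i]
        if z < lo - 1e-12 or z > hi + 1e-12:
            continue
        n2o_max = float(conc[:, i].max())
        if n2o_max <= 0:
            f = 2.0  # no accumulation: formula boundary, cloud sits at nox_init
        else:
            f = correction_factor(n2o_max, nox_init, exact=exact_correction)
        for n in range(1, len(times) - 1):
            if (ceiling_exclusion is not None and n2o_max > 0
                    and conc[n, i] > ceiling_exclusion * n2o_max):
                continue
            dcdt = (conc[n + 1, i] - conc[n - 1, i]) / (times[n + 1] - times[n - 1])
            rate = 2.0 * (dcdt + divergence[n, i - 1])
            app = float(apparent_nox(conc[n, i], nox_init, f))
            app = min(app, nox_init)
            points.append(InstantRatePoint(depth_m=float(z),
                                           time_h=float(times[n]),
                                           rate=float(rate),
                                           apparent_nox=app))
    return points
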