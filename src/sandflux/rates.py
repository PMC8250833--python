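"""Volumetric rate estimation from microsensor time series.

Two kinds of rate come out of this module:

* **Stop-flow point rates** -- the sensor sits at one depth, flow is halted,
  and the concentration drift over a short window gives a net volumetric
  consumption (or production) rate by ordinary least squares.

* **Depth-resolved potential denitrification rates** -- repeated N2O
  profiles measured under acetylene block are turned into a rate profile by
  the storage-plus-transport budget ``R = dC/dt + (J_out - J_in)/dz``, where
  ``dC/dt`` is the per-depth regression slope of N2O versus time and the
  ``J`` terms are Fickian fluxes through the layer boundaries
  (J = -phi^(4/3) D_w dC/dz).  Rates are reported per mole of N, i.e.
  2 x the N2O-based rate, in mmol N m^-3 sediment h^-1.

The storage term follows the porewater concentration directly (no porosity
multiplier); set ``porosity_on_storage=True`` for the stricter variant that
scales storage by phi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .profiles import Analyte, DepthProfile, ProfileSeries, SedimentCore
from . import units

logger = logging.getLogger(__name__)

#: QC thresholds for stop-flow regressions: flag fits with r2 at or below
#: 0.95 or slope p-value at or above 0.01.
QC_R2_MIN = 0.95
QC_P_MAX = 0.01

#: Fraction of the per-depth N2O maximum beyond which accumulation is no
#: longer treated as linear when regressing dC/dt (see linear_window_times).
DEFAULT_LINEAR_WINDOW_FRACTION = 0.8


@dataclass
class PointRateEstimate:
    """Net volumetric rate at one depth from a stop-flow regression.

    ``rate`` is positive for consumption (rate = -slope); ``qc_pass`` is
    False when r^2 <= 0.95 or p >= 0.01.
    """

    depth_m: float
    slope: float                # umol L^-1 h^-1
    rate: float                 # consumption-positive, umol L^-1 h^-1
    r_squared: float
    p_value: float
    n_points: int
    qc_pass: bool


@dataclass
class RateProfile:
    """Depth-resolved volumetric denitrification rates (per mole N)."""

    depths: np.ndarray          # m, interior depths only
    rates: np.ndarray           # mmol N m^-3 sediment h^-1
    rate_se: np.ndarray         # standard error, same units
    n_profiles_used: int


def stopflow_rate(times: np.ndarray, concentrations: np.ndarray,
                  window_h: float | None = None,
                  depth_m: float = float("nan")) -> PointRateEstimate:
    """OLS rate from a stop-flow concentration time series.

    Parameters
    ----------
    times, concentrations
        Elapsed time (h) and concentration (umol L^-1) at a fixed depth.
    window_h
        If given, only points with ``t <= times[0] + window_h`` enter the
        regression (e.g. ``10/60`` for a 10-min window).

    Returns
    -------
    PointRateEstimate
        With consumption reported as a positive rate (rate = -slope) and a
        QC flag requiring r^2 > 0.95 and p < 0.01.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size:
        raise ValidationError("times and concentrations differ in length")
    if window_h is not None:
        keep = t <= t[0] + window_h
        t, c = t[keep], c[keep]
    if t.size < 3:
        raise InsufficientDataError(
            f"stop-flow regression needs >= 3 points, got {t.size}")
    if np.allclose(c, c[0]):
        # degenerate: flat series, slope exactly 0 and no evidence against it
        return PointRateEstimate(depth_m=depth_m, slope=0.0, rate=0.0,
                                 r_squared=0.0, p_value=1.0,
                                 n_points=int(t.size), qc_pass=False)
    res = stats.linregress(t, c)
    r2 = float(res.rvalue ** 2)
    p = float(res.pvalue)
    return PointRateEstimate(
        depth_m=depth_m, slope=float(res.slope), rate=float(-res.slope),
        r_squared=r2, p_value=p, n_points=int(t.size),
        qc_pass=(r2 > QC_R2_MIN) and (p < QC_P_MAX))


def _check_regular_grid(depths: np.ndarray) -> float:
    spacing = np.diff(depths)
    if spacing.size == 0:
        raise ValidationError("profile needs >= 2 depths")
    dz = float(spacing[0])
    if not np.allclose(spacing, dz, rtol=0, atol=1e-9):
        raise ValidationError("depth grid is irregular")
    return dz


def diffusive_flux(profile: DepthProfile, core: SedimentCore,
                   tortuosity_exponent: float = units.TORTUOSITY_EXPONENT
                   ) -> np.ndarray:
    """Fickian flux through each boundary between adjacent samples.

    Returns an array of length ``len(depths) - 1``;  element ``i`` is the
    flux through the boundary between samples ``i`` and ``i+1`` in
    umol m^-2 h^-1, positive downward:

        J = -phi**e * D_w * dC/dz

    with the gradient taken as the finite difference over the grid spacing.

    Raises
    ------
    ValidationError
        If the depth grid spacing is not uniform.
    """
    _check_regular_grid(profile.depths)
    dz = float(profile.depths[1] - profile.depths[0])
    d_eff = core.effective_diffusivity(tortuosity_exponent)
    grad = np.diff(profile.concentrations) / dz   # mmol m^-3 per m
    return -d_eff * grad * units.UMOL_PER_MMOL


def flux_divergence(profile: DepthProfile, core: SedimentCore,
                    tortuosity_exponent: float = units.TORTUOSITY_EXPONENT
                    ) -> np.ndarray:
    """Net diffusive export (J_out - J_in) per volume at interior depths.

    For the layer centred on sample ``i``, the net flux out is the boundary
    flux below minus the boundary flux above; dividing by the layer
    thickness converts to a volumetric sink, mmol m^-3 h^-1.  The sum of
    (J_out - J_in) over interior layers telescopes to the difference
    between the bottom and top boundary fluxes.
    """
    j = diffusive_flux(profile, core, tortuosity_exponent)  # umol m^-2 h^-1
    dz = float(profile.depths[1] - profile.depths[0])
    net_out = j[1:] - j[:-1]                                # per interior sample
    return net_out / dz / units.UMOL_PER_MMOL


def linear_window_times(times: np.ndarray, conc: np.ndarray,
                        fraction: float = DEFAULT_LINEAR_WINDOW_FRACTION
                        ) -> np.ndarray:
    """Indices of the profiles used for the per-depth dC/dt regression.

    Accumulation curves flatten as the substrate pool is exhausted, so the
    regression uses profiles up to (and including) the first one whose
    concentration reaches ``fraction`` of the per-depth maximum.  At least
    three profiles are always retained.
    """
    conc = np.asarray(conc, dtype=float)
    n = conc.size
    ceiling = conc.max()
    if ceiling <= 0:
        return np.arange(n)
    crossing = np.nonzero(conc >= fraction * ceiling)[0]
    last = int(crossing[0]) if crossing.size else n - 1
    last = max(last, 2)          # keep at least 3 points
    return np.arange(last + 1)


def denit_rate_profile(series: ProfileSeries, core: SedimentCore,
                       linear_window_fraction: float | None =
                       DEFAULT_LINEAR_WINDOW_FRACTION,
                       tortuosity_exponent: float = units.TORTUOSITY_EXPONENT,
                       porosity_on_storage: bool = False) -> RateProfile:
    """Depth profile of potential denitrification rate from N2O series.

    Per interior sediment depth, the N2O-based rate is the regression slope
    of concentration versus time plus the mean (over the same profiles) of
    the net diffusive export divided by the layer thickness.  The returned
    rates are 2x the N2O rate, i.e. per mole of N, with standard errors
    propagated from the dC/dt regression.

    Parameters
    ----------
    linear_window_fraction
        Per-depth cutoff for the linear-accumulation window (None uses all
        profiles); see :func:`linear_window_times`.
    porosity_on_storage
        Multiply the storage term dC/dt by porosity.  Off by default: the
        budget then matches the conventional bookkeeping in which porewater
        concentration change is equated directly with the volumetric rate.

    Raises
    ------
    ValidationError  if the series is not N2O.
    InsufficientDataError  if fewer than 3 profiles.
    """
    if series.analyte is not Analyte.N2O:
        raise ValidationError(
            f"denitrification rates need N2O profiles, got {series.analyte}")
    if len(series) < 3:
        raise InsufficientDataError(
            f"need >= 3 profiles, got {len(series)}")

    sediment = [p.sediment_only() for p in series.profiles]
    depths = sediment[0].depths
    _check_regular_grid(depths)
    dz = float(depths[1] - depths[0])
    times = series.times
    conc = np.vstack([p.concentrations for p in sediment])
    n_t, n_z = conc.shape

    # (J_out - J_in)/dz at interior depths for every profile, mmol m^-3 h^-1
    divergence = np.vstack([flux_divergence(p, core, tortuosity_exponent)
                            for p in sediment])

    interior = np.arange(1, n_z - 1)
    rates = np.full(interior.size, np.nan)
    ses = np.full(interior.size, np.nan)
    phi = core.porosity if porosity_on_storage else 1.0
    n_used_max = 0
    for k, i in enumerate(interior):
        if linear_window_fraction is None:
            sel = np.arange(n_t)
        else:
            sel = linear_window_times(times, conc[:, i],
                                      linear_window_fraction)
        n_used_max = max(n_used_max, sel.size)
        res = stats.linregress(times[sel], conc[sel, i])
        dcdt = phi * res.slope                      # mmol m^-3 h^-1
        mean_div = divergence[sel, i - 1].mean()
        rates[k] = 2.0 * (dcdt + mean_div)
        se = res.stderr if np.isfinite(res.stderr) else 0.0
        ses[k] = 2.0 * phi * se
    return RateProfile(depths=depths[interior], rates=rates, rate_se=ses,
                       n_profiles_used=n_used_max)
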