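"""Penetration/saturation depths and the asymptotic deepening curve.

During downward percolation, oxygen and NOx fronts move deeper with time but
approach a maximum depth where consumption balances supply.  The penetration
depth of a single profile is the shallowest depth at which the concentration
drops to (effectively) zero; the saturation depth uses the substrate
concentration that sustains a specified fraction of the maximum
denitrification rate as its threshold.  A penetration-versus-time series is
summarised by the asymptotic curve

    d(t) = a - b * c**t        (0 < c < 1)

whose parameter ``a`` estimates the maximum penetration depth.

Depths are reported in cm (the conventional unit for these plots); profile
internals stay in m.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import lmfit
import numpy as np

from .errors import DomainError, FitError, InsufficientDataError, ValidationError
from .profiles import DepthProfile, KineticsFit, PenetrationFit, ProfileSeries
from .kinetics import saturating_concentration
from . import units

#: Sentinel returned when a profile never crosses the threshold.
BEYOND_GRID = float("inf")

#: Default "effectively zero" concentration, umol L^-1.  Sensor baseline
#: noise makes a literal zero ill-defined.
DEFAULT_THRESHOLD = 1.0

#: Default fraction of V_max defining the saturation depth.
DEFAULT_SATURATION_FRACTION = 0.9


class PenetrationKind(str, Enum):
    PENETRATION = "penetration"
    SATURATION = "saturation"


@dataclass
class PenetrationSeries:
    """Penetration (or saturation) depth versus elapsed time."""

    times_h: np.ndarray
    depths_cm: np.ndarray
    kind: PenetrationKind = PenetrationKind.PENETRATION
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.depths_cm = np.asarray(self.depths_cm, dtype=float)
        self.kind = PenetrationKind(self.kind)
        if self.times_h.size != self.depths_cm.size:
            raise ValidationError("times and depths differ in length")
        if self.threshold < 0:
            raise ValidationError("threshold must be >= 0")
        if self.kind is PenetrationKind.SATURATION and self.threshold <= 0:
            raise ValidationError("saturation series needs threshold > 0")


def penetration_depth(profile: DepthProfile,
                      threshold: float = DEFAULT_THRESHOLD,
                      interpolate: bool = False) -> float:
    """Shallowest sediment depth (cm) where concentration <= threshold.

    With ``interpolate`` the crossing is linearly interpolated between the
    bracketing samples; otherwise the first sample at or below the
    threshold is returned, matching the "first depth at which" reading
    convention.  Returns :data:`BEYOND_GRID` (inf) when the profile never
    crosses the threshold.
    """
    p = profile.sediment_only()
    if p.depths.size < 2:
        raise ValidationError("need >= 2 sediment depths")
    below = np.nonzero(p.concentrations <= threshold)[0]
    if below.size == 0:
        return BEYOND_GRID
    k = int(below[0])
    z = p.depths[k]
    if interpolate and k > 0:
        c0, c1 = p.concentrations[k - 1], p.concentrations[k]
        z0, z1 = p.depths[k - 1], p.depths[k]
        if c0 > c1:
            z = z0 + (c0 - threshold) / (c0 - c1) * (z1 - z0)
    return float(z * units.CM_PER_M)


def saturation_depth(profile: DepthProfile,
                     c_sat: float | None = None,
                     fit: KineticsFit | None = None,
                     fraction: float = DEFAULT_SATURATION_FRACTION,
                     interpolate: bool = False) -> float:
    """Depth (cm) where NOx falls below the rate-saturating concentration.

    ``c_sat`` may be given directly, or derived from a :class:`KineticsFit`
    as the concentration sustaining ``fraction`` of V_max.
    """
    if c_sat is None:
        if fit is None:
            raise DomainError("supply either c_sat or a KineticsFit")
        c_sat = saturating_concentration(fit, fraction)
    if c_sat <= 0:
        raise DomainError("c_sat must be > 0")
    return penetration_depth(profile, threshold=c_sat, interpolate=interpolate)


def penetration_series(series: ProfileSeries,
                       threshold: float = DEFAULT_THRESHOLD,
                       kind: PenetrationKind = PenetrationKind.PENETRATION,
                       interpolate: bool = False,
                       drop_beyond_grid: bool = True) -> PenetrationSeries:
    """Penetration depth of every profile in a time series."""
    times, depths = [], []
    for p in series.profiles:
        d = penetration_depth(p, threshold=threshold, interpolate=interpolate)
        if drop_beyond_grid and not np.isfinite(d):
            continue
        times.append(p.time_h)
        depths.append(d)
    return PenetrationSeries(times_h=np.array(times),
                             depths_cm=np.array(depths),
                             kind=kind, threshold=threshold)


def fit_asymptote(series: PenetrationSeries) -> PenetrationFit:
    """Least-squares fit of d(t) = a - b*c**t to a penetration series.

    Initialisation: a0 = max depth, b0 = a0 - d(first), c0 = 0.5; c is
    constrained to (0, 1) so the curve approaches its asymptote
    monotonically.  Returns the asymptote ``a`` with its standard error.

    Raises
    ------
    InsufficientDataError  if fewer than 4 points.
    FitError  on non-convergence.
    """
    t = series.times_h
    d = series.depths_cm
    finite = np.isfinite(d)
    t, d = t[finite], d[finite]
    if t.size < 4:
        raise InsufficientDataError(
            f"asymptote fit needs >= 4 points, got {t.size}")

    a0 = float(d.max())
    b0 = max(a0 - float(d[0]), 1e-6)

    model = lmfit.Model(lambda t, a, b, c: a - b * c ** t,
                        independent_vars=["t"])
    params = model.make_params(a=max(a0, 1e-6), b=b0, c=0.5)
    params["c"].set(min=1e-9, max=1.0 - 1e-9)
    params["b"].set(min=0.0)
    try:
        out = model.fit(d, params, t=t)
    except Exception as exc:  # lmfit wraps solver failures variously
        raise FitError(f"asymptote fit failed: {exc}") from exc
    if not out.success:
        raise FitError(f"asymptote fit did not converge: {out.message}")
    a_se = out.params["a"].stderr
    return PenetrationFit(a=float(out.params["a"].value),
                          b=float(out.params["b"].value),
                          c=float(out.params["c"].value),
                          a_se=float(a_se) if a_se is not None else float("nan"),
                          rss=float(np.sum(out.residual ** 2)))
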