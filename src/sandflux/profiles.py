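"""Domain types and delimited-text I/O for microsensor depth profiles.

A :class:`DepthProfile` is one analyte's concentration-versus-depth curve at a
single elapsed time; a :class:`ProfileSeries` is a stack of such profiles on a
shared depth grid, measured repeatedly during an incubation or percolation
experiment.  :class:`SedimentCore` carries the physical constants of the core
the profiles were measured in.

Profile tables are long-format delimited text with the header
``time_h,depth_m,conc_umol_L[,analyte,core_id]``, comma or tab separated,
UTF-8, ``.`` decimal.  Depths above the sediment-water interface (depth < 0,
overlying water) may be present; sediment computations ignore them.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from . import units

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("time_h", "depth_m", "conc_umol_L")


class Analyte(str, Enum):
    """Solute measured by the microsensor."""

    O2 = "o2"
    NOX = "nox"
    N2O = "n2o"

    @classmethod
    def parse(cls, value: "str | Analyte") -> "Analyte":
        if isinstance(value, Analyte):
            return value
        key = str(value).strip().lower()
        try:
            return cls(key)
        except ValueError as exc:
            raise ValidationError(f"unknown analyte {value!r}") from exc


class FitModel(str, Enum):
    """Saturating rate law used for kinetics fitting."""

    HILL = "hill"
    MICHAELIS_MENTEN = "michaelis_menten"


@dataclass
class DepthProfile:
    """One analyte's concentrations along a vertical depth grid at one time.

    Parameters
    ----------
    analyte
        Which solute the concentrations refer to.
    depths
        Depth below the sediment surface, m, strictly increasing.  Negative
        depths denote overlying water and are ignored by sediment
        computations.
    concentrations
        umol L^-1, same length as ``depths``.  Values may be negative
        (sensor baseline noise); use :func:`clip_negative` to zero them.
    time_h
        Elapsed time since the start of the experiment, h.
    """

    analyte: Analyte
    depths: np.ndarray
    concentrations: np.ndarray
    time_h: float

    def __post_init__(self) -> None:
        self.analyte = Analyte.parse(self.analyte)
        self.depths = np.asarray(self.depths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.depths.ndim != 1 or self.concentrations.ndim != 1:
            raise ValidationError("depths and concentrations must be 1-D")
        if self.depths.size != self.concentrations.size:
            raise ValidationError(
                f"length mismatch: {self.depths.size} depths vs "
                f"{self.concentrations.size} concentrations")
        if self.depths.size and np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing")
        if not np.all(np.isfinite(self.depths)):
            raise ValidationError("depths must be finite")
        if self.time_h < 0:
            raise ValidationError("time_h must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthProfile):
            return NotImplemented
        return (self.analyte is other.analyte
                and self.time_h == other.time_h
                and np.array_equal(self.depths, other.depths)
                and np.array_equal(self.concentrations, other.concentrations))

    @property
    def sediment_mask(self) -> np.ndarray:
        """Boolean mask of samples at or below the sediment-water interface."""
        return self.depths >= 0.0

    def sediment_only(self) -> "DepthProfile":
        """Profile restricted to sediment depths (depth >= 0)."""
        m = self.sediment_mask
        return replace(self, depths=self.depths[m],
                       concentrations=self.concentrations[m])


def clip_negative(profile: DepthProfile) -> DepthProfile:
    """Replace negative concentrations by zero.

    Negative readings are microbiosensor baseline noise; the number of
    clipped points is logged at INFO level.
    """
    negative = profile.concentrations < 0
    n = int(negative.sum())
    if n:
        logger.info("clipped %d negative concentration(s) at t=%.3g h",
                    n, profile.time_h)
    clipped = np.where(negative, 0.0, profile.concentrations)
    return replace(profile, concentrations=clipped)


@dataclass
class ProfileSeries:
    """Repeated :class:`DepthProfile` measurements of one analyte.

    All profiles must share one depth grid; times must be strictly
    increasing.  Rate estimation additionally requires at least three
    profiles, which is enforced by the consuming operations rather than
    here so that short series can still be read and inspected.
    """

    profiles: list[DepthProfile]
    core_id: str = "core"

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("ProfileSeries requires at least one profile")
        first = self.profiles[0]
        for p in self.profiles[1:]:
            if p.analyte is not first.analyte:
                raise ValidationError("all profiles must share one analyte")
            if p.depths.size != first.depths.size or not np.array_equal(
                    p.depths, first.depths):
                raise ValidationError("all profiles must share one depth grid")
        times = np.array([p.time_h for p in self.profiles])
        if np.any(np.diff(times) <= 0):
            raise ValidationError("profile times must be strictly increasing")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileSeries):
            return NotImplemented
        return (self.core_id == other.core_id
                and len(self.profiles) == len(other.profiles)
                and all(a == b for a, b in zip(self.profiles, other.profiles)))

    @property
    def analyte(self) -> Analyte:
        return self.profiles[0].analyte

    @property
    def depths(self) -> np.ndarray:
        return self.profiles[0].depths

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_h for p in self.profiles])

    @property
    def concentration_matrix(self) -> np.ndarray:
        """Concentrations as an (n_times, n_depths) array."""
        return np.vstack([p.concentrations for p in self.profiles])

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class SedimentCore:
    """Physical constants of a sediment core.

    porosity : dimensionless phi in (0, 1)
    diameter_m : inner core-tube diameter, m
    d_w : free-solution diffusion coefficient of the analyte, m^2 h^-1
    layer_thickness_m : vertical measurement resolution Delta z, m
    temperature_c : water temperature, degC (metadata only)
    """

    porosity: float = units.DEFAULT_POROSITY
    diameter_m: float = units.DEFAULT_CORE_DIAMETER
    d_w: float = units.DEFAULT_D_W
    layer_thickness_m: float = units.DEFAULT_DZ
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValidationError("porosity must be in (0, 1)")
        if self.diameter_m <= 0:
            raise ValidationError("diameter_m must be > 0")
        if self.d_w <= 0:
            raise ValidationError("d_w must be > 0")
        if self.layer_thickness_m <= 0:
            raise ValidationError("layer_thickness_m must be > 0")

    @property
    def cross_section_m2(self) -> float:
        """Core cross-sectional area, m^2."""
        return float(np.pi * (self.diameter_m / 2.0) ** 2)

    def effective_diffusivity(
            self, exponent: float = units.TORTUOSITY_EXPONENT) -> float:
        """phi**exponent * D_w, m^2 h^-1."""
        return units.effective_diffusivity(self.porosity, self.d_w, exponent)


@dataclass
class KineticsFit:
    """Fitted saturating rate law R(C) = V_max C^n / (K_M^n + C^n).

    Units: ``v_max`` mmol N m^-3 sediment h^-1, ``k_m`` umol L^-1,
    ``hill_n`` dimensionless (1 for Michaelis-Menten).
    """

    v_max: float
    k_m: float
    hill_n: float
    model: FitModel = FitModel.HILL
    rss: float = float("nan")
    aic: float = float("nan")
    n_points: int = 0
    v_max_se: float | None = None
    k_m_se: float | None = None
    hill_n_se: float | None = None

    def __post_init__(self) -> None:
        self.model = FitModel(self.model)
        if self.v_max <= 0:
            raise ValidationError("v_max must be > 0")
        if self.k_m <= 0:
            raise ValidationError("k_m must be > 0")
        if self.hill_n <= 0:
            raise ValidationError("hill_n must be > 0")
        if self.model is FitModel.MICHAELIS_MENTEN and self.hill_n != 1.0:
            raise ValidationError("Michaelis-Menten fixes hill_n = 1")


@dataclass
class PenetrationFit:
    """Asymptotic deepening curve d(t) = a - b * c**t.

    ``a`` is the asymptotic (maximum) penetration depth in cm with standard
    error ``a_se``; ``b`` (cm) and ``c`` (dimensionless, 0 < c < 1) shape the
    approach to the asymptote.
    """

    a: float
    b: float
    c: float
    a_se: float = float("nan")
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("asymptote a must be > 0")
        if not 0.0 < self.c < 1.0:
            raise ValidationError("coefficient c must be in (0, 1)")

    def depth_at(self, t_h: "float | np.ndarray") -> "float | np.ndarray":
        """Fitted penetration depth (cm) at elapsed time ``t_h`` (h)."""
        return self.a - self.b * self.c ** np.asarray(t_h, dtype=float)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_profile_table(path: "str | Path", analyte: "str | Analyte | None" = None,
                       clip_negatives: bool = True,
                       core_id: str | None = None) -> ProfileSeries:
    """Read a long-format profile table into a :class:`ProfileSeries`.

    Parameters
    ----------
    path
        Delimited text file (comma or tab, autodetected) with columns
        ``time_h, depth_m, conc_umol_L`` and optional ``analyte``/``core_id``.
    analyte
        Analyte of the series.  May be omitted when the file carries an
        ``analyte`` column with a single value.
    clip_negatives
        Zero out negative concentrations on read (sensor noise); disable to
        keep raw values.

    Raises
    ------
    FormatError
        Missing required columns or undecodable table.
    ValidationError
        Ragged depth grids, duplicate or non-monotonic depths, or an
        analyte mismatch.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path} is missing required column(s) {missing}")

    if analyte is None:
        if "analyte" not in table.columns:
            raise FormatError(
                f"{path} has no analyte column; pass analyte= explicitly")
        values = table["analyte"].unique()
        if len(values) != 1:
            raise ValidationError(
                f"{path} mixes analytes {sorted(values)}; read them separately")
        analyte = values[0]
    analyte = Analyte.parse(analyte)
    if "analyte" in table.columns:
        file_analytes = {Analyte.parse(v) for v in table["analyte"].unique()}
        if file_analytes != {analyte}:
            raise ValidationError(
                f"{path} holds {file_analytes}, not {analyte}")

    if core_id is None:
        if "core_id" in table.columns and table["core_id"].nunique() == 1:
            core_id = str(table["core_id"].iloc[0])
        else:
            core_id = path.stem

    profiles: list[DepthProfile] = []
    grid: np.ndarray | None = None
    for time_h, group in table.groupby("time_h", sort=True):
        group = group.sort_values("depth_m")
        depths = group["depth_m"].to_numpy(dtype=float)
        if np.any(np.diff(depths) == 0):
            raise ValidationError(
                f"duplicate depth at time {time_h} h in {path}")
        if grid is None:
            grid = depths
        elif depths.size != grid.size or not np.allclose(depths, grid,
                                                         rtol=0, atol=1e-12):
            raise ValidationError(
                f"ragged depth grid at time {time_h} h in {path}")
        profile = DepthProfile(
            analyte=analyte, depths=depths,
            concentrations=group["conc_umol_L"].to_numpy(dtype=float),
            time_h=float(time_h))
        if clip_negatives:
            profile = clip_negative(profile)
        profiles.append(profile)
    return ProfileSeries(profiles=profiles, core_id=core_id)


def write_profile_table(series: ProfileSeries, path: "str | Path") -> None:
    """Write the canonical long-format CSV for a :class:`ProfileSeries`.

    Floats are written with ``repr`` so that
    ``read_profile_table(write_profile_table(s)) == s`` to full float
    precision, and two writes of the same series are byte-identical.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("time_h,depth_m,conc_umol_L,analyte,core_id\n")
    for p in series.profiles:
        t = repr(float(p.time_h))
        for z, c in zip(p.depths, p.concentrations):
            buf.write(f"{t},{float(z)!r},{float(c)!r},{series.analyte.value},"
                      f"{series.core_id}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def series_from_arrays(analyte: "str | Analyte", depths: Sequence[float],
                       times: Sequence[float], conc: np.ndarray,
                       core_id: str = "core") -> ProfileSeries:
    """Build a :class:`ProfileSeries` from a (n_times, n_depths) array."""
    conc = np.asarray(conc, dtype=float)
    profiles = [DepthProfile(analyte=analyte, depths=np.asarray(depths, float),
                             concentrations=conc[i], time_h=float(t))
                for i, t in enumerate(times)]
    return ProfileSeries(profiles=profiles, core_id=core_id)
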