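"""End-to-end orchestration: rates -> kinetics -> penetration -> budget.

A :class:`RunConfig` (loadable from a YAML key-value file) names the input
profile tables and the thresholds in effect; :func:`run_all` executes the
selected stages in order, writes one machine-readable table per stage plus
a human-readable summary, and logs every default that was applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SandfluxError
from .profiles import Analyte, SedimentCore, read_profile_table
from .rates import denit_rate_profile
from .kinetics import compare_models, instantaneous_rate_cloud
from .penetration import (PenetrationKind, fit_asymptote, penetration_series,
                          saturating_concentration,
                          DEFAULT_SATURATION_FRACTION, DEFAULT_THRESHOLD)
from .budget import (FlowSpec, areal_uptake, fraction_of_supply,
                     imposed_flux, infiltration_rate, stoichiometric_n2o_ceiling,
                     theoretical_penetration)
from .profiles import FitModel
from . import units

logger = logging.getLogger(__name__)

ALL_STAGES = ("rates", "kinetics", "penetration", "budget")


@dataclass
class RunConfig:
    """Inputs, physical constants and thresholds for one pipeline run."""

    out_dir: Path
    core: SedimentCore = field(default_factory=SedimentCore)
    n2o_profiles: Path | None = None       # acetylene-block N2O series
    nox_profiles: Path | None = None       # percolation NOx series
    stages: tuple[str, ...] = ALL_STAGES
    nox_init: float = units.DEFAULT_NOX_INIT
    kinetics_depth_range_m: tuple[float, float] = (0.014, 0.020)
    penetration_threshold: float = DEFAULT_THRESHOLD
    saturation_fraction: float = DEFAULT_SATURATION_FRACTION
    flow_ml_min: float = 0.11
    duration_h: float = 8.0
    solute_conc: float = 15.0
    zone_thickness_m: float = 0.008
    supply_flux: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s) {sorted(unknown)}")
        if self.penetration_threshold <= 0:
            raise ConfigError("penetration_threshold must be > 0")
        if not 0 < self.saturation_fraction < 1:
            raise ConfigError("saturation_fraction must be in (0, 1)")
        for path in (self.n2o_profiles, self.nox_profiles):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"profile table not found: {path}")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        core = SedimentCore(**raw.pop("core", {}))
        for key in ("n2o_profiles", "nox_profiles"):
            if raw.get(key) is not None:
                raw[key] = (path.parent / raw[key]).resolve() \
                    if not Path(raw[key]).is_absolute() else Path(raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "kinetics_depth_range_m" in raw:
            raw["kinetics_depth_range_m"] = tuple(raw["kinetics_depth_range_m"])
        if "out_dir" not in raw:
            raw["out_dir"] = path.parent / "sandflux_out"
        return cls(core=core, **raw)


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and write their outputs.

    Returns a dict of the headline results (also written to
    ``summary.txt``).  A failing stage aborts the run with a
    :class:`SandfluxError` naming the stage.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    c_sat: float | None = None

    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "rates":
                if config.n2o_profiles is None:
                    raise ConfigError("rates stage needs n2o_profiles")
                series = read_profile_table(config.n2o_profiles, Analyte.N2O)
                rp = denit_rate_profile(series, config.core)
                pd.DataFrame({"depth_m": rp.depths,
                              "rate_mmolN_m3_h": rp.rates,
                              "se": rp.rate_se}).to_csv(
                    out / "rate_profile.csv", index=False)
                lo, hi = config.kinetics_depth_range_m
                plateau = rp.rates[(rp.depths >= lo)]
                summary["rate_plateau_mean"] = float(np.mean(plateau)) \
                    if plateau.size else float("nan")
            elif stage == "kinetics":
                if config.n2o_profiles is None:
                    raise ConfigError("kinetics stage needs n2o_profiles")
                series = read_profile_table(config.n2o_profiles, Analyte.N2O)
                cloud = instantaneous_rate_cloud(
                    series, config.core, config.kinetics_depth_range_m,
                    nox_init=config.nox_init)
                pd.DataFrame([{"depth_m": p.depth_m, "time_h": p.time_h,
                               "rate_mmolN_m3_h": p.rate,
                               "apparent_nox_umol_L": p.apparent_nox}
                              for p in cloud]).to_csv(
                    out / "kinetics_cloud.csv", index=False)
                fits = compare_models(cloud)
                hill = fits[FitModel.HILL]
                c_sat = saturating_concentration(hill,
                                                 config.saturation_fraction)
                report = {
                    model.value: {"v_max": f.v_max, "k_m": f.k_m,
                                  "hill_n": f.hill_n, "rss": f.rss,
                                  "aic": f.aic, "n_points": f.n_points}
                    for model, f in fits.items()}
                report["saturating_concentration_umol_L"] = float(c_sat)
                with open(out / "kinetics_fit.yaml", "w") as fh:
                    yaml.safe_dump(report, fh, sort_keys=True)
                summary["v_max"] = hill.v_max
                summary["k_m"] = hill.k_m
                summary["hill_n"] = hill.hill_n
                summary["c_sat"] = float(c_sat)
            elif stage == "penetration":
                if config.nox_profiles is None:
                    raise ConfigError("penetration stage needs nox_profiles")
                series = read_profile_table(config.nox_profiles, Analyte.NOX)
                pen = penetration_series(series, config.penetration_threshold)
                frames = [pd.DataFrame({"time_h": pen.times_h,
                                        "depth_cm": pen.depths_cm,
                                        "kind": pen.kind.value})]
                fit = fit_asymptote(pen)
                summary["penetration_asymptote_cm"] = fit.a
                result = {"penetration": {"a_cm": fit.a, "b": fit.b,
                                          "c": fit.c, "a_se": fit.a_se}}
                if c_sat is not None:
                    sat = penetration_series(series, c_sat,
                                             kind=PenetrationKind.SATURATION)
                    frames.append(pd.DataFrame({"time_h": sat.times_h,
                                                "depth_cm": sat.depths_cm,
                                                "kind": sat.kind.value}))
                    if sat.times_h.size >= 4:
                        sfit = fit_asymptote(sat)
                        result["saturation"] = {"a_cm": sfit.a, "b": sfit.b,
                                                "c": sfit.c, "a_se": sfit.a_se}
                        summary["saturation_asymptote_cm"] = sfit.a
                pd.concat(frames).to_csv(out / "penetration.csv", index=False)
                with open(out / "penetration_fit.yaml", "w") as fh:
                    yaml.safe_dump(result, fh, sort_keys=True)
            elif stage == "budget":
                flow = FlowSpec(flow_ml_min=config.flow_ml_min,
                                core=config.core,
                                duration_h=config.duration_h,
                                solute_conc=config.solute_conc)
                uptake = areal_uptake(summary.get("rate_plateau_mean", 0.0)
                                      or 0.0, config.zone_thickness_m)
                rows = {
                    "infiltration_L_m2_h": infiltration_rate(flow),
                    "imposed_flux_umol_m2_h": imposed_flux(flow),
                    "theoretical_penetration_cm": theoretical_penetration(flow),
                    "n2o_ceiling_umol_L":
                        stoichiometric_n2o_ceiling(config.nox_init),
                    "areal_uptake_umol_m2_h": uptake.areal_rate,
                    "uptake_percent_of_supply": fraction_of_supply(
                        uptake.areal_rate, config.supply_flux)
                        if uptake.areal_rate else 0.0,
                }
                pd.Series(rows).to_csv(out / "budget.csv", header=False)
                summary.update(rows)
        except SandfluxError as exc:
            raise SandfluxError(f"stage '{stage}' failed: {exc}") from exc

    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("sandflux pipeline summary\n")
        for key in sorted(summary):
            fh.write(f"{key}: {summary[key]:.6g}\n")
    return summary
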