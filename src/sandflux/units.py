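"""Unit conventions and physical defaults.

Conventions used throughout the package:

* depth          -- m, positive downward, 0 at the sediment-water interface
* concentration  -- umol L^-1 (numerically identical to mmol m^-3 of porewater)
* time           -- h
* volumetric rate-- mmol m^-3 sediment h^-1
* areal flux     -- umol m^-2 h^-1

All unit conversions live here so that the science modules never carry
magic factors.
"""

#: umol per mmol; converts mmol-based fluxes to the umol-based reporting unit.
UMOL_PER_MMOL = 1000.0

#: cm per m; outputs report penetration depths in cm, internals use m.
CM_PER_M = 100.0

#: minutes per hour.
MIN_PER_H = 60.0

#: L per m^3.
L_PER_M3 = 1000.0

#: mL per L.
ML_PER_L = 1000.0

#: Exponent of the porosity-power tortuosity correction, D_eff = phi**e * D_w.
TORTUOSITY_EXPONENT = 4.0 / 3.0

# --- Defaults typical of fine intertidal quartz sand ---

#: Sediment porosity (dimensionless).
DEFAULT_POROSITY = 0.38

#: Free-solution diffusion coefficient of N2O at 20 degC, m^2 h^-1.
DEFAULT_D_W = 6.58e-6

#: Vertical measurement resolution, m.
DEFAULT_DZ = 0.001

#: Core tube inner diameter, m.
DEFAULT_CORE_DIAMETER = 0.083

#: NOx concentration added at the start of acetylene-block incubations, umol L^-1.
DEFAULT_NOX_INIT = 20.0


def effective_diffusivity(porosity: float, d_w: float,
                          exponent: float = TORTUOSITY_EXPONENT) -> float:
    """Tortuosity-corrected sediment diffusivity, m^2 h^-1."""
    return porosity ** exponent * d_w
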