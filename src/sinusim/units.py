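"""Unit conversions used throughout the model.

All intracellular and plasma metabolite concentrations are carried in uM
(umol/L), hormones in nM and oxygen as a partial pressure in mmHg.  The
only non-trivial conversion is hepatic triglyceride, which is reported as
a percentage of total cell mass so that simulated steatosis can be read
against the clinical 5% (50 mg TG per g wet weight) diagnostic threshold.
"""

from __future__ import annotations

#: Molar masses (g/mol).  Dietary carbohydrate is counted as glucose and
#: dietary lipid as palmitate-equivalent free fatty acid; hepatic
#: triglyceride is counted as triolein.
GLUCOSE_MOLAR_MASS = 180.16
FFA_MOLAR_MASS = 256.4
TG_MOLAR_MASS = 885.4

#: Liver wet-tissue density (g/mL); 1.0 by default so that mg/g wet weight
#: and mg/mL are interchangeable.
TISSUE_DENSITY_G_PER_ML = 1.0

#: Diagnostic anchor: 5% of cell mass corresponds to 50 mg TG / g wet weight.
_PERCENT_PER_MG_PER_G = 5.0 / 50.0


def tg_um_per_percent(tg_molar_mass: float = TG_MOLAR_MASS,
                      density: float = TISSUE_DENSITY_G_PER_ML) -> float:
    """uM of cellular triglyceride corresponding to 1% of total cell mass."""
    # 1% <-> 10 mg/g <-> 10*density g/L  -> mol/L -> uM
    grams_per_l = 10.0 * density
    return grams_per_l / tg_molar_mass * 1e6


def tg_percent(tg_c_um: float, tg_molar_mass: float = TG_MOLAR_MASS,
               density: float = TISSUE_DENSITY_G_PER_ML) -> float:
    """Convert a cellular triglyceride concentration (uM) to % of cell mass.

    The conversion is linear and anchored so that the concentration
    equivalent to 50 mg TG per g wet weight maps to exactly 5.0%.

    Raises
    ------
    ValueError
        If ``tg_c_um`` is negative.
    """
    if tg_c_um < 0:
        raise ValueError(f"triglyceride concentration must be >= 0, got {tg_c_um}")
    return tg_c_um / tg_um_per_percent(tg_molar_mass, density)


def tg_um_from_percent(percent: float, tg_molar_mass: float = TG_MOLAR_MASS,
                       density: float = TISSUE_DENSITY_G_PER_ML) -> float:
    """Inverse of :func:`tg_percent`."""
    if percent < 0:
        raise ValueError(f"percentage must be >= 0, got {percent}")
    return percent * tg_um_per_percent(tg_molar_mass, density)


def grams_to_umol(grams: float, molar_mass: float) -> float:
    """Convert a mass in grams to umol for the given molar mass."""
    return grams / molar_mass * 1e6
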