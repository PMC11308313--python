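"""Unit conventions and centralized conversions.

The public interface of this package uses clinical bedside units
throughout:

==============  =========  =====================================
quantity        unit       rationale
==============  =========  =====================================
volume          mL         syringe and dead-volume scale
flow            mL/h       how pump rates are prescribed
time            h          matches mL/h
pressure        mbar       typical infusion-pump display unit
length          m          tubing/catheter lengths
diameter        mm         catheter inner diameters
viscosity       mPa*s      water is 1.0 at room temperature
resistance      mbar*h/mL  pressure drop per unit flow
compliance      mL/mbar    stored volume per unit pressure
==============  =========  =====================================

All conversions between these units and SI live here; no other module
converts units by hand.
"""

# SI conversion factors
MBAR_PER_PA = 1.0 / 100.0
H_PER_S = 1.0 / 3600.0
ML_PER_M3 = 1.0e6
M_PER_MM = 1.0e-3
PAS_PER_MPAS = 1.0e-3

#: multiply a resistance in Pa*s/m^3 by this to get mbar*h/mL
RESISTANCE_SI_TO_CLINICAL = MBAR_PER_PA * H_PER_S / ML_PER_M3

MIN_PER_H = 60.0


def resistance_si_to_clinical(r_pa_s_per_m3: float) -> float:
    """Convert a hydraulic resistance from Pa*s/m^3 to mbar*h/mL."""
    return r_pa_s_per_m3 * RESISTANCE_SI_TO_CLINICAL


def hours_to_minutes(t_h: float) -> float:
    return t_h * MIN_PER_H
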