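"""Unit conversions.

Internal canonical units are CGS-like: lengths in cm, times in seconds,
permeabilities in cm/s, diffusion constants in cm^2/s. Concentrations are in
arbitrary "model units" (only ratios, e.g. to a Michaelis constant, matter).
The experimental literature reports pulse kinetics in mm and hours, so the
presentation layer converts with the helpers below.
"""

S_PER_HR = 3600.0
CM_PER_MM = 0.1
CM_PER_UM = 1e-4

# 1 cm/s = 36 000 mm/hr ; 1 cm^2/s = 360 000 mm^2/hr
MMHR_PER_CMS = S_PER_HR / CM_PER_MM
MM2HR_PER_CM2S = S_PER_HR / CM_PER_MM**2


def cms_to_mmhr(x):
    """Convert a velocity or permeability from cm/s to mm/hr."""
    return x * MMHR_PER_CMS


def mmhr_to_cms(x):
    """Convert a velocity or permeability from mm/hr to cm/s."""
    return x / MMHR_PER_CMS


def cm2s_to_mm2hr(x):
    """Convert a diffusion constant or spreading rate from cm^2/s to mm^2/hr."""
    return x * MM2HR_PER_CM2S


def mm2hr_to_cm2s(x):
    """Convert a diffusion constant or spreading rate from mm^2/hr to cm^2/s."""
    return x / MM2HR_PER_CM2S


def um_to_cm(x):
    return x * CM_PER_UM


def cm_to_mm(x):
    return x / CM_PER_MM


def mm_to_cm(x):
    return x * CM_PER_MM


def hr_to_s(x):
    return x * S_PER_HR


def s_to_hr(x):
    return x / S_PER_HR
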