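"""Closed-form pulse kinetics and inverse inference.

A pulse travelling down a file of cells of length L coupled by the linear
flux law (polar permeability p, diffusion-like permeability q) moves at
velocity v and spreads at rate rho (the time derivative of its spatial
variance):

    v = p,            rho = L (p + 2q)              (rapid intracellular mixing)

With a finite intracellular diffusion constant D these become

    1/v = 1/p + (L/2D)(1 + 2 q/p),  rho <= L v (1 + 2 q/p),

the bound approaching equality as D grows. These four relations underlie all
the inverse inference here: the ratio q/p from measured (v, rho), the minimum
intracellular D consistent with a measured spreading rate, and the effective
lateral diffusion constant of coupled channels.

All operations are unit-safe in the sense that consistent inputs (all mm/hr,
or all cm/s) give the same dimensionless outputs; functions returning a
dimensional quantity state their units explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .units import mm2hr_to_cm2s

__all__ = [
    "CellGeometry",
    "KineticsPair",
    "simple_kinetics",
    "velocity_with_diffusion",
    "spreading_bound",
    "infer_qp",
    "min_diffusion",
    "effective_diffusion",
    "matched_permeability",
    "diffusion_time",
    "quadratic_scaling_prediction",
    "rescale_width_permeability",
    "vacuole_geometry",
]


@dataclass(frozen=True)
class CellGeometry:
    """Transporting-cell geometry: length, width (cm) and intracellular D."""

    L: float = 100e-4
    w: float = 20e-4
    D: float = 5e-6

    def __post_init__(self):
        if min(self.L, self.w, self.D) <= 0:
            raise ValueError("cell geometry values must be > 0")


@dataclass(frozen=True)
class KineticsPair:
    """Pulse velocity v and spreading rate rho = d(variance)/dt."""

    v: float
    rho: float

    def __post_init__(self):
        if self.v < 0 or self.rho < 0:
            raise ValueError("velocity and spreading rate must be >= 0")


def simple_kinetics(p: float, q: float, L: float) -> KineticsPair:
    """Kinetics v = p, rho = L(p + 2q) of the rapid-mixing cell-file model.

    Unit-agnostic: (p, q) in mm/hr with L in mm gives v in mm/hr and rho in
    mm^2/hr; cgs inputs give cgs outputs.
    """
    if p <= 0:
        raise ValueError("polar permeability p must be > 0")
    return KineticsPair(v=p, rho=L * (p + 2.0 * q))


def velocity_with_diffusion(p: float, q: float, L: float, D: float) -> float:
    """Pulse velocity with finite intracellular diffusion.

    1/v = 1/p + (L/2D)(1 + 2q/p). Recovers v = p as D -> inf and the
    diffusion-limited bound 2D/L as p -> inf with q = 0.
    """
    if p <= 0 or D <= 0:
        raise ValueError("p and D must be > 0")
    return 1.0 / (1.0 / p + (L / (2.0 * D)) * (1.0 + 2.0 * q / p))


def spreading_bound(v: float, L: float, qp_ratio: float) -> float:
    """Upper bound L*v*(1 + 2 q/p) on the spreading rate."""
    if v <= 0 or L <= 0 or qp_ratio < 0:
        raise ValueError("require v, L > 0 and q/p >= 0")
    return L * v * (1.0 + 2.0 * qp_ratio)


def infer_qp(v: float, rho: float, L: float) -> float:
    """Invert the kinetics for the permeability ratio q/p = (rho/(Lv) - 1)/2.

    A measured rho below L*v is inconsistent with the model (it would need
    q < 0); since measured spreading rates carry error bars this warns and
    returns the (negative) value rather than raising.
    """
    qp = (rho / (L * v) - 1.0) / 2.0
    if qp < 0:
        warnings.warn(
            "rho < L*v implies a negative q/p; measurement is inconsistent "
            "with the linear cell-file model",
            stacklevel=2,
        )
    return qp


def min_diffusion(v_mm_hr: float, rho_mm2_hr: float) -> float:
    """Minimum intracellular diffusion constant (cm^2/s) for a measured rho.

    Maximising v over p at fixed (rho, L, q/p) sends p -> inf, where
    v -> 2D/(L(1+2q/p)) while rho -> Lv(1+2q/p) at equality; eliminating
    L(1+2q/p) leaves D = rho/2 independent of v. Returned in cm^2/s from a
    spreading rate in mm^2/hr.
    """
    if v_mm_hr <= 0 or rho_mm2_hr <= 0:
        raise ValueError("v and rho must be > 0")
    return mm2hr_to_cm2s(rho_mm2_hr / 2.0)


def effective_diffusion(D: float, w: float, s: float) -> float:
    """Series combination 1/D_eff = 1/D + 1/(w s) for lateral movement.

    Lateral spread through a stack of channels of width w coupled by
    permeability s is diffusion-like with the membrane crossing (rate w*s)
    and intracellular diffusion (D) acting as resistances in series. s = 0
    returns 0 (no lateral movement).
    """
    if D <= 0 or w <= 0 or s < 0:
        raise ValueError("require D, w > 0 and s >= 0")
    if s == 0:
        return 0.0
    return 1.0 / (1.0 / D + 1.0 / (w * s))


def matched_permeability(D: float, w: float) -> float:
    """Lateral permeability matching membranes to cytoplasmic diffusion.

    The engineering criterion w*s = D (equal series resistances): larger s
    buys rapidly diminishing gains in D_eff beyond this point.
    """
    if D <= 0 or w <= 0:
        raise ValueError("require D, w > 0")
    return D / w


def diffusion_time(L_dist_cm: float, D_eff: float) -> float:
    """Time t = L^2 / D_eff (hours) to signal over a distance L_dist (cm)."""
    if L_dist_cm <= 0 or D_eff <= 0:
        raise ValueError("require positive distance and D_eff")
    return (L_dist_cm**2 / D_eff) / 3600.0


def quadratic_scaling_prediction(D_eff_ref: float, n_ref: int, n: int) -> float:
    """Predicted D_eff under quadratic scaling with the number of channels.

    If pulse broadening is controlled by the time to diffuse laterally across
    the whole stack (width proportional to n), matching models of different n
    requires D_eff proportional to n^2.
    """
    if D_eff_ref <= 0 or n_ref <= 0 or n <= 0:
        raise ValueError("require positive inputs")
    return D_eff_ref * (n / n_ref) ** 2


def rescale_width_permeability(s_ref: float, d: float, w_ref: float = 20e-4) -> float:
    """Rescale a lateral permeability for a channel of width d: s_ref*(d/w_ref).

    Narrower channels equilibrate faster for a given membrane permeability;
    scaling s by width reproduces the dynamics of the reference-width model,
    which is how cytosol (1 um) and vacuole (9 um half-width) channels are
    assigned permeabilities from the 20 um cell-file fit.
    """
    if s_ref < 0 or d <= 0 or w_ref <= 0:
        raise ValueError("require s_ref >= 0 and d, w_ref > 0")
    return s_ref * (d / w_ref)


def vacuole_geometry(
    cell_L: float = 100e-4, cell_w: float = 20e-4, cytoplasm_depth: float = 1e-4
) -> float:
    """Vacuole : cytoplasm volume ratio for a brick-shaped cell.

    The cytoplasm is a thin shell of the given depth inside a cell of square
    cross-section; the vacuole fills the rest. Defaults (100 x 20 um cell,
    1 um cytoplasm) give (18^2*98)/(20^2*100 - 18^2*98), about 4:1.
    """
    if not 0 < cytoplasm_depth < cell_w / 2:
        raise ValueError("cytoplasm depth must be in (0, cell_w/2)")
    vac = (cell_w - 2 * cytoplasm_depth) ** 2 * (cell_L - 2 * cytoplasm_depth)
    cyt = cell_w**2 * cell_L - vac
    return vac / cyt
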