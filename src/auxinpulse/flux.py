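"""Intercellular and inter-compartment flux laws.

All fluxes are per unit membrane area, in concentration x cm/s, and follow one
sign convention throughout the package: a positive flux moves auxin from the
first-named compartment to the second-named one (basipetal for axial faces,
"outward" for lateral couplings).

The laws implemented here are the building blocks of a chemiosmotic picture of
polar auxin transport: a polar + diffusion-like linear law between cells in a
file, the transporter algebra that reduces exporter/importer permeabilities
across an apoplastic gap to that linear law, Michaelis-Menten saturation of
carriers, asymmetric lateral exchange between unequal compartments
(cytosol/vacuole), and the weak-acid partitioning that sets passive membrane
permeabilities from pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearFluxParams",
    "TransporterParams",
    "SaturatingFluxParams",
    "AsymmetricLateralParams",
    "ChemiosmoticContext",
    "linear_flux",
    "transporter_flux",
    "derive_pq",
    "saturating_flux",
    "asymmetric_lateral_flux",
    "protonated_fraction",
    "passive_permeability",
    "AUXIN_PK",
]

#: pK of the carboxyl group of auxin (IAA).
AUXIN_PK = 4.7


def _check_nonneg_conc(*concs) -> None:
    for a in concs:
        if np.any(np.asarray(a) < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class LinearFluxParams:
    """Polar (p) plus diffusion-like (q) permeability, both in cm/s."""

    p: float
    q: float = 0.0

    def __post_init__(self):
        if self.p < 0 or self.q < 0:
            raise ValueError("permeabilities p, q must be >= 0")

    @property
    def qp_ratio(self) -> float:
        return self.q / self.p if self.p > 0 else math.inf


@dataclass(frozen=True)
class TransporterParams:
    """Exporter/importer permeabilities across one cell-cell interface.

    alpha1: total exporter permeability on the basal face of the upper cell.
    alpha2: total exporter permeability on the apical face of the lower cell.
    beta:   combined importer + passive permeability, equal on both faces.
    L0, D0: apoplast width (cm) and apoplastic diffusion constant (cm^2/s).
    """

    alpha1: float
    alpha2: float
    beta: float
    L0: float = 0.5e-4
    D0: float = 6.7e-6

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.beta, self.L0) < 0:
            raise ValueError("transporter permeabilities must be >= 0")
        if self.D0 <= 0:
            raise ValueError("apoplast diffusion constant D0 must be > 0")

    @property
    def r(self) -> float:
        """Dimensionless apoplast resistance parameter r = beta*L0/D0."""
        return self.beta * self.L0 / self.D0


@dataclass(frozen=True)
class SaturatingFluxParams:
    """Michaelis-Menten carrier kinetics.

    kappa1/kappa2 are the maximal directional fluxes (concentration x cm/s)
    and Km the half-saturation concentration. In the low-concentration limit
    the law is linear with permeability kappa/Km.
    """

    kappa1: float
    kappa2: float
    Km: float

    def __post_init__(self):
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("maximal fluxes kappa must be >= 0")
        if self.Km <= 0:
            raise ValueError("half-saturation constant Km must be > 0")

    @classmethod
    def from_permeability(cls, Km: float, s1: float, s2: float | None = None):
        """Build from linear-limit permeabilities, kappa_i = Km * s_i.

        With ``s2`` omitted the law is symmetric (kappa1 = kappa2 = Km*s1),
        the parameterisation used for saturable lateral couplings.
        """
        if s2 is None:
            s2 = s1
        return cls(kappa1=Km * s1, kappa2=Km * s2, Km=Km)


@dataclass(frozen=True)
class AsymmetricLateralParams:
    """Directional lateral permeabilities between two adjacent channels.

    s_fwd moves auxin channel1 -> channel2 (e.g. cytosol to vacuole), s_rev
    the reverse. Equal values recover the symmetric coupling s(a1 - a2).
    """

    s_fwd: float
    s_rev: float

    def __post_init__(self):
        if self.s_fwd < 0 or self.s_rev < 0:
            raise ValueError("lateral permeabilities must be >= 0")

    @classmethod
    def symmetric(cls, s: float):
        return cls(s_fwd=s, s_rev=s)


@dataclass(frozen=True)
class ChemiosmoticContext:
    """Compartment pH and membrane permeability to protonated auxin."""

    pH: float
    pK: float = AUXIN_PK
    P_IAAH: float = 4e-5

    def __post_init__(self):
        if self.P_IAAH <= 0:
            raise ValueError("P_IAAH must be > 0")


def linear_flux(params: LinearFluxParams, a_up, a_down):
    """Flux p*a_up + q*(a_up - a_down); positive is basipetal (up -> down)."""
    _check_nonneg_conc(a_up, a_down)
    return params.p * a_up + params.q * (a_up - a_down)


def transporter_flux(params: TransporterParams, a1, a2):
    """Flux (alpha1*a1 - alpha2*a2)/(2 + r) after eliminating the apoplast.

    The apoplastic concentrations are in quasi-steady state between export,
    import and diffusion across the gap; r = beta*L0/D0.
    """
    _check_nonneg_conc(a1, a2)
    return (params.alpha1 * a1 - params.alpha2 * a2) / (2.0 + params.r)


def derive_pq(params: TransporterParams) -> tuple[LinearFluxParams, float]:
    """Reduce transporter algebra to the linear law; return (params, q/p).

    p = (alpha1 - alpha2)/(2 + r), q = alpha2/(2 + r), q/p = alpha2/(alpha1 -
    alpha2). Requires alpha1 >= alpha2 so that p >= 0; for apolar exporters
    (alpha1 == alpha2) p = 0 and the ratio is flagged as infinite.
    """
    if params.alpha1 < params.alpha2:
        raise ValueError(
            "alpha1 must be >= alpha2 for a non-negative polar permeability"
        )
    denom = 2.0 + params.r
    p = (params.alpha1 - params.alpha2) / denom
    q = params.alpha2 / denom
    qp = math.inf if p == 0 else q / p
    return LinearFluxParams(p=p, q=q), qp


def saturating_flux(params: SaturatingFluxParams, a1, a2):
    """Michaelis-Menten flux kappa1*a1/(Km+a1) - kappa2*a2/(Km+a2)."""
    _check_nonneg_conc(a1, a2)
    Km = params.Km
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    out = params.kappa1 * a1 / (Km + a1) - params.kappa2 * a2 / (Km + a2)
    return out if out.ndim else float(out)


def asymmetric_lateral_flux(params: AsymmetricLateralParams, a1, a2):
    """Directional lateral flux s_fwd*a1 - s_rev*a2.

    Zero net flux at the equilibrium ratio a2/a1 = s_fwd/s_rev; reduces to the
    symmetric coupling s*(a1 - a2) when s_fwd == s_rev.
    """
    _check_nonneg_conc(a1, a2)
    return params.s_fwd * a1 - params.s_rev * a2


def protonated_fraction(pH, pK: float = AUXIN_PK):
    """Henderson-Hasselbalch fraction of auxin in the protonated (IAAH) form.

    1/(1 + 10^(pH - pK)); about one half at apoplastic pH ~ pK, and ~0.3% at
    cytoplasmic pH 7.2, which is the basis of chemiosmotic anion trapping.
    """
    return 1.0 / (1.0 + np.power(10.0, np.asarray(pH, dtype=float) - pK))


def passive_permeability(ctx: ChemiosmoticContext) -> float:
    """Effective total-auxin permeability out of a compartment at its pH.

    Only the protonated fraction crosses the membrane passively, so the
    effective permeability is P_IAAH * protonated_fraction(pH, pK).
    """
    return float(ctx.P_IAAH * protonated_fraction(ctx.pH, ctx.pK))
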