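"""Per-fiber-type metabolic core: rate laws and mass-balance helpers.

The kinetic core is a reduced mechanistic network (about twenty reactions
per fiber): glycogen phosphorylase, glycogen synthase, hexokinase/glucose
uptake, lumped glycolysis to pyruvate, lactate dehydrogenase, alanine
transaminase, lipolysis with glycerol release, fatty-acid activation,
creatine kinase, ATPase, pyruvate dehydrogenase, a lumped TCA/beta-oxidation
NADH supply, and lumped oxidative phosphorylation with O2 consumption and
proton bookkeeping.  Rate laws are saturating (Michaelis-Menten products)
multiplied by the exercise activation factor; free ADP and AMP are computed
from the creatine-kinase and adenylate-kinase near-equilibria rather than
integrated, which is what makes the AMP signal available to AMPK.

Concentrations are mmol/kg w.w., fluxes mmol/min/kg w.w., proton
concentration is mol/L for pH arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .physiology import ActivationParams, activation

__all__ = [
    "EquilibriumConstants",
    "RateLawConfig",
    "free_adp_amp",
    "ph_from_proton",
    "proton_from_ph",
    "michaelis",
    "atpase_rate",
    "glycogen_synthase_rate",
    "compartment_rhs",
    "cytosol_rhs",
    "mito_rhs",
]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Creatine-kinase and adenylate-kinase equilibrium constants.

    ``Keq_CK`` is the apparent CK constant in the direction
    PCr + ADP + H+ -> Cr + ATP, in L/mol so that it multiplies a proton
    concentration in mol/L; ``Keq_AK`` is dimensionless for
    2 ADP <-> ATP + AMP.
    """

    Keq_CK: float = 1.66e9
    Keq_AK: float = 1.05

    def __post_init__(self) -> None:
        if self.Keq_CK <= 0 or self.Keq_AK <= 0:
            raise ValueError("equilibrium constants must be positive")


def free_adp_amp(ATP: float, PCr: float, Cr: float, H: float,
                 keq: EquilibriumConstants = EquilibriumConstants()
                 ) -> tuple[float, float]:
    """Free cytosolic ADP and AMP from the CK and AK near-equilibria.

    ADP_free = ATP * Cr / (PCr * H * Keq_CK)  with H in mol/L,
    AMP_free = Keq_AK * ADP_free**2 / ATP.

    Raises on nonpositive PCr or H (the equilibria are undefined there).
    """
    if PCr <= 0:
        raise ValueError("PCr must be positive")
    if H <= 0:
        raise ValueError("H+ must be positive")
    adp = ATP * Cr / (PCr * H * keq.Keq_CK)
    amp = keq.Keq_AK * adp * adp / ATP if ATP > 0 else 0.0
    return adp, amp


def ph_from_proton(H: float) -> float:
    """pH from proton concentration in mol/L."""
    if H <= 0:
        raise ValueError("proton concentration must be positive")
    return -math.log10(H)


def proton_from_ph(pH: float) -> float:
    """Proton concentration (mol/L) from pH; exact inverse of
    :func:`ph_from_proton`."""
    return 10.0 ** (-pH)


def michaelis(c: float, km: float) -> float:
    """Saturation factor c / (km + c), clipped at zero substrate."""
    c = max(c, 0.0)
    return c / (km + c)


@dataclass(frozen=True)
class RateLawConfig:
    """One reaction's kinetic configuration.

    ``vmax`` in mmol/min/kg w.w.; ``km`` maps substrate name to its
    half-saturation constant; ``alpha`` maps fiber type ('I'/'II') to the
    exercise activation coefficient; ``stoichiometry`` maps species to net
    coefficients.
    """

    vmax: float
    km: Mapping[str, float] = field(default_factory=dict)
    alpha: Mapping[str, float] = field(default_factory=lambda: {"I": 0.0, "II": 0.0})
    tau: float = 0.4
    stoichiometry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("vmax must be nonnegative")


def atpase_rate(ATP: float, t: float, W_fiber: float, fiber_type: str,
                basal: float, alpha: Mapping[str, float], tau: float = 3.0,
                Km_ATP: float = 0.15, t_start: float = 0.0) -> float:
    """Basal ATP hydrolysis scaled by the exercise activation factor.

    The activation coefficient differs between fiber types (type II larger,
    reflecting the higher ATP cost of fast-twitch contraction).
    """
    act = activation(t, W_fiber, ActivationParams(alpha[fiber_type], tau, t_start))
    return basal * act * michaelis(ATP, Km_ATP)


def glycogen_synthase_rate(GLY: float, t: float, W: float, vmax: float,
                           K_gly: float, alpha: float, tau: float = 0.4,
                           t_start: float = 0.0) -> float:
    """Glycogen-synthase flux: decreases with glycogen content (saturating
    in 1/GLY), rises with exercise via the activation factor, and is the
    same law for both fiber types."""
    if GLY < 0:
        raise ValueError("glycogen must be nonnegative")
    act = activation(t, W, ActivationParams(alpha, tau, t_start))
    return vmax * (K_gly / (K_gly + GLY)) * act


def compartment_rhs(volume: float,
                    reactions: Mapping[str, Mapping[str, float]] | None = None,
                    rates: Mapping[str, float] | None = None,
                    transport_in: Mapping[str, float] | None = None,
                    transport_out: Mapping[str, float] | None = None,
                    ) -> dict[str, float]:
    """Dynamic mass balance of one compartment.

    ``reactions`` maps reaction name to its stoichiometry, ``rates`` to the
    corresponding rates (mmol/min/kg of the compartment); ``transport_in``
    and ``transport_out`` are per-species fluxes.  Returns dC/dt per species:

        dC_i/dt = (sum_r nu_ri * v_r + T_in,i - T_out,i) / V.
    """
    reactions = reactions or {}
    rates = rates or {}
    acc: dict[str, float] = {}
    for rname, stoich in reactions.items():
        v = rates.get(rname, 0.0)
        for sp, coeff in stoich.items():
            acc[sp] = acc.get(sp, 0.0) + coeff * v
    for sp, flux in (transport_in or {}).items():
        acc[sp] = acc.get(sp, 0.0) + flux
    for sp, flux in (transport_out or {}).items():
        acc[sp] = acc.get(sp, 0.0) - flux
    return {sp: val / volume for sp, val in acc.items()}


def cytosol_rhs(volume: float, reactions=None, rates=None,
                transport_blood=None, transport_mito=None) -> dict[str, float]:
    """Cytosolic mass balance: reaction turnover plus blood influx minus
    export to mitochondria, per unit cytosol volume."""
    return compartment_rhs(volume, reactions, rates,
                           transport_in=transport_blood,
                           transport_out=transport_mito)


def mito_rhs(volume: float, reactions=None, rates=None,
             transport_cyt=None) -> dict[str, float]:
    """Mitochondrial mass balance: reaction turnover plus influx from the
    cytosol, per unit mitochondrial volume."""
    return compartment_rhs(volume, reactions, rates, transport_in=transport_cyt)
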