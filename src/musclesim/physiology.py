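"""Organism-level physiology: exercise activation, blood flow and volume
dynamics, and inter-compartment transport fluxes.

Every exercise-sensitive flux in the model is scaled by the activation
multiplier

    f(t) = 1 + alpha * W * (1 - exp((t_start - t) / tau)),

a first-order rise from 1 at exercise onset toward the asymptote
``1 + alpha * W`` with time constant ``tau``.  Muscle blood flow Q and
muscle volume V_mus follow the same law around their resting values
(Q0 = 0.9 L/min for two legs, V_mus0 = 5 kg wet weight, tau = 0.4 min).

Transport between compartments is passive (linear in the concentration
difference, coefficient lambda) or facilitated (carrier-mediated,
difference of Michaelis saturations with maximal flux Rmax), both
multiplied by the activation factor.  Concentrations are in mmol/kg w.w.,
fluxes in mmol/min/kg w.w.; 1 kg w.w. is taken equivalent to 1 L where
blood flow couples to tissue mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ActivationParams",
    "BloodCompartment",
    "TransportParams",
    "FiberVolumes",
    "activation",
    "blood_flow",
    "muscle_volume",
    "passive_flux",
    "facilitated_flux",
    "blood_rhs",
    "PASSIVE_BLOOD_SPECIES",
    "FACILITATED_BLOOD_SPECIES",
    "PASSIVE_MITO_SPECIES",
    "FACILITATED_MITO_SPECIES",
    "BLOOD_SPECIES",
]

# species exchanged with blood and between cytosol and mitochondria
BLOOD_SPECIES = ("CO2", "O2", "Lac", "Ala", "Pyr", "H", "Glr", "Glc", "FFA")
PASSIVE_BLOOD_SPECIES = ("CO2", "O2", "Ala", "Glr")
FACILITATED_BLOOD_SPECIES = ("Glc", "Pyr", "Lac", "FFA", "H")
PASSIVE_MITO_SPECIES = ("CO2", "O2")
FACILITATED_MITO_SPECIES = ("H", "Pyr", "FAC", "CoA", "Pi")


@dataclass(frozen=True)
class ActivationParams:
    """First-order exercise activation: coefficient alpha (1/W), time
    constant tau (min), onset time t_start (min)."""

    alpha: float
    tau: float = 0.4
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def activation(t: float, W: float, p: ActivationParams) -> float:
    """Exercise activation multiplier at time ``t`` for constant work rate
    ``W`` from onset ``p.t_start``; equals 1 at rest and at onset and rises
    monotonically toward ``1 + alpha * W``."""
    if W == 0.0 or t <= p.t_start:
        return 1.0
    return 1.0 + p.alpha * W * (1.0 - math.exp((p.t_start - t) / p.tau))


@dataclass
class BloodCompartment:
    """Capillary blood + interstitial fluid, lumped (assumed equilibrated).

    ``V_bl`` is 20% of muscle volume; arterial concentrations are constant
    boundary conditions supplied by the (lumped) cardiorespiratory system.
    """

    V_mus0: float = 5.0
    Q0: float = 0.9
    C_art: dict[str, float] | None = None
    alpha_Q: float = 0.083
    alpha_V: float = 0.02
    tau: float = 0.4

    @property
    def V_bl0(self) -> float:
        return 0.2 * self.V_mus0

    @property
    def V_tis0(self) -> float:
        return 0.8 * self.V_mus0


def blood_flow(t: float, W: float, blood: BloodCompartment | None = None,
               t_start: float = 0.0) -> float:
    """Muscle blood flow Q(t) in L/min; Q0 at rest, linear in W at steady
    state with time constant 0.4 min."""
    b = blood or BloodCompartment()
    return b.Q0 * activation(t, W, ActivationParams(b.alpha_Q, b.tau, t_start))


def muscle_volume(t: float, W: float, blood: BloodCompartment | None = None,
                  t_start: float = 0.0) -> float:
    """Active muscle volume V_mus(t) in kg w.w."""
    b = blood or BloodCompartment()
    return b.V_mus0 * activation(t, W, ActivationParams(b.alpha_V, b.tau, t_start))


@dataclass(frozen=True)
class TransportParams:
    """Per-species transport parameters: passive permeability-surface area
    coefficient ``lam`` or facilitated ``Rmax``/``KM``, with activation."""

    lam: float = 0.0
    Rmax: float = 0.0
    KM: float = 1.0
    activation: ActivationParams = ActivationParams(alpha=0.0)


def passive_flux(C_a: float, C_b: float, lam: float, act: float = 1.0) -> float:
    """Passive diffusion flux a -> b: lambda * (C_a - C_b) * activation.

    Antisymmetric in its concentration arguments and zero at equality.
    """
    return lam * (C_a - C_b) * act


def facilitated_flux(C_a: float, C_b: float, Rmax: float, KM: float,
                     act: float = 1.0) -> float:
    """Carrier-mediated flux a -> b:
    Rmax * (C_a/(KM+C_a) - C_b/(KM+C_b)) * activation; bounded by
    +/- Rmax * activation and zero at equal concentrations."""
    return Rmax * (C_a / (KM + C_a) - C_b / (KM + C_b)) * act


def blood_rhs(C_bl: float, C_art: float, Q: float, T_R: float, T_W: float,
              V_bl: float, V_R: float, V_W: float) -> float:
    """Blood mass balance for one species:

    dC_bl/dt = (Q * (C_art - C_bl) - T_R * V_R - T_W * V_W) / V_bl,

    where T_R, T_W are the blood->cytosol fluxes (mmol/min/kg w.w.) into
    type I and type II fibers and V_* are compartment masses (kg w.w.).
    """
    return (Q * (C_art - C_bl) - T_R * V_R - T_W * V_W) / V_bl


@dataclass(frozen=True)
class FiberVolumes:
    """Fiber-type volumes and their cytosol/mitochondria partitions.

    Cytosolic fractions are 0.88 (type I) and 0.92 (type II); the remainder
    is mitochondrial, reflecting the higher mitochondrial content of
    slow-twitch fibers.
    """

    V_R: float = 2.0
    V_W: float = 2.0

    @property
    def V_cyt_R(self) -> float:
        return 0.88 * self.V_R

    @property
    def V_mit_R(self) -> float:
        return 0.12 * self.V_R

    @property
    def V_cyt_W(self) -> float:
        return 0.92 * self.V_W

    @property
    def V_mit_W(self) -> float:
        return 0.08 * self.V_W
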