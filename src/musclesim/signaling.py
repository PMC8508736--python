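"""Ca2+- and AMPK-dependent signal transduction.

Myoplasmic Ca2+ rises in proportion to the relative intensity of the
fiber's contractile activity; Ca2+-calmodulin then activates CaMKII
(autophosphorylation), the phosphatase calcineurin (which dephosphorylates
and thereby activates the CREB coactivator CRTC), and the kinase CaMKK2.
AMPK exists as three heterotrimers (alpha2-beta2-gamma1, alpha2-beta2-gamma3,
alpha1-beta2-gamma1) that share one mechanism and differ only in parameters:
Thr172 phosphorylation by LKB1 and CaMKK2, and dephosphorylation that is
suppressed by AMP binding (protection) and promoted by ATP.  The gamma3
complex has the lowest baseline activity and is the one that responds to
moderate/high-intensity exercise; total AMPK activity is the sum over
heterotrimers.  CaMKII and total AMPK activity converge on CREB1 Ser133.

All rate constants are per minute; protein amounts are normalized so each
pool total is 1 (phosphorylated amounts are therefore fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "CalciumParams",
    "HeterotrimerParams",
    "SignalingParams",
    "HETEROTRIMERS",
    "calcium_drive",
    "ca_calmodulin",
    "camkii_update",
    "camkii_steady_fraction",
    "ampk_update",
    "ampk_steady_fraction",
    "creb_crtc_update",
]

HETEROTRIMERS = ("a2b2g3", "a2b2g1", "a1b2g1")


@dataclass(frozen=True)
class CalciumParams:
    """Myoplasmic Ca2+ drive: resting level, rise per unit relative
    intensity, Hill constant for calmodulin binding, smoothing time."""

    Ca_rest: float = 0.1       # uM, time-averaged myoplasmic Ca2+ at rest
    Ca_slope: float = 1.2      # uM at full relative intensity
    tau_Ca: float = 0.3        # min, first-order smoothing
    K_CaM: float = 0.6         # uM, half-activation of calmodulin
    n_CaM: float = 4.0         # cooperative Ca-CaM binding (4 sites)


def calcium_drive(intensity_fraction: float, p: CalciumParams) -> float:
    """Steady-state myoplasmic Ca2+ (uM) at a given relative intensity
    (fraction of the fiber's maximal recruitment); linear in intensity,
    Ca_rest when the fiber is unrecruited.  The engine applies first-order
    smoothing with time constant ``tau_Ca`` around this target."""
    if not 0.0 <= intensity_fraction <= 1.0 + 1e-9:
        raise ValueError("intensity fraction must lie in [0, 1]")
    return p.Ca_rest + p.Ca_slope * intensity_fraction


def ca_calmodulin(Ca: float, p: CalciumParams) -> float:
    """Fraction of calmodulin in the active Ca2+-bound form (Hill)."""
    c = max(Ca, 0.0) ** p.n_CaM
    return c / (p.K_CaM ** p.n_CaM + c)


# --------------------------------------------------------------------------
# CaMKII


def camkii_update(CaMKII_p: float, CaCaM: float, k_act: float,
                  k_dp: float, total: float = 1.0) -> float:
    """dCaMKII_p/dt: Ca-calmodulin-driven phosphorylation of the free pool
    against a constitutive phosphatase."""
    return k_act * CaCaM * (total - CaMKII_p) - k_dp * CaMKII_p


def camkii_steady_fraction(CaCaM: float, k_act: float, k_dp: float) -> float:
    """Closed-form fixed point of :func:`camkii_update` (total = 1)."""
    a = k_act * CaCaM
    return a / (a + k_dp)


# --------------------------------------------------------------------------
# AMPK heterotrimers


@dataclass(frozen=True)
class HeterotrimerParams:
    """Kinetics of one AMPK heterotrimer.

    ``k_lkb1``/``k_camkk2``: phosphorylation rate constants (per min, per
    unit upstream activity); ``k_pp``: basal Thr172 dephosphorylation;
    ``K_amp``: AMP concentration (mmol/kg w.w.) at which phosphatase
    protection is half-maximal -- the gamma-subunit nucleotide sensitivity;
    ``baseline_activity`` and ``activity_scale`` map the phospho-fraction to
    an activity; ``total`` is the heterotrimer's share of the AMPK pool.
    """

    total: float
    k_lkb1: float
    k_camkk2: float
    k_pp: float
    K_amp: float
    amp_allosteric: float = 1.0   # Hill amplitude of allosteric activation
    K_amp_allosteric: float = 5e-4
    baseline_activity: float = 0.0
    activity_scale: float = 1.0


def _dephos_rate(k_pp: float, AMP: float, ATP: float, K_amp: float,
                 ATP_ref: float) -> float:
    """Effective dephosphorylation: promoted by ATP, suppressed by AMP."""
    return k_pp * (ATP / ATP_ref) / (1.0 + AMP / K_amp)


def ampk_update(p_frac: Mapping[str, float], AMP: float, ATP: float,
                CaMKK2_act: float, LKB1_act: float,
                params: Mapping[str, HeterotrimerParams],
                ATP_ref: float = 6.2,
                ) -> tuple[dict[str, float], dict[str, float], float]:
    """Per-heterotrimer dynamics and activities.

    ``p_frac`` maps heterotrimer name to its phosphorylated fraction.
    Returns ``(dp_dt, activity, total_activity)``: phosphorylation by LKB1
    and CaMKK2 acts on the unphosphorylated fraction; dephosphorylation is
    reduced by AMP (phosphatase protection) and increased by ATP; activity
    combines a baseline, the phosphorylation state and direct AMP
    allostery; total activity is the sum over heterotrimers weighted by
    their pool shares.
    """
    dp: dict[str, float] = {}
    act: dict[str, float] = {}
    for h, hp in params.items():
        p = p_frac[h]
        kin = hp.k_lkb1 * LKB1_act + hp.k_camkk2 * CaMKK2_act
        dp[h] = kin * (1.0 - p) - _dephos_rate(hp.k_pp, AMP, ATP, hp.K_amp, ATP_ref) * p
        allo = 1.0 + hp.amp_allosteric * AMP / (hp.K_amp_allosteric + AMP)
        act[h] = hp.total * (hp.baseline_activity + hp.activity_scale * p * allo)
    return dp, act, sum(act.values())


def ampk_steady_fraction(hp: HeterotrimerParams, AMP: float, ATP: float,
                         CaMKK2_act: float, LKB1_act: float,
                         ATP_ref: float = 6.2) -> float:
    """Closed-form phospho-fraction fixed point of one heterotrimer."""
    kin = hp.k_lkb1 * LKB1_act + hp.k_camkk2 * CaMKK2_act
    kout = _dephos_rate(hp.k_pp, AMP, ATP, hp.K_amp, ATP_ref)
    return kin / (kin + kout)


# --------------------------------------------------------------------------
# CREB1 / CRTC


def creb_crtc_update(CREB1_p: float, CRTC_d: float, CaMKII_p: float,
                     AMPK_total_activity: float, CN_act: float,
                     k_camkii: float, k_ampk: float, k_creb_dp: float,
                     k_cn: float, k_crtc_rp: float,
                     CREB_total: float = 1.0, CRTC_total: float = 1.0,
                     ) -> tuple[float, float]:
    """CREB1 Ser133 phosphorylation (by CaMKII and total AMPK activity) and
    CRTC Ser171 dephosphorylation/activation (by calcineurin), each against
    a constitutive counter-reaction.  Returns (dCREB1_p/dt, dCRTC_d/dt)."""
    d_creb = (k_camkii * CaMKII_p + k_ampk * AMPK_total_activity) * \
        (CREB_total - CREB1_p) - k_creb_dp * CREB1_p
    d_crtc = k_cn * CN_act * (CRTC_total - CRTC_d) - k_crtc_rp * CRTC_d
    return d_creb, d_crtc


@dataclass(frozen=True)
class SignalingParams:
    """Full signaling parameter set for one fiber type."""

    calcium: CalciumParams = field(default_factory=CalciumParams)
    # CaMKII
    k_camkii_act: float = 0.2
    k_camkii_dp: float = 0.1
    # calcineurin / CaMKK2 (algebraic, saturating in Ca-CaM)
    K_cn: float = 0.25
    K_camkk2: float = 0.25
    # CRTC
    k_cn: float = 1.0
    k_crtc_rp: float = 0.2
    # CREB1
    k_creb_camkii: float = 0.5
    k_creb_ampk: float = 0.5
    k_creb_dp: float = 0.12
    # AMPK
    lkb1_activity: float = 1.0
    ATP_ref: float = 6.2
    heterotrimers: dict[str, HeterotrimerParams] = field(default_factory=dict)
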