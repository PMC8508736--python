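# Frozen default configuration of the skeletal-muscle exercise simulator.
#
# Units: time min, power W, volumes kg wet weight (1 kg w.w. ~ 1 L for
# blood-flow coupling), concentrations mmol/kg w.w. except protons (mol/L),
# fluxes mmol/min/kg w.w., rate constants 1/min, activation coefficients 1/W.
#
# Initial concentrations are resting calibration inputs (typical literature
# resting values for human vastus lateralis); the engine refines them to the
# model's exact resting steady state by Newton iteration before simulating.

physiology:
  V_mus0: 5.0          # resting two-leg active muscle mass, kg w.w.
  Q0: 0.9              # resting muscle blood flow (two legs), L/min
  alpha_Q: 0.083       # blood-flow activation coefficient, 1/W
  alpha_V: 0.02        # muscle-volume activation coefficient, 1/W
  tau_QV: 0.4          # time constant of Q and V_mus responses, min
  beta_blood: 30.0     # effective blood acid-carrying capacity, mmol/L/pH
  arterial:            # constant arterial boundary concentrations
    O2: 8.6
    CO2: 21.0
    Glc: 5.0
    Lac: 0.8
    Pyr: 0.08
    Ala: 0.3
    Glr: 0.06
    FFA: 0.6
    H: 3.98e-8         # mol/L (arterial pH 7.4)

fibers:
  # equal fiber-type volumes: V_I = V_II = 0.5 * V_tis = 2 kg w.w.
  cyt_fraction: {I: 0.88, II: 0.92}
  Atot: 6.22           # adenine pool: ATP + free (CK-equilibrium) ADP
  Crtot: 39.0          # creatine pool PCr + Cr
  NADtot: 3.0          # mitochondrial NAD(H) pool
  beta_cyt: 45.0       # cytosolic buffer capacity, mmol/kg/pH
  beta_mit: 45.0
  Keq_CK: 1.66e9       # CK equilibrium constant, L/mol
  Keq_AK: 1.05         # AK equilibrium constant

transport:
  tau: 0.4
  alpha: {I: 0.03, II: 0.03}      # activation of transport fluxes per fiber W
  blood_passive:                   # lambda, 1/min
    CO2: 3.0
    O2: 0.30
    Ala: 0.10
    Glr: 0.10
  blood_facilitated:               # Rmax mmol/min/kg, KM mmol/kg (H: mol/L)
    Glc: {Rmax: 0.5,  KM: 1.5}
    Pyr: {Rmax: 0.2,  KM: 0.3}
    Lac: {Rmax: 8.0,  KM: 4.0}
    FFA: {Rmax: 0.3,  KM: 0.3}
    H:   {Rmax: 10.0, KM: 1.0e-7}
  mito_passive:                    # lambda, 1/min
    CO2: 20.0
    O2: 15.0
  mito_facilitated:
    H:   {Rmax: 2.0,  KM: 1.0e-7}
    Pyr: {Rmax: 4.0,  KM: 0.15}
    FAC: {Rmax: 0.6,  KM: 0.05}
    CoA: {Rmax: 0.05, KM: 0.05}
    Pi:  {Rmax: 1.0,  KM: 2.0}

metabolism:
  # Reduced kinetic core; vmax per kg w.w. fiber, alpha per fiber type.
  atpase:
    basal: 0.40
    alpha: {I: 0.70, II: 0.80}
    tau: 0.15          # fast ATPase response; supply lags (see oxphos tau)
    Km_ATP: 0.5
    nu_H: 0.40         # protons released per ATP hydrolyzed (buffered)
  glycogen_phosphorylase:
    vmax: 1.2
    alpha: {I: 0.12, II: 0.45}
    tau: 0.4
    K_gly: 150.0
    K_adp: 0.06
    K_pi: 1.0
  glycogen_synthase:
    vmax: 0.03
    alpha: 0.010       # same activation for both fiber types
    tau: 0.4
    K_gly: 100.0       # flux falls as glycogen accumulates
  hexokinase:
    vmax: 0.08
    alpha: {I: 0.10, II: 0.10}
    tau: 0.4
    Km_Glc: 0.15
    Km_ATP: 0.5
    K_hexp_inh: 0.5
  glycolysis:
    vmax: 1.5
    alpha: {I: 0.12, II: 0.45}
    tau: 0.4
    Km_HexP: 0.25
    K_adp: 0.06
    Km_Pi: 1.0
  ldh: {kf: 4.0, Keq: 12.0}        # Pyr + H <-> Lac, near-equilibrium
  alt: {kf: 0.06, Keq: 8.0}        # Pyr <-> Ala
  lipolysis:
    vmax: 0.004                    # glycerol release rate
    alpha: {I: 0.02, II: 0.005}
    tau: 1.0
    K_ffa_inh: 1.0
  fa_activation:
    vmax: 0.05
    Km_FFA: 0.3
    Km_CoA: 0.02
    Km_ATP: 0.5
  ck: {k: 60.0, nu_H: 0.9}         # fast reversible CK; forward consumes H+
  pdh:
    vmax: 0.5
    alpha: {I: 0.25, II: 0.12}     # pyruvate oxidation saturates earlier in II
    tau: 0.4
    Km_Pyr: 0.08
    Km_CoA: 0.02
    Km_NAD: 0.5
  tca:
    vmax: 4.0
    Km_ACoA: 0.05
    Km_NAD: 0.5
  beta_ox:
    vmax: 0.02
    alpha: {I: 0.20, II: 0.05}
    tau: 1.0
    Km_FAC: 0.01
    Km_CoA: 0.02
    Km_NAD: 0.5
  oxphos:
    vmax: 2.0                      # NADH oxidation at unit factors
    alpha: {I: 0.12, II: 0.08}
    tau: 0.6
    Km_NADH: 0.5
    K_adp: 0.045                   # Hill (n=2) half-point in free ADP
    Km_O2: 0.03
    P_per_NADH: 2.5                # ATP per NADH (P/O)
    nu_H: 1.0                      # protons consumed per NADH oxidized

initial:
  blood: {O2: 8.2, CO2: 22.0, Glc: 4.8, Lac: 0.9, Pyr: 0.09, Ala: 0.32,
          Glr: 0.07, FFA: 0.62, H: 4.2e-8}
  cytosol: {ATP: 6.2, PCr: 26.0, Cr: 13.0, Pi: 3.0, H: 1.0e-7, GLY: 85.0,
            Glc: 0.5, HexP: 0.3, Pyr: 0.1, Lac: 1.0, Ala: 1.5, Glr: 0.05,
            FFA: 0.4, FAC: 0.02, CoA: 0.1, O2: 7.5, CO2: 23.0}
  mito: {Pyr: 0.1, O2: 7.0, CO2: 23.0, H: 1.0e-7, Pi: 3.0, NADH: 0.3,
         FAC: 0.01, CoA: 0.3, ACoA: 0.05}

signaling:
  calcium:
    Ca_rest: 0.1       # uM, time-averaged myoplasmic Ca2+ at rest
    Ca_slope: 1.2      # uM rise at full relative intensity
    tau_Ca: 0.3
    K_CaM: 0.6
    n_CaM: 4.0         # cooperative Ca binding keeps the resting drive low
  camkii: {k_act: 0.2, k_dp: 0.1}
  calcineurin: {K: 0.25}
  camkk2: {K: 0.25}
  crtc: {k_cn: 1.0, k_rp: 0.2}
  creb: {k_camkii: 0.5, k_ampk: 0.5, k_dp: 0.12}
  lkb1_activity: 1.0
  ATP_ref: 6.2
  # Heterotrimer pool shares sum to 1; the gamma3 complex is the minor,
  # exercise-responsive, low-baseline-activity species.
  ampk:
    a2b2g3: {total: 0.20, k_lkb1: 0.004, k_camkk2: 0.14, k_pp: 1.0,
             K_amp: 1.0e-4, amp_allosteric: 2.0, K_amp_allosteric: 5.0e-4,
             baseline_activity: 0.02, activity_scale: 1.0}
    a2b2g1: {total: 0.65, k_lkb1: 0.006, k_camkk2: 0.004, k_pp: 0.25,
             K_amp: 2.0e-2, amp_allosteric: 1.0, K_amp_allosteric: 5.0e-3,
             baseline_activity: 0.10, activity_scale: 1.0}
    a1b2g1: {total: 0.15, k_lkb1: 0.006, k_camkk2: 0.004, k_pp: 0.25,
             K_amp: 2.0e-2, amp_allosteric: 1.0, K_amp_allosteric: 5.0e-3,
             baseline_activity: 0.10, activity_scale: 1.0}

genes:
  # drive references (resting CREB_p * CRTC product; resting X protein) are
  # written by the calibration script from the solved resting state
  creb_crtc_ref: 0.0048
  x_protein_ref: 1.0
  NR4A3:    {k0: 0.020, vmax: 0.40, K: 0.15, n: 2.0, kdeg: 0.023}
  NR4A2:    {k0: 0.016, vmax: 0.25, K: 0.20, n: 2.0, kdeg: 0.014}
  X:        {k0: 0.020, vmax: 0.40, K: 0.15, n: 2.0, kdeg: 0.020,
             k_translate: 0.005, k_prot_deg: 0.005}
  PPARGC1A: {k0: 0.008, vmax: 0.10, K: 5.0, n: 2.0, kdeg: 0.005}

protocol:
  W_max: 250.0         # power at full recruitment / VO2max equivalent
  theta: 0.24          # type-II recruitment onset fraction of W_max
  cap_I: 125.0         # per-fiber-type peak powers (sum to W_max)
  cap_II: 125.0
  ramp_slope: 10.0     # W/min (derived: 24% of 250 W reached at minute 6)
  fatigue: {enabled: false, decline: 0.0}

variants:
  x_factor_enabled: true
  direct_creb_regulation: false

solver:
  rtol: 1.0e-8
  atol: 1.0e-10
  method: LSODA
  output_dt: 0.25      # min
  baseline_min: 10.0   # resting segment simulated before exercise onset
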