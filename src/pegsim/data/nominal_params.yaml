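# Nominal population PK/PD parameter set (version-controlled; see docs/methods.md).
# Calibrated once by scripts/calibrate.py against the published summary
# benchmarks in pegsim.params.BENCHMARKS.  Units: h, mg, L, mg/L, cm/year.
version: nominal-2026-09
pk:
  cl_pop: 0.022      # L/h at 25 kg -> t1/2 ~ 3.3 d; >=95 % of steady state by week 12
  v_pop: 2.5         # L at 25 kg (~0.1 L/kg, PEG conjugate stays near plasma)
  ka_pop: 0.03       # 1/h, slow SC absorption (tmax ~ 2.5 d)
  f_bio: 1.0
  wt_ref: 25.0       # kg, mid-range of the banded target weights
  exp_cl: 0.75
  exp_v: 1.0
  omega_cl: 0.25
  omega_v: 0.20
  omega_ka: 0.35
  sigma_prop: 0.15
  sigma_add: 0.01
idr:
  kin: 5.4           # ng/mL/h; typical baseline r0 = kin/kout = 180 ng/mL
  kout: 0.03         # 1/h, IGF-1 turnover t1/2 ~ 23 h
  smax: 3.304        # maximal fractional stimulation of production
  sc50: 3.5          # mg/L
  omega_r0: 0.30
  omega_smax: 0.25
  sigma_igf: 0.10
gv:
  e0: 3.57           # cm/year, typical pre-treatment GV
  emax_gv: 7.490    # cm/year drug-attributable ceiling
  auc50: 25.81      # mg*h/L interval AUC at half-maximal effect
  lam: 0.0788        # 1/year first-to-second-year attenuation
  omega_gv: 2.65      # additive SD on the Emax term
  sigma_gv: 0.5      # cm/year residual SD on observed GV
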