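# Packaged parameter set for the ErbB signaling model.
# Units: concentrations in nM, time in minutes, bimolecular rate
# constants in /nM/min.  These constants are package-owned calibrated
# values (see scripts/calibrate_signaling.py for the calibration
# procedure and residuals); they are not literature measurements.

units:
  concentration: nM
  time: min
totals:
  EGFR: 100.0
  ErbB2: 100.0
  ErbB3: 20.0
  Grb2: 100.0
  GAB1: 60.0
  Shc: 100.0
  PI3K: 50.0
  Ras: 200.0
  Raf: 100.0
  MEK: 200.0
  ERK: 300.0
  AKT: 200.0
  PIP2: 600.0
  PTEN: 50.0
  PTP: 50.0
scenario:
  egf_dose: 8.0
  nrg_dose: 25.0
  lapatinib_saturating: 1000.0
  t_end: 60.0
  readout: peak
  overexpression_factor: 10.0
rates:
  kon_egf: 0.05
  koff_egf: 0.1
  kon_nrg: 0.004
  koff_nrg: 0.25
  kon_lap: 1.0
  koff_lap: 1.0
  kon_d11: 0.01
  kon_d12: 0.005
  kon_d23: 2.0e-06
  kon_d13: 4.0e-07
  kon_d33: 0.012075
  koff_dim: 0.1
  k_const: 0.0
  k1068: 2.0
  k1173: 2.0
  k_p3: 60.0
  erbb3_cat_scale: 0.001
  k_ptp: 0.03
  k_ptp3: 0.001
  kon_grb2: 0.1
  koff_grb2: 3.0
  kon_gab1: 0.1
  koff_gab1: 1.0
  kon_shc: 0.1
  koff_shc: 3.0
  k_rasact: 0.003
  k_rasact2: 5.0e-05
  k_rasdeact: 0.5
  k_rafact: 0.002
  k_rafdeact: 0.2
  k_mekact: 0.002
  k_mekdeact: 0.2
  k_erkact: 0.002
  k_erkdeact: 0.2
  kon_pi3k: 0.05
  koff_pi3k: 1.0
  kon_pi3k3: 0.2
  koff_pi3k3: 2.0
  k_pip: 0.01
  kon_pten: 0.1
  koff_pten: 0.1
  kcat_pten: 2.0
  kon_akt: 0.01
  koff_akt: 0.5
  k_aktact: 1.0
  k_aktdeact: 0.3
  k_int: 0.02
  k_int_c: 0.005
mutants:
  WT:
    s1068: 1.0
    s1173: 1.0
    atp_scale: 1.0
    ligand_independent_rate: 0.0
  L834R:
    s1068: 0.17003
    s1173: 0.06283
    atp_scale: 1.0
    ligand_independent_rate: 2.0e-05
  del723-729insS:
    s1068: 0.75
    s1173: 0.75
    atp_scale: 1.0
    ligand_independent_rate: 0.0001
  L834R/T766M:
    s1068: 100.0
    s1173: 100.0
    atp_scale: 1.0
    ligand_independent_rate: 2.0e-05
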