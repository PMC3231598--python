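# Reference five-electrode panel: one perchlorate-selective membrane (P1),
# three sulfide-selective membranes (S1-S3) and one generic anion-exchanger
# membrane (G) that responds to both ions.  Slopes, detection limits and
# log selectivity coefficients are the measured response characteristics of
# the corresponding all-solid-state metallophtalocyanine/quaternary-ammonium
# ISE array; standard potentials (e0) are arbitrary per-electrode constants
# (they cancel in slope and selectivity recovery).  The background activity
# of each electrode is derived at load time from its detection limit at the
# calibration reference ionic strength.
activity:
  formalism: davies
  A: 0.511
calibration_reference_ionic_strength_M: 0.05
ions:
  - name: ClO4
    charge: -1
  - name: S
    charge: -2
sensors:
  - id: P1
    primary_ion: ClO4
    e0_mV: 210.0
    slope_mV_per_decade: -57.7
    detection_limit_M: 5.2e-6
    log_k_pot:
      S: -1.96
    noise_sd_mV: 0.5
    drift_sd_per_session_mV: 2.0
  - id: S1
    primary_ion: S
    e0_mV: 152.0
    slope_mV_per_decade: -33.3
    detection_limit_M: 1.3e-5
    log_k_pot:
      ClO4: -2.68
    noise_sd_mV: 0.5
    drift_sd_per_session_mV: 2.0
  - id: S2
    primary_ion: S
    e0_mV: 168.0
    slope_mV_per_decade: -30.9
    detection_limit_M: 9.8e-6
    log_k_pot:
      ClO4: -3.23
    noise_sd_mV: 0.5
    drift_sd_per_session_mV: 2.0
  - id: S3
    primary_ion: S
    e0_mV: 143.0
    slope_mV_per_decade: -28.9
    detection_limit_M: 9.9e-6
    log_k_pot:
      ClO4: -3.75
    noise_sd_mV: 0.5
    drift_sd_per_session_mV: 2.0
  # The generic quaternary-ammonium membrane is characterized against either
  # ion in practice (its selectivity coefficient toward perchlorate exceeds 1:
  # a Hofmeister-type preference for the lipophilic anion).  As a forward
  # model it is encoded once, with its preferred ion (perchlorate) as the
  # primary: this reproduces the membrane's Nernstian perchlorate response
  # and keeps it cross-responsive to sulfide throughout the working range.
  - id: G
    primary_ion: ClO4
    e0_mV: 96.0
    slope_mV_per_decade: -60.1
    detection_limit_M: 7.5e-6
    log_k_pot:
      S: -1.25
    noise_sd_mV: 0.5
    drift_sd_per_session_mV: 2.0
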