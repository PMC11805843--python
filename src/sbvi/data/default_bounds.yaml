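# Default per-harmonic candidate bounds for the impedance inverse search.
# Linear-velocity convention (dyn*s/cm^3, pressure per linear velocity).
# Representative of published human input-impedance ranges spanning normal
# and aortic-stenosis vascular states; not the table of any single study.
# The engine widens each range a further 20% (expansion_fraction) before
# sampling. Phase bounds for harmonic 0 are pinned to zero.
expansion_fraction: 0.20
harmonics:
  - {harmonic: 0, amplitude_min: 400.0, amplitude_max: 2000.0, phase_min: 0.0, phase_max: 0.0}
  - {harmonic: 1, amplitude_min: 50.0, amplitude_max: 400.0, phase_min: -1.6, phase_max: 0.3}
  - {harmonic: 2, amplitude_min: 35.0, amplitude_max: 300.0, phase_min: -1.4, phase_max: 0.4}
  - {harmonic: 3, amplitude_min: 25.0, amplitude_max: 250.0, phase_min: -1.2, phase_max: 0.5}
  - {harmonic: 4, amplitude_min: 20.0, amplitude_max: 220.0, phase_min: -1.0, phase_max: 0.5}
  - {harmonic: 5, amplitude_min: 20.0, amplitude_max: 200.0, phase_min: -0.9, phase_max: 0.5}
  - {harmonic: 6, amplitude_min: 20.0, amplitude_max: 200.0, phase_min: -0.8, phase_max: 0.5}
  - {harmonic: 7, amplitude_min: 20.0, amplitude_max: 190.0, phase_min: -0.8, phase_max: 0.5}
  - {harmonic: 8, amplitude_min: 15.0, amplitude_max: 190.0, phase_min: -0.7, phase_max: 0.5}
  - {harmonic: 9, amplitude_min: 15.0, amplitude_max: 180.0, phase_min: -0.7, phase_max: 0.5}
  - {harmonic: 10, amplitude_min: 15.0, amplitude_max: 180.0, phase_min: -0.7, phase_max: 0.5}
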