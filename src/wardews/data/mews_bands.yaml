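# Early-warning-score band criteria (MEWS bands; SpO2 band from the UK
# National Early Warning Score, which MEWS lacks).  For each parameter the
# bands are listed in increasing value order as inclusive upper edges at the
# stated resolution; the last band is open-ended (upper: null = +inf).
# A temperature measurement is banded identically whether it is axillary
# (sensor) or tympanic (nurse); SBP and TT enter only the nurse score.
version: 1
parameters:
  RR:            # breaths/min
    resolution: 1
    bands:
      - {upper: 8, points: 2}
      - {upper: 14, points: 0}
      - {upper: 20, points: 1}
      - {upper: 29, points: 2}
      - {upper: null, points: 3}
  HR:            # beats/min
    resolution: 1
    bands:
      - {upper: 40, points: 2}
      - {upper: 50, points: 1}
      - {upper: 100, points: 0}
      - {upper: 110, points: 1}
      - {upper: 129, points: 2}
      - {upper: null, points: 3}
  SPO2:          # %
    resolution: 1
    bands:
      - {upper: 91, points: 3}
      - {upper: 93, points: 2}
      - {upper: 95, points: 1}
      - {upper: null, points: 0}
  SBP:           # mm Hg
    resolution: 1
    bands:
      - {upper: 70, points: 3}
      - {upper: 80, points: 2}
      - {upper: 100, points: 1}
      - {upper: 200, points: 0}
      - {upper: null, points: 2}
  AT:            # degC (axillary, sensor)
    resolution: 0.1
    bands:
      - {upper: 34.9, points: 2}
      - {upper: 38.4, points: 0}
      - {upper: null, points: 2}
  TT:            # degC (tympanic, nurse); same banding as AT
    resolution: 0.1
    bands:
      - {upper: 34.9, points: 2}
      - {upper: 38.4, points: 0}
      - {upper: null, points: 2}
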