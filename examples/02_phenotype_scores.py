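"""Phenotype a single hand-built encounter: SIRS day, APS, KDIGO stage.

A patient turns tachycardic and febrile on hospital day 1 and their
creatinine rises from 1.0 to 1.7 mg/dL: the pipeline should date SIRS
qualification to day 1, score the APACHE-II acute-physiology points from
the most abnormal same-day values, and stage the kidney injury.
"""

import pandas as pd
import sirsfluids as sf
from sirsfluids.phenotype import compute_aps, kdigo_stage
from sirsfluids.tables import empty_table

day0, day1 = pd.Timestamp("2012-03-01 09:00"), pd.Timestamp("2012-03-02 09:00")
vitals = pd.DataFrame([
    {"encounter_id": "E1", "vital": "heart_rate", "value": 84., "datetime": day0},
    {"encounter_id": "E1", "vital": "heart_rate", "value": 118., "datetime": day1},
    {"encounter_id": "E1", "vital": "temperature", "value": 38.9, "datetime": day1},
])
labs = pd.DataFrame([
    {"encounter_id": "E1", "analyte": "creatinine", "value": 1.0, "unit": "mg/dL",
     "specimen": "serum", "datetime": day0},
    {"encounter_id": "E1", "analyte": "creatinine", "value": 1.7, "unit": "mg/dL",
     "specimen": "serum", "datetime": day1 + pd.Timedelta(days=1)},
])

event = sf.detect_sirs(vitals, labs, encounter_id="E1")
print("SIRS qualification:", event.qualification_date.date(),
      "criteria:", sorted(event.criteria_met))

sirs = sf.detect_sirs(vitals, labs)
aps = compute_aps(labs, vitals, sirs)
print("APS:", int(aps['aps'].iloc[0]),
      "(HR 118 -> 2 points, temp 38.9 -> 1 point; missing variables score 0)")

kd = kdigo_stage(labs, sirs)
print(f"KDIGO: baseline {kd['baseline_creatinine'].iloc[0]:.1f}, "
      f"peak {kd['peak_creatinine'].iloc[0]:.1f} -> stage {kd['stage'].iloc[0]}"
      " (>=1.5x baseline)")
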