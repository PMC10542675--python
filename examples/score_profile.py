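"""Score one participant's raw survey answers into the nine-domain
traffic-light profile and the continuous DRP total."""

import pandas as pd

from drisk import score_dataframe

row = {
    "participant_id": "demo", "wave": "BL",
    # alcohol: 10 drinks/week but 4 on a big night -> medium
    "drinks_per_week": 10, "max_drinks_per_occasion": 4, "abstains": False,
    "smoking": "none",
    # BMI 27.7 -> medium
    "height_m": 1.70, "weight_kg": 80,
    # 180 moderate minutes = 720 MET-minutes -> sufficient (low)
    "light_min": 60, "moderate_min": 180, "vigorous_min": 0,
    # cardiometabolic: hypertension diagnosed and medically managed -> low
    "htn_diagnosis": "yes", "htn_checkups": True,
    "htn_managed": "medically_managed",
    "chol_diagnosis": "no", "chol_checkups": True, "chol_managed": "n/a",
    "diab_diagnosis": "no", "diab_checkups": True, "diab_managed": "n/a",
}
row.update({f"mind_{i}": 1.0 for i in range(1, 10)})    # MIND adherence 9.0
row.update({f"mind_{i}": 0.0 for i in range(10, 15)})   # -> medium band
row.update({f"cog_{i}": 3 for i in range(1, 12)})       # 33 -> low risk

scored = score_dataframe(pd.DataFrame([row]))
print(scored[[f"risk_{d}" for d in
              ("alcohol", "bmi", "diet")]].iloc[0].to_string())
print(f"drp_total = {scored.loc[0, 'drp_total']}")
# Three domains at medium (alcohol, bmi, diet) and six at low give a DRP
# total of 1.5 out of 9: each medium level contributes 0.5 risk points.
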