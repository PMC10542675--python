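# Per-(domain, level) recommendation texts for the personalised risk
# report.  Seeded from the published intervention guidance; override with a
# custom template file for production wording.  Low-risk levels carry no
# recommendation; unknown levels prompt completion of the missing items.
alcohol:
  medium: "Aim to drink less than two standard alcoholic drinks per day."
  high: "Reduce alcohol consumption: drink less than two standard drinks per day and stay within 14 standard drinks per week."
bmi:
  medium: "Work toward and keep a healthy body-mass index (18.5-24.9) through diet and regular activity."
  high: "Talk with your health care provider about a plan for reaching a healthy body-mass index."
hypertension:
  medium: "Keep up regular check-ups and work with your doctor toward managing your blood pressure."
  high: "Ensure your blood pressure is checked regularly and medically managed."
cholesterol:
  medium: "Keep up regular check-ups and work with your doctor toward managing your cholesterol."
  high: "Ensure your cholesterol is checked regularly and medically managed."
diabetes:
  medium: "Keep up regular check-ups and work with your doctor toward managing your blood sugar."
  high: "Ensure your diabetes risk is checked regularly and medically managed."
smoking:
  medium: "Work toward quitting smoking entirely; occasional smoking still carries risk."
  high: "Quit smoking: support from your doctor or a quit-line can help."
cognitive_activity:
  high: "Engage regularly in social and cognitively stimulating activities - several times a month across a range of activities."
physical_activity:
  high: "Engage regularly in 150 minutes per week of moderate physical activity."
diet:
  medium: "Move further toward a Mediterranean style diet: more leafy greens, berries, nuts, fish and olive oil."
  high: "Adopt a Mediterranean style diet; your current eating pattern is associated with elevated risk."
unknown: "Some answers for this domain were missing; complete them at your next survey for a full profile."
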