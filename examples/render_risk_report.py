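"""Render a participant's personalised traffic-light risk report with a
year-on-year DRP-total trace."""

from drisk import (SimConfig, build_panel, render_report, simulate_cohort)

raw, _ = simulate_cohort(SimConfig(n_participants=5,
                                   apply_missingness=False), seed=6)
panel = build_panel(raw)
pid = panel["participant_id"].iloc[0]
history = panel[panel["participant_id"] == pid].sort_values("wave_date")

print(render_report(history, fmt="markdown"))
# Each domain renders green/orange/red for low/medium/high risk; every
# non-low domain carries an action recommendation, and the trace at the
# bottom shows the participant's DRP total at every completed wave.
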