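"""Personalised traffic-light risk-profile reports.

Renders, per participant, the nine behaviour domains with their
traffic-light colour (low → green, medium → orange, high → red, unknown →
grey), a recommendation for every non-low domain drawn from a template
table keyed on (domain, level), and the wave-by-wave DRP-total trace so
year-on-year change is visible.  Output is deterministic markdown or HTML
(the timestamp is injectable so documents can be compared byte-for-byte).
"""

from __future__ import annotations

import html as _html
from pathlib import Path

import pandas as pd
import yaml

from .scoring import DOMAINS

__all__ = ["load_template", "render_report", "default_template_path"]

LEVEL_COLOURS = {"low": "green", "medium": "orange", "high": "red",
                 "unknown": "grey"}

DOMAIN_TITLES = {
    "alcohol": "Alcohol consumption",
    "bmi": "Body mass index",
    "hypertension": "Blood pressure management",
    "cholesterol": "Cholesterol management",
    "diabetes": "Diabetes management",
    "smoking": "Smoking",
    "cognitive_activity": "Cognitive activity",
    "physical_activity": "Physical activity",
    "diet": "Diet (MIND adherence)",
}


def default_template_path() -> Path:
    return Path(__file__).parent / "data" / "recommendations.yaml"


def load_template(path=None) -> dict:
    with open(path or default_template_path()) as fh:
        return yaml.safe_load(fh)


def _recommendation(template: dict, domain: str, level: str) -> str | None:
    if level == "low":
        return None
    if level == "unknown":
        text = template.get("unknown")
        if text is None:
            raise KeyError(f"template has no entry for ({domain}, unknown)")
        return text
    try:
        return template[domain][level]
    except KeyError:
        raise KeyError(f"template has no entry for ({domain}, {level})") from None


def render_report(profile_history: pd.DataFrame, template: dict | None = None,
                  fmt: str = "markdown", generated: str = "") -> str:
    """Render one participant's report from their scored wave history.

    ``profile_history`` holds one row per scored wave (columns
    ``wave``, ``drp_total``, ``risk_<domain>``...), ordered oldest first;
    the latest wave defines the current profile.  ``generated`` is an
    injectable timestamp string (empty by default, keeping output
    deterministic).
    """
    if len(profile_history) < 1:
        raise ValueError("need at least one scored wave")
    template = template or load_template()
    hist = profile_history.reset_index(drop=True)
    latest = hist.iloc[-1]
    pid = str(latest.get("participant_id", ""))

    entries = []
    for d in DOMAINS:
        level = str(latest[f"risk_{d}"])
        colour = LEVEL_COLOURS[level]
        rec = _recommendation(template, d, level)
        entries.append((DOMAIN_TITLES[d], level, colour, rec))

    trace = [(str(r["wave"]),
              "n/a" if pd.isna(r["drp_total"]) else f"{r['drp_total']:.1f}")
             for _, r in hist.iterrows()]

    if fmt == "markdown":
        return _render_markdown(pid, entries, trace, latest, generated)
    if fmt == "html":
        return _render_html(pid, entries, trace, latest, generated)
    raise ValueError(f"unknown format: {fmt!r}")


def _total_str(latest) -> str:
    t = latest["drp_total"]
    return "undefined (missing answers)" if pd.isna(t) else f"{t:.1f} / 9"


def _render_markdown(pid, entries, trace, latest, generated) -> str:
    lines = [f"# Dementia Risk Profile — participant {pid}", ""]
    if generated:
        lines += [f"_Generated: {generated}_", ""]
    lines += [f"**Current DRP total: {_total_str(latest)}** "
              "(low risk = 0, medium = 0.5, high = 1 per domain)", "",
              "| Domain | Risk level | Colour |", "|---|---|---|"]
    recs = []
    for title, level, colour, rec in entries:
        lines.append(f"| {title} | {level} | {colour} |")
        if rec:
            recs.append(f"- **{title}:** {rec}")
    lines += ["", "## Recommendations", ""]
    lines += recs if recs else ["All domains are low risk — keep it up!"]
    lines += ["", "## Your DRP total by wave", ""]
    lines += [f"- {wave}: {total}" for wave, total in trace]
    return "\n".join(lines) + "\n"


def _render_html(pid, entries, trace, latest, generated) -> str:
    e = _html.escape
    rows = []
    for title, level, colour, rec in entries:
        rows.append(
            f'<tr><td>{e(title)}</td>'
            f'<td style="background:{colour};color:white">{e(level)}</td>'
            f'<td>{e(rec) if rec else ""}</td></tr>')
    trace_items = "".join(f"<li>{e(w)}: {e(t)}</li>" for w, t in trace)
    gen = f"<p><em>Generated: {e(generated)}</em></p>" if generated else ""
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>Dementia Risk Profile — {e(pid)}</title></head><body>"
        f"<h1>Dementia Risk Profile — participant {e(pid)}</h1>{gen}"
        f"<p><strong>Current DRP total: {e(_total_str(latest))}</strong></p>"
        "<table border='1'><tr><th>Domain</th><th>Risk level</th>"
        f"<th>Recommendation</th></tr>{''.join(rows)}</table>"
        f"<h2>Your DRP total by wave</h2><ul>{trace_items}</ul>"
        "</body></html>\n")
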