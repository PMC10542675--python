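"""Independent brute-force rule-table scorer used only as a test oracle.

Deliberately written as literal transcriptions of the published cut-point
table, structured differently from the package implementation (explicit
rule tables and chained conditions, no shared code)."""

import math


def _miss(x):
    return x is None or (isinstance(x, float) and math.isnan(x))


def oracle_alcohol(week, occ, abstains):
    if abstains is True:
        return "low"
    if _miss(week):
        return "unknown"
    if week > 14:
        return "high"
    if _miss(occ):
        return "unknown"
    if occ > 2:
        return "medium"
    return "low"


def oracle_bmi(height, weight):
    if _miss(height) or _miss(weight):
        return "unknown"
    bmi = weight / (height * height)
    if 18 <= bmi <= 24.999999999:
        return "low"
    if bmi < 18:
        return "medium"
    if bmi < 30:
        return "medium"
    return "high"


_CARDIO_RULES = {
    # (diagnosis, checkups, managed) -> level; None entries = any value
    ("no", True, None): "low",
    ("yes", None, "medically_managed"): "low",
    ("unsure", True, None): "medium",
    ("yes", True, "working_toward"): "medium",
    ("no", False, None): "high",
}


def oracle_cardio(dx, checkups, managed):
    if _miss(dx):
        return "unknown"
    for (rdx, rcu, rmg), lv in _CARDIO_RULES.items():
        if rdx != dx:
            continue
        if rcu is not None and (_miss(checkups) or bool(checkups) != rcu):
            continue
        if rmg is not None and (_miss(managed) or managed != rmg):
            continue
        return lv
    # remaining: diagnosed, not medically managed
    if dx == "yes":
        if _miss(checkups) or _miss(managed):
            return "unknown"
        return "high"
    return "unknown"


def oracle_smoking(s):
    table = {"none": "low", "occasional": "medium", "weekly_or_more": "high"}
    return table.get(s, "unknown") if not _miss(s) else "unknown"


def oracle_met(light, mod, vig):
    if _miss(light) or _miss(mod) or _miss(vig):
        return None
    return light * 3.3 + mod * 4 + vig * 8


def oracle_physical(light, mod, vig):
    met = oracle_met(light, mod, vig)
    if met is None:
        return "unknown"
    return "low" if met >= 600 else "high"


def oracle_cognitive(codes):
    if any(_miss(c) for c in codes):
        return "unknown"
    return "low" if sum(codes) >= 33 else "high"


def oracle_mind(comps):
    if any(_miss(c) for c in comps):
        return "unknown"
    s = sum(comps)
    if s >= 12:
        return "low"
    if s >= 7.5:
        return "medium"
    return "high"


def oracle_row(row):
    """Score a raw-response mapping into the nine domain levels."""
    g = row.get
    return {
        "alcohol": oracle_alcohol(g("drinks_per_week"),
                                  g("max_drinks_per_occasion"), g("abstains")),
        "bmi": oracle_bmi(g("height_m"), g("weight_kg")),
        "hypertension": oracle_cardio(g("htn_diagnosis"), g("htn_checkups"),
                                      g("htn_managed")),
        "cholesterol": oracle_cardio(g("chol_diagnosis"), g("chol_checkups"),
                                     g("chol_managed")),
        "diabetes": oracle_cardio(g("diab_diagnosis"), g("diab_checkups"),
                                  g("diab_managed")),
        "smoking": oracle_smoking(g("smoking")),
        "cognitive_activity": oracle_cognitive(
            [g(f"cog_{i}") for i in range(1, 12)]),
        "physical_activity": oracle_physical(g("light_min"), g("moderate_min"),
                                             g("vigorous_min")),
        "diet": oracle_mind([g(f"mind_{i}") for i in range(1, 15)]),
    }


def oracle_total(levels):
    if any(v == "unknown" for v in levels.values()):
        return None
    return 0.5 * sum(v == "medium" for v in levels.values()) \
        + 1.0 * sum(v == "high" for v in levels.values())
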