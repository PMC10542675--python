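"""Scoring of the knowledge and motivation survey instruments.

Two instruments are supported:

* **KoDeRR** (Knowledge of Dementia Risk Reduction): three subscales scored
  as counts of correct responses against an answer key — general knowledge
  (0–22), strategy knowledge (0–20) and misconception discernment (0–12).

* **MCHLB-DRR** (Motivation to Change Health and Lifestyle Behaviours for
  Dementia Risk Reduction): seven Health-Beliefs-Model dimensions scored as
  item sums — perceived susceptibility (5–20), severity (6–25), benefits
  (5–20), barriers (5–20), cues to action (5–20), self-efficacy (2–10) and
  general health motivation (5–20).  Higher scores mean a stronger standing
  on the construct; barriers are inverted in interpretation only.

Item structure (item counts, column prefixes, response scales, answer keys)
is configuration, not code: the published subscale ranges pin down the
defaults but not the items themselves.  Incomplete subscales yield a missing
score (no prorating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "load_item_map",
    "KODERR_SUBSCALES",
    "MCHLB_DIMENSIONS",
    "default_koderr_config",
    "default_mchlb_config",
    "koderr_item_columns",
    "mchlb_item_columns",
    "score_koderr",
    "score_mchlb",
]

#: subscale -> (n_items, printed score range)
KODERR_SUBSCALES = {
    "general_knowledge": (22, (0, 22)),
    "strategy_knowledge": (20, (0, 20)),
    "misconception_discernment": (12, (0, 12)),
}

#: dimension -> (n_items, item response scale (lo, hi), printed score range)
MCHLB_DIMENSIONS = {
    "susceptibility": (5, (1, 4), (5, 20)),
    "severity": (6, (1, 4), (6, 25)),
    "benefits": (5, (1, 4), (5, 20)),
    "barriers": (5, (1, 4), (5, 20)),
    "cues_to_action": (5, (1, 4), (5, 20)),
    "self_efficacy": (2, (1, 5), (2, 10)),
    "general_health_motivation": (5, (1, 4), (5, 20)),
}

_KODERR_PREFIX = {
    "general_knowledge": "koderr_gen",
    "strategy_knowledge": "koderr_strat",
    "misconception_discernment": "koderr_misc",
}
_MCHLB_PREFIX = {
    "susceptibility": "mchlb_susc",
    "severity": "mchlb_sev",
    "benefits": "mchlb_ben",
    "barriers": "mchlb_barr",
    "cues_to_action": "mchlb_cue",
    "self_efficacy": "mchlb_se",
    "general_health_motivation": "mchlb_ghm",
}


@dataclass
class SubscaleSpec:
    name: str
    items: list[str]
    score_range: tuple[float, float]
    answer_key: dict[str, object] | None = None  # KoDeRR only
    response_scale: tuple[float, float] | None = None  # MCHLB only


def koderr_item_columns(subscale: str) -> list[str]:
    n, _ = KODERR_SUBSCALES[subscale]
    return [f"{_KODERR_PREFIX[subscale]}_{i}" for i in range(1, n + 1)]


def mchlb_item_columns(dimension: str) -> list[str]:
    n, _, _ = MCHLB_DIMENSIONS[dimension]
    return [f"{_MCHLB_PREFIX[dimension]}_{i}" for i in range(1, n + 1)]


def default_koderr_config() -> dict[str, SubscaleSpec]:
    """Default KoDeRR item map: per subscale, items named ``<prefix>_i``
    with correct answer 1 (responses coded 1 = correct option chosen)."""
    out = {}
    for name, (n, rng) in KODERR_SUBSCALES.items():
        items = koderr_item_columns(name)
        out[name] = SubscaleSpec(name, items, rng, answer_key={c: 1 for c in items})
    return out


def default_mchlb_config() -> dict[str, SubscaleSpec]:
    """Default MCHLB-DRR item map consistent with the printed subscale
    ranges (e.g. susceptibility 5 items × 1–4, self-efficacy 2 × 1–5)."""
    out = {}
    for name, (n, scale, rng) in MCHLB_DIMENSIONS.items():
        out[name] = SubscaleSpec(name, mchlb_item_columns(name), rng,
                                 response_scale=scale)
    return out


def load_item_map(path) -> dict[str, dict[str, SubscaleSpec]]:
    """Load instrument item maps from YAML/JSON.

    Layout::

        koderr:
          general_knowledge:
            items: [q1, q2, ...]
            answer_key: {q1: 3, q2: 1, ...}   # optional; default 1
        mchlb:
          susceptibility:
            items: [s1, ...]
            response_scale: [1, 4]

    Returns ``{"koderr": {...}, "mchlb": {...}}`` with whatever sections
    the file declares; unspecified subscales keep their defaults.
    """
    import json
    text = open(path).read()
    raw = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
        else json.loads(text)
    out = {"koderr": default_koderr_config(), "mchlb": default_mchlb_config()}
    for name, entry in (raw.get("koderr") or {}).items():
        items = list(entry["items"])
        key = entry.get("answer_key") or {c: 1 for c in items}
        rng = tuple(entry.get("score_range", (0, len(items))))
        out["koderr"][name] = SubscaleSpec(name, items, rng,
                                           answer_key=dict(key))
    for name, entry in (raw.get("mchlb") or {}).items():
        items = list(entry["items"])
        scale = tuple(entry.get("response_scale", (1, 4)))
        rng = tuple(entry.get("score_range",
                              (len(items) * scale[0], len(items) * scale[1])))
        out["mchlb"][name] = SubscaleSpec(name, items, rng,
                                          response_scale=scale)
    return out


def _subscale_config(config, default_factory):
    if config is None:
        return default_factory()
    return config


def score_koderr(df: pd.DataFrame, config: dict[str, SubscaleSpec] | None = None
                 ) -> pd.DataFrame:
    """Score KoDeRR responses: per-subscale counts of correct answers.

    Missing items count as incorrect (scored 0) and set
    ``koderr_<subscale>_incomplete``.  Rows with every item of a subscale
    missing get a missing score.
    """
    config = _subscale_config(config, default_koderr_config)
    out = pd.DataFrame(index=df.index)
    for name, spec in config.items():
        n_expected, rng = KODERR_SUBSCALES.get(name, (len(spec.items), spec.score_range))
        if len(spec.items) != n_expected:
            raise ValueError(
                f"KoDeRR subscale {name!r} configured with {len(spec.items)} items, "
                f"expected {n_expected} for printed range {rng}")
        missing_cols = [c for c in spec.items if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing KoDeRR item columns: {missing_cols}")
        resp = df[spec.items]
        correct = pd.DataFrame(
            {c: (resp[c] == spec.answer_key[c]) & resp[c].notna() for c in spec.items}
        )
        any_missing = resp.isna().any(axis=1)
        all_missing = resp.isna().all(axis=1)
        score = correct.sum(axis=1).astype(float)
        score[all_missing] = np.nan
        out[name] = score.clip(*spec.score_range)
        out[f"{name}_incomplete"] = any_missing
    return out


def score_mchlb(df: pd.DataFrame, config: dict[str, SubscaleSpec] | None = None
                ) -> pd.DataFrame:
    """Score MCHLB-DRR responses: per-dimension item sums clamped to the
    printed range.

    Any missing item renders the dimension score missing (flagged
    ``<dimension>_incomplete``); responses outside the configured scale
    raise a validation error.
    """
    config = _subscale_config(config, default_mchlb_config)
    out = pd.DataFrame(index=df.index)
    for name, spec in config.items():
        missing_cols = [c for c in spec.items if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing MCHLB item columns: {missing_cols}")
        resp = df[spec.items].apply(pd.to_numeric, errors="coerce")
        lo, hi = spec.response_scale
        vals = resp.to_numpy(dtype=float)
        bad = (~np.isnan(vals)) & ((vals < lo) | (vals > hi))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"MCHLB {name!r} item {spec.items[j]} response {vals[i, j]} outside "
                f"scale [{lo}, {hi}]")
        incomplete = resp.isna().any(axis=1)
        score = resp.sum(axis=1, min_count=len(spec.items))
        out[name] = score.clip(*spec.score_range)
        out[f"{name}_incomplete"] = incomplete
    return out
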