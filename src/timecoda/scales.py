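"""Scoring of the self-reported mental-health instruments.

Four outcomes are used throughout the package:

* **GDS-10** — 10-item Geriatric Depression Scale, yes/no items.  Items
  1, 5 and 8 (1-based, questionnaire order) are positively worded, so a
  *no* on those counts toward the score; a *yes* counts on the rest.
  Score 0–10, higher = more depressive symptoms.
* **Three-item loneliness scale** — items coded 1 ("hardly ever"),
  2 ("some of the time"), 3 ("often"); summed score 3–9, higher = lonelier.
* **Cantril ladder** — single 0–10 self-rating of life/happiness.
* **SF-12 MCS** — mental component summary, accepted as a pre-computed
  number on the 0–100 norm scale (mean 50, SD 10); its proprietary
  scoring coefficients are not implemented here.

Change scores are wave 1 minus wave 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GDS10_REVERSE_ITEMS",
    "OutcomePanel",
    "OUTCOME_RANGES",
    "score_gds10",
    "score_loneliness",
    "score_cantril",
    "check_mcs",
    "compute_change",
    "score_item_table",
]

#: 1-based indices of the positively worded GDS-10 items ("satisfied with
#: your life", "feel happy", "full of energy") whose *negative* answer scores.
GDS10_REVERSE_ITEMS: frozenset[int] = frozenset({1, 5, 8})

OUTCOME_RANGES: dict[str, tuple[float, float]] = {
    "depression": (0, 10),
    "loneliness": (3, 9),
    "happiness": (0, 10),
    "mcs": (0, 100),
}


def _coerce_binary(item, index: int) -> int | None:
    if item is None or (isinstance(item, float) and math.isnan(item)):
        return None
    if isinstance(item, str):
        s = item.strip().lower()
        if s in {"yes", "y", "1", "true"}:
            return 1
        if s in {"no", "n", "0", "false"}:
            return 0
        raise ValueError(f"GDS-10 item {index}: cannot read {item!r} as yes/no")
    v = int(item)
    if v not in (0, 1):
        raise ValueError(f"GDS-10 item {index}: expected 0/1 (no/yes), got {item!r}")
    return v


def score_gds10(items: Sequence, missing: str = "reject") -> int:
    """Score a 10-item GDS response vector (1 = yes, 0 = no, in item order).

    The negative responses to items 1, 5 and 8 and the positive responses
    to the remaining items are summed, giving 0–10 with higher scores
    meaning more depressive symptoms.

    ``missing`` policy for None/NaN items: ``"reject"`` (default) raises;
    ``"prorate"`` rescales the observed sum to 10 items and rounds, but
    only when at least 8 items were answered.  Proration is an extension
    beyond the source instrument's published rule and is off by default.
    """
    items = list(items)
    if len(items) != 10:
        raise ValueError(f"GDS-10 takes exactly 10 items, got {len(items)}")
    coded = [_coerce_binary(it, i + 1) for i, it in enumerate(items)]
    answered = [(i + 1, v) for i, v in enumerate(coded) if v is not None]
    if len(answered) < 10:
        if missing == "reject":
            missing_idx = [i + 1 for i, v in enumerate(coded) if v is None]
            raise ValueError(f"GDS-10 items {missing_idx} missing")
        if missing != "prorate":
            raise ValueError(f"unknown missing policy {missing!r}")
        if len(answered) < 8:
            raise ValueError(
                f"cannot prorate GDS-10 with only {len(answered)} answered items"
            )
    raw = sum(
        (1 - v) if idx in GDS10_REVERSE_ITEMS else v for idx, v in answered
    )
    if len(answered) == 10:
        return int(raw)
    return int(round(raw * 10.0 / len(answered)))


def score_loneliness(items: Sequence) -> int:
    """Sum of the three loneliness items, each coded 1/2/3; range 3-9."""
    items = list(items)
    if len(items) != 3:
        raise ValueError(f"loneliness scale takes exactly 3 items, got {len(items)}")
    out = 0
    for i, it in enumerate(items, start=1):
        if it is None or (isinstance(it, float) and math.isnan(it)):
            raise ValueError(f"loneliness item {i} missing")
        v = int(it)
        if v not in (1, 2, 3):
            raise ValueError(
                f"loneliness item {i}: codes are 1 (hardly ever), 2 (some of"
                f" the time), 3 (often); got {it!r}"
            )
        out += v
    return out


def score_cantril(value) -> int:
    """Validate a Cantril-ladder response (integer step 0-10)."""
    v = int(value)
    if not 0 <= v <= 10:
        raise ValueError(f"Cantril ladder steps run 0-10, got {value!r}")
    return v


def check_mcs(value) -> float:
    """Validate a pre-computed SF-12 mental component summary (0-100)."""
    v = float(value)
    if not 0 <= v <= 100:
        raise ValueError(f"SF-12 MCS is norm-scored on 0-100, got {value!r}")
    return v


@dataclass(frozen=True)
class OutcomePanel:
    """The four mental-health scores for one participant at one wave."""

    depression: int
    loneliness: int
    happiness: int
    mcs: float
    wave: int

    def __post_init__(self) -> None:
        for name in ("depression", "loneliness", "happiness", "mcs"):
            lo, hi = OUTCOME_RANGES[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v!r} outside its range [{lo}, {hi}]")
        if self.wave not in (0, 1):
            raise ValueError(f"wave must be 0 or 1, got {self.wave!r}")


def compute_change(panel_w0: OutcomePanel, panel_w1: OutcomePanel) -> dict[str, float]:
    """Wave-to-wave change per indicator: wave 1 value minus wave 0 value."""
    if panel_w0.wave != 0 or panel_w1.wave != 1:
        raise ValueError(
            f"expected a wave-0 and a wave-1 panel, got waves"
            f" {panel_w0.wave} and {panel_w1.wave}"
        )
    return {
        name: getattr(panel_w1, name) - getattr(panel_w0, name)
        for name in ("depression", "loneliness", "happiness", "mcs")
    }


GDS_COLUMNS = [f"gds_q{i}" for i in range(1, 11)]
LONE_COLUMNS = [f"lone_q{i}" for i in range(1, 4)]


def score_item_table(items: pd.DataFrame, missing: str = "reject") -> pd.DataFrame:
    """Score an item-level table into outcome columns.

    Expects columns ``gds_q1..gds_q10``, ``lone_q1..lone_q3``, ``cantril``
    and ``mcs`` (plus any passthrough columns such as participant id and
    ``wave``).  Rows with missing or invalid items get NaN for the affected
    outcome only — analyses are listwise per outcome, so one unanswered
    scale does not drop the participant from the others.
    """
    out = items.drop(columns=GDS_COLUMNS + LONE_COLUMNS + ["cantril", "mcs"],
                     errors="ignore").copy()

    def _safe(fn, row) -> float:
        try:
            return float(fn(row))
        except (ValueError, TypeError):
            return float("nan")

    if set(GDS_COLUMNS) <= set(items.columns):
        out["depression"] = [
            _safe(lambda r: score_gds10(r, missing=missing), row)
            for row in items[GDS_COLUMNS].itertuples(index=False)
        ]
    if set(LONE_COLUMNS) <= set(items.columns):
        out["loneliness"] = [
            _safe(score_loneliness, row)
            for row in items[LONE_COLUMNS].itertuples(index=False)
        ]
    if "cantril" in items.columns:
        out["happiness"] = [_safe(score_cantril, v) for v in items["cantril"]]
    if "mcs" in items.columns:
        out["mcs"] = [_safe(check_mcs, v) for v in items["mcs"]]
    return out
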