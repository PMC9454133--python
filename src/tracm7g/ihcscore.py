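"""IHC H-score and high/low expression classification.

The H-score summarizes immunohistochemical staining: for each staining
intensity level i in {0, 1, 2, 3}, the percentage of positive cells at that
intensity is binned to a 0-4 score and the H-score is the sum of
i x bin(percent_i). Samples at or above the cutoff (default 6, the cohort
median) are classified as high expression.

Percent bins are left-closed: [0,5) -> 0, [5,25) -> 1, [25,50) -> 2,
[50,75) -> 3, [75,100] -> 4.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

INTENSITY_LEVELS = (0, 1, 2, 3)
DEFAULT_CUTOFF = 6


def percent_bin(p: float) -> int:
    """Bin a cell percentage to the 0-4 score (left-closed intervals)."""
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentage out of range [0, 100]: {p}")
    if p < 5:
        return 0
    if p < 25:
        return 1
    if p < 50:
        return 2
    if p <= 75:  # 75 exactly stays in the 50-75 bin; the top bin is > 75
        return 3
    return 4


def h_score(obs: Mapping[int, float]) -> int:
    """H-score = sum over intensities i of i x percent_bin(percent_i).

    ``obs`` maps intensity level (0-3) to the percentage of cells at that
    intensity; percentages must be non-negative and sum to at most 100
    (within a small tolerance).
    """
    total = 0.0
    for level, pct in obs.items():
        if level not in INTENSITY_LEVELS:
            raise ValueError(f"unknown intensity level {level!r}")
        if pct < 0:
            raise ValueError(f"negative percentage at intensity {level}")
        total += pct
    if total > 100.0 + 1e-6:
        raise ValueError(f"percentages sum to {total} > 100")
    return sum(level * percent_bin(float(obs.get(level, 0.0))) for level in INTENSITY_LEVELS)


def classify_expression(h: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """'high' when the H-score reaches the cutoff (inclusive), else 'low'."""
    if h < 0:
        raise ValueError("H-score must be non-negative")
    return "high" if h >= cutoff else "low"


def score_table(samples: pd.DataFrame, cutoff: int = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Score a table with columns pct0..pct3 (percent of cells per intensity)."""
    cols = [f"pct{i}" for i in INTENSITY_LEVELS]
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = samples.copy()
    out["h_score"] = [
        h_score({i: float(row[f"pct{i}"]) for i in INTENSITY_LEVELS})
        for _, row in samples.iterrows()
    ]
    out["expression"] = [classify_expression(h, cutoff) for h in out["h_score"]]
    return out
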