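"""Posture and Physical Activity Index: the cut-point comparator.

Each minute inside a sitting bout is classified by its vertical-axis count:
inactive sitting when VA < 75 cpm, active sitting otherwise (strict
less-than, so a minute exactly at the cut-point is active).  Daily summaries
divide each participant's total inactive/active sitting minutes across valid
bouts by their number of valid wear days.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import SittingBout

__all__ = ["DEFAULT_CUTPOINT", "classify_minutes", "summarize"]

DEFAULT_CUTPOINT = 75.0


def classify_minutes(va_cpm: Sequence[float], cutpoint: float = DEFAULT_CUTPOINT) -> np.ndarray:
    """True where a minute is inactive sitting (VA strictly below the cut-point)."""
    va = np.asarray(va_cpm, dtype=float)
    if va.size and (~np.isfinite(va) | (va < 0)).any():
        raise ValueError("VA counts must be finite and nonnegative")
    return va < cutpoint


def summarize(
    bouts: Sequence[SittingBout],
    valid_days: pd.DataFrame,
    cutpoint: float = DEFAULT_CUTPOINT,
) -> pd.DataFrame:
    """Average daily inactive/active sitting minutes per participant.

    Minutes are classified across all valid bouts and divided by the
    participant's number of valid wear days; participants with no valid day
    are absent.  Inactive + active equals total sitting minutes per valid
    day exactly (rescaled final-fraction minutes count as one minute and are
    classified on their rescaled cpm).
    """
    n_days = valid_days.groupby("participant")["day"].nunique()
    inact: dict = {}
    act: dict = {}
    for b in bouts:
        flags = classify_minutes(b.va_cpm, cutpoint)
        inact[b.participant] = inact.get(b.participant, 0) + int(flags.sum())
        act[b.participant] = act.get(b.participant, 0) + int((~flags).sum())
    rows = []
    for pid, nd in n_days.items():
        if nd == 0:
            continue
        rows.append(
            {
                "participant": pid,
                "inactive_min": inact.get(pid, 0) / nd,
                "active_min": act.get(pid, 0) / nd,
                "n_valid_days": int(nd),
            }
        )
    return pd.DataFrame(rows, columns=["participant", "inactive_min", "active_min", "n_valid_days"])
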