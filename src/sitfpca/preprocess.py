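"""Raw device streams -> valid concurrent waking-wear sitting bouts.

The pipeline mirrors how posture events from a thigh sensor and 1-second
tri-axial counts from a waist accelerometer are combined in sedentary
behavior studies: waking windows are the complement of logged in-bed time,
additional non-wear is detected from runs of zero counts, sitting events are
intersected with waking wear, and per-second counts inside each resulting
bout are aggregated to counts per minute (cpm) with the vector magnitude
VM = sqrt(VA^2 + HA^2 + PPA^2) computed from the minute totals.  A trailing
bout fraction shorter than 30 s is dropped; a fraction of f >= 30 s is
rescaled by 60/f to approximate a full minute.

Days are valid when both devices were worn concurrently and total daily
sitting time is between 5 and 15 hours; bouts are valid when they are at
most 60 minutes long and fall on a valid day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SittingBout",
    "derive_waking_windows",
    "detect_nonwear",
    "extract_sitting_bouts",
    "summarize_days",
    "filter_valid",
    "daily_activity_summaries",
    "bouts_frame",
    "FRACTION_KEEP_S",
]

FRACTION_KEEP_S = 30  # trailing fractions of >= 30 s are rescaled, shorter dropped

Interval = tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class SittingBout:
    """One uninterrupted concurrent waking-wear sitting interval.

    ``va_cpm``/``vm_cpm`` hold one entry per retained minute (the last one
    possibly rescaled from a >= 30 s fraction); ``raw_length_s`` is the
    unrounded bout duration in seconds.
    """

    participant: object
    day: object
    start: pd.Timestamp
    raw_length_s: int
    va_cpm: np.ndarray
    vm_cpm: np.ndarray

    def __post_init__(self) -> None:
        self.va_cpm = np.asarray(self.va_cpm, dtype=float)
        self.vm_cpm = np.asarray(self.vm_cpm, dtype=float)
        if self.n_minutes < 1:
            raise ValueError("a bout must retain at least one minute")
        if self.va_cpm.shape != self.vm_cpm.shape:
            raise ValueError("va_cpm and vm_cpm must align")
        if (self.vm_cpm + 1e-9 < self.va_cpm).any():
            raise ValueError("VM must dominate every axis component")
        expected = self.raw_length_s // 60 + (
            1 if self.raw_length_s % 60 >= FRACTION_KEEP_S else 0
        )
        if self.n_minutes != expected:
            raise ValueError(
                f"n_minutes {self.n_minutes} inconsistent with raw length "
                f"{self.raw_length_s} s (expected {expected})"
            )

    @property
    def n_minutes(self) -> int:
        return self.va_cpm.size


# ---------------------------------------------------------------------------
# interval helpers (timezone-naive, left-closed second grid)
# ---------------------------------------------------------------------------


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((s, e))
    return sorted(out)


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out = list(a)
    for s2, e2 in b:
        nxt = []
        for s1, e1 in out:
            if e2 <= s1 or s2 >= e1:
                nxt.append((s1, e1))
                continue
            if s1 < s2:
                nxt.append((s1, s2))
            if e2 < e1:
                nxt.append((e2, e1))
        out = nxt
    return sorted(out)


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals, merging touching/overlapping ones."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def derive_waking_windows(sleep: pd.DataFrame) -> pd.DataFrame:
    """Per-day waking windows as the complement of logged in-bed time.

    Each sleep record is an overnight in-bed interval (``bed_start`` <
    ``bed_end``, usually crossing midnight).  Day d's waking window runs from
    the end of the night finishing on d to the start of the night beginning
    on d; days missing either bound, or fully covered by an in-bed interval,
    are dropped rather than imputed.
    """
    df = sleep.copy()
    df["bed_start"] = pd.to_datetime(df["bed_start"])
    df["bed_end"] = pd.to_datetime(df["bed_end"])
    if (df["bed_start"] >= df["bed_end"]).any():
        bad = df[df["bed_start"] >= df["bed_end"]].iloc[0]
        raise ValueError(
            f"in-bed interval with bed_start >= bed_end for participant "
            f"{bad['participant']} on {bad['date']}"
        )
    rows = []
    for pid, grp in df.groupby("participant", sort=True):
        grp = grp.sort_values("bed_start")
        prev_end = None
        for _, rec in grp.iterrows():
            if prev_end is not None and rec["bed_start"] < prev_end:
                raise ValueError(
                    f"overlapping in-bed intervals for participant {pid} "
                    f"around {rec['date']}"
                )
            prev_end = rec["bed_end"]
        ends_on = {rec["bed_end"].normalize(): rec["bed_end"] for _, rec in grp.iterrows()}
        starts_on = {
            rec["bed_start"].normalize(): rec["bed_start"] for _, rec in grp.iterrows()
        }
        for day in sorted(set(ends_on) & set(starts_on)):
            w0, w1 = ends_on[day], starts_on[day]
            if w0 < w1:
                rows.append(
                    {"participant": pid, "date": day.date(), "wake_start": w0, "wake_end": w1}
                )
    return pd.DataFrame(rows, columns=["participant", "date", "wake_start", "wake_end"])


def detect_nonwear(
    counts: pd.DataFrame, window_minutes: int = 90, tolerance_minutes: int = 2
) -> pd.DataFrame:
    """Non-wear intervals from long runs of zero counts.

    Minute-level vector-magnitude totals are scanned for maximal intervals of
    at least ``window_minutes`` that start and end with zero minutes and
    contain at most ``tolerance_minutes`` nonzero minutes in their interior —
    a parameterized consecutive-zero detector whose defaults mirror the
    headline parameters of the detection rule used with waist accelerometers
    (90-minute window, 2-minute spike tolerance).
    """
    rows = []
    if len(counts) == 0:
        return pd.DataFrame(columns=["participant", "start", "end"])
    df = counts.copy()
    df["minute"] = pd.to_datetime(df["timestamp"]).dt.floor("min")
    for pid, grp in df.groupby("participant", sort=True):
        per_min = grp.groupby("minute")[["va", "ha", "ppa"]].sum()
        minutes = per_min.index.to_numpy()
        zero = (per_min.to_numpy() == 0).all(axis=1)
        # zero-runs as (start_idx, end_idx) half-open
        runs = []
        i = 0
        while i < zero.size:
            if zero[i]:
                j = i
                while j < zero.size and zero[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        taken_until = -1
        for ri, (s, e) in enumerate(runs):
            if s <= taken_until:
                continue
            end, nonzero_inside = e, 0
            for s2, e2 in runs[ri + 1 :]:
                gap = s2 - end
                if nonzero_inside + gap > tolerance_minutes:
                    break
                nonzero_inside += gap
                end = e2
            if end - s >= window_minutes:
                rows.append(
                    {
                        "participant": pid,
                        "start": pd.Timestamp(minutes[s]),
                        "end": pd.Timestamp(minutes[end - 1]) + pd.Timedelta(minutes=1),
                    }
                )
                taken_until = end - 1
    return pd.DataFrame(rows, columns=["participant", "start", "end"])


def _aggregate_minutes(axes: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-second (n x 3) axis counts -> (va_cpm, vm_cpm) with the 30 s rule."""
    n = axes.shape[0]
    full, frac = divmod(n, 60)
    mins = []
    for k in range(full):
        mins.append(axes[60 * k : 60 * (k + 1)].sum(axis=0))
    if frac >= FRACTION_KEEP_S:
        mins.append(axes[60 * full :].sum(axis=0) * (60.0 / frac))
    if not mins:
        return None
    per_min = np.vstack(mins)
    va = per_min[:, 0]
    vm = np.sqrt((per_min**2).sum(axis=1))
    return va, vm


def extract_sitting_bouts(
    events: pd.DataFrame,
    waking_windows: pd.DataFrame,
    nonwear: pd.DataFrame,
    counts: pd.DataFrame,
) -> list[SittingBout]:
    """Concurrent waking-wear sitting bouts with minute-level VA and VM.

    Sitting events are merged into maximal sitting runs, intersected with the
    waking windows, and split by detected non-wear; each remaining interval
    becomes one bout whose per-second counts are aggregated to cpm.  Bouts
    whose count coverage has gaps are dropped with a warning; bouts retaining
    no minute (< 30 s) are discarded silently.
    """
    events = events.copy()
    events["start"] = pd.to_datetime(events["start"])
    counts = counts.copy()
    counts["timestamp"] = pd.to_datetime(counts["timestamp"])
    bouts: list[SittingBout] = []
    for pid, ev in events.groupby("participant", sort=True):
        sit = _merge(
            [
                (r["start"], r["start"] + pd.Timedelta(seconds=int(r["duration_s"])))
                for _, r in ev[ev["posture"] == "sitting"].iterrows()
            ]
        )
        nw = [
            (pd.Timestamp(r["start"]), pd.Timestamp(r["end"]))
            for _, r in nonwear[nonwear["participant"] == pid].iterrows()
        ]
        cnt = counts[counts["participant"] == pid].sort_values("timestamp")
        sec = cnt["timestamp"].astype("int64").to_numpy() // 1_000_000_000
        axes_all = cnt[["va", "ha", "ppa"]].to_numpy(dtype=float)
        windows = waking_windows[waking_windows["participant"] == pid]
        for _, w in windows.iterrows():
            day_intervals = _subtract(
                _intersect(sit, [(w["wake_start"], w["wake_end"])]), nw
            )
            for s0, s1 in day_intervals:
                dur = int((s1 - s0).total_seconds())
                if dur < FRACTION_KEEP_S:
                    continue
                t0 = int(s0.value // 1_000_000_000)
                i0 = np.searchsorted(sec, t0)
                i1 = i0 + dur
                if i1 > sec.size or not np.array_equal(
                    sec[i0:i1], np.arange(t0, t0 + dur)
                ):
                    warnings.warn(
                        f"dropping bout at {s0} for participant {pid}: "
                        "count coverage incomplete",
                        stacklevel=2,
                    )
                    continue
                agg = _aggregate_minutes(axes_all[i0:i1])
                if agg is None:
                    continue
                va, vm = agg
                bouts.append(
                    SittingBout(
                        participant=pid,
                        day=w["date"],
                        start=s0,
                        raw_length_s=dur,
                        va_cpm=va,
                        vm_cpm=vm,
                    )
                )
    return bouts


def summarize_days(
    events: pd.DataFrame,
    waking_windows: pd.DataFrame,
    bouts: Sequence[SittingBout],
    min_sit_min: float = 300.0,
    max_sit_min: float = 900.0,
) -> pd.DataFrame:
    """Per participant-day totals and the valid-day flag.

    Sitting time is the total raw length of concurrent sitting bouts;
    standing and stepping time come from the posture events clipped to the
    waking window.  A day is valid when it has concurrent wear (it appears
    here with any sitting bout at all) and total sitting within
    [``min_sit_min``, ``max_sit_min``] minutes.
    """
    events = events.copy()
    events["start"] = pd.to_datetime(events["start"])
    sit_s: dict[tuple, float] = {}
    for b in bouts:
        sit_s[(b.participant, b.day)] = sit_s.get((b.participant, b.day), 0.0) + b.raw_length_s
    rows = []
    for _, w in waking_windows.iterrows():
        pid, day = w["participant"], w["date"]
        ev = events[events["participant"] == pid]
        upright_min = {}
        for posture in ("standing", "stepping"):
            ivs = [
                (r["start"], r["start"] + pd.Timedelta(seconds=int(r["duration_s"])))
                for _, r in ev[ev["posture"] == posture].iterrows()
            ]
            clipped = _intersect(ivs, [(w["wake_start"], w["wake_end"])])
            upright_min[posture] = sum((e - s).total_seconds() for s, e in clipped) / 60.0
        total_sit = sit_s.get((pid, day), 0.0) / 60.0
        rows.append(
            {
                "participant": pid,
                "day": day,
                "total_sitting_min": total_sit,
                "standing_min": upright_min["standing"],
                "stepping_min": upright_min["stepping"],
                "valid_day": bool(
                    total_sit > 0 and min_sit_min <= total_sit <= max_sit_min
                ),
            }
        )
    return pd.DataFrame(rows)


def filter_valid(
    bouts: Sequence[SittingBout],
    summaries: pd.DataFrame,
    max_bout_min: int = 60,
) -> tuple[list[SittingBout], pd.DataFrame, dict]:
    """Valid bouts (on valid days, <= ``max_bout_min`` minutes) + exclusions.

    Valid-day status is evaluated on total daily sitting before the
    bout-length filter; participants with no valid day are removed entirely.
    """
    valid_days = {
        (r["participant"], r["day"]) for _, r in summaries.iterrows() if r["valid_day"]
    }
    on_valid = [b for b in bouts if (b.participant, b.day) in valid_days]
    kept = [b for b in on_valid if b.n_minutes <= max_bout_min]
    participants = {b.participant for b in kept}
    final = [b for b in kept if b.participant in participants]
    day_table = summaries[summaries["valid_day"]].reset_index(drop=True)
    day_table = day_table[day_table["participant"].isin(participants)].reset_index(drop=True)
    report = {
        "n_bouts_in": len(bouts),
        "n_bouts_on_invalid_days": len(bouts) - len(on_valid),
        "n_bouts_overlong": len(on_valid) - len(kept),
        "n_bouts_valid": len(final),
        "n_days_in": int(len(summaries)),
        "n_days_valid": int(len(day_table)),
        "n_participants_in": int(summaries["participant"].nunique()) if len(summaries) else 0,
        "n_participants_valid": len(participants),
    }
    return final, day_table, report


def daily_activity_summaries(
    summaries: pd.DataFrame, valid_days: pd.DataFrame
) -> pd.DataFrame:
    """Average daily non-sitting (standing + stepping) time over valid days."""
    merged = summaries.merge(
        valid_days[["participant", "day"]], on=["participant", "day"], how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=["participant", "n_valid_days", "nonsitting_min"])
    merged["nonsitting"] = merged["standing_min"] + merged["stepping_min"]
    out = (
        merged.groupby("participant")
        .agg(n_valid_days=("day", "nunique"), nonsitting_min=("nonsitting", "mean"))
        .reset_index()
    )
    return out


def bouts_frame(bouts: Sequence[SittingBout]) -> pd.DataFrame:
    """Long bout-minute table (one row per retained minute) for registration."""
    rows = []
    for i, b in enumerate(bouts):
        for m in range(b.n_minutes):
            rows.append(
                {
                    "participant": b.participant,
                    "day": b.day,
                    "bout_id": i,
                    "bout_length": b.n_minutes,
                    "minute_index": m + 1,
                    "va_cpm": b.va_cpm[m],
                    "vm_cpm": b.vm_cpm[m],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "day",
            "bout_id",
            "bout_length",
            "minute_index",
            "va_cpm",
            "vm_cpm",
        ],
    )
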