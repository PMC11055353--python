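"""Registration of sitting bouts onto the common ordered-bout index domain.

A participant-day's sitting bouts are ordered by their length b = 1..B minutes
and concatenated, so that the b-minute bout occupies the b consecutive grid
indices following the bouts of length 1..b-1.  The resulting index domain has
T(B) = B(B+1)/2 points (1830 for the default B = 60) and is shared by every
participant-day: minute m of a b-minute bout always lands at the same index
t = b(b-1)/2 + m, which makes counts within equal-length bouts directly
comparable across days and participants.  Bout lengths a participant-day did
not register leave their whole block of b indices missing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "triangular_length",
    "bout_index",
    "inverse_bout_index",
    "bout_block",
    "RegisteredDay",
    "register_day",
    "register_days",
    "MissingnessSummary",
    "build_matrix",
    "write_matrix",
]


def triangular_length(B: int) -> int:
    """Number of grid points T(B) = B(B+1)/2 of the ordered-bout domain."""
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    return B * (B + 1) // 2


def bout_index(b: int, m: int, B: int = 60) -> int:
    """Map minute m of the b-minute bout to the 1-based grid index t.

    t = b(b-1)/2 + m, so the length-b block occupies indices
    b(b-1)/2 + 1 .. b(b+1)/2.
    """
    if not 1 <= b <= B:
        raise ValueError(f"bout length b={b} outside 1..{B}")
    if not 1 <= m <= b:
        raise ValueError(f"minute m={m} outside 1..{b}")
    return b * (b - 1) // 2 + m


def inverse_bout_index(t: int, B: int = 60) -> tuple[int, int]:
    """Invert :func:`bout_index`: grid index t -> (bout length b, minute m)."""
    T = triangular_length(B)
    if not 1 <= t <= T:
        raise ValueError(f"index t={t} outside 1..{T}")
    b = math.ceil((math.sqrt(8 * t + 1) - 1) / 2)
    m = t - b * (b - 1) // 2
    return b, m


def bout_block(b: int, B: int = 60) -> slice:
    """0-based slice of the length-b block within a T(B)-vector."""
    start = bout_index(b, 1, B) - 1
    return slice(start, start + b)


@dataclass
class RegisteredDay:
    """One participant-day curve X_ij(t) on the ordered-bout domain.

    ``values`` holds the minute-level VM counts (cpm) at observed indices and
    NaN elsewhere; ``mask`` is True where observed.  Each bout block is either
    fully observed or fully missing.
    """

    participant: object
    day: object
    values: np.ndarray
    mask: np.ndarray
    B: int = 60

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        T = triangular_length(self.B)
        if self.values.shape != (T,) or self.mask.shape != (T,):
            raise ValueError(
                f"values/mask must have length T(B)={T}, got "
                f"{self.values.shape}/{self.mask.shape}"
            )
        obs = self.values[self.mask]
        if obs.size and (~np.isfinite(obs) | (obs < 0)).any():
            raise ValueError("observed values must be finite and >= 0")
        for b in range(1, self.B + 1):
            block = self.mask[bout_block(b, self.B)]
            if block.any() and not block.all():
                raise ValueError(f"bout block b={b} is partially observed")

    @property
    def registered_lengths(self) -> np.ndarray:
        """Sorted bout lengths present on this participant-day."""
        return np.array(
            [b for b in range(1, self.B + 1) if self.mask[bout_block(b, self.B)].all()]
        )


def register_day(
    bouts: Iterable[Sequence[float]],
    B: int = 60,
    participant: object = None,
    day: object = None,
) -> RegisteredDay:
    """Place one participant-day's bouts on the ordered-bout grid.

    ``bouts`` is an iterable of per-minute VM vectors (one entry per bout, the
    bout length being the vector length).  Multiple bouts of the same length
    are averaged element-wise; lengths that never occur leave their block
    missing.  The result does not depend on the order of ``bouts``.
    """
    T = triangular_length(B)
    sums = np.zeros(T)
    counts = np.zeros(B, dtype=int)
    for vm in bouts:
        vm = np.asarray(vm, dtype=float)
        if vm.ndim != 1 or vm.size < 1:
            raise ValueError("each bout must be a non-empty 1-D minute vector")
        b = vm.size
        if b > B:
            raise ValueError(f"bout length {b} exceeds B={B}; filter upstream")
        sums[bout_block(b, B)] += vm
        counts[b - 1] += 1
    values = np.full(T, np.nan)
    mask = np.zeros(T, dtype=bool)
    for b in range(1, B + 1):
        if counts[b - 1]:
            blk = bout_block(b, B)
            values[blk] = sums[blk] / counts[b - 1]
            mask[blk] = True
    return RegisteredDay(participant, day, values, mask, B)


def register_days(bout_minutes: pd.DataFrame, B: int = 60) -> list[RegisteredDay]:
    """Register every participant-day of a bout-minute table.

    ``bout_minutes`` has one row per bout-minute with columns ``participant``,
    ``day``, ``bout_id``, ``minute_index`` (1-based within the bout) and
    ``vm_cpm`` — the long format written by the preprocessing stage.
    """
    required = {"participant", "day", "bout_id", "minute_index", "vm_cpm"}
    missing = required - set(bout_minutes.columns)
    if missing:
        raise ValueError(f"bout_minutes lacks columns {sorted(missing)}")
    out: list[RegisteredDay] = []
    for (pid, day), grp in bout_minutes.groupby(["participant", "day"], sort=True):
        vectors = [
            g.sort_values("minute_index")["vm_cpm"].to_numpy()
            for _, g in grp.groupby("bout_id", sort=True)
        ]
        out.append(register_day(vectors, B=B, participant=pid, day=day))
    return out


@dataclass
class MissingnessSummary:
    """Bookkeeping of unregistered bouts in a registered curve matrix.

    ``m_b[b-1]`` counts participant-days (rows) whose length-b block is
    missing; the overall cell-missing rate is sum_b m_b * b / (n_rows * T(B)).
    """

    m_b: np.ndarray
    n_rows: int
    B: int
    T: int = field(init=False)

    def __post_init__(self) -> None:
        self.m_b = np.asarray(self.m_b, dtype=int)
        self.T = triangular_length(self.B)
        if self.m_b.shape != (self.B,):
            raise ValueError("m_b must have one entry per bout length")

    @property
    def unregistered_rate(self) -> np.ndarray:
        """Per-length fraction of rows without a b-minute bout."""
        return self.m_b / self.n_rows

    @property
    def mean_unregistered_rate(self) -> float:
        """Average of the per-length unregistered rates over b = 1..B."""
        return float(self.unregistered_rate.mean())

    @property
    def overall_missing_rate(self) -> float:
        """Fraction of missing cells in the n_rows x T matrix."""
        b = np.arange(1, self.B + 1)
        return float((self.m_b * b).sum() / (self.n_rows * self.T))

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "T": self.T,
            "n_rows": self.n_rows,
            "m_b": self.m_b.tolist(),
            "unregistered_rate": self.unregistered_rate.tolist(),
            "mean_unregistered_rate": self.mean_unregistered_rate,
            "overall_missing_rate": self.overall_missing_rate,
        }


def summarize_mask(mask: np.ndarray, B: int) -> MissingnessSummary:
    """Missingness bookkeeping for a (rows x T(B)) observation mask."""
    mask = np.asarray(mask, dtype=bool)
    n_rows = mask.shape[0]
    m_b = np.empty(B, dtype=int)
    for b in range(1, B + 1):
        blk = mask[:, bout_block(b, B)]
        if not np.array_equal(blk.all(axis=1), blk.any(axis=1)):
            raise ValueError(f"bout block b={b} partially observed in some row")
        m_b[b - 1] = int((~blk.all(axis=1)).sum())
    return MissingnessSummary(m_b, n_rows, B)


def build_matrix(
    days: Sequence[RegisteredDay],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, MissingnessSummary]:
    """Stack registered days into the curve matrix consumed by the MFPCA fit.

    Returns ``(matrix, mask, index, summary)`` with rows ordered by
    (participant, day).  All-missing rows (days that registered no bout at
    all) are excluded before stacking; duplicate (participant, day) pairs are
    an error.
    """
    if not days:
        raise ValueError("no registered days supplied")
    B = days[0].B
    if any(d.B != B for d in days):
        raise ValueError("all rows must share the same B")
    kept = [d for d in days if d.mask.any()]
    order = sorted(range(len(kept)), key=lambda i: (repr(kept[i].participant), repr(kept[i].day)))
    kept = [kept[i] for i in order]
    index = pd.DataFrame(
        {"participant": [d.participant for d in kept], "day": [d.day for d in kept]}
    )
    if index.duplicated().any():
        dupes = index[index.duplicated()].to_records(index=False).tolist()
        raise ValueError(f"duplicate (participant, day) rows: {dupes}")
    matrix = np.vstack([d.values for d in kept])
    mask = np.vstack([d.mask for d in kept])
    return matrix, mask, index, summarize_mask(mask, B)


def write_matrix(
    path_prefix: str,
    matrix: np.ndarray,
    mask: np.ndarray,
    index: pd.DataFrame,
    summary: MissingnessSummary,
) -> None:
    """Write the curve matrix, mask and missingness summary to disk.

    Emits ``<prefix>_curves.csv`` (wide, columns t1..tT with the row index
    columns first), ``<prefix>_mask.csv`` and ``<prefix>_missingness.json``.
    """
    T = matrix.shape[1]
    cols = [f"t{t}" for t in range(1, T + 1)]
    for arr, name in ((matrix, "curves"), (mask.astype(int), "mask")):
        df = pd.concat(
            [index.reset_index(drop=True), pd.DataFrame(arr, columns=cols)], axis=1
        )
        df.to_csv(f"{path_prefix}_{name}.csv", index=False)
    with open(f"{path_prefix}_missingness.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
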