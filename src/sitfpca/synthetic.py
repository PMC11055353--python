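"""Synthetic data with known ground truth for every pipeline stage.

Two levels of generation are provided:

* model-level: curves drawn from the two-level functional PCA model
  X_ij(t) = mu(t) + eta_j(t) + sum_k xi_ik phi1_k(t) + sum_l zeta_ijl phi2_l(t) + eps,
  with the truth (mean, eigenfunctions, eigenvalues, noise) held in a
  :class:`CurveTruth`, plus a block-missingness operator that removes whole
  bout blocks the way unregistered bout lengths do in real registered data;

* device-level: 1-second tri-axial count streams, posture event tables and
  sleep logs emulating a waist accelerometer worn together with a thigh
  posture sensor, with the scripted or simulated sitting schedule returned as
  ground truth for oracle tests of the preprocessing stage.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta_dist

from .registration import bout_block, triangular_length

__all__ = [
    "make_fourier_eigenbasis",
    "CurveTruth",
    "SimulatedDataset",
    "simulate_curves",
    "reference_curve_truth",
    "simple_curve_truth",
    "reference_missingness_curve",
    "missingness_curve_for_overall",
    "expected_missing_rates",
    "apply_bout_missingness",
    "MaskingReport",
    "BehaviorParams",
    "SegmentSpec",
    "DeviceStreams",
    "simulate_device_streams",
    "simulate_covariates",
    "simulate_outcomes",
    "write_streams",
]

_ORTHO_TOL = 1e-8


def make_fourier_eigenbasis(K: int, T: int) -> np.ndarray:
    """K orthonormal smooth vectors on the grid 1..T (rows of the result).

    Alternating sine/cosine Fourier shapes, re-orthonormalized with a QR pass
    so the discrete inner product (unit grid spacing) satisfies
    sum_t phi_k(t) phi_m(t) = delta_km to machine precision.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if T < 2 * K:
        raise ValueError(f"basis under-resolved: need T >= 2K, got K={K}, T={T}")
    t = np.arange(1, T + 1)
    cols = []
    for k in range(1, K + 1):
        freq = (k + 1) // 2
        phase = 2 * np.pi * freq * t / T
        cols.append(np.sin(phase) if k % 2 else np.cos(phase))
    q, _ = np.linalg.qr(np.column_stack(cols))
    basis = q.T
    # fix sign: largest-|value| entry positive
    for row in basis:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return basis


def _check_orthonormal(rows: np.ndarray, label: str) -> None:
    gram = rows @ rows.T
    if not np.allclose(gram, np.eye(rows.shape[0]), atol=_ORTHO_TOL):
        raise ValueError(f"{label} eigenfunctions are not orthonormal (tol {_ORTHO_TOL})")


@dataclass
class CurveTruth:
    """Ground-truth ingredients of the two-level functional model.

    ``mean_fn`` is mu(t); ``day_shifts`` stacks eta_j(t) for day index
    j = 1..d_max; eigenfunction matrices hold one orthonormal row per
    component with strictly decreasing positive eigenvalues; ``noise_sd`` is
    the measurement-error standard deviation sigma.
    """

    T: int
    mean_fn: np.ndarray
    day_shifts: np.ndarray
    level1_eigenfunctions: np.ndarray
    level1_eigenvalues: np.ndarray
    level2_eigenfunctions: np.ndarray
    level2_eigenvalues: np.ndarray
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_fn = np.asarray(self.mean_fn, dtype=float)
        self.day_shifts = np.atleast_2d(np.asarray(self.day_shifts, dtype=float))
        self.level1_eigenfunctions = np.atleast_2d(
            np.asarray(self.level1_eigenfunctions, dtype=float)
        )
        self.level2_eigenfunctions = np.atleast_2d(
            np.asarray(self.level2_eigenfunctions, dtype=float)
        )
        self.level1_eigenvalues = np.asarray(self.level1_eigenvalues, dtype=float)
        self.level2_eigenvalues = np.asarray(self.level2_eigenvalues, dtype=float)
        arrays = (
            self.mean_fn,
            self.day_shifts,
            self.level1_eigenfunctions,
            self.level1_eigenvalues,
            self.level2_eigenfunctions,
            self.level2_eigenvalues,
        )
        if any(not np.isfinite(a).all() for a in arrays) or not np.isfinite(self.noise_sd):
            raise ValueError("truth fields must be finite")
        if self.mean_fn.shape != (self.T,):
            raise ValueError("mean_fn must have length T")
        if self.day_shifts.shape[1] != self.T:
            raise ValueError("day_shifts must have T columns")
        for fns, vals, label in (
            (self.level1_eigenfunctions, self.level1_eigenvalues, "level-1"),
            (self.level2_eigenfunctions, self.level2_eigenvalues, "level-2"),
        ):
            if fns.shape != (vals.size, self.T):
                raise ValueError(f"{label} eigenfunction/eigenvalue shapes disagree")
            _check_orthonormal(fns, label)
            if (vals <= 0).any():
                raise ValueError(f"{label} eigenvalues must be positive")
            if vals.size > 1 and not (np.diff(vals) < 0).all():
                raise ValueError(f"{label} eigenvalues must be strictly decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def K1(self) -> int:
        return self.level1_eigenvalues.size

    @property
    def K2(self) -> int:
        return self.level2_eigenvalues.size

    @property
    def d_max(self) -> int:
        return self.day_shifts.shape[0]


@dataclass
class SimulatedDataset:
    """Curves drawn from a :class:`CurveTruth` together with their scores.

    Rows are participant-days; ``index`` maps each row to (participant, day);
    ``mask`` flags observed cells.  ``truth_scores_level1`` has one row per
    participant (xi_ik); ``truth_scores_level2`` one row per participant-day
    (zeta_ijl).
    """

    curves: np.ndarray
    mask: np.ndarray
    index: pd.DataFrame
    truth_scores_level1: np.ndarray
    truth_scores_level2: np.ndarray
    truth: CurveTruth

    @property
    def subjects(self) -> np.ndarray:
        return self.index["participant"].to_numpy()

    @property
    def days(self) -> np.ndarray:
        return self.index["day"].to_numpy()


def simulate_curves(
    truth: CurveTruth,
    n: int,
    days_per_subject: int | Sequence[int],
    seed: int | None = None,
) -> SimulatedDataset:
    """Draw fully observed curves from the two-level model.

    Scores are xi_ik ~ N(0, lambda1_k) per participant and
    zeta_ijl ~ N(0, lambda2_l) per participant-day; noise is iid
    N(0, sigma^2) per grid point.  ``days_per_subject`` is a scalar or a
    length-n sequence; day j uses the truth's day shift eta_j.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if np.isscalar(days_per_subject):
        days = np.full(n, int(days_per_subject))
    else:
        days = np.asarray(days_per_subject, dtype=int)
        if days.shape != (n,):
            raise ValueError("days_per_subject must be a scalar or length-n sequence")
    if (days < 1).any():
        raise ValueError("each subject needs at least one day")
    if days.max() > truth.d_max:
        raise ValueError(
            f"requested {days.max()} days but truth has day shifts for {truth.d_max}"
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_rows = int(days.sum())
    xi = rng.normal(size=(n, truth.K1)) * np.sqrt(truth.level1_eigenvalues)
    zeta = rng.normal(size=(n_rows, truth.K2)) * np.sqrt(truth.level2_eigenvalues)
    eps = rng.normal(scale=truth.noise_sd, size=(n_rows, truth.T)) if truth.noise_sd else 0.0

    subj = np.repeat(np.arange(1, n + 1), days)
    day = np.concatenate([np.arange(1, d + 1) for d in days])
    curves = (
        truth.mean_fn
        + truth.day_shifts[day - 1]
        + xi[subj - 1] @ truth.level1_eigenfunctions
        + zeta @ truth.level2_eigenfunctions
        + eps
    )
    index = pd.DataFrame({"participant": subj, "day": day})
    return SimulatedDataset(
        curves=curves,
        mask=np.ones_like(curves, dtype=bool),
        index=index,
        truth_scores_level1=xi,
        truth_scores_level2=zeta,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# reference truths
# ---------------------------------------------------------------------------


def reference_curve_truth(
    B: int = 15,
    mean_level: float = 200.0,
    noise_sd: float = 0.5,
    d_max: int = 9,
    seed: int = 0,
) -> CurveTruth:
    """Study-conditions truth: 2 subject-level + 6 day-level components.

    The eigenvalue spectrum is chosen so the pooled 90%-of-total-variance rule
    needs all eight components (the smallest carries just under 11% of the
    total) and so the subject level carries 28% of the variance — mirroring a
    two-plus-six component structure with roughly a 30/70 between/within
    split.  Eigenfunctions are disjoint Fourier shapes (components 1–2 at the
    subject level, 3–8 at the day level), hence orthonormal within and across
    levels.
    """
    T = triangular_length(B)
    basis = make_fourier_eigenbasis(8, T)
    t = np.arange(1, T + 1)
    mean_fn = mean_level * np.exp(-3.0 * t / T) + 20.0
    return CurveTruth(
        T=T,
        mean_fn=mean_fn,
        day_shifts=np.zeros((d_max, T)),
        level1_eigenfunctions=basis[:2],
        level1_eigenvalues=np.array([3.3, 2.5]),
        level2_eigenfunctions=basis[2:8],
        level2_eigenvalues=np.array([2.8, 2.6, 2.45, 2.3, 2.25, 2.2]),
        noise_sd=noise_sd,
        seed=seed,
    )


def simple_curve_truth(
    B: int = 15,
    lambda1: Sequence[float] = (4.0, 1.5),
    lambda2: Sequence[float] = (3.0, 1.2, 0.5),
    noise_sd: float = 0.5,
    d_max: int = 9,
    seed: int = 0,
) -> CurveTruth:
    """Well-separated spectra for eigenfunction-recovery experiments."""
    T = triangular_length(B)
    K1, K2 = len(lambda1), len(lambda2)
    basis = make_fourier_eigenbasis(K1 + K2, T)
    return CurveTruth(
        T=T,
        mean_fn=np.zeros(T),
        day_shifts=np.zeros((d_max, T)),
        level1_eigenfunctions=basis[:K1],
        level1_eigenvalues=np.asarray(lambda1, dtype=float),
        level2_eigenfunctions=basis[K1:],
        level2_eigenvalues=np.asarray(lambda2, dtype=float),
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# block missingness
# ---------------------------------------------------------------------------

# Shape of the bout-length missingness profile: probability that a
# participant-day lacks a b-minute bout, rising from 0.8% at b=1 to 93% at
# b=60 along a beta-CDF curve whose shape parameters were solved so that the
# mean unregistered rate over b is 71% and the length-weighted overall
# cell-missing rate is 83% — the four rates observed in a reference cohort of
# postmenopausal women wearing both devices for a week.
_REF_P_FIRST = 0.008
_REF_P_LAST = 0.93
_REF_ALPHA = 0.5836423750003258
_REF_BETA = 1.9132470671766015


def reference_missingness_curve(
    B: int = 60,
    p_first: float = _REF_P_FIRST,
    p_last: float = _REF_P_LAST,
    alpha: float = _REF_ALPHA,
    beta: float = _REF_BETA,
) -> Callable[[np.ndarray], np.ndarray]:
    """Cohort-calibrated probability that a b-minute bout is unregistered.

    Returns a vectorized callable p(b) for b in 1..B.  For B other than 60
    the same shape is rescaled onto the shorter length range, keeping the
    endpoint rates.
    """

    def prob(b):
        u = (np.asarray(b, dtype=float) - 1.0) / (B - 1.0)
        return p_first + (p_last - p_first) * _beta_dist.cdf(u, alpha, beta)

    return prob


def expected_missing_rates(
    prob: Callable[[np.ndarray], np.ndarray], B: int
) -> dict[str, float]:
    """Mean unregistered rate and length-weighted overall cell-missing rate."""
    b = np.arange(1, B + 1)
    p = np.asarray(prob(b), dtype=float)
    return {
        "mean_unregistered_rate": float(p.mean()),
        "overall_missing_rate": float((b * p).sum() / triangular_length(B)),
    }


def missingness_curve_for_overall(
    B: int,
    overall: float,
    base: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Tilt a base curve on the logit scale to hit a target overall rate.

    Solves for a scalar shift d so that the length-weighted overall
    cell-missing rate of expit(logit(p(b)) + d) equals ``overall``.
    """
    from scipy.optimize import brentq
    from scipy.special import expit, logit

    if not 0 < overall < 1:
        raise ValueError("overall must be in (0, 1)")
    base = base or reference_missingness_curve(B)
    b = np.arange(1, B + 1)
    lo = logit(np.clip(np.asarray(base(b), dtype=float), 1e-12, 1 - 1e-12))
    T = triangular_length(B)

    def gap(d):
        return (b * expit(lo + d)).sum() / T - overall

    d = brentq(gap, -30.0, 30.0)
    return lambda bb: expit(
        logit(np.clip(np.asarray(base(bb), dtype=float), 1e-12, 1 - 1e-12)) + d
    )


@dataclass
class MaskingReport:
    """Realized missingness produced by :func:`apply_bout_missingness`."""

    target_prob: np.ndarray
    realized_prob: np.ndarray
    overall_missing_rate: float
    n_rows_in: int
    n_rows_dropped: int


def apply_bout_missingness(
    data: SimulatedDataset,
    unregistered_prob: Callable[[np.ndarray], np.ndarray] | Sequence[float] | float,
    seed: int,
) -> tuple[SimulatedDataset, MaskingReport]:
    """Blank whole bout blocks at random, bout length by bout length.

    For every row and every bout length b, the length-b block is set missing
    with probability ``unregistered_prob(b)`` — blocks are removed atomically,
    never partially, emulating a participant-day that registered no b-minute
    bout.  Rows left with no observed cell are dropped (their level-2 scores
    and index rows with them).  The grid length must be triangular so the
    indices partition into bout blocks.
    """
    T = data.curves.shape[1]
    B = int(round((np.sqrt(8 * T + 1) - 1) / 2))
    if triangular_length(B) != T:
        raise ValueError(f"grid length {T} is not triangular: cannot partition into bouts")
    b = np.arange(1, B + 1)
    if callable(unregistered_prob):
        p = np.asarray(unregistered_prob(b), dtype=float)
    else:
        p = np.broadcast_to(np.asarray(unregistered_prob, dtype=float), (B,)).copy()
    if p.shape != (B,) or ((p < 0) | (p > 1)).any():
        raise ValueError("unregistered_prob must map 1..B into [0, 1]")

    rng = np.random.default_rng(seed)
    n_rows = data.curves.shape[0]
    drop = rng.random(size=(n_rows, B)) < p  # row x bout-length
    mask = data.mask.copy()
    for length in range(1, B + 1):
        mask[drop[:, length - 1], bout_block(length, B)] = False

    keep = mask.any(axis=1)
    curves = np.where(mask, data.curves, np.nan)
    report = MaskingReport(
        target_prob=p,
        realized_prob=drop.mean(axis=0),
        overall_missing_rate=float(1.0 - mask.mean()),
        n_rows_in=n_rows,
        n_rows_dropped=int((~keep).sum()),
    )
    masked = SimulatedDataset(
        curves=curves[keep],
        mask=mask[keep],
        index=data.index.loc[keep].reset_index(drop=True),
        truth_scores_level1=data.truth_scores_level1,
        truth_scores_level2=data.truth_scores_level2[keep],
        truth=data.truth,
    )
    return masked, report


# ---------------------------------------------------------------------------
# device-level streams
# ---------------------------------------------------------------------------


@dataclass
class SegmentSpec:
    """One scripted posture segment with constant per-second axis counts."""

    posture: str
    duration_s: int
    counts_per_s: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class BehaviorParams:
    """Waking-day behavior model for the device-stream generator.

    Days alternate sitting with standing/stepping segments whose durations
    are exponential with the given means.  Per-second axis counts are Poisson
    with a per-minute intensity drawn per posture: sitting intensities are
    mostly low with occasional bursts (zero-inflated lognormal, calibrated so
    minute-level sitting VM has median ≈ 20 cpm, a long upper tail around the
    97.5th percentile of ≈ 1000 cpm); standing is low, stepping high.  A
    ``script`` (per day, per segment) overrides the stochastic schedule for
    oracle tests.
    """

    wake_time: str = "06:30"
    bed_time: str = "22:30"
    start_date: str = "2021-05-03"
    mean_sit_min: float = 15.0
    mean_stand_min: float = 6.0
    mean_step_min: float = 3.0
    sit_rate_median: float = 0.2
    sit_rate_log_sd: float = 2.0
    sit_zero_prob: float = 0.3
    stand_rate: float = 1.5
    step_rate: float = 30.0
    axis_ratios: tuple[float, float, float] = (1.0, 0.8, 0.6)
    script: Sequence[Sequence[SegmentSpec]] | None = None

    def waking_seconds(self) -> tuple[int, int]:
        wake = _time_to_seconds(self.wake_time)
        bed = _time_to_seconds(self.bed_time)
        if bed - wake < 3600:
            raise ValueError("waking window must be at least 1 hour")
        return wake, bed


def _time_to_seconds(hhmm: str) -> int:
    h, m = hhmm.split(":")
    return int(h) * 3600 + int(m) * 60


@dataclass
class DeviceStreams:
    """The three raw tables plus the generator's ground-truth bout list."""

    events: pd.DataFrame
    counts: pd.DataFrame
    sleep: pd.DataFrame
    truth_bouts: pd.DataFrame
    params: BehaviorParams
    seed: int


def _day_segments(
    params: BehaviorParams, rng: np.random.Generator, day: int
) -> list[SegmentSpec]:
    """Posture segments spanning one waking window, sitting first."""
    wake, bed = params.waking_seconds()
    if params.script is not None:
        segs = list(params.script[day])
        total = sum(s.duration_s for s in segs)
        if total > bed - wake:
            raise ValueError("scripted day exceeds the waking window")
        if total < bed - wake:  # pad with standing so events cover the day
            segs.append(SegmentSpec("standing", bed - wake - total))
        return segs
    # Days open and close with an upright segment of at least 3 minutes —
    # longer than the non-wear spike tolerance — so the overnight zero-count
    # runs terminate exactly at the waking-window bounds and the schedule
    # itself is the exact bout oracle.
    edge_s = 180
    segs: list[SegmentSpec] = []
    remaining = bed - wake
    sitting = False
    upright = "standing"
    first = True
    while remaining > 0:
        if sitting:
            posture = "sitting"
            dur = int(max(60, rng.exponential(params.mean_sit_min * 60)))
            if dur > remaining - edge_s:  # keep room for a closing upright segment
                dur = remaining - edge_s
            if dur < 60:
                sitting = False
                continue
        else:
            posture = upright
            mean = params.mean_stand_min if upright == "standing" else params.mean_step_min
            upright = "stepping" if upright == "standing" else "standing"
            dur = int(min(remaining, max(edge_s if first else 60, rng.exponential(mean * 60))))
            first = False
        segs.append(SegmentSpec(posture, dur))
        remaining -= dur
        sitting = not sitting
    return segs


def _segment_counts(
    seg: SegmentSpec, params: BehaviorParams, rng: np.random.Generator, scripted: bool
) -> np.ndarray:
    """Per-second (duration x 3) axis counts for one segment."""
    n = seg.duration_s
    if scripted:
        return np.tile(np.asarray(seg.counts_per_s, dtype=float), (n, 1))
    ratios = np.asarray(params.axis_ratios)
    if seg.posture == "sitting":
        n_min = n // 60 + (1 if n % 60 else 0)
        burst = rng.random(n_min) >= params.sit_zero_prob
        rate = np.where(
            burst,
            params.sit_rate_median
            * np.exp(rng.normal(0.0, params.sit_rate_log_sd, n_min)),
            0.0,
        )
        per_sec = np.repeat(rate, 60)[:n]
    elif seg.posture == "standing":
        per_sec = np.full(n, params.stand_rate) * rng.uniform(0.3, 1.7, n)
    else:  # stepping
        per_sec = np.full(n, params.step_rate) * rng.uniform(0.6, 1.4, n)
    return rng.poisson(per_sec[:, None] * ratios).astype(float)


def _truth_bouts_for_day(
    segs: list[SegmentSpec], day_start: pd.Timestamp, wake: int, bed: int
) -> list[dict]:
    """Maximal sitting runs within the waking window, from the schedule."""
    out = []
    pos = wake
    run_start = None
    for seg in segs + [SegmentSpec("standing", 0)]:  # sentinel closes a final run
        if seg.posture == "sitting" and run_start is None:
            run_start = pos
        elif seg.posture != "sitting" and run_start is not None:
            out.append((run_start, pos))
            run_start = None
        pos += seg.duration_s
    bouts = []
    for s0, s1 in out:
        dur = s1 - s0
        frac = dur % 60
        n_minutes = dur // 60 + (1 if frac >= 30 else 0)
        bouts.append(
            {
                "start": day_start + pd.Timedelta(seconds=s0),
                "duration_s": dur,
                "n_minutes": n_minutes,
            }
        )
    return bouts


def simulate_device_streams(
    n: int, days: int, params: BehaviorParams | None = None, seed: int = 0
) -> DeviceStreams:
    """Generate event, count and sleep tables for n participants x days.

    The count table has one row per second of the simulated wear period
    (devices worn around the clock); the event table tiles each day without
    gaps or overlaps, with the overnight in-bed period emitted as a sitting
    (non-upright) event; the sleep log holds one in-bed interval per night,
    including the night ending on the first morning so every study day has
    both waking-window bounds.
    """
    if n <= 0 or days <= 0:
        raise ValueError("n and days must be positive")
    params = params or BehaviorParams()
    wake, bed = params.waking_seconds()
    start = pd.Timestamp(params.start_date)
    rng = np.random.default_rng(seed)

    events, sleep_rows, counts_frames, truth_rows = [], [], [], []
    for pid in range(1, n + 1):
        prev_night = start - pd.Timedelta(days=1)
        sleep_rows.append(
            {
                "participant": pid,
                "date": prev_night.date(),
                "bed_start": prev_night + pd.Timedelta(seconds=bed),
                "bed_end": start + pd.Timedelta(seconds=wake),
            }
        )
        sec_counts = np.zeros((days * 86400, 3))
        for d in range(days):
            day_start = start + pd.Timedelta(days=d)
            if d == 0:  # midnight -> first wake: tail of the first night, non-upright
                events.append(
                    {
                        "participant": pid,
                        "start": day_start,
                        "duration_s": wake,
                        "posture": "sitting",
                    }
                )
            segs = _day_segments(params, rng, d)
            pos = wake
            for seg in segs:
                if seg.duration_s == 0:
                    continue
                events.append(
                    {
                        "participant": pid,
                        "start": day_start + pd.Timedelta(seconds=pos),
                        "duration_s": seg.duration_s,
                        "posture": seg.posture,
                    }
                )
                block = _segment_counts(seg, params, rng, params.script is not None)
                off = d * 86400 + pos
                sec_counts[off : off + seg.duration_s] = block
                pos += seg.duration_s
            # overnight in-bed period: non-upright posture, zero counts
            night_end = (
                start + pd.Timedelta(days=d + 1, seconds=wake)
                if d + 1 < days
                else day_start + pd.Timedelta(days=1)
            )
            events.append(
                {
                    "participant": pid,
                    "start": day_start + pd.Timedelta(seconds=bed),
                    "duration_s": int(
                        (night_end - day_start - pd.Timedelta(seconds=bed)).total_seconds()
                    ),
                    "posture": "sitting",
                }
            )
            sleep_rows.append(
                {
                    "participant": pid,
                    "date": day_start.date(),
                    "bed_start": day_start + pd.Timedelta(seconds=bed),
                    "bed_end": day_start + pd.Timedelta(days=1, seconds=wake),
                }
            )
            for bout in _truth_bouts_for_day(segs, day_start, wake, bed):
                truth_rows.append({"participant": pid, "day": day_start.date(), **bout})
        ts = start + pd.to_timedelta(np.arange(days * 86400), unit="s")
        counts_frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "timestamp": ts,
                    "va": sec_counts[:, 0].astype(int),
                    "ha": sec_counts[:, 1].astype(int),
                    "ppa": sec_counts[:, 2].astype(int),
                }
            )
        )

    events_df = (
        pd.DataFrame(events).sort_values(["participant", "start"]).reset_index(drop=True)
    )
    truth_cols = ["participant", "day", "start", "duration_s", "n_minutes"]
    truth_df = (
        pd.DataFrame(truth_rows, columns=truth_cols)
        .sort_values(["participant", "start"])
        .reset_index(drop=True)
        if truth_rows
        else pd.DataFrame(columns=truth_cols)
    )
    return DeviceStreams(
        events=events_df,
        counts=pd.concat(counts_frames, ignore_index=True),
        sleep=pd.DataFrame(sleep_rows),
        truth_bouts=truth_df,
        params=params,
        seed=seed,
    )


def write_streams(streams: DeviceStreams, outdir: str) -> None:
    """Write the three stream CSVs and a JSON truth sidecar."""
    import os

    os.makedirs(outdir, exist_ok=True)
    streams.events.to_csv(os.path.join(outdir, "events.csv"), index=False)
    streams.counts.to_csv(os.path.join(outdir, "counts.csv"), index=False)
    streams.sleep.to_csv(os.path.join(outdir, "sleep.csv"), index=False)
    truth = streams.truth_bouts.copy()
    truth["start"] = truth["start"].astype(str)
    truth["day"] = truth["day"].astype(str)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(
            {"seed": streams.seed, "bouts": truth.to_dict(orient="records")}, fh, indent=2
        )


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def simulate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Baseline covariates shaped like an older overweight female cohort.

    Age ~ N(68, 7.3), BMI ~ N(32.3, 4.9); race (white), college education,
    employment and hypertension are Bernoulli at 92%, 72%, 40% and 52%;
    valid wear days 1..9 centered near 5.7; daily non-sitting minutes
    ~ N(263, 91).  Binary variables are coded 0/1.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant": np.arange(1, n + 1),
            "age": rng.normal(68.2, 7.3, n).round(1),
            "race_white": (rng.random(n) < 0.922).astype(int),
            "education_college": (rng.random(n) < 0.721).astype(int),
            "employed": (rng.random(n) < 0.399).astype(int),
            "bmi": rng.normal(32.3, 4.9, n).round(1),
            "hypertension": (rng.random(n) < 0.523).astype(int),
            "n_valid_days": np.clip(rng.poisson(5.7, n), 1, 9),
            "nonsitting_min": np.clip(rng.normal(262.6, 91.0, n), 30, None).round(1),
        }
    )


def simulate_outcomes(
    level1_scores: np.ndarray,
    beta: Sequence[float] | Mapping[str, Sequence[float]],
    covariates: pd.DataFrame,
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcomes from a linear model on level-1 scores plus covariates.

    ``beta`` is (intercept, score coefficients..., covariate coefficients...)
    — one vector producing a single ``outcome`` column, or a mapping from
    outcome name (e.g. ``sbp``/``dbp``) to such a vector, each with
    independent N(0, noise_sd^2) errors.  Returns ``(outcomes, design)``
    where the design matrix (with intercept) enables closed-form oracle
    refits.  The covariate table must be full rank.
    """
    scores = np.atleast_2d(np.asarray(level1_scores, dtype=float))
    if scores.shape[0] != len(covariates):
        raise ValueError("scores and covariates must have the same number of rows")
    cov_cols = [c for c in covariates.columns if c != "participant"]
    X_cov = covariates[cov_cols].to_numpy(dtype=float)
    if X_cov.size and np.linalg.matrix_rank(X_cov) < X_cov.shape[1]:
        raise ValueError("covariate table is rank-deficient")
    X = np.column_stack([np.ones(scores.shape[0]), scores, X_cov])
    names = (
        ["intercept"]
        + [f"pc{k + 1}" for k in range(scores.shape[1])]
        + cov_cols
    )
    betas = beta if isinstance(beta, Mapping) else {"outcome": beta}
    rng = np.random.default_rng(seed)
    out = {}
    if "participant" in covariates.columns:
        out["participant"] = covariates["participant"].to_numpy()
    for name, vec in betas.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (X.shape[1],):
            raise ValueError(
                f"beta for {name!r} must have length {X.shape[1]} "
                "(intercept + scores + covariates)"
            )
        out[name] = X @ vec + (rng.normal(0.0, noise_sd, X.shape[0]) if noise_sd else 0.0)
    design = pd.DataFrame(X, columns=names)
    return pd.DataFrame(out), design
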