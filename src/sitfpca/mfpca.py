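"""Two-level functional principal component analysis on the bout domain.

The model decomposes registered participant-day curves as

    X_ij(t) = mu(t) + eta_j(t) + sum_k xi_ik phi1_k(t)
              + sum_l zeta_ijl phi2_l(t) + eps_ij(t),

with subject-level (between, level 1) and day-level (within, level 2)
eigenfunctions phi and mean-zero Gaussian scores whose variances are the
eigenvalues lambda.  Estimation is method-of-moments: the total covariance is
built from products of residual pairs within a row, the between-subject
covariance from residual pairs in different rows (days) of the same subject,
and the within-subject covariance is their difference.  With missing cells
each covariance entry uses only the pairs where both points were observed.
Eigenanalysis uses the rectangle rule with unit grid spacing (the domain is
an index set of minutes), components are retained until a pooled 90% of the
total variance is explained, and scores are predicted jointly per subject as
best linear unbiased predictors (BLUPs) from the observed entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, ndimage

__all__ = [
    "MfpcaModel",
    "estimate_mean_and_shift",
    "CovarianceEstimates",
    "estimate_covariances",
    "eigendecompose_level",
    "select_components",
    "estimate_scores",
    "fit_mfpca",
    "reconstruct",
    "variance_summary",
]

_JITTER = 1e-8


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class MfpcaModel:
    """Fitted two-level functional PCA.

    ``phi1``/``phi2`` store one eigenfunction per row (orthonormal under the
    unit-spacing discrete inner product, sign fixed so the largest-magnitude
    entry is positive); ``lambda1_full``/``lambda2_full`` keep the complete
    nonnegative spectra used for variance accounting; ``scores1`` has one row
    per subject (xi), ``scores2`` one row per participant-day (zeta).
    ``eta`` is indexed by within-subject day order (1-based).
    """

    T: int
    mu: np.ndarray
    eta: np.ndarray
    phi1: np.ndarray
    lambda1: np.ndarray
    phi2: np.ndarray
    lambda2: np.ndarray
    sigma2: float
    lambda1_full: np.ndarray
    lambda2_full: np.ndarray
    scores1: np.ndarray | None = None
    scores2: np.ndarray | None = None
    subjects: np.ndarray | None = None
    row_subjects: np.ndarray | None = None
    row_days: np.ndarray | None = None
    row_day_order: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def N1(self) -> int:
        return self.phi1.shape[0]

    @property
    def N2(self) -> int:
        return self.phi2.shape[0]

    @property
    def rho(self) -> float:
        """Share of total variance at the subject level (full spectra)."""
        s1, s2 = self.lambda1_full.sum(), self.lambda2_full.sum()
        return float(s1 / (s1 + s2))

    @property
    def pve1(self) -> np.ndarray:
        """Within-level variance share of each retained level-1 component."""
        tot = self.lambda1_full.sum()
        return self.lambda1 / tot if tot > 0 else np.zeros_like(self.lambda1)

    @property
    def pve2(self) -> np.ndarray:
        tot = self.lambda2_full.sum()
        return self.lambda2 / tot if tot > 0 else np.zeros_like(self.lambda2)

    def save(self, path: str) -> None:
        """Serialize to a single .npz bundle (arrays + config echo)."""
        np.savez(
            path,
            config=np.array([repr(self.config)]),
            **{
                k: getattr(self, k)
                for k in (
                    "mu",
                    "eta",
                    "phi1",
                    "lambda1",
                    "phi2",
                    "lambda2",
                    "lambda1_full",
                    "lambda2_full",
                    "scores1",
                    "scores2",
                    "subjects",
                    "row_subjects",
                    "row_days",
                    "row_day_order",
                )
                if getattr(self, k) is not None
            },
            sigma2=self.sigma2,
            T=self.T,
        )


# ---------------------------------------------------------------------------
# estimation steps
# ---------------------------------------------------------------------------


def _day_order(subjects: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Within-subject 1-based order of day ids (ties broken by appearance)."""
    order = np.empty(subjects.size, dtype=int)
    df = pd.DataFrame({"s": subjects, "d": days})
    for _, grp in df.groupby("s", sort=False):
        ranks = grp["d"].rank(method="first").astype(int)
        order[grp.index.to_numpy()] = ranks.to_numpy()
    return order


def estimate_mean_and_shift(
    matrix: np.ndarray, mask: np.ndarray, day_order: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise overall mean mu(t) and day-order shifts eta_j(t).

    mu(t) averages the observed values at t over all rows; eta_j(t) is the
    mean among rows with within-subject day order j minus mu(t), set to 0
    where day j has no observation.  Grid points observed in no row at all
    are an error (reduce B or supply more data).
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.where(mask, matrix, 0.0)
    counts = mask.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(
            f"grid points observed in zero rows (1-based t): {(empty + 1).tolist()[:20]}"
        )
    mu = vals.sum(axis=0) / counts
    J = int(day_order.max())
    eta = np.zeros((J, matrix.shape[1]))
    for j in range(1, J + 1):
        rows = day_order == j
        cnt = mask[rows].sum(axis=0)
        with np.errstate(invalid="ignore"):
            day_mean = np.where(cnt > 0, vals[rows].sum(axis=0) / np.maximum(cnt, 1), np.nan)
        eta[j - 1] = np.where(cnt > 0, day_mean - mu, 0.0)
    return mu, eta


@dataclass
class CovarianceEstimates:
    """Between/within covariance surfaces and the noise variance.

    ``k_total`` has its diagonal replaced by the off-diagonal extrapolation
    used to identify sigma2, so ``k_between + k_within = k_total`` exactly by
    construction.  ``raw_diag`` keeps the unadjusted diagonal (signal +
    sigma2); ``imputed_fraction`` reports surface cells with no observed pair.
    """

    k_between: np.ndarray
    k_within: np.ndarray
    k_total: np.ndarray
    sigma2: float
    raw_diag: np.ndarray
    imputed_fraction: float
    smoothed: bool


def _fill_empty_cells(K: np.ndarray) -> np.ndarray:
    """Fill NaN cells by iterated local averaging of observed neighbors."""
    filled = K.copy()
    while np.isnan(filled).any():
        hole = np.isnan(filled)
        have = (~hole).astype(float)
        s = ndimage.uniform_filter(np.where(hole, 0.0, filled), size=5, mode="constant")
        w = ndimage.uniform_filter(have, size=5, mode="constant")
        ready = hole & (w > 1e-12)
        if not ready.any():
            raise ValueError("cannot impute empty covariance cells: no observed neighbors")
        filled[ready] = s[ready] / w[ready]
    return filled


def _pair_average(
    A_num: np.ndarray, A_cnt: np.ndarray
) -> tuple[np.ndarray, float]:
    """Elementwise ratio with NaN where no pair contributed."""
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(A_cnt > 0, A_num / np.maximum(A_cnt, 1), np.nan)
    frac_empty = float(np.isnan(K).mean())
    return K, frac_empty


def estimate_covariances(
    resid: np.ndarray,
    mask: np.ndarray,
    subjects: np.ndarray,
    smooth: str = "auto",
    bandwidth: float = 1.5,
) -> CovarianceEstimates:
    """Method-of-moments covariance surfaces from (masked) residuals.

    ``k_total(s,t)`` averages products of same-row residual pairs,
    ``k_between(s,t)`` products of residual pairs from different days of the
    same subject; each cell uses only pairs with both points observed.  The
    noise variance is the mean gap between the raw diagonal of the total
    surface and its extrapolation from adjacent off-diagonal entries, floored
    at zero.  ``smooth`` is ``"auto"`` (kernel-smooth surfaces only when some
    cells had no pairs), ``"on"`` or ``"off"``.
    """
    if smooth not in ("auto", "on", "off"):
        raise ValueError("smooth must be 'auto', 'on' or 'off'")
    mask = np.asarray(mask, dtype=bool)
    R = np.where(mask, resid, 0.0)
    M = mask.astype(float)
    T = R.shape[1]

    tot_num = R.T @ R
    tot_cnt = M.T @ M
    k_total, frac_tot = _pair_average(tot_num, tot_cnt)

    df = pd.DataFrame({"s": subjects})
    groups = df.groupby("s", sort=False).indices
    bet_num = np.zeros((T, T))
    bet_cnt = np.zeros((T, T))
    for rows in groups.values():
        if len(rows) < 2:
            continue
        Rs, Ms = R[rows], M[rows]
        sr, sm = Rs.sum(axis=0), Ms.sum(axis=0)
        bet_num += np.outer(sr, sr) - Rs.T @ Rs
        bet_cnt += np.outer(sm, sm) - Ms.T @ Ms
    if bet_cnt.max() == 0:
        raise ValueError(
            "no subject has two days with overlapping observations: "
            "within-subject covariance unidentifiable"
        )
    k_between, frac_bet = _pair_average(bet_num, bet_cnt)

    frac_empty = max(frac_tot, frac_bet)
    if frac_empty > 0.95:
        raise ValueError(f"{frac_empty:.0%} of covariance cells have no observed pair")
    if frac_tot > 0:
        k_total = _fill_empty_cells(k_total)
    if frac_bet > 0:
        k_between = _fill_empty_cells(k_between)

    raw_diag = np.diag(k_total).copy()
    pred_diag = np.empty(T)
    for t in range(T):
        neighbors = []
        if t > 0:
            neighbors.append(k_total[t, t - 1])
        if t + 1 < T:
            neighbors.append(k_total[t, t + 1])
        # single-point grids have no off-diagonal: noise unidentifiable, gap 0
        pred_diag[t] = np.mean(neighbors) if neighbors else raw_diag[t]
    sigma2 = max(0.0, float(np.mean(raw_diag - pred_diag)))
    np.fill_diagonal(k_total, pred_diag)

    do_smooth = smooth == "on" or (smooth == "auto" and frac_empty > 0)
    if do_smooth:
        k_total = ndimage.gaussian_filter(k_total, sigma=bandwidth, mode="nearest")
        k_between = ndimage.gaussian_filter(k_between, sigma=bandwidth, mode="nearest")

    k_total = 0.5 * (k_total + k_total.T)
    k_between = 0.5 * (k_between + k_between.T)
    k_within = k_total - k_between
    return CovarianceEstimates(
        k_between=k_between,
        k_within=k_within,
        k_total=k_total,
        sigma2=sigma2,
        raw_diag=raw_diag,
        imputed_fraction=frac_empty,
        smoothed=do_smooth,
    )


def eigendecompose_level(K: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Discrete eigendecomposition of a covariance surface.

    Unit grid spacing makes the quadrature trivial: eigenvalues of the matrix
    are the functional eigenvalues and eigenvectors (unit Euclidean norm) are
    the eigenfunctions.  Negative eigenvalues are truncated and excluded;
    each eigenfunction's largest-magnitude entry is made positive.  Returns
    (eigenfunctions as rows, eigenvalues) sorted by decreasing eigenvalue.
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=tol * max(1.0, np.abs(K).max())):
        raise ValueError("covariance surface is not symmetric")
    w, v = linalg.eigh(0.5 * (K + K.T))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # exclude negative eigenvalues and numerical zeros (relative to the top)
    floor = w.max() * 1e-12 if w.size and w.max() > 0 else 0.0
    keep = w > floor
    w, v = w[keep], v[:, keep]
    phi = v.T.copy()
    for row in phi:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return phi, w


def select_components(
    lambda1_full: np.ndarray,
    lambda2_full: np.ndarray,
    total_pve: float = 0.90,
) -> tuple[int, int]:
    """Pooled greedy component selection at a total-variance threshold.

    Components from both levels are pooled, sorted by eigenvalue, and added
    until their cumulative share of the grand total reaches ``total_pve``;
    the per-level counts of the selected set are returned, with a floor of
    one component per level.
    """
    l1 = np.asarray(lambda1_full, dtype=float)
    l2 = np.asarray(lambda2_full, dtype=float)
    if (l1 < 0).any() or (l2 < 0).any():
        raise ValueError("spectra must be nonnegative")
    total = l1.sum() + l2.sum()
    if total <= 0:
        raise ValueError("all-zero spectra: nothing to select")
    pooled = sorted(
        [(lam, 1) for lam in l1] + [(lam, 2) for lam in l2], key=lambda x: -x[0]
    )
    n1 = n2 = 0
    acc = 0.0
    for lam, level in pooled:
        acc += lam
        if level == 1:
            n1 += 1
        else:
            n2 += 1
        if acc / total >= total_pve:
            break
    n1 = max(n1, 1) if l1.size else n1
    n2 = max(n2, 1) if l2.size else n2
    return n1, n2


def estimate_scores(
    model: MfpcaModel,
    matrix: np.ndarray,
    mask: np.ndarray,
    subjects: np.ndarray,
    day_order: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint BLUP of subject scores xi and day scores zeta from observed cells.

    For each subject the observed residuals of all its days are stacked and
    the Gaussian model implied by (phi, lambda, sigma2) is solved in its
    small mixed-model form: (Z'Z + sigma2 * Lambda^{-1} + jitter) theta = Z'r.
    With full observation and sigma2 = 0 this reduces to least-squares
    projection onto the retained eigenfunctions, and the subject score xi_ik
    is by construction shared across the subject's days.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        bad = np.flatnonzero(~mask.any(axis=1))
        raise ValueError(f"rows with zero observed entries: {bad.tolist()[:10]}")
    N1, N2 = model.N1, model.N2
    eta_rows = model.eta[np.asarray(day_order, dtype=int) - 1]
    resid = np.where(mask, matrix - model.mu - eta_rows, 0.0)

    # prior precision of each score, with zero-variance components pinned to 0
    def inv_lam(lams: np.ndarray) -> np.ndarray:
        return np.where(lams > 0, model.sigma2 / np.maximum(lams, 1e-300), 1e12)

    pen1, pen2 = inv_lam(model.lambda1), inv_lam(model.lambda2)

    uniq, inverse = np.unique(subjects, return_inverse=True)
    scores1 = np.zeros((uniq.size, N1))
    scores2 = np.zeros((matrix.shape[0], N2))
    for si in range(uniq.size):
        rows = np.flatnonzero(inverse == si)
        d = rows.size
        q = N1 + d * N2
        A = np.zeros((q, q))
        rhs = np.zeros(q)
        A[:N1, :N1] += np.diag(pen1)
        for jj, r in enumerate(rows):
            obs = mask[r]
            P1 = model.phi1[:, obs]
            P2 = model.phi2[:, obs]
            rr = resid[r, obs]
            sl = slice(N1 + jj * N2, N1 + (jj + 1) * N2)
            A[:N1, :N1] += P1 @ P1.T
            A[:N1, sl] += P1 @ P2.T
            A[sl, :N1] += P2 @ P1.T
            A[sl, sl] += P2 @ P2.T + np.diag(pen2)
            rhs[:N1] += P1 @ rr
            rhs[sl] += P2 @ rr
        A[np.diag_indices_from(A)] += _JITTER
        theta = linalg.solve(A, rhs, assume_a="pos")
        scores1[si] = theta[:N1]
        for jj, r in enumerate(rows):
            scores2[r] = theta[N1 + jj * N2 : N1 + (jj + 1) * N2]
    return scores1, scores2


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def fit_mfpca(
    matrix: np.ndarray,
    mask: np.ndarray,
    subjects: Sequence,
    days: Sequence | None = None,
    pve: float = 0.90,
    smooth: str = "auto",
    bandwidth: float = 1.5,
    on_empty_columns: str = "error",
) -> MfpcaModel:
    """Fit the full two-level model from a registered curve matrix.

    ``subjects``/``days`` identify each row; ``days`` defaults to the order
    of appearance within each subject.  ``on_empty_columns`` controls grid
    points observed in no row: ``"error"`` (default) or ``"drop"`` (fit on
    the observed subgrid and zero-pad mean, shifts and eigenfunctions back to
    the full grid).
    """
    matrix = np.asarray(matrix, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    subjects = np.asarray(subjects)
    n_rows, T = matrix.shape
    if mask.shape != matrix.shape or subjects.shape != (n_rows,):
        raise ValueError("matrix, mask and subjects must align")
    if days is None:  # order of appearance per subject
        days = np.zeros(n_rows, dtype=int)
        seen: dict = {}
        for i, s in enumerate(subjects):
            seen[s] = seen.get(s, 0) + 1
            days[i] = seen[s]
    days = np.asarray(days)
    day_order = _day_order(subjects, days)

    obs_cols = mask.any(axis=0)
    if not obs_cols.all():
        if on_empty_columns == "error":
            empty = np.flatnonzero(~obs_cols)
            raise ValueError(
                f"grid points observed in zero rows (1-based t): {(empty + 1).tolist()[:20]}"
            )
        if on_empty_columns != "drop":
            raise ValueError("on_empty_columns must be 'error' or 'drop'")
    sub = obs_cols if not obs_cols.all() else slice(None)
    m_work, k_work = matrix[:, sub], mask[:, sub]

    mu, eta = estimate_mean_and_shift(m_work, k_work, day_order)
    resid = m_work - mu - eta[day_order - 1]
    cov = estimate_covariances(resid, k_work, subjects, smooth=smooth, bandwidth=bandwidth)
    phi1f, lam1f = eigendecompose_level(cov.k_between)
    phi2f, lam2f = eigendecompose_level(cov.k_within)
    if lam1f.size == 0:
        phi1f, lam1f = np.zeros((1, m_work.shape[1])), np.zeros(1)
        phi1f[0, 0] = 1.0
    if lam2f.size == 0:
        phi2f, lam2f = np.zeros((1, m_work.shape[1])), np.zeros(1)
        phi2f[0, 0] = 1.0
    if lam1f.sum() + lam2f.sum() <= 0:  # fully degenerate (noise-free constant) input
        N1, N2 = 1, 1
    else:
        N1, N2 = select_components(lam1f, lam2f, pve)
    N1, N2 = min(N1, lam1f.size), min(N2, lam2f.size)

    def pad(rows2d: np.ndarray) -> np.ndarray:
        if obs_cols.all():
            return rows2d
        out = np.zeros((rows2d.shape[0], T))
        out[:, obs_cols] = rows2d
        return out

    model = MfpcaModel(
        T=T,
        mu=pad(mu[None, :])[0],
        eta=pad(eta),
        phi1=pad(phi1f[:N1]),
        lambda1=lam1f[:N1],
        phi2=pad(phi2f[:N2]),
        lambda2=lam2f[:N2],
        sigma2=cov.sigma2,
        lambda1_full=lam1f,
        lambda2_full=lam2f,
        subjects=np.unique(subjects),
        row_subjects=subjects,
        row_days=days,
        row_day_order=day_order,
        config={
            "pve": pve,
            "smooth": smooth,
            "bandwidth": bandwidth,
            "imputed_fraction": cov.imputed_fraction,
            "smoothed": cov.smoothed,
            "n_rows": n_rows,
            "dropped_columns": int((~obs_cols).sum()) if not obs_cols.all() else 0,
        },
    )
    scores1, scores2 = estimate_scores(model, matrix, mask, subjects, day_order)
    model.scores1, model.scores2 = scores1, scores2
    return model


def _row_for(model: MfpcaModel, subject, day) -> int:
    hits = np.flatnonzero((model.row_subjects == subject) & (model.row_days == day))
    if hits.size != 1:
        raise KeyError(f"unknown (participant, day) = ({subject!r}, {day!r})")
    return int(hits[0])


def reconstruct(model: MfpcaModel, subject, day, stage: int = 4) -> np.ndarray:
    """Incremental fitted curve for one participant-day.

    Stage 1 is the overall mean mu; stage 2 adds the day shift eta_j; stage 3
    the subject-level component sum; stage 4 the day-level component sum.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be 1..4")
    r = _row_for(model, subject, day)
    curve = model.mu.copy()
    if stage >= 2:
        curve = curve + model.eta[model.row_day_order[r] - 1]
    if stage >= 3:
        si = int(np.flatnonzero(model.subjects == subject)[0])
        curve = curve + model.scores1[si] @ model.phi1
    if stage >= 4:
        curve = curve + model.scores2[r] @ model.phi2
    return curve


def variance_summary(model: MfpcaModel) -> pd.DataFrame:
    """Per-level, per-component eigenvalues and variance proportions.

    ``within_level_share`` is lambda_k over the level's full spectrum total;
    ``total_share`` is over the grand total.  ``rho`` (the level-1 share of
    total variance) is available as ``model.rho``.
    """
    rows = []
    grand = model.lambda1_full.sum() + model.lambda2_full.sum()
    for level, lams, full in (
        (1, model.lambda1, model.lambda1_full),
        (2, model.lambda2, model.lambda2_full),
    ):
        tot = full.sum()
        for k, lam in enumerate(lams, start=1):
            rows.append(
                {
                    "level": level,
                    "component": k,
                    "eigenvalue": float(lam),
                    "within_level_share": float(lam / tot) if tot > 0 else 0.0,
                    "total_share": float(lam / grand) if grand > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)
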