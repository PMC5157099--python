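"""Purity and ploidy estimation from segmented log-ratios.

Segment log-ratios are modeled as Gaussian around
``log2((p*C + 2(1-p)) / (p*D + 2(1-p)))`` where p is purity, C the segment's
integer tumor copy number and D the tumor ploidy (length-weighted mean copy
number). A 2D grid search over (purity, ploidy) finds candidate local
optima; each is refined by a heated Gibbs sampler that assigns integer copy
numbers 0..7 (plus a catch-all subclonal state) to segments, fine-tunes
purity on a 0.15..0.95 grid, and re-calibrates a global log-ratio shift.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Optional, Sequence

import numpy as np

from .segmentation import SUBCLONAL, Segment

COPY_MAX = 7
N_STATES = COPY_MAX + 2  # integer states 0..7 plus subclonal
SUBCLONAL_COL = N_STATES - 1

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def expected_log_ratio(p: float, C, D) -> np.ndarray:
    """Expected segment log2 ratio for copy number C at purity p and ploidy D."""
    C = np.asarray(C, dtype=float)
    num = p * C + 2.0 * (1.0 - p)
    den = p * np.asarray(D, dtype=float) + 2.0 * (1.0 - p)
    with np.errstate(divide="ignore"):
        return np.log2(num / den)


def segment_loglik(r, sigma, num_targets, p, C, D):
    """Log-likelihood of a segment mean log-ratio, weighted by its target count."""
    if np.any(np.asarray(C) < 0):
        raise ValueError("copy number C must be >= 0")
    mu = expected_log_ratio(p, C, D)
    z = (np.asarray(r) - mu) / sigma
    return num_targets * (-LOG_SQRT_2PI - np.log(sigma) - 0.5 * z * z)


def subclonal_loglik(sigma, num_targets):
    """Constant log-density of the catch-all subclonal state.

    Equal to a Gaussian 2-sigma mismatch, so a segment goes subclonal only
    when every integer state fits worse than two standard errors.
    """
    return num_targets * (-LOG_SQRT_2PI - np.log(sigma) - 2.0)


@dataclasses.dataclass(eq=False)
class Solution:
    """One purity/ploidy candidate with its segment copy assignment."""

    purity: float
    ploidy: float
    C: list  # per segment: int 0..7 or SUBCLONAL
    posteriors: np.ndarray  # segments x 9 (0..7, subclonal), rows sum to 1
    shift: float  # log-ratio calibration shift added to every r
    cn_loglik: float
    grid_purity: float = np.nan
    grid_ploidy: float = np.nan
    snv_loglik: float = 0.0
    K: list = dataclasses.field(default_factory=list)
    gof: Optional[float] = None
    flags: set = dataclasses.field(default_factory=set)
    bootstrap_value: Optional[float] = None
    rank: Optional[int] = None
    discarded: bool = False
    variant_loglik: Optional[np.ndarray] = None  # per-variant max-state loglik
    variant_table: Optional[object] = None

    @property
    def total_loglik(self) -> float:
        return self.cn_loglik + self.snv_loglik


def _seg_arrays(segments: Sequence[Segment]):
    r = np.array([s.r for s in segments])
    sig = np.array([s.sigma for s in segments])
    nt = np.array([s.num_targets for s in segments], dtype=float)
    l = np.array([s.size for s in segments], dtype=float)
    return r, sig, nt, l


def _loglik_matrix(r, sig, nt, p, D, shift=0.0):
    """(segments x 9) log-likelihood table at fixed purity/ploidy/shift."""
    mu = expected_log_ratio(p, np.arange(COPY_MAX + 1), D)  # (8,)
    z = (r[:, None] + shift - mu[None, :]) / sig[:, None]
    ll = nt[:, None] * (-LOG_SQRT_2PI - np.log(sig)[:, None] - 0.5 * z * z)
    sub = subclonal_loglik(sig, nt)
    return np.concatenate([ll, sub[:, None]], axis=1)


def assignment_ploidy(C_cols: np.ndarray, l: np.ndarray, fallback: float) -> float:
    """Length-weighted mean copy number; subclonal segments are excluded."""
    integer = C_cols < SUBCLONAL_COL
    if not integer.any():
        return fallback
    return float(np.sum(l[integer] * C_cols[integer]) / np.sum(l[integer]))


def _joint_loglik(C_cols, r, sig, nt, l, p, shift, fallback_D) -> float:
    D = assignment_ploidy(C_cols, l, fallback_D)
    M = _loglik_matrix(r, sig, nt, p, D, shift)
    return float(M[np.arange(len(C_cols)), C_cols].sum())


def grid_search(
    segments: Sequence[Segment],
    purities: Optional[np.ndarray] = None,
    ploidies: Optional[np.ndarray] = None,
    max_candidates: int = 20,
    use_logsumexp: bool = False,
) -> list[tuple[float, float, float]]:
    """2D grid search for candidate (purity, ploidy) optima.

    The score at each grid point is the sum over segments of the best (or,
    with *use_logsumexp*, the log-sum-exp) copy-state log-likelihood treating
    ploidy as continuous. Returns local optima (purity, ploidy, score) sorted
    by score, best first; plateau ridges are collapsed to their highest-purity
    representative.
    """
    if len(segments) == 0:
        raise ValueError("no segments")
    if purities is None:
        purities = np.round(np.arange(0.15, 0.951, 0.05), 4)
    if ploidies is None:
        ploidies = np.round(np.arange(1.0, 6.01, 0.1), 4)
    r, sig, nt, _ = _seg_arrays(segments)

    C = np.arange(COPY_MAX + 1, dtype=float)
    P, Dg = purities[:, None], ploidies[None, :]
    num = P[..., None] * C + 2.0 * (1.0 - P[..., None])  # (np, 1, 8)
    den = P * Dg + 2.0 * (1.0 - P)  # (np, nd)
    with np.errstate(divide="ignore"):
        mu = np.log2(num[:, :, None, :] / den[:, :, None, None])  # (np, nd, 1, 8)
    z = (r[None, None, :, None] - mu) / sig[None, None, :, None]
    ll = nt[None, None, :, None] * (
        -LOG_SQRT_2PI - np.log(sig)[None, None, :, None] - 0.5 * z * z
    )
    sub = subclonal_loglik(sig, nt)  # (S,)
    full = np.concatenate(
        [ll, np.broadcast_to(sub[None, None, :, None], ll.shape[:3] + (1,))], axis=3
    )
    if use_logsumexp:
        from scipy.special import logsumexp

        per_seg = logsumexp(full, axis=3)
    else:
        per_seg = full.max(axis=3)
    score = per_seg.sum(axis=2)  # (np, nd)

    # local optima: >= all 8 neighbors (ties allowed, collapsed below)
    padded = np.full((score.shape[0] + 2, score.shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = score
    neigh = np.stack(
        [
            padded[1 + di : padded.shape[0] - 1 + di, 1 + dj : padded.shape[1] - 1 + dj]
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if (di, dj) != (0, 0)
        ]
    )
    is_opt = score >= neigh.max(axis=0)

    # collapse connected near-equal plateaus (ridges) to one representative:
    # the highest-scoring, then highest-purity point of each component
    from scipy import ndimage

    labels, n_comp = ndimage.label(is_opt, structure=np.ones((3, 3), dtype=int))
    kept: list[tuple[int, int]] = []
    for lab in range(1, n_comp + 1):
        comp = np.argwhere(labels == lab)
        vals = score[comp[:, 0], comp[:, 1]]
        if vals.max() - vals.min() < 1e-6:
            sel = comp[np.lexsort((comp[:, 1], -comp[:, 0]))][0]
            kept.append((int(sel[0]), int(sel[1])))
        else:  # genuine distinct optima touching through exact ties: keep each peak
            top = comp[vals >= vals.max() - 1e-6]
            sel = top[np.lexsort((top[:, 1], -top[:, 0]))][0]
            kept.append((int(sel[0]), int(sel[1])))
            for ij in comp[vals < vals.max() - 1e-6]:
                kept.append((int(ij[0]), int(ij[1])))
    kept.sort(key=lambda ij: -score[ij])
    kept = kept[:max_candidates]
    return [(float(purities[i]), float(ploidies[j]), float(score[i, j])) for i, j in kept]


PURITY_GRID = np.round(np.arange(0.15, 0.9501, 0.01), 4)


def fit_solution(
    segments: Sequence[Segment],
    purity: float,
    ploidy: float,
    seed: int = 0,
    max_sweeps: int = 100,
    optimize_purity: bool = True,
    optimize_shift: bool = True,
    shift_factor: float = 0.25,
    ploidy_discard: float = 0.75,
    purity_window: float = 0.1,
) -> Solution:
    """Refine a grid-search candidate by heated Gibbs copy-number assignment.

    Each sweep samples segment copy states from the heated posterior
    (temperature annealed 4 -> 1), then purity over the 0.15..0.95 grid
    (restricted to *purity_window* around the candidate so each local optimum
    is fine-tuned within its own basin rather than collapsing onto a global
    coverage-only attractor), then a global log-ratio calibration shift
    within +/- *shift_factor* times the mean segment sigma; ploidy is
    recomputed from the assignment each sweep.
    Convergence: the maximum-likelihood assignment unchanged for 3 sweeps.
    If the converged ploidy moved more than *ploidy_discard* from the
    candidate, one retry widens the shift range to 1x the mean sigma; a
    still-divergent solution is flagged discarded.
    """
    sol = _fit_once(
        segments, purity, ploidy, seed, max_sweeps,
        optimize_purity, optimize_shift, shift_factor, purity_window,
    )
    if abs(sol.ploidy - ploidy) > ploidy_discard and optimize_shift:
        sol = _fit_once(
            segments, purity, ploidy, seed + 1, max_sweeps,
            optimize_purity, optimize_shift, 1.0, purity_window,
        )
        if abs(sol.ploidy - ploidy) > ploidy_discard:
            sol.discarded = True
            sol.flags.add("PLOIDY_DIVERGED")
    sol.grid_purity = purity
    sol.grid_ploidy = ploidy
    return sol


def _fit_once(
    segments, purity, ploidy, seed, max_sweeps,
    optimize_purity, optimize_shift, shift_factor, purity_window=0.1,
) -> Solution:
    rng = np.random.default_rng(seed)
    r, sig, nt, l = _seg_arrays(segments)
    S = len(segments)
    mean_sig = float(sig.mean())
    shift_grid = (
        np.linspace(-shift_factor * mean_sig, shift_factor * mean_sig, 11)
        if optimize_shift
        else np.array([0.0])
    )
    if optimize_purity:
        p_grid = PURITY_GRID[np.abs(PURITY_GRID - purity) <= purity_window + 1e-9]
    else:
        p_grid = np.array([purity])

    p = float(p_grid[np.argmin(np.abs(p_grid - purity))])
    shift = 0.0
    M = _loglik_matrix(r, sig, nt, p, ploidy, shift)
    C_cols = M.argmax(axis=1)

    best_score = -np.inf
    best = (C_cols.copy(), p, shift)
    prev_ml = None
    stable = 0
    for k in range(max_sweeps):
        T = max(1.0, 4.0 * 0.9**k)
        D = assignment_ploidy(C_cols, l, ploidy)

        M = _loglik_matrix(r, sig, nt, p, D, shift)
        g = rng.gumbel(size=M.shape)
        C_cols = np.argmax(M / T + g, axis=1)
        D = assignment_ploidy(C_cols, l, ploidy)

        if optimize_purity:
            ll_p = _assignment_loglik_over_grid(r, sig, nt, C_cols, p_grid, D, shift)
            p = float(p_grid[_gumbel_pick(ll_p / T, rng)])
        if optimize_shift:
            ll_s = _assignment_loglik_over_shifts(r, sig, nt, C_cols, p, D, shift_grid)
            shift = float(shift_grid[_gumbel_pick(ll_s / T, rng)])

        ml = _loglik_matrix(r, sig, nt, p, assignment_ploidy(C_cols, l, ploidy), shift).argmax(axis=1)
        score = _joint_loglik(ml, r, sig, nt, l, p, shift, ploidy)
        if score > best_score:
            best_score, best = score, (ml.copy(), p, shift)
        if prev_ml is not None and np.array_equal(ml, prev_ml):
            stable += 1
            if stable >= 3:
                break
        else:
            stable = 0
        prev_ml = ml

    # deterministic coordinate-wise polish from the best visited configuration
    C_cols, p, shift = best
    for _ in range(25):
        D = assignment_ploidy(C_cols, l, ploidy)
        new_C = _loglik_matrix(r, sig, nt, p, D, shift).argmax(axis=1)
        D = assignment_ploidy(new_C, l, ploidy)
        new_p = p
        if optimize_purity:
            ll_p = _assignment_loglik_over_grid(r, sig, nt, new_C, p_grid, D, shift)
            new_p = float(p_grid[int(np.argmax(ll_p))])
        new_shift = shift
        if optimize_shift:
            ll_s = _assignment_loglik_over_shifts(r, sig, nt, new_C, new_p, D, shift_grid)
            new_shift = float(shift_grid[int(np.argmax(ll_s))])
        if np.array_equal(new_C, C_cols) and new_p == p and new_shift == shift:
            break
        C_cols, p, shift = new_C, new_p, new_shift
    if S <= 6:
        # small problems admit exact joint optimization over all assignments
        C_ex = _exhaustive_assignment(r, sig, nt, l, p, shift, ploidy)
        if _joint_loglik(C_ex, r, sig, nt, l, p, shift, ploidy) > _joint_loglik(
            C_cols, r, sig, nt, l, p, shift, ploidy
        ):
            C_cols = C_ex
    score = _joint_loglik(C_cols, r, sig, nt, l, p, shift, ploidy)
    if score < best_score:
        C_cols, p, shift = best
        score = best_score

    D = assignment_ploidy(C_cols, l, ploidy)
    M = _loglik_matrix(r, sig, nt, p, D, shift)
    M_shift = M - M.max(axis=1, keepdims=True)
    post = np.exp(M_shift)
    post /= post.sum(axis=1, keepdims=True)

    C_states = [SUBCLONAL if c == SUBCLONAL_COL else int(c) for c in C_cols]
    return Solution(
        purity=p,
        ploidy=D,
        C=C_states,
        posteriors=post,
        shift=shift,
        cn_loglik=score,
    )


def _assignment_loglik(r, sig, nt, C_cols, p, D, shift) -> float:
    M = _loglik_matrix(r, sig, nt, p, D, shift)
    return float(M[np.arange(len(C_cols)), C_cols].sum())


def _split_assignment(C_cols):
    integer = C_cols < SUBCLONAL_COL
    return integer, C_cols[integer].astype(float)


def _assignment_loglik_over_grid(r, sig, nt, C_cols, p_grid, D, shift) -> np.ndarray:
    """Joint log-likelihood of a fixed assignment over the purity grid."""
    integer, C = _split_assignment(C_cols)
    sub = float(subclonal_loglik(sig[~integer], nt[~integer]).sum())
    ri, si, ni = r[integer] + shift, sig[integer], nt[integer]
    P = p_grid[:, None]
    mu = np.log2((P * C + 2.0 * (1.0 - P)) / (P * D + 2.0 * (1.0 - P)))
    z = (ri[None, :] - mu) / si[None, :]
    ll = ni[None, :] * (-LOG_SQRT_2PI - np.log(si)[None, :] - 0.5 * z * z)
    return ll.sum(axis=1) + sub


def _assignment_loglik_over_shifts(r, sig, nt, C_cols, p, D, shift_grid) -> np.ndarray:
    """Joint log-likelihood of a fixed assignment over the shift grid."""
    integer, C = _split_assignment(C_cols)
    sub = float(subclonal_loglik(sig[~integer], nt[~integer]).sum())
    mu = expected_log_ratio(p, C, D)
    z = (r[integer][None, :] + shift_grid[:, None] - mu[None, :]) / sig[integer][None, :]
    ll = nt[integer][None, :] * (-LOG_SQRT_2PI - np.log(sig[integer])[None, :] - 0.5 * z * z)
    return ll.sum(axis=1) + sub


def _gumbel_pick(logw: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.argmax(logw + rng.gumbel(size=logw.shape)))


def _exhaustive_assignment(r, sig, nt, l, p, shift, fallback_D) -> np.ndarray:
    """Vectorized argmax over all {0..7, subclonal}^S assignments (S small)."""
    S = len(r)
    combos = np.indices((N_STATES,) * S).reshape(S, -1).T  # (9^S, S)
    integer = combos < SUBCLONAL_COL
    lw = l[None, :] * integer
    wsum = lw.sum(axis=1)
    with np.errstate(invalid="ignore"):
        D = np.where(wsum > 0, (lw * combos).sum(axis=1) / np.maximum(wsum, 1e-300), fallback_D)
    q = 2.0 * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.log2((p * combos + q) / (p * D[:, None] + q))
    z = (r[None, :] + shift - mu) / sig[None, :]
    ll = nt[None, :] * (-LOG_SQRT_2PI - np.log(sig)[None, :] - 0.5 * z * z)
    sub = subclonal_loglik(sig, nt)
    ll = np.where(integer, ll, sub[None, :])
    ll = np.where(np.isnan(ll), -np.inf, ll)  # e.g. C=0 at purity 1
    return combos[int(np.argmax(ll.sum(axis=1)))].copy()


def exhaustive_ml_assignment(
    segments: Sequence[Segment], purity: float, fallback_D: float
) -> list[int]:
    """Brute-force argmax over integer assignments {0..7}^S (purity fixed).

    Independent oracle for the heated-Gibbs fit on small fixtures; ploidy in
    the likelihood denominator is recomputed from each candidate assignment.
    """
    r, sig, nt, l = _seg_arrays(segments)
    S = len(segments)
    best, best_score = None, -np.inf
    for combo in itertools.product(range(COPY_MAX + 1), repeat=S):
        C_cols = np.array(combo)
        score = _joint_loglik(C_cols, r, sig, nt, l, purity, 0.0, fallback_D)
        if score > best_score:
            best_score, best = score, combo
    return list(best)


def ingest_external_segmentation(
    seg_df, intervals, sigma_default: float = 0.1
) -> list[Segment]:
    """Build segments from a SEG table on a simulated target grid.

    Each SEG row becomes a segment whose num_targets counts the overlapping
    intervals; sigma comes from a ``seg.sd`` column when present, else
    *sigma_default*. Rows overlapping no target are dropped with a warning.
    """
    import logging

    from .intervals import targets_frame

    log = logging.getLogger(__name__)
    targets = targets_frame(intervals) if not hasattr(intervals, "columns") else intervals
    segments: list[Segment] = []
    n_dropped = 0
    for _, row in seg_df.iterrows():
        chrom = str(row["chrom"])
        g = targets[targets["chrom"] == chrom]
        start0 = int(row["loc.start"]) - 1
        end = int(row["loc.end"])
        sel = (g["start"] < end) & (g["end"] > start0)
        idx = g.index[sel].to_numpy()
        if len(idx) == 0:
            n_dropped += 1
            continue
        sigma = float(row["seg.sd"]) if "seg.sd" in row.index and np.isfinite(row.get("seg.sd", np.nan)) else sigma_default
        r = float(row["seg.mean"])
        seg = Segment(
            chrom=chrom,
            tindex=idx,
            gstart=int(g.loc[idx[0], "start"]),
            gend=int(g.loc[idx[-1], "end"]),
            values=np.full(len(idx), r),
            weights=np.ones(len(idx)),
        )
        seg.r = r
        seg.sigma = max(sigma, 1e-4)
        segments.append(seg)
    if n_dropped:
        log.warning("dropped %d SEG rows overlapping no target", n_dropped)
    ingest_external_segmentation.last_dropped = n_dropped  # type: ignore[attr-defined]
    return segments
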