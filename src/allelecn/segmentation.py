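"""Weighted circular binary segmentation and allelic-fraction refinement.

The log-ratio profile is cut recursively by maximizing the weighted
two-sample statistic over all circular arcs; breakpoints are accepted by a
permutation test. Germline heterozygous SNPs then refine the result:
borderline breakpoints without allelic support are pruned, copy-neutral LOH
change points invisible in coverage are split out, and Ward clustering
re-centers segments that share a copy-number state.

The ``segment_fn`` argument of :func:`segment_profile` is the plug-in point
for substituting an external segmentation algorithm.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

SUBCLONAL = "SUBCLONAL"

SIGMA_FLOOR = 1e-4


@dataclasses.dataclass(eq=False)
class Segment:
    """Contiguous run of retained targets with one copy-number state."""

    chrom: str
    tindex: np.ndarray  # global target indices (retained grid)
    gstart: int  # genomic start (0-based) of first member target
    gend: int  # genomic end (exclusive) of last member target
    values: np.ndarray  # member log-ratios
    weights: np.ndarray  # member target weights
    r: float = 0.0  # mean log-ratio
    sigma: float = SIGMA_FLOOR  # standard error of r
    snp_pos: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0, dtype=np.int64))
    snp_fracs: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))
    bp_pvalue: Optional[float] = None  # p-value of the breakpoint at this segment's left edge
    C: object = None  # int 0..7 or SUBCLONAL once assigned
    K: Optional[int] = None  # minor copy number
    loh: bool = False

    @property
    def num_targets(self) -> int:
        return len(self.tindex)

    @property
    def size(self) -> int:
        """Genomic length in bp (ploidy weighting)."""
        return self.gend - self.gstart

    @property
    def se(self) -> float:
        """Standard error of the segment mean log-ratio."""
        return self.sigma / math.sqrt(self.num_targets)

    def recompute_stats(self) -> None:
        """Mean log-ratio and per-target log-ratio SD (sigma, floored at 1e-4)."""
        w = self.weights
        m = float(np.average(self.values, weights=w))
        if len(self.values) > 1:
            var = float(np.average((self.values - m) ** 2, weights=w))
            var *= len(self.values) / (len(self.values) - 1)
            sd = math.sqrt(var)
        else:
            sd = 0.0
        self.r = m
        self.sigma = max(sd, SIGMA_FLOOR)


def _make_segment(chrom, tindex, starts, ends, values, weights, pvalue=None) -> Segment:
    seg = Segment(
        chrom=chrom,
        tindex=np.asarray(tindex),
        gstart=int(starts[0]),
        gend=int(ends[-1]),
        values=np.asarray(values, dtype=float),
        weights=np.asarray(weights, dtype=float),
        bp_pvalue=pvalue,
    )
    seg.recompute_stats()
    return seg


def _max_arc_stat(cx: np.ndarray, cw: np.ndarray, ii: np.ndarray, jj: np.ndarray):
    """Max |weighted two-sample statistic| over arcs (i, j] given cumsums."""
    total_x = cx[..., -1:]
    total_w = cw[..., -1:]
    a = cx[..., jj] - cx[..., ii]
    w1 = cw[..., jj] - cw[..., ii]
    b = total_x - a
    w2 = total_w - w1
    z = (a / w1 - b / w2) / np.sqrt(1.0 / w1 + 1.0 / w2)
    np.abs(z, out=z)
    k = np.argmax(z, axis=-1)
    zmax = np.take_along_axis(z, np.expand_dims(k, -1), axis=-1)[..., 0]
    return zmax, k


def _cbs_test(
    x: np.ndarray,
    w: np.ndarray,
    alpha: float,
    permutations: int,
    rng: np.random.Generator,
):
    """Permutation test for the best circular split of one segment.

    Returns (pvalue, (i, j)) where the arc (i, j] against its complement is
    the maximizing split, or (1.0, None) when no split is admissible. The
    p-value uses the add-one estimator with sequential early stopping: the
    test stops rejecting once the estimate is clearly above alpha, and stops
    accepting once no permuted statistic has reached the observed one over
    enough draws to resolve the alpha boundary.
    """
    n = len(x)
    if n < 2:
        return 1.0, None
    ii, jj = np.triu_indices(n, k=1)
    keep = (jj - ii) < n  # complement must be non-empty; always true for k>=1
    ii, jj = ii[keep], jj[keep]

    cx = np.concatenate([[0.0], np.cumsum(w * x)])
    cw = np.concatenate([[0.0], np.cumsum(w)])
    obs, k = _max_arc_stat(cx, cw, ii, jj)
    obs = float(obs)
    best = (int(ii[int(k)]), int(jj[int(k)]))

    exceed = 0
    done = 0
    block = 250
    while done < permutations:
        b = min(block, permutations - done)
        u = rng.random((b, n))
        order = np.argsort(u, axis=1)
        xs = x[order]
        ws = w[order]
        cxs = np.concatenate([np.zeros((b, 1)), np.cumsum(ws * xs, axis=1)], axis=1)
        cws = np.concatenate([np.zeros((b, 1)), np.cumsum(ws, axis=1)], axis=1)
        zmax, _ = _max_arc_stat(cxs, cws, ii, jj)
        exceed += int(np.sum(zmax >= obs - 1e-12))
        done += b
        phat = (exceed + 1) / (done + 1)
        if exceed >= 20 and phat > 2 * alpha:
            return phat, best  # clearly above alpha
        if exceed == 0 and done >= max(1000, min(permutations, int(2.0 / alpha))):
            return 1.0 / (done + 1), best
    return (exceed + 1) / (done + 1), best


def segment_cbs(
    profile,
    alpha: float = 0.001,
    permutations: int = 10_000,
    seed: int = 0,
    min_width: int = 2,
) -> list[Segment]:
    """Segment a LogRatioProfile by weighted circular binary segmentation.

    Returns segments tiling the retained targets of every chromosome, each
    carrying the permutation p-value of the breakpoint at its left edge
    (None at chromosome starts). sigma is the weighted SD of member
    log-ratios over sqrt(num_targets), floored at 1e-4.
    """
    rng = np.random.default_rng(seed)
    targets = profile.targets
    mask = profile.mask
    segments: list[Segment] = []
    tidx_all = np.flatnonzero(mask)
    chrom_arr = targets["chrom"].to_numpy()
    starts_all = targets["start"].to_numpy()
    ends_all = targets["end"].to_numpy()

    for chrom in dict.fromkeys(chrom_arr[tidx_all]):  # preserve order
        tidx = tidx_all[chrom_arr[tidx_all] == chrom]
        x = profile.r[tidx]
        w = profile.weights[tidx]
        cuts = _cbs_recurse(x, w, alpha, permutations, rng, min_width)
        bounds = [0] + sorted(cuts) + [len(tidx)]
        pvals = dict(cuts)
        for a, b in zip(bounds[:-1], bounds[1:]):
            sel = tidx[a:b]
            segments.append(
                _make_segment(
                    chrom, sel, starts_all[sel], ends_all[sel], x[a:b], w[a:b],
                    pvalue=pvals.get(a),
                )
            )
    return segments


def _cbs_recurse(x, w, alpha, permutations, rng, min_width, offset=0) -> dict[int, float]:
    """Recursive CBS on one chromosome; returns {cut position: p-value}."""
    n = len(x)
    if n < 2 * min_width or np.allclose(x, x[0]):
        return {}
    p, best = _cbs_test(x, w, alpha, permutations, rng)
    if best is None or p > alpha:
        return {}
    i, j = best
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    if not cuts:
        return {}
    out = {offset + c: p for c in cuts}
    bounds = [0] + cuts + [n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.update(
            _cbs_recurse(x[a:b], w[a:b], alpha, permutations, rng, min_width, offset + a)
        )
    return out


def mirrored(f: np.ndarray) -> np.ndarray:
    """Fold allelic fractions around 0.5: min(f, 1 - f)."""
    f = np.asarray(f, dtype=float)
    return np.minimum(f, 1.0 - f)


def select_het_snps(variants_df, targets, flank: int = 50):
    """Heterozygous germline SNP candidates for segmentation refinement.

    dbSNP members with allelic fraction in [0.1, 0.9] located within a target
    or its 50 bp flank. Returns (positions, mirrored fractions, chroms),
    position-sorted within chromosome.
    """
    if variants_df is None or len(variants_df) == 0:
        import pandas as pd

        empty = np.empty(0)
        return np.empty(0, dtype=np.int64), empty, np.empty(0, dtype=object)
    df = variants_df
    cand = df[(df["in_dbsnp"]) & (df["f"] >= 0.1) & (df["f"] <= 0.9)]
    keep = []
    t_by_chrom = {c: g for c, g in targets.groupby("chrom", sort=False)}
    for idx, row in cand.iterrows():
        g = t_by_chrom.get(row["chrom"])
        if g is None:
            continue
        pos0 = row["pos"] - 1
        hit = np.searchsorted(g["start"].to_numpy() - flank, pos0, side="right") - 1
        if hit >= 0 and pos0 < g["end"].to_numpy()[hit] + flank:
            keep.append(idx)
    sel = df.loc[keep]
    return (
        sel["pos"].to_numpy() - 1,
        mirrored(sel["f"].to_numpy()),
        sel["chrom"].to_numpy(),
    )


def attach_snps(segments: Sequence[Segment], snp_pos, snp_mirr, snp_chrom) -> None:
    """Assign het-SNP mirrored fractions to their covering segments (50 bp flanks)."""
    for seg in segments:
        sel = (
            (snp_chrom == seg.chrom)
            & (snp_pos >= seg.gstart - 50)
            & (snp_pos < seg.gend + 50)
        )
        order = np.argsort(snp_pos[sel], kind="stable")
        seg.snp_pos = snp_pos[sel][order]
        seg.snp_fracs = snp_mirr[sel][order]


def _merge_pair(left: Segment, right: Segment) -> Segment:
    seg = Segment(
        chrom=left.chrom,
        tindex=np.concatenate([left.tindex, right.tindex]),
        gstart=left.gstart,
        gend=right.gend,
        values=np.concatenate([left.values, right.values]),
        weights=np.concatenate([left.weights, right.weights]),
        bp_pvalue=left.bp_pvalue,
    )
    seg.recompute_stats()
    order = np.argsort(np.concatenate([left.snp_pos, right.snp_pos]), kind="stable")
    seg.snp_pos = np.concatenate([left.snp_pos, right.snp_pos])[order]
    seg.snp_fracs = np.concatenate([left.snp_fracs, right.snp_fracs])[order]
    return seg


def prune_breakpoints(
    segments: Sequence[Segment],
    alpha_keep: float = 0.001,
    p_merge: float = 0.2,
    min_snps: int = 3,
) -> list[Segment]:
    """Remove borderline breakpoints without allelic-fraction support.

    A breakpoint with CBS p-value > *alpha_keep* is removed (its flanking
    segments merged) when the mirrored allelic fractions of the two sides are
    not significantly different (Welch two-sided t-test p > *p_merge*), or
    when either side has fewer than *min_snps* SNPs. Breakpoints at or below
    *alpha_keep* are always kept.
    """
    out: list[Segment] = []
    for seg in segments:
        if (
            out
            and out[-1].chrom == seg.chrom
            and seg.bp_pvalue is not None
            and seg.bp_pvalue > alpha_keep
        ):
            left = out[-1]
            if len(left.snp_fracs) < min_snps or len(seg.snp_fracs) < min_snps:
                different = False
            else:
                _, p = stats.ttest_ind(left.snp_fracs, seg.snp_fracs, equal_var=False)
                different = bool(p <= p_merge)
            if not different:
                out[-1] = _merge_pair(left, seg)
                continue
        out.append(seg)
    return out


def split_cnloh(
    segments: Sequence[Segment],
    alpha_loh: float = 0.005,
    min_snps: int = 10,
) -> list[Segment]:
    """Split segments at copy-neutral LOH change points found in allelic fractions.

    Within each segment the candidate split minimizing the pooled SD of
    mirrored fractions (each side keeping >= *min_snps* SNPs) is accepted when
    a Welch two-sided t-test between the sides reaches *alpha_loh*; accepted
    halves are recursed. Children keep the parent's mean log-ratio (the split
    is copy-neutral by construction).
    """
    out: list[Segment] = []
    for seg in segments:
        out.extend(_split_recurse(seg, alpha_loh, min_snps))
    return out


def _split_recurse(seg: Segment, alpha_loh: float, min_snps: int) -> list[Segment]:
    m = len(seg.snp_fracs)
    if m < 2 * min_snps:
        return [seg]
    f = seg.snp_fracs
    best_k, best_sd = None, np.inf
    for k in range(min_snps, m - min_snps + 1):
        a, b = f[:k], f[k:]
        pooled = math.sqrt((k * a.var() + (m - k) * b.var()) / m)
        if pooled < best_sd:
            best_sd, best_k = pooled, k
    a, b = f[:best_k], f[best_k:]
    _, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(p) or p > alpha_loh:
        return [seg]
    cut_pos = (seg.snp_pos[best_k - 1] + seg.snp_pos[best_k]) // 2 + 1
    t_starts = getattr(seg, "_target_starts", None)
    if t_starts is None:
        # fall back: split targets proportionally to the SNP cut position
        frac = (cut_pos - seg.gstart) / max(seg.gend - seg.gstart, 1)
        n_left = int(round(frac * seg.num_targets))
        n_left = min(max(n_left, 1), seg.num_targets - 1)
    else:
        n_left = int(np.searchsorted(t_starts, cut_pos))
        n_left = min(max(n_left, 1), seg.num_targets - 1)
    if seg.num_targets < 2:
        return [seg]

    def child(sl_t, sl_s) -> Segment:
        c = Segment(
            chrom=seg.chrom,
            tindex=seg.tindex[sl_t],
            gstart=seg.gstart if sl_t.start == 0 else int(cut_pos),
            gend=seg.gend if sl_t.stop == seg.num_targets else int(cut_pos),
            values=seg.values[sl_t],
            weights=seg.weights[sl_t],
            bp_pvalue=seg.bp_pvalue if sl_t.start == 0 else 0.0,
        )
        c.recompute_stats()
        c.r = seg.r  # copy-neutral split: children keep the parent's log-ratio
        c.snp_pos = seg.snp_pos[sl_s]
        c.snp_fracs = seg.snp_fracs[sl_s]
        return c

    left = child(slice(0, n_left), slice(0, best_k))
    right = child(slice(n_left, seg.num_targets), slice(best_k, m))
    return _split_recurse(left, alpha_loh, min_snps) + _split_recurse(right, alpha_loh, min_snps)


def merge_ward(segments: Sequence[Segment], noise_scale: Optional[float] = None) -> list[Segment]:
    """Ward-cluster segments in (log-ratio, mirrored fraction) space.

    Segments in one cluster are assigned the cluster's target-weighted mean
    log-ratio; genomic boundaries are unchanged. Segments without SNPs use a
    mirrored-fraction mean of 0.5. The tree is cut at 0.5 x *noise_scale*
    (default: the mean standard error of the segment means).
    """
    segments = list(segments)
    if len(segments) < 2:
        return segments
    if noise_scale is None:
        noise_scale = float(np.mean([s.se for s in segments]))
    from scipy.cluster.hierarchy import fcluster, linkage

    feats = np.array(
        [
            [s.r, float(np.mean(s.snp_fracs)) if len(s.snp_fracs) else 0.5]
            for s in segments
        ]
    )
    link = linkage(feats, method="ward")
    labels = fcluster(link, t=0.5 * max(noise_scale, 1e-6), criterion="distance")
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        nt = np.array([segments[i].num_targets for i in idx], dtype=float)
        mean_r = float(np.average([segments[i].r for i in idx], weights=nt))
        for i in idx:
            segments[i].r = mean_r
    return segments


SegmentFn = Callable[..., list[Segment]]


def segment_profile(
    profile,
    variants_df=None,
    alpha: float = 0.001,
    permutations: int = 10_000,
    seed: int = 0,
    prune_alpha_keep: float = 0.001,
    prune_p_merge: float = 0.2,
    alpha_loh: float = 0.005,
    min_snps_loh: int = 10,
    ward_noise_scale: Optional[float] = None,
    segment_fn: Optional[SegmentFn] = None,
) -> list[Segment]:
    """Full segmentation stage: CBS (or a plug-in), prune, LOH split, Ward merge."""
    fn = segment_fn or segment_cbs
    segments = fn(profile, alpha=alpha, permutations=permutations, seed=seed)
    # annotate member target starts so copy-neutral splits can cut the grid
    starts_all = profile.targets["start"].to_numpy()
    for seg in segments:
        seg._target_starts = starts_all[seg.tindex]
    if variants_df is not None and len(variants_df):
        pos, mirr, chroms = select_het_snps(variants_df, profile.targets)
        attach_snps(segments, pos, mirr, chroms)
    segments = prune_breakpoints(segments, prune_alpha_keep, prune_p_merge)
    for seg in segments:
        seg._target_starts = starts_all[seg.tindex]
    segments = split_cnloh(segments, alpha_loh, min_snps_loh)
    segments = merge_ward(segments, ward_noise_scale)
    return segments
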