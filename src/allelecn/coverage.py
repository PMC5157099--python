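"""GC normalization, pool-of-normals database and log-ratio computation.

The pool of normals serves three purposes: selecting a best process-matched
normal for a tumor (Euclidean distance on the first three principal
components of GC-normalized, scale-capped coverage), down-weighting targets
whose coverage is unstable across normals (segmentation weights proportional
to the inverse coverage-ratio standard deviation), and masking targets with
low median coverage (below 20% of their chromosome's median).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

SEX_CHROMS_X = {"chrX", "X"}
SEX_CHROMS_Y = {"chrY", "Y"}


def gc_normalize(
    coverage: np.ndarray,
    gc_fraction: np.ndarray,
    span: float = 0.3,
    min_bin_count: int = 50,
    max_bins: int = 40,
) -> np.ndarray:
    """Remove the GC-content trend from a coverage vector.

    The trend is estimated as the running median of coverage over
    equal-frequency GC bins (*span* caps the bin fraction of the data, so the
    effective smoothing window is comparable to a loess span); coverage is
    divided by its bin's median and rescaled to preserve the sample mean.
    Because the median of a rescaled bin is the rescaled median, the
    operation is exactly idempotent. Zero-coverage targets stay zero.
    """
    coverage = np.asarray(coverage, dtype=float)
    gc = np.asarray(gc_fraction, dtype=float)
    nz = (coverage > 0) & np.isfinite(gc)
    if not nz.any():
        raise ValueError("all-zero coverage: nothing to normalize")
    if nz.sum() < 100:
        log.warning("only %d nonzero targets for GC normalization", int(nz.sum()))

    y = coverage[nz].astype(float)
    x = gc[nz]
    n = len(y)
    n_bins = int(np.clip(n // min_bin_count, 1, min(max_bins, max(int(1 / span), 1) * 10)))
    # equal-frequency bins over the observed GC range
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    trend = np.empty(n)
    for b in range(n_bins):
        sel = which == b
        med = np.median(y[sel]) if sel.any() else y.mean()
        trend[sel] = max(med, 1e-12)
    target_mean = y.mean()
    y = y / trend
    y *= target_mean / y.mean()

    out = np.zeros_like(coverage)
    out[nz] = y
    # targets with coverage but unknown GC pass through unchanged
    other = (coverage > 0) & ~nz
    out[other] = coverage[other]
    return out


@dataclasses.dataclass
class NormalDB:
    """Pool-of-normals database on a fixed target grid."""

    sample_ids: list[str]
    matrix: np.ndarray  # targets x normals, GC-normalized coverage
    target_median: np.ndarray  # per-target median coverage across normals
    ratio_sd: np.ndarray  # per-target SD of coverage ratios vs pool median
    weights: np.ndarray  # per-target segmentation weight, mean 1 over retained
    mask: np.ndarray  # True for retained targets (low-coverage rule)
    chroms: np.ndarray  # per-target chromosome names
    pca_components: np.ndarray  # (3, targets) basis on capped, centered coverage
    pca_mean: np.ndarray  # per-target centering used by the PCA
    pca_scores: np.ndarray  # normals x 3 projections
    cap: float = 100.0
    schema_version: int = 1

    @property
    def n_normals(self) -> int:
        return self.matrix.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            schema_version=self.schema_version,
            sample_ids=np.asarray(self.sample_ids, dtype=str),
            matrix=self.matrix,
            target_median=self.target_median,
            ratio_sd=self.ratio_sd,
            weights=self.weights,
            mask=self.mask,
            chroms=np.asarray(self.chroms, dtype=str),
            pca_components=self.pca_components,
            pca_mean=self.pca_mean,
            pca_scores=self.pca_scores,
            cap=self.cap,
        )

    @classmethod
    def load(cls, path) -> "NormalDB":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                sample_ids=[str(s) for s in z["sample_ids"]],
                matrix=z["matrix"],
                target_median=z["target_median"],
                ratio_sd=z["ratio_sd"],
                weights=z["weights"],
                mask=z["mask"],
                chroms=z["chroms"],
                pca_components=z["pca_components"],
                pca_mean=z["pca_mean"],
                pca_scores=z["pca_scores"],
                cap=float(z["cap"]),
                schema_version=int(z["schema_version"]),
            )


def _cap_scale(vec: np.ndarray, cap: float) -> np.ndarray:
    """Rescale a coverage vector so its maximum equals *cap*.

    Scaling both up and down makes normal selection invariant to global
    sequencing depth.
    """
    m = vec.max()
    if m <= 0:
        return vec.copy()
    return vec * (cap / m)


def build_normaldb(
    normal_coverages: np.ndarray,
    chroms: Sequence[str],
    sample_ids: Optional[Sequence[str]] = None,
    cap: float = 100.0,
    weight_ceiling: float = 3.0,
    low_coverage_fraction: float = 0.2,
) -> NormalDB:
    """Build the pool-of-normals database from GC-normalized coverage.

    *normal_coverages* is targets x normals. Weights are proportional to the
    inverse per-target SD of coverage ratios (each normal against the pool
    median), clipped at *weight_ceiling* after scaling to mean 1 and then
    renormalized to mean 1. Targets whose median coverage falls below
    ``low_coverage_fraction`` of their chromosome's median are masked out.
    """
    mat = np.asarray(normal_coverages, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need >=2 normal samples to build a pool-of-normals DB")
    n_targets, n_normals = mat.shape
    if sample_ids is None:
        sample_ids = [f"normal{i + 1}" for i in range(n_normals)]
    chroms = np.asarray(chroms)
    if len(chroms) != n_targets:
        raise ValueError("chroms length does not match coverage matrix")

    # bring samples to a common scale first so weights are invariant to
    # per-sample sequencing depth, then compare each to the pool median
    col_means = mat.mean(axis=0)
    if np.any(col_means <= 0):
        raise ValueError("normal sample with non-positive mean coverage")
    norm_mat = mat / col_means[None, :]
    target_median = np.median(norm_mat, axis=1) * col_means.mean()

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = norm_mat / np.maximum(np.median(norm_mat, axis=1), 1e-12)[:, None]
    ratio_sd = ratios.std(axis=1, ddof=1)
    ratio_sd[np.median(norm_mat, axis=1) <= 0] = np.inf

    finite = np.isfinite(ratio_sd)
    max_sd = ratio_sd[finite].max() if finite.any() else 0.0
    if max_sd <= 1e-12:  # degenerate pool (e.g. identical normals)
        weights = np.ones(n_targets)
    else:
        w = 1.0 / np.maximum(ratio_sd, 1e-12)
        w[~np.isfinite(w)] = 0.0
        if w.mean() <= 0:
            weights = np.ones(n_targets)
        else:
            w = w / w.mean()
            w = np.minimum(w, weight_ceiling)
            w = np.maximum(w, 1e-6)
            weights = w / w.mean()

    # low-coverage mask: strict < at the 20% rule
    mask = np.ones(n_targets, dtype=bool)
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        chrom_median = np.median(target_median[sel])
        # strict < at the threshold, with a guard for float round-off
        mask[sel] = target_median[sel] >= low_coverage_fraction * chrom_median * (1 - 1e-12)
    # renormalize weights over retained targets to mean 1
    if mask.any() and weights[mask].mean() > 0:
        weights = weights / weights[mask].mean()

    from sklearn.decomposition import PCA

    capped = np.stack([_cap_scale(mat[:, j], cap) for j in range(n_normals)], axis=0)
    n_comp = min(3, n_normals, n_targets)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(capped)
    components = pca.components_
    if n_comp < 3:  # pad to a fixed 3-component basis
        components = np.vstack([components, np.zeros((3 - n_comp, n_targets))])
        scores = np.hstack([scores, np.zeros((n_normals, 3 - n_comp))])

    return NormalDB(
        sample_ids=list(sample_ids),
        matrix=mat,
        target_median=target_median,
        ratio_sd=ratio_sd,
        weights=weights,
        mask=mask,
        chroms=chroms,
        pca_components=components,
        pca_mean=pca.mean_,
        pca_scores=scores,
        cap=cap,
    )


def select_best_normal(
    tumor_coverage: np.ndarray, db: NormalDB, n_best: int = 1
) -> tuple[list[str], np.ndarray]:
    """Pick the n_best pool normals closest to the tumor on the PCA basis.

    Returns the selected sample ids and the reference coverage: the single
    best normal, or for n_best > 1 the average of the selected normals
    weighted inversely by PC-space distance.
    """
    if db.n_normals == 0:
        raise ValueError("empty normal database")
    n_best = min(n_best, db.n_normals)
    capped = _cap_scale(np.asarray(tumor_coverage, dtype=float), db.cap)
    proj = db.pca_components @ (capped - db.pca_mean)
    dist = np.linalg.norm(db.pca_scores - proj[None, :], axis=1)
    order = np.argsort(dist, kind="stable")[:n_best]
    ids = [db.sample_ids[i] for i in order]
    if n_best == 1:
        return ids, db.matrix[:, order[0]].copy()
    d = dist[order]
    if np.any(d < 1e-12):
        w = (d < 1e-12).astype(float)
    else:
        w = 1.0 / d
    w = w / w.sum()
    return ids, db.matrix[:, order] @ w


@dataclasses.dataclass
class LogRatioProfile:
    """Per-target log2 tumor/reference coverage ratios with weights and mask."""

    targets: pd.DataFrame  # chrom/start/end/gc rows aligned with vectors
    r: np.ndarray  # log-ratio; NaN at masked targets
    weights: np.ndarray
    mask: np.ndarray  # True for retained targets
    sex: str = UNKNOWN


def compute_log_ratios(
    tumor: np.ndarray,
    reference: np.ndarray,
    db: Optional[NormalDB] = None,
    targets: Optional[pd.DataFrame] = None,
    sex: str = UNKNOWN,
) -> LogRatioProfile:
    """Mean-centered log2 tumor/reference ratios on retained targets.

    Targets where the reference has zero coverage are additionally masked
    with a logged count. Without a pool of normals the weights are all one
    and no low-coverage mask applies.
    """
    tumor = np.asarray(tumor, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = len(tumor)
    mask = db.mask.copy() if db is not None else np.ones(n, dtype=bool)
    weights = db.weights.copy() if db is not None else np.ones(n)

    zero_ref = mask & (reference <= 0)
    if zero_ref.any():
        log.info("masking %d targets with zero reference coverage", int(zero_ref.sum()))
        mask &= reference > 0
    mask &= tumor > 0

    r = np.full(n, np.nan)
    t_mean = tumor[mask].mean()
    ref_mean = reference[mask].mean()
    r[mask] = np.log2((tumor[mask] / t_mean) / (reference[mask] / ref_mean))
    return LogRatioProfile(targets=targets, r=r, weights=weights, mask=mask, sex=sex)


def detect_sex(coverage: np.ndarray, chroms: Sequence[str]) -> str:
    """Call sample sex from relative sex-chromosome coverage.

    male: mean chrY coverage > 25% of the autosomal mean and chrX < 75%;
    female: chrY < 5% and chrX >= 75%; anything else (including missing sex
    chromosomes) is unknown and treated as female downstream, with a warning.
    """
    chroms = np.asarray(chroms)
    coverage = np.asarray(coverage, dtype=float)
    is_x = np.isin(chroms, list(SEX_CHROMS_X))
    is_y = np.isin(chroms, list(SEX_CHROMS_Y))
    is_auto = ~is_x & ~is_y
    if not is_x.any() or not is_auto.any():
        log.warning("no chrX or autosomal targets: sex unknown")
        return UNKNOWN
    auto_mean = coverage[is_auto].mean()
    if auto_mean <= 0:
        return UNKNOWN
    x_frac = coverage[is_x].mean() / auto_mean
    y_frac = coverage[is_y].mean() / auto_mean if is_y.any() else None
    if y_frac is not None and y_frac > 0.25 and x_frac < 0.75:
        return MALE
    if y_frac is not None and y_frac < 0.05 and x_frac >= 0.75:
        return FEMALE
    if y_frac is None:
        log.warning("no chrY targets: sex unknown")
    return UNKNOWN
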