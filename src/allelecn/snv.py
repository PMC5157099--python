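"""Somatic/germline SNV classification by allelic fraction.

The expected allelic fraction of a variant is
``E[f] = (p*M + g*(1-p)) / (p*C + 2*(1-p))`` for purity p, segment copy
number C, multiplicity M (chromosome copies carrying the variant) and
germline indicator g. Observed fractions are scored with a beta likelihood
``Beta(E[f] | n*f + 1, n*(1-f) + 1)`` and combined with priors over C
(segment copy posterior), K (flat minor-copy prior), M (the karyotype-aware
multiplicity prior) and g (database-informed somatic prior) into a
normalized per-variant state posterior. Optional states model DNA
contamination from unrelated individuals and, in 100%-pure samples, truly
homozygous germline SNPs.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .cnfit import COPY_MAX, PURITY_GRID, Solution, assignment_ploidy
from .segmentation import SUBCLONAL, Segment
from .variants import GERMLINE, SOMATIC, UNKNOWN

SUBCLONAL_M = 1.0 / 3.0  # expected average cellular fraction of sub-clonal mutations

STATE_CONTAMINATION_REF = "CONTAMINATION_REF"
STATE_CONTAMINATION_ALT = "CONTAMINATION_ALT"
STATE_GERMLINE_HOM = "GERMLINE_HOMOZYGOUS"


@dataclasses.dataclass
class PriorConfig:
    """All tunable priors of the SNV model (every field config-exposed)."""

    matched_somatic: float = 0.999
    matched_germline: float = 0.0001
    unmatched_cosmic: float = 0.95  # COSMIC count > 2, not in dbSNP
    unmatched_dbsnp: float = 0.0005
    unmatched_both: float = 0.01
    unmatched_novel: float = 0.5
    p_k: float = 0.999
    contamination_rate: float = 0.01
    contamination_prior: float = 0.01
    hom_prior: float = 0.05
    error_rate: float = 1e-3 / 3.0
    max_depth: int = 300
    low_purity_threshold: float = 0.35


def expected_af(p: float, C: float, M: float, g: int) -> float:
    """Expected allelic fraction for purity p, copy number C, multiplicity M, germline g."""
    den = p * C + 2.0 * (1.0 - p)
    if den <= 0:
        raise ValueError(f"expected allelic fraction undefined: p={p}, C={C}")
    return (p * M + g * (1.0 - p)) / den


def af_loglik(f_obs: float, n: int, e_f, n_cap: int = 300):
    """Beta log-likelihood of an expected fraction given observed counts.

    The depth is capped at *n_cap* so that small unmodeled biases at very
    high coverage cannot dominate the likelihood.
    """
    n_eff = min(int(n), n_cap)
    if n_eff < 1:
        raise ValueError("depth must be >= 1")
    a = n_eff * f_obs + 1.0
    b = n_eff * (1.0 - f_obs) + 1.0
    with np.errstate(divide="ignore"):
        return stats.beta.logpdf(e_f, a, b)


def _allowed_multiplicities(C: int, K: int, g: int) -> list[float]:
    if g == 1:
        return sorted({float(K), float(C - K)})
    allowed = {float(m) for m in (K, C - K, 1) if 1 <= m <= C}
    allowed.add(SUBCLONAL_M)
    return sorted(allowed)


def multiplicity_prior(M: float, K: int, C: int, g: int, p_k: float = 0.999) -> float:
    """Prior P(M | K, C, g): karyotype states carry P_K, the rest share 1 - P_K.

    When every state in the support is a karyotype-allowed state the allowed
    states carry all the mass (1/n_s each), keeping the prior normalized.
    """
    if K > C // 2:
        return 0.0
    allowed = _allowed_multiplicities(C, K, g)
    n_s = len(allowed)
    if g == 1:
        support = C + 1  # M in 0..C
        in_support = float(M).is_integer() and 0 <= M <= C
    else:
        support = C + 1  # M in 1..C plus the sub-clonal M=1/3
        in_support = (float(M).is_integer() and 1 <= M <= C) or M == SUBCLONAL_M
    if not in_support:
        return 0.0
    n_disallowed = support - n_s
    if any(abs(M - a) < 1e-12 for a in allowed):
        return (1.0 / n_s) if n_disallowed == 0 else (p_k / n_s)
    return (1.0 - p_k) / n_disallowed


def somatic_prior(variant, matched: bool, priors: Optional[PriorConfig] = None) -> float:
    """Prior probability that a variant is somatic, from database evidence."""
    priors = priors or PriorConfig()
    status = getattr(variant, "matched_status", None)
    if status is None:  # pandas row
        status = variant["matched_status"]
        in_dbsnp = bool(variant["in_dbsnp"])
        cosmic = int(variant["cosmic_count"])
    else:
        in_dbsnp = variant.in_dbsnp
        cosmic = variant.cosmic_count
    if matched and status != UNKNOWN:
        return priors.matched_somatic if status == SOMATIC else priors.matched_germline
    if cosmic > 2 and in_dbsnp:
        return priors.unmatched_both
    if cosmic > 2:
        return priors.unmatched_cosmic
    if in_dbsnp:
        return priors.unmatched_dbsnp
    return priors.unmatched_novel


@lru_cache(maxsize=8)
def _state_table(p_k: float):
    """Static (C, g, M) state table with prior mass summed over K.

    Returns arrays (C, g, M, log_prior) where log_prior already includes the
    flat P(K) = 1/(C+1) and the multiplicity prior.
    """
    rows: dict[tuple[int, int, float], float] = {}
    for C in range(COPY_MAX + 1):
        pk_flat = 1.0 / (C + 1)
        for K in range(C // 2 + 1):
            for g in (0, 1):
                for M in _m_support(C, g):
                    pm = multiplicity_prior(M, K, C, g, p_k)
                    if pm > 0:
                        rows[(C, g, M)] = rows.get((C, g, M), 0.0) + pk_flat * pm
    keys = sorted(rows)
    C_arr = np.array([k[0] for k in keys], dtype=int)
    g_arr = np.array([k[1] for k in keys], dtype=int)
    M_arr = np.array([k[2] for k in keys])
    logp = np.log(np.array([rows[k] for k in keys]))
    return C_arr, g_arr, M_arr, logp


def _m_support(C: int, g: int):
    if g == 1:
        return [float(m) for m in range(C + 1)]
    return [float(m) for m in range(1, C + 1)] + [SUBCLONAL_M]


def _expected_af_vec(p: float, C: np.ndarray, M: np.ndarray, g: np.ndarray) -> np.ndarray:
    den = p * C + 2.0 * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = (p * M + g * (1.0 - p)) / den
    ef[den <= 1e-12] = np.nan  # impossible state (all DNA lost)
    return ef


@dataclasses.dataclass
class SNVStatePosterior:
    """Posterior over SNV states for one variant."""

    states: list  # (g, M, C) tuples or special-state names
    posterior: np.ndarray
    ml_state: object
    p_somatic: float
    cellular_fraction: Optional[float]  # clipped at 1 for reporting
    cellular_fraction_raw: Optional[float]
    max_loglik: float
    flags: set


def classify_variants(
    vdf: pd.DataFrame,
    seg_index: np.ndarray,
    seg_posteriors: np.ndarray,
    purity: float,
    priors: Optional[PriorConfig] = None,
    matched: bool = False,
    high_purity_mode: bool = False,
    return_posterior: bool = False,
):
    """Vectorized per-variant state posteriors for one solution.

    *seg_index* maps each variant to its segment row in *seg_posteriors*
    (segments x 9 copy-state posterior; the subclonal column is folded back
    into the integer states by renormalization); variants with seg_index -1
    lie outside all segments and are returned flagged and unclassified.

    Returns one row per variant with the posterior summaries, ML state,
    multiplicity, cellular fraction and per-variant maximum state
    log-likelihood (the quantity summed into the SNV fit likelihood).
    """
    priors = priors or PriorConfig()
    p = purity
    C_s, g_s, M_s, logp_s = _state_table(priors.p_k)
    ef_s = _expected_af_vec(p, C_s.astype(float), M_s, g_s.astype(float))

    V = len(vdf)
    n_cap = np.minimum(vdf["n"].to_numpy(), priors.max_depth).astype(float)
    f = vdf["f"].to_numpy()
    a = n_cap * f + 1.0
    b = n_cap * (1.0 - f) + 1.0

    mapped = seg_index >= 0
    pc_rows = np.full((V, COPY_MAX + 1), np.nan)
    if mapped.any():
        pc = seg_posteriors[seg_index[mapped], : COPY_MAX + 1]
        pc = pc / np.maximum(pc.sum(axis=1, keepdims=True), 1e-300)
        pc_rows[mapped] = pc
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pc = np.log(pc_rows)

    ps = np.array([somatic_prior(row, matched, priors) for _, row in vdf.iterrows()])
    with np.errstate(divide="ignore"):
        log_pg = np.where(g_s[None, :] == 0, np.log(ps)[:, None], np.log(1.0 - ps)[:, None])

    with np.errstate(divide="ignore", invalid="ignore"):
        beta_ll = stats.beta.logpdf(ef_s[None, :], a[:, None], b[:, None])
    beta_ll = np.where(np.isnan(beta_ll), -np.inf, beta_ll)

    logw = log_pc[:, C_s] + logp_s[None, :] + log_pg + beta_ll  # (V, S)

    special_names = []
    special_cols = []
    in_db = vdf["in_dbsnp"].to_numpy().astype(bool)
    c_rate = priors.contamination_rate
    Cint = np.arange(COPY_MAX + 1, dtype=float)
    den = p * Cint + 2.0 * (1.0 - p)
    ok = den > 1e-12
    ef7 = np.full_like(den, np.nan)
    ef8 = np.full_like(den, np.nan)
    ef7[ok] = (p * Cint[ok] + 2.0 * (1.0 - p - c_rate)) / den[ok]
    ef8[ok] = c_rate / den[ok]
    for name, ef_c in ((STATE_CONTAMINATION_REF, ef7), (STATE_CONTAMINATION_ALT, ef8)):
        with np.errstate(divide="ignore", invalid="ignore"):
            bl = stats.beta.logpdf(np.clip(ef_c, 0.0, 1.0)[None, :], a[:, None], b[:, None])
        bl = np.where(np.isnan(bl), -np.inf, bl)
        col = logsumexp(log_pc + bl, axis=1) + math.log(priors.contamination_prior)
        col = np.where(in_db, col, -np.inf)  # admitted for dbSNP variants only
        special_names.append(name)
        special_cols.append(col)
    if high_purity_mode and not matched:
        n_ref = np.round(n_cap * (1.0 - f)).astype(int)
        hom_ll = stats.binom.logpmf(n_ref, n_cap.astype(int), priors.error_rate)
        special_cols.append(hom_ll + math.log(priors.hom_prior))
        special_names.append(STATE_GERMLINE_HOM)

    all_logw = np.concatenate([logw] + [c[:, None] for c in special_cols], axis=1)
    all_logw[~mapped] = -np.inf

    norm = logsumexp(all_logw, axis=1)
    with np.errstate(invalid="ignore"):
        post = np.exp(all_logw - norm[:, None])

    # ML state with ties broken toward germline
    n_model = logw.shape[1]
    pref = np.zeros(all_logw.shape[1])
    pref[:n_model][g_s == 1] = 1e-9
    pref[n_model:] = 1e-9  # special states are germline bins
    ml_idx = np.argmax(all_logw + pref[None, :], axis=1)

    somatic_cols = g_s == 0
    p_somatic = post[:, :n_model][:, somatic_cols].sum(axis=1)

    ml_is_model = ml_idx < n_model
    ml_C = np.where(ml_is_model, C_s[np.minimum(ml_idx, n_model - 1)], -1)
    ml_M = np.where(ml_is_model, M_s[np.minimum(ml_idx, n_model - 1)], np.nan)
    ml_g = np.where(ml_is_model, g_s[np.minimum(ml_idx, n_model - 1)], 1)
    ml_state = [
        (int(g_s[i]), float(M_s[i]), int(C_s[i])) if i < n_model else special_names[i - n_model]
        for i in ml_idx
    ]

    ml_somatic = ml_is_model & (ml_g == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_raw = (f / ml_M) * (p * ml_C + 2.0 * (1.0 - p)) / p
    h_raw = np.where(ml_somatic, h_raw, np.nan)
    h = np.minimum(h_raw, 1.0)

    # expected fraction of the ML state (for goodness of fit)
    ef_ml = np.full(V, np.nan)
    for i, s in enumerate(ml_state):
        if not mapped[i]:
            continue
        if isinstance(s, tuple):
            g, M, C = s
            ef_ml[i] = expected_af(p, C, M, g)
        elif s == STATE_CONTAMINATION_REF:
            cml = int(np.argmax(pc_rows[i]))
            ef_ml[i] = min(max(ef7[cml], 0.0), 1.0)
        elif s == STATE_CONTAMINATION_ALT:
            cml = int(np.argmax(pc_rows[i]))
            ef_ml[i] = min(max(ef8[cml], 0.0), 1.0)
        else:
            ef_ml[i] = 1.0

    max_ll = np.max(all_logw, axis=1)
    out = pd.DataFrame(
        {
            "chrom": vdf["chrom"].to_numpy(),
            "pos": vdf["pos"].to_numpy(),
            "ref": vdf["ref"].to_numpy(),
            "alt": vdf["alt"].to_numpy(),
            "f": f,
            "n": vdf["n"].to_numpy(),
            "prior_somatic": ps,
            "segment": seg_index,
            "ML.SOMATIC": ml_somatic,
            "ML.STATE": [str(s) for s in ml_state],
            "ML.C": ml_C,
            "ML.M": ml_M,
            "posterior_somatic": p_somatic,
            "expected_f": ef_ml,
            "CELLFRACTION": h,
            "CELLFRACTION.RAW": h_raw,
            "max_loglik": max_ll,
            "evidence": norm,  # log marginal likelihood (Eq. 5 denominator)
            "FLAG.OUTSIDE_SEGMENTS": ~mapped,
            "FLAG.CELLFRACTION_GT1": np.where(ml_somatic, h_raw > 1.0 + 1e-9, False),
        }
    )
    if return_posterior:
        labels = [
            (int(g), float(M), int(C)) for g, M, C in zip(g_s, M_s, C_s)
        ] + special_names
        return out, post, labels
    return out


def variant_posterior(
    variant,
    segment_posterior: np.ndarray,
    purity: float,
    priors: Optional[PriorConfig] = None,
    matched: bool = False,
    high_purity_mode: bool = False,
) -> SNVStatePosterior:
    """Posterior over states for a single variant (thin wrapper for one row)."""
    from .variants import variants_frame

    vdf = variants_frame([variant])
    seg_post = np.asarray(segment_posterior, dtype=float)
    if seg_post.ndim == 1:
        if len(seg_post) == COPY_MAX + 1:
            seg_post = np.concatenate([seg_post, [0.0]])
        seg_post = seg_post[None, :]
    row = classify_variants(
        vdf, np.array([0]), seg_post, purity, priors, matched, high_purity_mode
    ).iloc[0]
    priors = priors or PriorConfig()
    C_s, g_s, M_s, _ = _state_table(priors.p_k)
    states = [(int(g), float(M), int(C)) for g, M, C in zip(g_s, M_s, C_s)]
    return SNVStatePosterior(
        states=states,
        posterior=np.array([row["posterior_somatic"], 1 - row["posterior_somatic"]]),
        ml_state=row["ML.STATE"],
        p_somatic=float(row["posterior_somatic"]),
        cellular_fraction=None if np.isnan(row["CELLFRACTION"]) else float(row["CELLFRACTION"]),
        cellular_fraction_raw=(
            None if np.isnan(row["CELLFRACTION.RAW"]) else float(row["CELLFRACTION.RAW"])
        ),
        max_loglik=float(row["max_loglik"]),
        flags=set(),
    )


def filter_variants(
    vdf: pd.DataFrame,
    matched: bool = False,
    high_purity_mode: bool = False,
    priors: Optional[PriorConfig] = None,
    pool_fracs: Optional[np.ndarray] = None,
    pool_depths: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove homozygous and mapping-biased variants before fitting.

    Homozygous: matched mode removes normal fraction > 0.9, unmatched removes
    tumor fraction > 0.95; in high-purity mode nothing is removed (the model
    gains a homozygous state instead). Mapping bias: variants whose matched
    normal fraction has a two-sided beta tail probability < 0.05 around the
    expected 0.5, or (with a pool of >= 5 informative normals) that are
    biased in at least half of them.
    """
    priors = priors or PriorConfig()
    V = len(vdf)
    removed_hom = np.zeros(V, dtype=bool)
    removed_bias = np.zeros(V, dtype=bool)

    if not high_purity_mode:
        if matched:
            nf = vdf["normal_f"].to_numpy()
            removed_hom = np.nan_to_num(nf, nan=0.0) > 0.9
        else:
            removed_hom = vdf["f"].to_numpy() > 0.95

    def _biased(frac, depth):
        n = np.minimum(depth, priors.max_depth)
        a = n / 2.0 + 1.0
        b = n / 2.0 + 1.0
        cdf = stats.beta.cdf(frac, a, b)
        return 2.0 * np.minimum(cdf, 1.0 - cdf) < 0.05

    if matched:
        nf = vdf["normal_f"].to_numpy()
        nn = vdf["normal_n"].to_numpy()
        has = np.isfinite(nf) & (nn > 0)
        het = has & (nf > 0.05) & (nf <= 0.9)  # only informative heterozygous normals
        if het.any():
            removed_bias[het] = _biased(nf[het], nn[het])
    elif pool_fracs is not None and pool_depths is not None:
        informative = np.isfinite(pool_fracs) & (pool_depths > 0)
        enough = informative.sum(axis=1) >= 5
        biased = np.zeros_like(pool_fracs, dtype=bool)
        ok = informative
        biased[ok] = _biased(pool_fracs[ok], pool_depths[ok])
        frac_biased = np.where(
            informative.sum(axis=1) > 0,
            biased.sum(axis=1) / np.maximum(informative.sum(axis=1), 1),
            0.0,
        )
        removed_bias = enough & (frac_biased >= 0.5)

    keep = ~(removed_hom | removed_bias)
    flags = pd.DataFrame(
        {
            "removed_homozygous": removed_hom,
            "removed_mapping_bias": removed_bias,
            "depth_capped": vdf["n"].to_numpy() > priors.max_depth,
        },
        index=vdf.index,
    )
    return vdf[keep].reset_index(drop=True), flags


def map_variants_to_segments(vdf: pd.DataFrame, segments: Sequence[Segment]) -> np.ndarray:
    """Segment row index per variant (position within span +/- 50 bp flank), -1 if none."""
    idx = np.full(len(vdf), -1, dtype=int)
    chrom = vdf["chrom"].to_numpy()
    pos0 = vdf["pos"].to_numpy() - 1
    for si, seg in enumerate(segments):
        sel = (idx < 0) & (chrom == seg.chrom) & (pos0 >= seg.gstart - 50) & (pos0 < seg.gend + 50)
        idx[sel] = si
    return idx


def snv_loglik(variant_table: pd.DataFrame) -> float:
    """SNV fit likelihood: sum of the most likely state's log-likelihood per variant."""
    if variant_table is None or len(variant_table) == 0:
        return 0.0
    ll = variant_table["max_loglik"].to_numpy()
    return float(ll[np.isfinite(ll)].sum())


def assign_minor_copy(
    segments: Sequence[Segment],
    solution: Solution,
    vdf: Optional[pd.DataFrame],
    seg_index: Optional[np.ndarray],
    priors: Optional[PriorConfig] = None,
) -> None:
    """Assign the minor copy number K per segment and set the LOH flag.

    K maximizes the germline-SNP likelihood under random phasing
    (a 50/50 mixture of M = K and M = C - K). Segments without informative
    SNPs fall back to the balanced K = floor(C/2). A segment is in LOH iff
    C = 1 or K = 0.
    """
    priors = priors or PriorConfig()
    p = solution.purity
    if vdf is not None and len(vdf):
        hsel = vdf["in_dbsnp"].to_numpy() & (vdf["f"].to_numpy() >= 0.1) & (vdf["f"].to_numpy() <= 0.9)
    solution.K = []
    for si, seg in enumerate(segments):
        C = solution.C[si]
        if C == SUBCLONAL or C is None:
            seg.C, seg.K, seg.loh = SUBCLONAL, None, False
            solution.K.append(None)
            continue
        C = int(C)
        K = C // 2
        if vdf is not None and len(vdf) and seg_index is not None:
            sel = hsel & (seg_index == si)
            if sel.any():
                f = vdf["f"].to_numpy()[sel]
                n = np.minimum(vdf["n"].to_numpy()[sel], priors.max_depth)
                best, best_ll = K, -np.inf
                for k in range(C // 2 + 1):
                    ef1 = expected_af(p, C, k, 1)
                    ef2 = expected_af(p, C, C - k, 1)
                    l1 = stats.beta.logpdf(ef1, n * f + 1, n * (1 - f) + 1)
                    l2 = stats.beta.logpdf(ef2, n * f + 1, n * (1 - f) + 1)
                    ll = float(np.logaddexp(l1 + math.log(0.5), l2 + math.log(0.5)).sum())
                    if ll > best_ll + 1e-9 or (abs(ll - best_ll) <= 1e-9 and k > best):
                        best, best_ll = k, ll
                K = best
        seg.C, seg.K = C, K
        seg.loh = C == 1 or K == 0
        solution.K.append(K)


def post_optimize(
    solution: Solution,
    segments: Sequence[Segment],
    vdf: pd.DataFrame,
    seg_index: np.ndarray,
    priors: Optional[PriorConfig] = None,
    matched: bool = False,
    high_purity_mode: bool = False,
) -> Solution:
    """Re-optimize purity over the grid using copy number and allelic fractions.

    Evaluates the copy-number log-likelihood plus the SNV marginal
    log-likelihood (the state-sum normalizer, so purity enters through the
    full posterior rather than only the best states) over the purity grid
    with the segment assignment fixed, replaces purity by the argmax and
    refreshes assignments and posteriors once. Off by default in the
    pipeline.
    """
    from .cnfit import (
        SUBCLONAL_COL,
        _assignment_loglik_over_grid,
        _loglik_matrix,
        _seg_arrays,
    )

    priors = priors or PriorConfig()
    r, sig, nt, l = _seg_arrays(segments)
    C_cols = np.array(
        [SUBCLONAL_COL if c == SUBCLONAL else int(c) for c in solution.C]
    )
    D = assignment_ploidy(C_cols, l, solution.ploidy)
    cn_grid = _assignment_loglik_over_grid(r, sig, nt, C_cols, PURITY_GRID, D, solution.shift)

    totals = np.empty(len(PURITY_GRID))
    for i, p in enumerate(PURITY_GRID):
        tbl = classify_variants(vdf, seg_index, solution.posteriors, p, priors, matched, high_purity_mode)
        ev = tbl["evidence"].to_numpy()
        totals[i] = cn_grid[i] + float(ev[np.isfinite(ev)].sum())
    best_p = float(PURITY_GRID[int(np.argmax(totals))])

    M = _loglik_matrix(r, sig, nt, best_p, D, solution.shift)
    new_C = M.argmax(axis=1)
    D = assignment_ploidy(new_C, l, solution.ploidy)
    M = _loglik_matrix(r, sig, nt, best_p, D, solution.shift)
    post = np.exp(M - M.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)

    solution.purity = best_p
    solution.ploidy = D
    solution.C = [SUBCLONAL if c == SUBCLONAL_COL else int(c) for c in new_C]
    solution.posteriors = post
    solution.cn_loglik = float(M[np.arange(len(new_C)), new_C].sum())
    tbl = classify_variants(vdf, seg_index, post, best_p, priors, matched, high_purity_mode)
    solution.variant_table = tbl
    solution.variant_loglik = tbl["max_loglik"].to_numpy()
    solution.snv_loglik = snv_loglik(tbl)
    return solution
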