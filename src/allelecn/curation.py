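"""Solution ranking, goodness of fit, bootstrap re-ranking and curation flags."""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnfit import Solution
from .segmentation import SUBCLONAL, Segment

WORST_FIT_DEVIATION = 0.2  # mean |f_obs - E[f]| anchoring GoF = 0%


@dataclasses.dataclass
class FlagThresholds:
    """Config-exposed thresholds behind every curation flag."""

    noisy_sigma: float = 0.25
    rare_ploidy_low: float = 1.5
    rare_ploidy_high: float = 4.5
    excessive_loh: float = 0.9
    excessive_hom_loss: float = 0.05
    non_aberrant: float = 0.01
    polygenomic: float = 0.2
    contamination: float = 0.02
    low_gof: float = 75.0


@dataclasses.dataclass
class CurationReport:
    solutions: list  # ranked, non-discarded first; rank 1 = best total loglik
    flags: set
    needs_curation: bool


def goodness_of_fit(variant_table: pd.DataFrame) -> float:
    """SNV fit quality in percent: 100 at perfect fit, 0 at mean deviation 0.2.

    The deviation is the mean absolute difference between observed allelic
    fractions and the expectation of each variant's most likely state.
    """
    ok = np.isfinite(variant_table["expected_f"].to_numpy())
    if not ok.any():
        raise ValueError("no variants with a fitted state: GoF undefined")
    d = float(
        np.mean(
            np.abs(
                variant_table["f"].to_numpy()[ok] - variant_table["expected_f"].to_numpy()[ok]
            )
        )
    )
    return 100.0 * max(0.0, 1.0 - d / WORST_FIT_DEVIATION)


def bootstrap_rank(
    solutions: Sequence[Solution],
    replicates: int = 500,
    seed: int = 0,
    min_variants: int = 20,
    top: int = 2,
) -> list[Solution]:
    """Re-rank solutions over variant resamples; drop never-competitive optima.

    Each replicate resamples variants with replacement and re-ranks by
    copy-number plus resampled SNV log-likelihood. A solution's bootstrap
    value is the fraction of replicates it ranks first; solutions never in
    the top *top* are removed. With fewer than *min_variants* variants the
    procedure is skipped with a flag.
    """
    solutions = [s for s in solutions if not s.discarded]
    if len(solutions) == 1:
        solutions[0].bootstrap_value = 1.0
        return solutions
    mat = np.stack([s.variant_loglik for s in solutions], axis=1)  # V x S
    V = mat.shape[0]
    if V < min_variants:
        for s in solutions:
            s.flags.add("too few variants for bootstrap")
        return list(solutions)
    cn = np.array([s.cn_loglik for s in solutions])
    rng = np.random.default_rng(seed)
    first = np.zeros(len(solutions))
    ever_top = np.zeros(len(solutions), dtype=bool)
    for _ in range(replicates):
        idx = rng.integers(0, V, size=V)
        totals = cn + mat[idx].sum(axis=0)
        order = np.argsort(-totals, kind="stable")
        first[order[0]] += 1
        ever_top[order[:top]] = True
    first /= replicates
    kept = []
    for i, s in enumerate(solutions):
        s.bootstrap_value = float(first[i])
        if ever_top[i]:
            kept.append(s)
    kept.sort(key=lambda s: -s.total_loglik)
    if kept and kept[0].bootstrap_value is not None and kept[0].bootstrap_value < 0.95:
        for s in kept:
            s.flags.add("ambiguous solutions")
    return kept


def flag_sample(
    solution: Solution,
    segments: Sequence[Segment],
    thresholds: Optional[FlagThresholds] = None,
    contamination_fraction: Optional[float] = None,
) -> set:
    """Quality and plausibility flags for the maximum-likelihood solution."""
    t = thresholds or FlagThresholds()
    flags: set[str] = set()
    sig = np.array([s.sigma for s in segments])
    if sig.mean() > t.noisy_sigma:
        flags.add("NOISY_SEGMENTATION")
    if solution.ploidy < t.rare_ploidy_low or solution.ploidy > t.rare_ploidy_high:
        flags.add("RARE_PLOIDY")
    lengths = np.array([s.size for s in segments], dtype=float)
    total = lengths.sum()
    if total > 0:
        loh_len = sum(s.size for s in segments if s.loh)
        if loh_len / total > t.excessive_loh:
            flags.add("EXCESSIVE_LOH")
        hom_len = sum(
            s.size for si, s in enumerate(segments) if solution.C[si] == 0
        )
        if hom_len / total > t.excessive_hom_loss:
            flags.add("EXCESSIVE_HOMOZYGOUS_LOSS")
        aberrant_len = sum(
            s.size
            for si, s in enumerate(segments)
            if not (solution.C[si] == 2 and (s.K is None or s.K == 1))
        )
        if aberrant_len / total < t.non_aberrant:
            flags.add("NON_ABERRANT")
        sub_len = sum(
            s.size for si, s in enumerate(segments) if solution.C[si] == SUBCLONAL
        )
        if sub_len / total > t.polygenomic:
            flags.add("POLYGENOMIC")
    if contamination_fraction is not None and contamination_fraction >= t.contamination:
        flags.add("CONTAMINATION")
    if solution.gof is not None and solution.gof < t.low_gof:
        flags.add("LOW_GOF")
    solution.flags |= flags
    return flags


def rank_solutions(
    solutions: Sequence[Solution],
    low_purity_threshold: float = 0.35,
    equalize_low_purity_haploid: bool = True,
) -> list[Solution]:
    """Sort by total log-likelihood, best first; discarded solutions excluded.

    With *equalize_low_purity_haploid* (default), a leading near-haploid
    solution at low purity loses its rank to a near-diploid alternative when
    the log-likelihood gap is smaller than log(2): in low-purity samples a
    missing chromosome barely unbalances germline fractions, so haploid and
    diploid solutions are given the same effective prior.
    """
    ranked = sorted(
        (s for s in solutions if not s.discarded), key=lambda s: -s.total_loglik
    )
    if (
        equalize_low_purity_haploid
        and len(ranked) >= 2
        and ranked[0].purity < low_purity_threshold
        and ranked[0].ploidy < 1.5
    ):
        for j, alt in enumerate(ranked[1:], start=1):
            if 1.5 <= alt.ploidy < 2.5 and ranked[0].total_loglik - alt.total_loglik < np.log(2):
                ranked.insert(0, ranked.pop(j))
                break
    for i, s in enumerate(ranked):
        s.rank = i + 1
    return ranked
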