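"""End-to-end pipeline: normalize, segment, fit, classify, rank, write.

Stages are deterministic given the run config's single seed, which fans out
to per-stage seeds by fixed offsets. Stage results are cached under the
output prefix keyed by a hash of the config and input files, so re-running
an identical configuration is a per-stage no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cnfit, coverage, curation, io, segmentation, snv
from .intervals import read_intervals, targets_frame
from .variants import read_variants, variants_frame

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Every tunable default of the pipeline; serialized into each run."""

    seed: int = 0
    matched: bool = False
    high_purity_mode: bool = False
    post_optimize: bool = False
    # coverage normalization
    gc_span: float = 0.3
    n_best_normals: int = 1
    normaldb_cap: float = 100.0
    weight_ceiling: float = 3.0
    low_coverage_fraction: float = 0.2
    # segmentation
    cbs_alpha: float = 0.01
    cbs_permutations: int = 10_000
    prune_alpha_keep: float = 0.001
    prune_p_merge: float = 0.2
    alpha_loh: float = 0.005
    min_snps_loh: int = 10
    segmentation_plugin: str = "cbs"
    # purity/ploidy search
    min_purity: float = 0.15
    max_purity: float = 0.95
    purity_step: float = 0.05
    min_ploidy: float = 1.0
    max_ploidy: float = 6.0
    ploidy_step: float = 0.1
    max_candidates: int = 20
    max_copy: int = 7
    use_logsumexp: bool = False
    # SNV model
    priors: snv.PriorConfig = dataclasses.field(default_factory=snv.PriorConfig)
    equalize_low_purity_haploid: bool = True
    # curation
    bootstrap_replicates: int = 500
    flag_thresholds: curation.FlagThresholds = dataclasses.field(
        default_factory=curation.FlagThresholds
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        priors = snv.PriorConfig(**d.pop("priors", {}))
        flags = curation.FlagThresholds(**d.pop("flag_thresholds", {}))
        return cls(priors=priors, flag_thresholds=flags, **d)


@dataclasses.dataclass
class RunInputs:
    intervals: object  # path or list of TargetInterval
    tumor_coverage: object  # path or vector
    normal_coverages: Optional[list] = None  # paths or matrix
    normaldb: Optional[object] = None  # path or NormalDB
    vcf: Optional[object] = None  # path or list of VariantObservation
    seg: Optional[object] = None  # path or DataFrame: external segmentation
    sample_id: str = "sample"


@dataclasses.dataclass
class RunResult:
    report: curation.CurationReport
    best: cnfit.Solution
    segments: list
    variant_table: Optional[pd.DataFrame]
    sex: str
    config: RunConfig
    output_paths: dict


def _config_hash(config: RunConfig, inputs: RunInputs) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(config.to_dict(), sort_keys=True, default=str).encode())
    for attr in ("intervals", "tumor_coverage", "normal_coverages", "normaldb", "vcf", "seg"):
        val = getattr(inputs, attr)
        paths = val if isinstance(val, (list, tuple)) else [val]
        for v in paths:
            if isinstance(v, (str, Path)) and Path(v).exists():
                h.update(Path(v).read_bytes())
            else:
                h.update(repr(type(v)).encode())
    return h.hexdigest()


class _StageCache:
    """Per-stage pickle cache keyed by the run hash."""

    def __init__(self, prefix: Optional[Path], run_hash: str):
        self.dir = Path(str(prefix) + ".cache") if prefix is not None else None
        self.run_hash = run_hash
        if self.dir is not None:
            self.dir.mkdir(parents=True, exist_ok=True)

    def get(self, stage: str):
        if self.dir is None:
            return None
        f = self.dir / f"{stage}.pkl"
        if not f.exists():
            return None
        try:
            with open(f, "rb") as fh:
                payload = pickle.load(fh)
        except Exception:
            return None
        if payload.get("hash") != self.run_hash:
            return None
        log.info("stage %s: cached result reused", stage)
        return payload["value"]

    def put(self, stage: str, value) -> None:
        if self.dir is None:
            return
        with open(self.dir / f"{stage}.pkl", "wb") as fh:
            pickle.dump({"hash": self.run_hash, "value": value}, fh)


def run_pipeline(
    config: RunConfig,
    inputs: RunInputs,
    out_prefix: Optional[object] = None,
) -> RunResult:
    """Execute the full pipeline and (optionally) write result files."""
    t0 = time.time()
    prefix = Path(out_prefix) if out_prefix is not None else None
    cache = _StageCache(prefix, _config_hash(config, inputs))
    seed = config.seed

    # --- inputs ---------------------------------------------------------
    intervals = (
        read_intervals(inputs.intervals)
        if isinstance(inputs.intervals, (str, Path))
        else list(inputs.intervals)
    )
    targets = targets_frame(intervals)
    gc = targets["gc"].to_numpy()
    chroms = targets["chrom"].to_numpy()

    vdf = None
    if inputs.vcf is not None:
        if isinstance(inputs.vcf, pd.DataFrame):
            vdf = inputs.vcf
        elif isinstance(inputs.vcf, (str, Path)):
            vdf = variants_frame(read_variants(inputs.vcf))
        else:
            vdf = variants_frame(list(inputs.vcf))

    # --- segmentation (or external SEG entry point) ---------------------
    if inputs.seg is not None:
        seg_df = (
            io.read_seg(inputs.seg) if isinstance(inputs.seg, (str, Path)) else inputs.seg
        )
        segments = cnfit.ingest_external_segmentation(seg_df, targets)
        sex = coverage.UNKNOWN
        log.info("external segmentation: %d segments (coverage stages skipped)", len(segments))
    else:
        segments, sex = cache.get("segmentation") or (None, None)
        if segments is None:
            segments, sex = _coverage_and_segmentation(config, inputs, intervals, targets, gc, chroms, vdf, seed)
            cache.put("segmentation", (segments, sex))
    if not segments:
        raise ValueError("no segments produced; inconsistent inputs?")

    # --- purity/ploidy fitting ------------------------------------------
    fit = cache.get("fit")
    if fit is None:
        purities = np.round(
            np.arange(config.min_purity, config.max_purity + 1e-9, config.purity_step), 4
        )
        ploidies = np.round(
            np.arange(config.min_ploidy, config.max_ploidy + 1e-9, config.ploidy_step), 4
        )
        optima = cnfit.grid_search(
            segments, purities, ploidies,
            max_candidates=config.max_candidates,
            use_logsumexp=config.use_logsumexp,
        )
        log.info("grid search: %d local optima", len(optima))
        solutions = [
            cnfit.fit_solution(segments, p, d, seed=seed + 100 + i)
            for i, (p, d, _) in enumerate(optima)
        ]
        # candidates that converged onto the same (purity, ploidy) are duplicates
        uniq: dict = {}
        for sol in solutions:
            key = (round(sol.purity, 4), round(sol.ploidy, 3), sol.discarded)
            if key not in uniq or sol.cn_loglik > uniq[key].cn_loglik:
                uniq[key] = sol
        solutions = list(uniq.values())
        cache.put("fit", solutions)
    else:
        solutions = fit

    # --- SNV fitting -----------------------------------------------------
    variant_table = None
    copy_number_only = vdf is None or len(vdf) == 0
    if not copy_number_only:
        fdf, _vflags = snv.filter_variants(
            vdf, matched=config.matched, high_purity_mode=config.high_purity_mode,
            priors=config.priors,
        )
        seg_index = snv.map_variants_to_segments(fdf, segments)
        for sol in solutions:
            tbl = snv.classify_variants(
                fdf, seg_index, sol.posteriors, sol.purity,
                priors=config.priors, matched=config.matched,
                high_purity_mode=config.high_purity_mode,
            )
            sol.variant_table = tbl
            sol.variant_loglik = tbl["max_loglik"].to_numpy()
            sol.snv_loglik = snv.snv_loglik(tbl)
        if config.post_optimize:
            for sol in solutions:
                snv.post_optimize(
                    sol, segments, fdf, seg_index, config.priors,
                    config.matched, config.high_purity_mode,
                )
    else:
        for sol in solutions:
            sol.flags.add("no variants")

    # --- ranking, bootstrap, flags --------------------------------------
    ranked = curation.rank_solutions(
        solutions,
        low_purity_threshold=config.priors.low_purity_threshold,
        equalize_low_purity_haploid=config.equalize_low_purity_haploid,
    )
    if not ranked:
        raise ValueError("all candidate solutions were discarded")
    if not copy_number_only and len(ranked) >= 2:
        ranked = curation.bootstrap_rank(
            ranked, replicates=config.bootstrap_replicates, seed=seed + 7
        )
        ranked = curation.rank_solutions(
            ranked,
            low_purity_threshold=config.priors.low_purity_threshold,
            equalize_low_purity_haploid=config.equalize_low_purity_haploid,
        )
    best = ranked[0]

    contamination_fraction = None
    if not copy_number_only:
        fdf2 = best.variant_table
        seg_index = fdf2["segment"].to_numpy()
        snv.assign_minor_copy(
            segments, best,
            fdf if not copy_number_only else None,
            seg_index, config.priors,
        )
        best.gof = curation.goodness_of_fit(best.variant_table)
        variant_table = best.variant_table
        in_db = fdf["in_dbsnp"].to_numpy()
        if in_db.any():
            contam = variant_table["ML.STATE"].str.startswith("CONTAMINATION").to_numpy()
            contamination_fraction = float(contam[in_db].sum() / in_db.sum())
    else:
        snv.assign_minor_copy(segments, best, None, None, config.priors)

    curation.flag_sample(best, segments, config.flag_thresholds, contamination_fraction)
    if copy_number_only:
        best.flags.add("copy-number-only")
    report = curation.CurationReport(
        solutions=ranked, flags=set(best.flags), needs_curation=bool(best.flags)
    )

    # --- outputs ---------------------------------------------------------
    output_paths: dict = {}
    if prefix is not None:
        output_paths = io.write_outputs(
            prefix, inputs.sample_id, best, segments, variant_table, report
        )
        config.to_yaml(Path(str(prefix) + "_config.yaml"))
        output_paths["config"] = Path(str(prefix) + "_config.yaml")
    log.info(
        "pipeline done in %.1fs: purity %.2f ploidy %.2f (%d solutions)",
        time.time() - t0, best.purity, best.ploidy, len(ranked),
    )
    return RunResult(
        report=report,
        best=best,
        segments=segments,
        variant_table=variant_table,
        sex=sex,
        config=config,
        output_paths=output_paths,
    )


def _coverage_and_segmentation(config, inputs, intervals, targets, gc, chroms, vdf, seed):
    """Stages GC-normalize -> pool -> log-ratios -> sex -> segmentation."""
    tumor_raw = (
        io.read_coverage(inputs.tumor_coverage, intervals)
        if isinstance(inputs.tumor_coverage, (str, Path))
        else np.asarray(inputs.tumor_coverage, dtype=float)
    )
    tumor = coverage.gc_normalize(tumor_raw, gc, span=config.gc_span)

    if inputs.normaldb is not None:
        db = (
            coverage.NormalDB.load(inputs.normaldb)
            if isinstance(inputs.normaldb, (str, Path))
            else inputs.normaldb
        )
    elif inputs.normal_coverages is not None:
        mats = []
        for nc in inputs.normal_coverages:
            vec = (
                io.read_coverage(nc, intervals)
                if isinstance(nc, (str, Path))
                else np.asarray(nc, dtype=float)
            )
            mats.append(coverage.gc_normalize(vec, gc, span=config.gc_span))
        if len(mats) == 1:
            db = None
            reference = mats[0]
        else:
            db = coverage.build_normaldb(
                np.stack(mats, axis=1), chroms,
                cap=config.normaldb_cap,
                weight_ceiling=config.weight_ceiling,
                low_coverage_fraction=config.low_coverage_fraction,
            )
    else:
        raise ValueError("need normal_coverages or a normaldb")
    if inputs.normaldb is not None or (inputs.normal_coverages and len(inputs.normal_coverages) > 1):
        ids, reference = coverage.select_best_normal(tumor, db, n_best=config.n_best_normals)
        log.info("best normal(s): %s", ",".join(ids))
    sex = coverage.detect_sex(tumor_raw, chroms)
    profile = coverage.compute_log_ratios(tumor, reference, db, targets, sex)

    # sex rule: males lose chrX and chrY from the model; everyone loses chrY
    drop = np.isin(chroms, list(coverage.SEX_CHROMS_Y))
    if sex == coverage.MALE:
        drop |= np.isin(chroms, list(coverage.SEX_CHROMS_X))
    profile.mask &= ~drop

    segments = segmentation.segment_profile(
        profile,
        vdf,
        alpha=config.cbs_alpha,
        permutations=config.cbs_permutations,
        seed=seed + 11,
        prune_alpha_keep=config.prune_alpha_keep,
        prune_p_merge=config.prune_p_merge,
        alpha_loh=config.alpha_loh,
        min_snps_loh=config.min_snps_loh,
    )
    log.info("segmentation: %d segments over %d targets", len(segments), int(profile.mask.sum()))
    return segments, sex
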