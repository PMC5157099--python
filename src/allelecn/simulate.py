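"""Synthetic tumor samples with known purity, ploidy and copy states.

The generator emulates a hybrid-capture benchmarking design: a
piecewise-constant integer copy-number genome is laid over a target grid,
normal coverage is scaled by ``(p*C + 2(1-p))/2`` and multiplied by
target-specific capture factors plus sampling noise, and allelic fractions
of germline SNPs (randomly phased to the maternal or paternal chromosome)
and somatic mutations are drawn binomially around their expected fractions.

Two stock designs are provided: exome-like (2,000 targets spread over 22
autosomes, 100x) and panel-like (560 gene clusters of small targets at
400x).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .variants import GERMLINE, SOMATIC

N_AUTOSOMES = 22


@dataclasses.dataclass
class SimulatedTruth:
    purity: float
    targets: pd.DataFrame  # chrom/start/end/gc
    seg_bounds: np.ndarray  # segment start indices into the target grid (+ end)
    C: np.ndarray  # per-segment total copy number
    K: np.ndarray  # per-segment minor copy number
    ploidy: float  # length-weighted mean copy number, exact
    seg_of_target: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.C)


@dataclasses.dataclass
class SimulatedSample:
    truth: SimulatedTruth
    tumor_coverage: np.ndarray
    reference_coverage: np.ndarray
    normal_pool: np.ndarray  # targets x normals
    variants: pd.DataFrame  # includes truth columns (true_status, true_M, ...)
    seed: int
    design: dict


def _make_targets(n_targets: int, design: str, rng: np.random.Generator) -> pd.DataFrame:
    chroms, starts, ends = [], [], []
    per_chrom = np.full(N_AUTOSOMES, n_targets // N_AUTOSOMES)
    per_chrom[: n_targets % N_AUTOSOMES] += 1
    for c in range(N_AUTOSOMES):
        name = f"chr{c + 1}"
        pos = 1_000_000
        n_c = int(per_chrom[c])
        if design == "panel":
            # genes of ~5 adjacent small targets separated by large gaps
            t = 0
            while t < n_c:
                gene_size = min(int(rng.integers(4, 8)), n_c - t)
                for _ in range(gene_size):
                    chroms.append(name)
                    starts.append(pos)
                    ends.append(pos + 120)
                    pos += 320
                    t += 1
                pos += 200_000
        else:
            for _ in range(n_c):
                chroms.append(name)
                starts.append(pos)
                ends.append(pos + 150)
                pos += 3_000
    gc = np.clip(rng.normal(0.45, 0.07, size=len(chroms)), 0.2, 0.8)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "gc": gc, "on_target": True}
    )


def simulate_genome(
    n_segments: int,
    n_targets: int,
    purity: float,
    target_ploidy: float,
    seed: int,
    design: str = "exome",
    min_targets: int = 5,
    ploidy_tol: float = 0.15,
    max_copy: int = 7,
    force_copy: Optional[int] = None,
) -> SimulatedTruth:
    """Draw a piecewise-constant integer copy-number genome.

    Segment lengths are log-normal in target counts (minimum *min_targets*);
    per-segment copy numbers are drawn around *target_ploidy* and adjusted by
    single-segment steps until the exact length-weighted mean is within
    *ploidy_tol* of the target. *force_copy* fixes every segment's copy
    number (degenerate flat genomes for tests).
    """
    rng = np.random.default_rng(seed)
    targets = _make_targets(n_targets, design, rng)

    # partition targets into segments, respecting chromosome boundaries
    chrom_sizes = targets.groupby("chrom", sort=False).size().to_numpy()
    mean_len = max(n_targets / n_segments, min_targets)
    bounds = [0]
    seg_chrom_end = np.cumsum(chrom_sizes)
    pos = 0
    while pos < n_targets:
        chrom_end = seg_chrom_end[np.searchsorted(seg_chrom_end, pos, side="right")]
        ln = max(min_targets, int(round(rng.lognormal(np.log(mean_len), 0.6))))
        nxt = min(pos + ln, chrom_end)
        if chrom_end - nxt < min_targets:
            nxt = chrom_end
        bounds.append(int(nxt))
        pos = nxt
    bounds = np.array(bounds)
    S = len(bounds) - 1
    lengths = np.empty(S)
    starts_arr = targets["start"].to_numpy()
    ends_arr = targets["end"].to_numpy()
    for i in range(S):
        lengths[i] = ends_arr[bounds[i + 1] - 1] - starts_arr[bounds[i]]

    if force_copy is not None:
        C = np.full(S, int(force_copy))
    else:
        C = np.clip(rng.poisson(target_ploidy, size=S), 0, max_copy)
        for attempt in range(20_000):
            ploidy = float(np.sum(lengths * C) / lengths.sum())
            if abs(ploidy - target_ploidy) <= ploidy_tol:
                break
            i = int(rng.integers(S))
            if ploidy < target_ploidy and C[i] < max_copy:
                C[i] += 1
            elif ploidy > target_ploidy and C[i] > 0:
                C[i] -= 1
        else:
            raise RuntimeError(
                f"could not reach target ploidy {target_ploidy} within tolerance"
            )
    K = np.array([rng.integers(0, c // 2 + 1) if c > 0 else 0 for c in C])
    ploidy = float(np.sum(lengths * C) / lengths.sum())

    seg_of_target = np.empty(n_targets, dtype=int)
    for i in range(S):
        seg_of_target[bounds[i] : bounds[i + 1]] = i
    return SimulatedTruth(
        purity=purity,
        targets=targets,
        seg_bounds=bounds,
        C=C,
        K=K,
        ploidy=ploidy,
        seg_of_target=seg_of_target,
    )


def simulate_coverage(
    truth: SimulatedTruth,
    depth: float,
    noise_cv: float = 0.2,
    seed: int = 0,
    n_normals: int = 4,
    gc_bias_sd: float = 0.4,
):
    """Tumor, reference and pool-of-normals coverage for a simulated genome.

    Reference coverage is depth times a target-specific capture factor
    (log-normal, CV *noise_cv*) shared by all samples; the tumor scales it by
    ``(p*C + 2(1-p))/2`` per target. Each sample adds independent log-normal
    sampling noise whose CV shrinks as sqrt(100/depth), and its own mild GC
    bias slope.
    """
    rng = np.random.default_rng(seed)
    p = truth.purity
    n = len(truth.targets)
    gc = truth.targets["gc"].to_numpy()

    sigma_cap = np.sqrt(np.log1p(noise_cv**2))
    capture = np.exp(rng.normal(0.0, sigma_cap, size=n))
    base = depth * capture

    cv_s = noise_cv * np.sqrt(100.0 / depth)
    sigma_s = np.sqrt(np.log1p(cv_s**2))

    def sample_noise():
        slope = rng.normal(0.0, gc_bias_sd)
        return np.exp(rng.normal(0.0, sigma_s, size=n)) * np.exp(slope * (gc - gc.mean()))

    ratio = (p * truth.C[truth.seg_of_target] + 2.0 * (1.0 - p)) / 2.0
    tumor = base * ratio * sample_noise()
    normals = np.stack([base * sample_noise() for _ in range(n_normals)], axis=1)
    reference = normals[:, 0]
    return tumor, reference, normals


def simulate_variants(
    truth: SimulatedTruth,
    depth: float,
    n_germline: Optional[int] = None,
    n_somatic: int = 100,
    subclonal_fraction: float = 0.2,
    seed: int = 0,
    dbsnp_fn_rate: float = 0.01,
    somatic_dbsnp_rate: float = 0.001,
    somatic_cosmic_rate: float = 0.05,
) -> pd.DataFrame:
    """Germline SNPs and somatic mutations with binomially sampled fractions.

    Germline SNPs sit on random targets, phased to one parental chromosome
    (multiplicity K or C-K); somatic mutations are clonal (M=1) except for a
    *subclonal_fraction* share carried at the model's average sub-clonal
    multiplicity M=1/3. Depths are Poisson around *depth*; alt counts are
    binomial around the expected fraction. dbSNP membership is true for
    germline up to a small false-negative rate and false for somatic up to a
    small overlap rate.
    """
    rng = np.random.default_rng(seed)
    p = truth.purity
    n_targets = len(truth.targets)
    if n_germline is None:
        n_germline = max(n_targets // 10, 1)

    starts = truth.targets["start"].to_numpy()
    ends = truth.targets["end"].to_numpy()
    chroms = truth.targets["chrom"].to_numpy()

    rows = []

    def emit(tidx, g, M, subclonal):
        seg = truth.seg_of_target[tidx]
        C = int(truth.C[seg])
        den = p * C + 2.0 * (1.0 - p)
        ef = (p * M + g * (1.0 - p)) / den if den > 0 else 0.0
        ef = min(max(ef, 0.0), 1.0)
        n = max(int(rng.poisson(depth)), 10)
        alt = int(rng.binomial(n, ef))
        pos = int((starts[tidx] + ends[tidx]) // 2) + 1  # 1-based
        if g == 1:
            in_db = rng.random() >= dbsnp_fn_rate
            cosmic = 0
        else:
            in_db = rng.random() < somatic_dbsnp_rate
            cosmic = int(rng.integers(3, 30)) if rng.random() < somatic_cosmic_rate else 0
        rows.append(
            {
                "chrom": chroms[tidx],
                "pos": pos,
                "ref": "A",
                "alt": "T",
                "f": alt / n,
                "n": n,
                "alt_count": alt,
                "in_dbsnp": bool(in_db),
                "cosmic_count": cosmic,
                "matched_status": "unknown",
                "normal_f": np.nan,
                "normal_n": 0,
                "true_status": GERMLINE if g == 1 else SOMATIC,
                "true_M": M,
                "true_subclonal": subclonal,
                "true_segment": int(seg),
                "true_C": C,
            }
        )

    germ_targets = rng.choice(n_targets, size=min(n_germline, n_targets), replace=False)
    for tidx in germ_targets:
        seg = truth.seg_of_target[tidx]
        C, K = int(truth.C[seg]), int(truth.K[seg])
        M = K if rng.random() < 0.5 else C - K  # random parental phase
        emit(int(tidx), 1, float(M), False)

    eligible = np.flatnonzero(truth.C[truth.seg_of_target] >= 1)
    if n_somatic > 0 and len(eligible) > 0:
        som_targets = rng.choice(eligible, size=n_somatic, replace=True)
        for tidx in som_targets:
            sub = rng.random() < subclonal_fraction
            emit(int(tidx), 0, 1.0 / 3.0 if sub else 1.0, sub)

    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        # avoid duplicate positions (two variants on one target)
        dup = df.duplicated(subset=["chrom", "pos"], keep=False)
        df.loc[dup, "pos"] += np.arange(dup.sum()) % 50
    return df


def simulate_sample(
    purity: float,
    target_ploidy: float,
    seed: int,
    design: str = "exome",
    n_targets: Optional[int] = None,
    depth: Optional[float] = None,
    n_segments: int = 40,
    n_somatic: int = 100,
    noise_cv: float = 0.2,
    n_normals: int = 4,
    subclonal_fraction: float = 0.2,
) -> SimulatedSample:
    """One complete synthetic tumor: genome, coverage, pool of normals, variants."""
    if n_targets is None:
        n_targets = 2000 if design == "exome" else 3000
    if depth is None:
        depth = 100.0 if design == "exome" else 400.0
    truth = simulate_genome(
        n_segments, n_targets, purity, target_ploidy, seed, design=design
    )
    tumor, reference, normals = simulate_coverage(
        truth, depth, noise_cv=noise_cv, seed=seed + 1_000_003, n_normals=n_normals
    )
    variants = simulate_variants(
        truth, depth, n_somatic=n_somatic, subclonal_fraction=subclonal_fraction,
        seed=seed + 2_000_003,
    )
    return SimulatedSample(
        truth=truth,
        tumor_coverage=tumor,
        reference_coverage=reference,
        normal_pool=normals,
        variants=variants,
        seed=seed,
        design={
            "design": design,
            "n_targets": n_targets,
            "depth": depth,
            "n_segments": truth.n_segments,
            "n_variants": len(variants),
        },
    )


def write_vcf(variants: pd.DataFrame, path, sample_id: str = "TUMOR") -> None:
    """Write simulated variants as a minimal VCFv4.2 with AD/DP and DB/Cnt INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">\n')
        fh.write('##INFO=<ID=Cnt,Number=1,Type=Integer,Description="COSMIC occurrence count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in range(1, N_AUTOSOMES + 1):
            fh.write(f"##contig=<ID=chr{c}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        rs = 1000
        for _, v in variants.iterrows():
            info = []
            if v["in_dbsnp"]:
                info.append("DB")
            if v["cosmic_count"] > 0:
                info.append(f"Cnt={int(v['cosmic_count'])}")
            vid = f"rs{rs}" if v["in_dbsnp"] else "."
            rs += 1
            alt = int(v.get("alt_count", round(v["f"] * v["n"])))
            ref_c = int(v["n"]) - alt
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v['ref']}\t{v['alt']}\t.\t.\t"
                f"{';'.join(info) or '.'}\tGT:AD:DP\t0/1:{ref_c},{alt}:{int(v['n'])}\n"
            )


def write_sample(sample: SimulatedSample, outdir, name: str = "sim") -> dict[str, Path]:
    """Write coverage TSVs, a VCF, an interval BED and a truth JSON for one sample."""
    from .intervals import TargetInterval, write_bed
    from .io import write_coverage

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = sample.truth.targets
    intervals = [
        TargetInterval(r.chrom, int(r.start), int(r.end), float(r.gc))
        for r in t.itertuples()
    ]
    paths: dict[str, Path] = {}
    paths["intervals"] = outdir / f"{name}_targets.bed"
    write_bed(intervals, paths["intervals"])
    paths["tumor"] = outdir / f"{name}_tumor_coverage.tsv"
    write_coverage(paths["tumor"], intervals, sample.tumor_coverage)
    for j in range(sample.normal_pool.shape[1]):
        key = f"normal{j + 1}"
        paths[key] = outdir / f"{name}_{key}_coverage.tsv"
        write_coverage(paths[key], intervals, sample.normal_pool[:, j])
    paths["vcf"] = outdir / f"{name}.vcf"
    write_vcf(sample.variants, paths["vcf"])
    truth = {
        "purity": sample.truth.purity,
        "ploidy": sample.truth.ploidy,
        "C": sample.truth.C.tolist(),
        "K": sample.truth.K.tolist(),
        "seg_bounds": sample.truth.seg_bounds.tolist(),
        "seed": sample.seed,
        "design": sample.design,
    }
    paths["truth"] = outdir / f"{name}_truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
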