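"""Coverage tables, SEG files and result writers.

Coverage input follows the GATK DepthOfCoverage ``sample_interval_summary``
dialect (rows keyed by 1-based ``chrom:start-end`` interval strings) or a
plain 4-column TSV (chrom, start, end, average_coverage; 0-based half-open),
auto-detected by header. SEG files use 1-based start coordinates, matching
how SEG output is commonly consumed downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import TargetInterval


class CoverageAlignmentError(ValueError):
    """Coverage rows do not match the loaded target set."""


def read_coverage(path, intervals: Sequence[TargetInterval]) -> np.ndarray:
    """Read per-target average coverage aligned to *intervals* (target order)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    lowered = [h.lower() for h in header]
    if "target" in lowered:  # GATK sample_interval_summary dialect
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        avg_col = next(c for c in df.columns if "average" in c or c == "mean_coverage")
        keys = df["target"].astype(str).values
        cov = df[avg_col].to_numpy(dtype=float)
    elif {"chrom", "start", "end"} <= set(lowered):
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        avg_col = next(c for c in df.columns if "coverage" in c)
        keys = (
            df["chrom"].astype(str) + ":" + (df["start"] + 1).astype(str) + "-" + df["end"].astype(str)
        ).values
        cov = df[avg_col].to_numpy(dtype=float)
    else:
        raise CoverageAlignmentError(f"{path}: unrecognized coverage header {header!r}")

    mapping: dict[str, float] = {}
    for k, v in zip(keys, cov):
        if k in mapping:
            raise CoverageAlignmentError(f"{path}: duplicate interval row {k}")
        mapping[k] = v
    wanted = [iv.key for iv in intervals]
    missing = [k for k in wanted if k not in mapping]
    if missing:
        head = ", ".join(missing[:5])
        raise CoverageAlignmentError(
            f"{path}: {len(missing)} target(s) missing from coverage file: {head}"
        )
    return np.array([mapping[k] for k in wanted], dtype=float)


def write_coverage(path, intervals: Sequence[TargetInterval], coverage: np.ndarray) -> None:
    """Write a GATK-dialect interval summary (total = average x width)."""
    with open(path, "w") as fh:
        fh.write("Target\ttotal_coverage\taverage_coverage\n")
        for iv, c in zip(intervals, coverage):
            fh.write(f"{iv.key}\t{c * len(iv):.8g}\t{c:.8g}\n")


SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file; returns columns ID/chrom/loc.start/loc.end/num.mark/seg.mean."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        c = col.lower().replace("_", ".")
        if c in {"id", "sample", "sampleid", "sample.id"}:
            rename[col] = "ID"
        elif c in {"chrom", "chromosome", "chr"}:
            rename[col] = "chrom"
        elif c in {"loc.start", "start"}:
            rename[col] = "loc.start"
        elif c in {"loc.end", "end"}:
            rename[col] = "loc.end"
        elif c in {"num.mark", "num.targets", "nummark"}:
            rename[col] = "num.mark"
        elif c in {"seg.mean", "segmean", "mean"}:
            rename[col] = "seg.mean"
    df = df.rename(columns=rename)
    missing = [c for c in SEG_COLUMNS if c not in df.columns and c != "num.mark"]
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {missing}")
    return df


def write_seg(path, seg: pd.DataFrame) -> None:
    cols = [c for c in SEG_COLUMNS if c in seg.columns]
    cols += [c for c in seg.columns if c not in cols]
    seg.to_csv(path, sep="\t", index=False, float_format="%.8g", columns=cols)


def write_outputs(
    path_prefix,
    sample_id: str,
    solution,
    segments,
    variant_table: Optional[pd.DataFrame],
    report=None,
) -> dict[str, Path]:
    """Write the SEG file, variant TSV and run summary for a ranked solution.

    Returns the paths written. The summary is emitted twice: a human-readable
    text file and a machine-readable key-value (YAML) file.
    """
    import yaml

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for seg in segments:
        c = seg.C
        rows.append(
            {
                "ID": sample_id,
                "chrom": seg.chrom,
                "loc.start": seg.gstart + 1,
                "loc.end": seg.gend,
                "num.mark": seg.num_targets,
                "seg.mean": seg.r,
                "C": "NA" if c is None else c,
                "K": "NA" if seg.K is None else seg.K,
                "LOH": bool(seg.loh),
            }
        )
    seg_path = prefix.with_suffix(".seg")
    write_seg(seg_path, pd.DataFrame(rows))
    paths["seg"] = seg_path

    if variant_table is not None:
        var_path = Path(str(prefix) + "_variants.tsv")
        variant_table.to_csv(var_path, sep="\t", index=False, float_format="%.6g")
        paths["variants"] = var_path

    flags = sorted(solution.flags)
    summary = {
        "sample": sample_id,
        "purity": round(float(solution.purity), 6),
        "ploidy": round(float(solution.ploidy), 6),
        "cn_loglik": round(float(solution.cn_loglik), 6),
        "snv_loglik": round(float(solution.snv_loglik), 6),
        "total_loglik": round(float(solution.total_loglik), 6),
        "gof_percent": None if solution.gof is None else round(float(solution.gof), 3),
        "bootstrap_value": (
            None if solution.bootstrap_value is None else round(float(solution.bootstrap_value), 4)
        ),
        "flags": flags,
        "needs_curation": bool(flags),
    }
    if report is not None:
        summary["n_solutions"] = len(report.solutions)
    yaml_path = Path(str(prefix) + "_summary.yaml")
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    paths["summary_yaml"] = yaml_path

    txt_path = Path(str(prefix) + "_summary.txt")
    with open(txt_path, "w") as fh:
        fh.write(f"Sample: {sample_id}\n")
        fh.write(f"Purity: {summary['purity']:.3f}\n")
        fh.write(f"Ploidy: {summary['ploidy']:.3f}\n")
        gof = summary["gof_percent"]
        fh.write(f"Goodness of fit: {'NA' if gof is None else f'{gof:.1f}%'}\n")
        fh.write(f"Log-likelihood (copy number): {summary['cn_loglik']:.3f}\n")
        fh.write(f"Log-likelihood (SNV): {summary['snv_loglik']:.3f}\n")
        fh.write(f"Log-likelihood (total): {summary['total_loglik']:.3f}\n")
        bv = summary["bootstrap_value"]
        fh.write(f"Bootstrap value: {'NA' if bv is None else f'{bv:.3f}'}\n")
        fh.write(f"Flags: {', '.join(flags) if flags else 'none'}\n")
        fh.write(f"Curation needed: {'yes' if flags else 'no'}\n")
    paths["summary_txt"] = txt_path
    return paths
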