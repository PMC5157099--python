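"""Target intervals: the per-target genomic grid of a capture assay.

All internal coordinates are 0-based half-open. BED input is taken as-is;
Picard interval lists (1-based closed) are converted on read.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class TargetInterval:
    """One captured target region.

    gc_fraction is the G+C fraction over the interval sequence, in [0, 1],
    or None when unknown. on_target distinguishes capture targets from
    auxiliary (e.g. off-target) bins; only on-target intervals enter the
    copy-number model.
    """

    chrom: str
    start: int
    end: int
    gc_fraction: Optional[float] = None
    on_target: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")

    @property
    def key(self) -> str:
        """GATK-style 1-based interval string, e.g. 'chr1:101-200'."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


class IntervalFormatError(ValueError):
    """Unknown or malformed interval file."""


class IntervalValidationError(ValueError):
    """Intervals unsorted or overlapping."""


def _chromosome_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), c)
    return (1, 0, c)


def validate_intervals(intervals: Sequence[TargetInterval]) -> None:
    """Check per-chromosome sorting and non-overlap; raise naming the first offender."""
    last: dict[str, TargetInterval] = {}
    for iv in intervals:
        prev = last.get(iv.chrom)
        if prev is not None:
            if iv.start < prev.start:
                raise IntervalValidationError(f"unsorted interval {iv.key} after {prev.key}")
            if iv.start < prev.end:
                raise IntervalValidationError(f"interval {iv.key} overlaps {prev.key}")
        last[iv.chrom] = iv


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T) over a sequence; ambiguous bases excluded from both counts."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("interval sequence contains no unambiguous bases")
    return gc / acgt


def read_intervals(path, reference=None) -> list[TargetInterval]:
    """Read a BED (0-based half-open) or Picard interval list (1-based closed).

    gc_fraction is taken from an optional numeric column (BED column 4, after
    name-less 3-column lines; interval-list column 6) when present, otherwise
    computed from *reference* (a pyfaidx.Fasta or any mapping of chrom to
    sequence) if one is given.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("track", "browser", "#"))
    ]
    if not lines:
        raise IntervalFormatError(f"{path}: empty interval file")

    picard = lines[0].startswith("@") or _looks_picard(lines)
    body = [ln for ln in lines if not ln.startswith("@")]

    intervals: list[TargetInterval] = []
    for ln in body:
        fields = ln.split("\t") if "\t" in ln else ln.split()
        if len(fields) < 3:
            raise IntervalFormatError(f"{path}: expected >=3 columns, got {ln!r}")
        chrom = fields[0]
        try:
            a, b = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise IntervalFormatError(f"{path}: non-numeric coordinates in {ln!r}") from exc
        if picard:
            start, end = a - 1, b
            gc = _maybe_float(fields[5]) if len(fields) > 5 else None
        else:
            start, end = a, b
            gc = _maybe_float(fields[3]) if len(fields) > 3 else None
        if gc is None and reference is not None:
            seq = str(reference[chrom][start:end])
            gc = gc_content(seq)
        intervals.append(TargetInterval(chrom, start, end, gc))

    # validate in file order (unsorted input is an input error, not repaired),
    # then order chromosomes canonically for the internal grid
    validate_intervals(intervals)
    intervals.sort(key=lambda iv: (_chromosome_sort_key(iv.chrom), iv.start))
    return intervals


def _looks_picard(lines: Iterable[str]) -> bool:
    for ln in lines:
        if ln.startswith("@"):
            return True
        fields = ln.split("\t") if "\t" in ln else ln.split()
        # interval list body: chrom start end strand name
        return len(fields) >= 5 and fields[3] in {"+", "-"}
    return False


def _maybe_float(s: str) -> Optional[float]:
    try:
        v = float(s)
    except ValueError:
        return None
    return v if 0.0 <= v <= 1.0 else None


def targets_frame(intervals: Sequence[TargetInterval]) -> pd.DataFrame:
    """Vectorized view of an interval list (one row per target, input order)."""
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": np.array([iv.start for iv in intervals], dtype=np.int64),
            "end": np.array([iv.end for iv in intervals], dtype=np.int64),
            "gc": np.array(
                [np.nan if iv.gc_fraction is None else iv.gc_fraction for iv in intervals]
            ),
            "on_target": [iv.on_target for iv in intervals],
        }
    )


def write_bed(intervals: Sequence[TargetInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            gc = "" if iv.gc_fraction is None else f"\t{iv.gc_fraction:.6g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{gc}\n")
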