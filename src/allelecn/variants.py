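"""SNV observations and VCF ingestion."""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SOMATIC = "somatic"
GERMLINE = "germline"
UNKNOWN = "unknown"


@dataclasses.dataclass
class VariantObservation:
    """One SNV with its allelic-fraction evidence.

    f is alt reads over total reads in the tumor; n the total read depth.
    matched_status comes from a matched-normal comparison and is 'unknown'
    whenever no matched normal was supplied.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    f: float
    n: int
    in_dbsnp: bool = False
    cosmic_count: int = 0
    matched_status: str = UNKNOWN
    normal_f: Optional[float] = None
    normal_n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"allelic fraction {self.f} outside [0, 1]")
        if self.n < 1:
            raise ValueError(f"depth {self.n} < 1")
        if self.cosmic_count < 0:
            raise ValueError("cosmic_count < 0")
        if self.matched_status not in (SOMATIC, GERMLINE, UNKNOWN):
            raise ValueError(f"bad matched_status {self.matched_status!r}")


def read_variants(
    path,
    tumor_sample: Optional[str] = None,
    normal_sample: Optional[str] = None,
    cosmic_key: str = "Cnt",
) -> list[VariantObservation]:
    """Read SNVs from a VCF (e.g. MuTect output) into VariantObservation records.

    Non-SNV records are skipped with a logged count. The tumor sample is the
    named one, or the only/first sample; a second sample (or *normal_sample*)
    provides matched-normal fractions and a somatic/germline matched_status.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: no sample columns in VCF")
    if tumor_sample is None:
        tumor_idx = 0
        if normal_sample is not None:
            tumor_idx = next(i for i, s in enumerate(samples) if s != normal_sample)
    else:
        if tumor_sample not in samples:
            raise ValueError(f"{path}: tumor sample {tumor_sample!r} not in VCF")
        tumor_idx = samples.index(tumor_sample)
    normal_idx = None
    if normal_sample is not None:
        normal_idx = samples.index(normal_sample)
    elif len(samples) == 2:
        normal_idx = 1 - tumor_idx

    out: list[VariantObservation] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"{path}: AD field missing at {rec.CHROM}:{rec.POS}")
        ref_c, alt_c = int(ad[tumor_idx][0]), int(ad[tumor_idx][1])
        n = ref_c + alt_c
        if n < 1:
            n_skipped += 1
            continue
        f = alt_c / n
        in_dbsnp = bool(rec.INFO.get("DB")) or (rec.ID is not None and rec.ID.startswith("rs"))
        cosmic = rec.INFO.get(cosmic_key)
        cosmic_count = int(cosmic) if cosmic is not None else 0

        status, nf, nn = UNKNOWN, None, None
        if normal_idx is not None:
            nref, nalt = int(ad[normal_idx][0]), int(ad[normal_idx][1])
            nn = nref + nalt
            nf = nalt / nn if nn > 0 else 0.0
            if rec.INFO.get("SOMATIC") is not None:
                status = SOMATIC
            else:
                status = SOMATIC if nf < 0.03 else GERMLINE
        out.append(
            VariantObservation(
                rec.CHROM, rec.POS, rec.REF, rec.ALT[0], f, n,
                in_dbsnp=in_dbsnp, cosmic_count=cosmic_count,
                matched_status=status, normal_f=nf, normal_n=nn,
            )
        )
    if n_skipped:
        log.info("skipped %d non-SNV or zero-depth records in %s", n_skipped, path)
    read_variants.last_skipped = n_skipped  # type: ignore[attr-defined]
    return out


def variants_frame(variants: Sequence[VariantObservation]) -> pd.DataFrame:
    """Tabular view of a variant list (one row per SNV, input order)."""
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": np.array([v.pos for v in variants], dtype=np.int64),
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "f": np.array([v.f for v in variants]),
            "n": np.array([v.n for v in variants], dtype=np.int64),
            "in_dbsnp": np.array([v.in_dbsnp for v in variants], dtype=bool),
            "cosmic_count": np.array([v.cosmic_count for v in variants], dtype=np.int64),
            "matched_status": [v.matched_status for v in variants],
            "normal_f": np.array(
                [np.nan if v.normal_f is None else v.normal_f for v in variants]
            ),
            "normal_n": np.array(
                [0 if v.normal_n is None else v.normal_n for v in variants], dtype=np.int64
            ),
        }
    )
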