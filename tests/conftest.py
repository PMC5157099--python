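import numpy as np
import pandas as pd
import pytest

from allelecn.coverage import LogRatioProfile
from allelecn.segmentation import Segment


def make_targets(n, chrom="chr1", start=1_000_000, width=150, gap=3_000):
    starts = start + np.arange(n) * gap
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": starts,
            "end": starts + width,
            "gc": np.full(n, 0.45),
            "on_target": True,
        }
    )


def make_profile(r, chrom="chr1", weights=None, targets=None):
    r = np.asarray(r, dtype=float)
    n = len(r)
    if targets is None:
        targets = make_targets(n, chrom=chrom)
    if weights is None:
        weights = np.ones(n)
    return LogRatioProfile(
        targets=targets, r=r, weights=np.asarray(weights, float),
        mask=np.ones(n, dtype=bool),
    )


def make_segment(r, sigma, num_targets, chrom="chr1", gstart=0, size=1_000_000,
                 snp_fracs=None, snp_pos=None, bp_pvalue=None):
    """Segment with prescribed summary stats (values crafted to match)."""
    values = np.full(num_targets, r)
    seg = Segment(
        chrom=chrom,
        tindex=np.arange(num_targets),
        gstart=gstart,
        gend=gstart + size,
        values=values,
        weights=np.ones(num_targets),
        bp_pvalue=bp_pvalue,
    )
    seg.r = float(r)
    seg.sigma = float(sigma)
    if snp_fracs is not None:
        seg.snp_fracs = np.asarray(snp_fracs, float)
        seg.snp_pos = (
            np.asarray(snp_pos)
            if snp_pos is not None
            else gstart + np.linspace(10, size - 10, len(seg.snp_fracs)).astype(np.int64)
        )
    return seg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
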