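"""Cohort-level benchmarking on synthetic samples.

Runs the full pipeline over cohorts of simulated tumors (exome-like: 2,000
targets at 100x; panel-like: 560-gene design, ~3,000 targets at 400x) with
purity uniform on [0.2, 0.8] and target ploidy uniform on [1, 6], and
reports truth-vs-estimate recovery and somatic/germline classification
accuracy.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .intervals import TargetInterval
from .pipeline import RunConfig, RunInputs, run_pipeline
from .variants import SOMATIC


def run_sample(sample, seed: int, config: Optional[RunConfig] = None):
    """Run the pipeline tumor-only on one SimulatedSample (in-memory I/O)."""
    t = sample.truth.targets
    intervals = [
        TargetInterval(r.chrom, int(r.start), int(r.end), float(r.gc))
        for r in t.itertuples()
    ]
    config = config or RunConfig()
    config.seed = seed
    inputs = RunInputs(
        intervals=intervals,
        tumor_coverage=sample.tumor_coverage,
        normal_coverages=[sample.normal_pool[:, j] for j in range(sample.normal_pool.shape[1])],
        vcf=sample.variants,
        sample_id=f"sim{seed}",
    )
    return run_pipeline(config, inputs)


def classification_accuracy(result, sample) -> tuple[float, pd.DataFrame]:
    """Fraction of variants with correct somatic/germline ML label."""
    tbl = result.variant_table
    truth = sample.variants[["chrom", "pos", "true_status", "true_C"]]
    merged = tbl.merge(truth, on=["chrom", "pos"], how="inner")
    correct = (merged["ML.SOMATIC"] & (merged["true_status"] == SOMATIC)) | (
        ~merged["ML.SOMATIC"] & (merged["true_status"] != SOMATIC)
    )
    merged["correct"] = correct
    return float(correct.mean()), merged


def run_cohort(
    design: str = "exome",
    n_samples: int = 20,
    base_seed: int = 1,
    config: Optional[RunConfig] = None,
    with_accuracy: bool = False,
) -> pd.DataFrame:
    """Simulate and fit a cohort; one row of truth and estimates per sample.

    Sample i uses seed base_seed*1000 + i for both the generator and the
    pipeline; purity/ploidy are drawn once from a cohort-level generator
    seeded with base_seed.
    """
    from .simulate import simulate_sample

    rng = np.random.default_rng(base_seed)
    rows = []
    for i in range(1, n_samples + 1):
        purity = float(rng.uniform(0.2, 0.8))
        ploidy = float(rng.uniform(1.0, 6.0))
        seed = base_seed * 1000 + i
        sample = simulate_sample(purity, ploidy, seed, design=design)
        result = run_sample(sample, seed, config)
        row = {
            "seed": seed,
            "true_purity": purity,
            "true_ploidy": sample.truth.ploidy,
            "est_purity": result.best.purity,
            "est_ploidy": result.best.ploidy,
            "n_solutions": len(result.report.solutions),
            "gof": result.best.gof,
        }
        if with_accuracy:
            row["accuracy"], _ = classification_accuracy(result, sample)
        rows.append(row)
    return pd.DataFrame(rows)


def pearson(x, y) -> float:
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])


def recovery_stats(cohort: pd.DataFrame, purity_floor: float = 0.35) -> dict:
    """Pearson correlations between truth and estimates for one cohort."""
    hi = cohort[cohort["true_purity"] >= purity_floor]
    return {
        "r_purity": pearson(cohort["true_purity"], cohort["est_purity"]),
        "r_ploidy": pearson(cohort["true_ploidy"], cohort["est_ploidy"]),
        "r_ploidy_high_purity": pearson(hi["true_ploidy"], hi["est_ploidy"]),
        "n": len(cohort),
        "n_high_purity": len(hi),
    }
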