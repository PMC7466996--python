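"""Spike-in calibrated total-mRNA-per-cell quantification.

A fixed amount of S. paradoxus cells is mixed into every S. cerevisiae
sample at a constant OD ratio, so the paradoxus read mass is a shared
internal standard: the cerevisiae/paradoxus read ratio divided by the
cerevisiae cell count of the mixed aliquot is proportional to total mRNA
per cell, in units comparable across samples of one experiment (it is
invariant to sequencing depth).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["total_mrna_per_cell", "spikein_table", "condition_summary",
           "flag_spike_outliers"]


def total_mrna_per_cell(cer_reads, par_reads, cells):
    """Relative total mRNA per cell: (cer_reads / par_reads) / cells."""
    cer = np.asarray(cer_reads, dtype=float)
    par = np.asarray(par_reads, dtype=float)
    n = np.asarray(cells, dtype=float)
    if np.any(par <= 0):
        raise ValueError("par_reads must be positive")
    if np.any(n <= 0):
        raise ValueError("cells must be positive")
    out = (cer / par) / n
    return float(out) if out.ndim == 0 else out


def spikein_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Append the per-sample total-mRNA value to a spike-in sample table."""
    out = samples.copy()
    out["total_mrna_per_cell"] = total_mrna_per_cell(
        out["cer_reads"], out["par_reads"], out["cells"])
    return out


def condition_summary(samples: pd.DataFrame,
                      value_col: str = "total_mrna_per_cell",
                      group_col: str = "condition") -> pd.DataFrame:
    """Group mean and standard error of per-sample values.

    SE is sd/sqrt(n) with ddof=1; reported as missing for single
    replicates.
    """
    def _agg(vals: pd.Series) -> pd.Series:
        n = vals.notna().sum()
        se = vals.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan
        return pd.Series({"mean": vals.mean(), "se": se, "n": n})

    return samples.groupby(group_col)[value_col].apply(_agg).unstack()


def flag_spike_outliers(samples: pd.DataFrame, n_mad: float = 3.0) -> pd.Series:
    """QC flag: samples whose paradoxus reads stray >n_mad MADs from batch.

    The spike is mixed at a constant OD ratio, so wildly deviant
    paradoxus read counts indicate a mixing or counting problem.
    """
    par = samples["par_reads"].astype(float)
    med = par.median()
    mad = (par - med).abs().median()
    if mad == 0:
        return pd.Series(False, index=samples.index, name="spike_outlier")
    flags = ((par - med).abs() / mad) > n_mad
    if flags.any():
        logger.info("flag_spike_outliers: %d outlier sample(s)", int(flags.sum()))
    return flags.rename("spike_outlier")
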