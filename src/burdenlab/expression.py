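"""Expression-signature statistics for burden libraries and compendia.

The central quantities:

``E_g`` — the growth-rate response of a gene: the ordinary-least-squares
slope of its log2 expression against the relative growth rate of the
strains it was measured in.  Comparable across datasets ("Burden",
"Genetic", "Environmental"), it separates the burden-specific signature
from the generic slow-growth program.

``delta`` — the expression-dependent bias: the slope of a strain's
per-gene relative expression change (vs wild type, after within-sample
sum normalization) against log10 wild-type abundance.  A pure global
scale-up of transcription reads as delta = 0; failure to scale up highly
expressed genes reads as delta < 0.

Plus compendium correlations (the burden-vs-growth correlation plane for
mutant classification), top/bottom responder sets, hypergeometric gene-set
enrichment with Benjamini-Hochberg adjustment, and the GFP-library
high/low burden ratio trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_log2",
    "relative_change_vs_wt",
    "growth_response",
    "signature_correlation",
    "burden_growth_plane",
    "expression_bias",
    "per_mutant_bias",
    "top_bottom_sets",
    "enrichment",
    "gfp_ratio_trend",
    "GfpTrendResult",
]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error for one simple regression."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("degenerate predictor (zero variance)")
    yc = y - y.mean()
    slope = float(xc @ yc) / sxx
    if n > 2:
        rss = float(yc @ yc) - slope**2 * sxx
        se = np.sqrt(max(rss, 0.0) / (n - 2) / sxx)
    else:
        se = np.nan
    return slope, float(se)


def normalize_log2(matrix: pd.DataFrame, conditions=None) -> pd.DataFrame:
    """Mean-normalize each gene within each condition, then log2.

    Every gene row is divided by its mean over the samples of each
    condition (all samples form one condition when ``conditions`` is
    None), so back-transformed per-condition row means equal 1.
    """
    if (matrix <= 0).any().any():
        bad = matrix.index[(matrix <= 0).any(axis=1)]
        raise ValueError(f"non-positive expression for gene(s): {list(bad[:5])}")
    if conditions is None:
        conditions = pd.Series("all", index=matrix.columns)
    else:
        conditions = pd.Series(conditions, index=matrix.columns)
    out = matrix.copy().astype(float)
    for _, cols in conditions.groupby(conditions):
        sub = out[cols.index]
        out[cols.index] = sub.div(sub.mean(axis=1), axis=0)
    return np.log2(out)


def relative_change_vs_wt(matrix: pd.DataFrame, wt_sample: str,
                          sample: str) -> pd.Series:
    """Per-gene log2 change of relative abundance in ``sample`` vs WT.

    Samples are sum-normalized first, so a global scale-up of every
    transcript yields zero change for every gene.
    """
    rel = matrix.div(matrix.sum(axis=0), axis=1)
    return np.log2(rel[sample] / rel[wt_sample]).rename("relative_change")


def growth_response(log2_matrix: pd.DataFrame, strains: pd.DataFrame,
                    dataset: str = "Burden") -> pd.DataFrame:
    """Per-gene E_g: OLS slope of log2 expression on relative growth rate.

    ``strains`` maps sample_id to relative_growth_rate.  Genes with fewer
    than 3 finite samples are omitted (logged).  Returns a frame indexed
    by gene_id with E_g, stderr, n_samples and the dataset label.
    """
    growth = strains.set_index("sample_id")["relative_growth_rate"]
    cols = [c for c in log2_matrix.columns if c in growth.index]
    if len(cols) < 3:
        raise ValueError("need >= 3 matched samples")
    x_full = growth[cols].to_numpy(dtype=float)
    values = log2_matrix[cols].to_numpy(dtype=float)

    rows, skipped = {}, 0
    for gene, y in zip(log2_matrix.index, values):
        ok = np.isfinite(y)
        if ok.sum() < 3:
            skipped += 1
            continue
        slope, se = _ols_slope(x_full[ok], y[ok])
        rows[gene] = (slope, se, int(ok.sum()))
    if skipped:
        logger.info("growth_response: omitted %d genes with <3 samples", skipped)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["E_g", "stderr", "n_samples"])
    out.index.name = "gene_id"
    out["dataset"] = dataset
    return out


def signature_correlation(profile_a: pd.Series, profile_b: pd.Series,
                          gene_subset=None) -> tuple[float, int]:
    """Pearson r between two per-gene profiles over shared finite genes."""
    joined = pd.concat([profile_a, profile_b], axis=1, join="inner").dropna()
    if gene_subset is not None:
        joined = joined.loc[joined.index.intersection(pd.Index(gene_subset))]
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} shared genes; need >= 3")
    r = float(stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])[0])
    return r, n


def _mean_correlation(column: pd.Series, profiles) -> float:
    """Arithmetic mean of Pearson r against one or several profiles."""
    if isinstance(profiles, pd.Series):
        profiles = [profiles]
    return float(np.mean([signature_correlation(column, p)[0] for p in profiles]))


def burden_growth_plane(signatures: pd.DataFrame, burden_response,
                        growth_response_avg) -> pd.DataFrame:
    """Per-mutant correlation with the burden and growth responses.

    For each mutant signature column: Pearson r with the burden E_g
    profile and with the external growth-rate response.  When several
    condition/dataset profiles are given, per-profile correlations are
    averaged arithmetically.  Returns the (r_burden, r_growth) scatter
    table underlying mutant classification.
    """
    rows = []
    for mutant in signatures.columns:
        col = signatures[mutant]
        rows.append({
            "mutant_id": mutant,
            "r_burden": _mean_correlation(col, burden_response),
            "r_growth": _mean_correlation(col, growth_response_avg),
        })
    return pd.DataFrame(rows).set_index("mutant_id")


def _bias_fit(change: np.ndarray, log10_abund: np.ndarray,
              label: str, n_min: int = 3):
    if change.size < n_min:
        return None
    slope, se = _ols_slope(log10_abund, change)
    return {"subset": label, "delta": slope, "sem": se, "n_genes": change.size}


def expression_bias(relative_change: pd.Series, wt_abundance: pd.Series,
                    tata_flags: pd.Series | None = None) -> pd.DataFrame:
    """Expression-dependent bias delta for all genes and TATA strata.

    OLS slope of the relative expression change on log10 wild-type
    abundance, with the slope's SEM, for subsets ``all``, ``TATA`` and
    ``non-TATA`` (strata smaller than 3 genes are omitted).
    """
    df = pd.concat({"change": relative_change, "abund": wt_abundance},
                   axis=1, join="inner").dropna()
    if (df["abund"] <= 0).any():
        raise ValueError("wild-type abundance must be positive")
    x = np.log10(df["abund"].to_numpy())
    y = df["change"].to_numpy(dtype=float)
    rows = [_bias_fit(y, x, "all")]
    if tata_flags is not None:
        flags = tata_flags.reindex(df.index).fillna(False).astype(bool).to_numpy()
        rows.append(_bias_fit(y[flags], x[flags], "TATA"))
        rows.append(_bias_fit(y[~flags], x[~flags], "non-TATA"))
    return pd.DataFrame([r for r in rows if r is not None]).set_index("subset")


def per_mutant_bias(signatures: pd.DataFrame, wt_abundance: pd.Series,
                    growth_rates: pd.Series) -> pd.DataFrame:
    """delta per mutant signature, paired with the mutant's growth rate."""
    rows = []
    for mutant in signatures.columns:
        fit = expression_bias(signatures[mutant], wt_abundance).loc["all"]
        rows.append({"mutant_id": mutant, "delta": fit["delta"],
                     "sem": fit["sem"],
                     "relative_growth_rate": growth_rates.get(mutant, np.nan)})
    return pd.DataFrame(rows).set_index("mutant_id")


def top_bottom_sets(profile: pd.DataFrame, n: int) -> tuple[list, list]:
    """Top-n and bottom-n genes ranked by E_g (ties by gene_id)."""
    if n > len(profile) // 2:
        raise ValueError("n exceeds half the number of genes")
    ranked = profile.reset_index().sort_values(
        ["E_g", "gene_id"], ascending=[True, True])
    bottom = ranked["gene_id"].head(n).tolist()
    top = (profile.reset_index()
           .sort_values(["E_g", "gene_id"], ascending=[False, True])
           ["gene_id"].head(n).tolist())
    return top, bottom


def enrichment(query_set, gene_groups: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query set in gene groups.

    For each group: overlap k, tail probability P(X >= k) for drawing
    |query| genes from a universe of size M containing |group| marked
    genes, and Benjamini-Hochberg adjusted p across groups.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_set)
    if not query <= universe:
        raise ValueError("query set must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, members in gene_groups.items():
        group = set(members) & universe
        k = len(query & group)
        p = float(stats.hypergeom.sf(k - 1, M, len(group), n))
        rows.append({"group": name, "group_size": len(group),
                     "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("group")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class GfpTrendResult:
    """Per-protein high/low burden GFP ratios with a smoothed trend."""

    table: pd.DataFrame  # ratio + informative flag per protein
    trend: pd.DataFrame  # lowess of ratio vs log10 control abundance
    mean_increase_pct: float
    n_informative: int


def gfp_ratio_trend(high_burden_medians: pd.Series,
                    low_burden_medians: pd.Series,
                    control_abundance: pd.Series,
                    autofluorescence_threshold: float = 200.0,
                    lowess_frac: float = 0.3,
                    lowess_it: int = 2) -> GfpTrendResult:
    """High/low burden median-GFP ratios across the fusion library.

    Proteins whose median fluorescence does not exceed the
    autofluorescence threshold in both subpopulations are excluded.  The
    ratio is smoothed against log10 control abundance by lowess, and the
    mean percentage increase over informative proteins reported.
    """
    df = pd.concat({"high": high_burden_medians, "low": low_burden_medians,
                    "abund": control_abundance}, axis=1, join="inner").dropna()
    informative = (df["high"] > autofluorescence_threshold) & \
                  (df["low"] > autofluorescence_threshold)
    if not informative.any():
        raise ValueError("no protein above the autofluorescence threshold")
    df["ratio"] = df["high"] / df["low"]
    df["informative"] = informative
    sub = df[informative]
    smooth = sm_lowess(sub["ratio"].to_numpy(),
                       np.log10(sub["abund"].to_numpy()),
                       frac=lowess_frac, it=lowess_it, return_sorted=True)
    trend = pd.DataFrame(smooth, columns=["log10_abundance", "ratio_trend"])
    mean_pct = 100.0 * (float(sub["ratio"].mean()) - 1.0)
    return GfpTrendResult(df, trend, mean_pct, int(informative.sum()))
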