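"""Synthetic data emulating a protein-burden study in budding yeast.

Generators for every input the analysis stages consume:

* a gene catalog with log-normal initiation attempt rates, a TATA subset
  drawn from the high-rate tail (bursty/high-expression proxy), genomic
  coordinates and mRNA decay rates;
* a burden library — strains carrying 0-20 tandem copies of a strong
  promoter-driven reporter, with linearly decreasing growth rate and
  linearly increasing cell size, whose global transcription capacity
  rises with copy number while per-gene output saturates under the
  promoter-clearance dead time;
* a deletion-mutant signature compendium with transcription-capacity
  mutants, slow-growth-only mutants and null mutants (truth labels kept);
* stranded ChIP read-start tracks over a genome + integrated-plasmid
  joint reference; and
* two-species spike-in read-count tables for absolute mRNA calibration.

Every generator is a pure function of its configuration and seed.  The
library uses the analytic dead-time mean rate a/(1+a*tau) (the event-level
simulator lives in :mod:`burdenlab.initiation` and is cross-checked
against it), with multiplicative log-normal measurement noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chip import ReadStartTrack
from .fitness import CompetitionSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "MutantCompendium",
    "gen_gene_catalog",
    "gen_burden_library",
    "gen_mutant_compendium",
    "gen_competition_series",
    "gen_chip_tracks",
    "gen_spikein_counts",
    "wt_abundance",
    "genome_length",
]

# stage salts so each generator has an independent stream from one seed
_STAGE = {"catalog": 11, "library": 23, "compendium": 37, "chip": 53,
          "spikein": 71}

# typical yeast mRNA decay: half-life ~20 min
_MEAN_DECAY_PER_S = math.log(2) / (20 * 60)

# 1.5 kb genes every 3 kb: with the 500 bp promoter-side extension used by
# the ChIP signal regions, neighboring regions stay disjoint (500 bp gaps)
_GENE_SPACING_BP = 3000
_GENE_LEN_BP = 1500


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic burden experiment.

    Defaults emulate the profiled libraries: strains of 0-20 tandem
    reporter copies, ~-30% growth and ~+50% size at 20 copies, a
    dead time near the polymerase-clearance limit (~1.05 s), and
    attempt rates spanning the abundance spectrum so the top of the
    distribution sits in the saturating regime (a*tau of order 1-10).
    ``capacity_slope`` (global attempt-rate scale-up per copy) defaults
    to 0.0375/copy, i.e. capacity factor 1.75 at 20 copies.
    """

    seed: int = 0
    n_genes: int = 2000
    tata_fraction: float = 0.2
    abundance_log_mean: float = -3.0  # ln attempts/s
    abundance_log_sd: float = 1.5
    dead_time_s: float = 1.05
    copy_numbers: tuple = (0, 2, 5, 10, 15, 20)
    capacity_slope: float = 0.0375  # per copy
    growth_slope: float = 0.015  # relative growth lost per copy
    size_slope: float = 0.025  # relative size gained per copy
    noise_log2_sd: float = 0.1
    n_mutants: int = 60
    frag_len_bp: int = 120
    background_rate: float = 0.002  # reads per bp
    plasmid_len_bp: int = 8000

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_mutants < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.tata_fraction <= 1.0:
            raise ValueError("tata_fraction must lie in [0, 1]")
        for name in ("abundance_log_sd", "dead_time_s", "capacity_slope",
                     "growth_slope", "size_slope", "noise_log2_sd",
                     "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frag_len_bp < 1 or self.plasmid_len_bp < 1:
            raise ValueError("lengths must be positive")
        if any(c < 0 or c != int(c) for c in self.copy_numbers):
            raise ValueError("copy_numbers must be non-negative integers")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class MutantCompendium:
    """Deletion-mutant signatures with generator truth retained.

    ``signatures``: gene x mutant log2-ratio matrix.  ``mutants``: one row
    per mutant with its truth class (``capacity`` / ``slow_growth`` /
    ``null``), capacity factor g (NaN outside the capacity class) and
    relative growth rate.  ``growth_program``: the shared per-gene vector
    behind slow-growth signatures, usable as a synthetic external
    growth-response profile.
    """

    signatures: pd.DataFrame
    mutants: pd.DataFrame
    growth_program: pd.Series


def _saturated_rate(a: np.ndarray, tau: float, g: float = 1.0) -> np.ndarray:
    """Mean initiation rate under capacity factor g and dead time tau."""
    ga = g * a
    return ga / (1.0 + ga * tau)


def gen_gene_catalog(config: SimConfig) -> pd.DataFrame:
    """Gene catalog: attempt rates, TATA flags, coordinates, decay rates.

    Attempt rates are log-normal.  round(tata_fraction * n_genes) genes
    are flagged TATA, sampled from the top attempt-rate quantile.  Genes
    are tiled along one chromosome with alternating strands; tss/tts are
    stored promoter-to-terminator (tss > tts on the − strand), 0-based.
    """
    if config.n_genes == 0:
        raise ValueError("cannot generate an empty catalog (n_genes=0)")
    rng = config.rng("catalog")
    n = config.n_genes
    attempt = np.exp(rng.normal(config.abundance_log_mean,
                                config.abundance_log_sd, n))
    decay = np.exp(rng.normal(math.log(_MEAN_DECAY_PER_S), 0.3, n))

    n_tata = round(config.tata_fraction * n)
    is_tata = np.zeros(n, dtype=bool)
    if n_tata:
        pool = max(n_tata, math.ceil(0.25 * n))  # top quartile, widened if needed
        top = np.argsort(attempt)[::-1][:pool]
        is_tata[rng.choice(top, size=n_tata, replace=False)] = True

    starts = 300 + _GENE_SPACING_BP * np.arange(n)
    ends = starts + _GENE_LEN_BP
    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    tss = np.where(strand == "+", starts, ends)
    tts = np.where(strand == "+", ends, starts)

    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "attempt_rate": attempt,
        "is_tata": is_tata,
        "tss": tss,
        "tts": tts,
        "strand": strand,
        "decay_rate": decay,
    })


def wt_abundance(catalog: pd.DataFrame, config: SimConfig) -> pd.Series:
    """Noise-free wild-type mRNA abundance per gene.

    The dead-time mean initiation rate over the decay rate, at capacity
    factor 1.  Serves as the independent abundance axis for
    expression-bias fits: regressing a change measured against sample A
    on an abundance axis containing sample A's own noise would bias the
    slope (regression dilution with correlated errors).
    """
    a = catalog["attempt_rate"].to_numpy()
    vals = _saturated_rate(a, config.dead_time_s) / catalog["decay_rate"].to_numpy()
    return pd.Series(vals, index=pd.Index(catalog["gene_id"], name="gene_id"),
                     name="wt_abundance")


def genome_length(catalog: pd.DataFrame) -> int:
    """Length of the single synthetic chromosome holding the catalog."""
    return int(max(catalog["tss"].max(), catalog["tts"].max()) + 1000)


def gen_burden_library(catalog: pd.DataFrame,
                       config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix and strain table for the burden copy series.

    For copy number c the global capacity factor is g(c) = 1 +
    capacity_slope*c; each gene's realized initiation rate is the
    dead-time mean g*a/(1+g*a*tau) and its mRNA abundance that rate over
    its decay rate, perturbed by multiplicative log-normal noise.  Strain
    growth is 1 - growth_slope*c and size 1 + size_slope*c.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    max_copy = max(config.copy_numbers)
    if 1.0 - config.growth_slope * max_copy <= 0:
        raise ValueError("growth_slope * max copy number implies non-positive growth")
    rng = config.rng("library")
    tau = config.dead_time_s
    a = catalog["attempt_rate"].to_numpy()
    decay = catalog["decay_rate"].to_numpy()

    cols, strains = {}, []
    for c in config.copy_numbers:
        g = 1.0 + config.capacity_slope * c
        abundance = _saturated_rate(a, tau, g) / decay
        noise = 2.0 ** rng.normal(0.0, config.noise_log2_sd, a.size)
        sample = f"copy{int(c):02d}"
        cols[sample] = abundance * noise
        strains.append({"sample_id": sample, "copy_number": int(c),
                        "relative_growth_rate": 1.0 - config.growth_slope * c,
                        "relative_size": 1.0 + config.size_slope * c})
    expr = pd.DataFrame(cols, index=pd.Index(catalog["gene_id"], name="gene_id"))
    return expr, pd.DataFrame(strains)


def gen_mutant_compendium(catalog: pd.DataFrame,
                          config: SimConfig) -> MutantCompendium:
    """Log2-ratio signatures for three labeled mutant classes.

    *capacity* mutants scale every attempt rate by g < 1, so through the
    dead-time model their signatures fall with expression (mean-centered,
    matching the relative framing of compendium profiles); *slow_growth*
    mutants share one growth-program vector scaled by their growth
    deficit; *null* mutants are noise only.
    """
    if config.n_mutants < 2:
        raise ValueError("need n_mutants >= 2")
    rng = config.rng("compendium")
    tau = config.dead_time_s
    a = catalog["attempt_rate"].to_numpy()
    n_genes = a.size
    n_cap = config.n_mutants // 3
    n_slow = config.n_mutants // 3
    n_null = config.n_mutants - n_cap - n_slow

    # the slow-growth program is orthogonal to log abundance by
    # construction: slow growth alone carries no expression-dependent bias
    program = rng.standard_normal(n_genes) * 0.5
    wt_abund = np.log10(_saturated_rate(a, tau) / catalog["decay_rate"].to_numpy())
    design = np.column_stack([np.ones(n_genes), wt_abund])
    program -= design @ np.linalg.lstsq(design, program, rcond=None)[0]
    base = np.log2(_saturated_rate(a, tau))

    cols, meta = {}, []
    for i in range(n_cap):
        g = rng.uniform(0.4, 0.9)
        sig = np.log2(_saturated_rate(a, tau, g)) - base
        sig -= sig.mean()
        cols[f"cap{i:03d}"] = sig + rng.normal(0, config.noise_log2_sd, n_genes)
        meta.append({"mutant_id": f"cap{i:03d}", "truth_class": "capacity",
                     "capacity_factor": g,
                     "relative_growth_rate": 1.0 - 0.5 * (1.0 - g)})
    for i in range(n_slow):
        deficit = rng.uniform(0.1, 0.4)
        sig = 2.0 * deficit * program
        cols[f"slow{i:03d}"] = sig + rng.normal(0, config.noise_log2_sd, n_genes)
        meta.append({"mutant_id": f"slow{i:03d}", "truth_class": "slow_growth",
                     "capacity_factor": np.nan,
                     "relative_growth_rate": 1.0 - deficit})
    for i in range(n_null):
        cols[f"null{i:03d}"] = rng.normal(0, config.noise_log2_sd, n_genes)
        meta.append({"mutant_id": f"null{i:03d}", "truth_class": "null",
                     "capacity_factor": np.nan,
                     "relative_growth_rate": rng.uniform(0.98, 1.02)})

    index = pd.Index(catalog["gene_id"], name="gene_id")
    return MutantCompendium(
        signatures=pd.DataFrame(cols, index=index),
        mutants=pd.DataFrame(meta),
        growth_program=pd.Series(program, index=index, name="growth_program"),
    )


def gen_competition_series(true_advantage: float, n_timepoints: int = 8,
                           generations_per_interval: float = 3.3,
                           f0: float = 0.5, noise_sd: float = 0.0,
                           seed: int = 0) -> CompetitionSeries:
    """Logistic competition series with a known WT log2-odds slope.

    ``true_advantage`` is the WT reference's per-generation log2-odds
    gain; observation noise (sd ``noise_sd``) is added on the log2-odds
    scale before transforming back to frequencies.
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    gen = generations_per_interval * np.arange(n_timepoints)
    log_odds = math.log2(f0 / (1.0 - f0)) + true_advantage * gen
    if noise_sd > 0:
        log_odds = log_odds + rng.normal(0.0, noise_sd, n_timepoints)
    f = 2.0 ** log_odds / (1.0 + 2.0 ** log_odds)
    return CompetitionSeries(gen, f)


def gen_chip_tracks(catalog: pd.DataFrame, config: SimConfig,
                    promoter_weights, plasmid_weight: float,
                    n_reads: int = 100_000, seed: int | None = None) -> ReadStartTrack:
    """Stranded read-start tracks over the genome + plasmid joint reference.

    ``n_reads`` fragments of ``frag_len_bp`` are centered on promoter
    points (gene TSSs plus one plasmid locus) with intensities
    proportional to the weights; each fragment is sequenced from one
    random end, registering a + start at its left edge or a − start at
    its right edge.  Uniform Poisson background is added per strand at
    ``background_rate / 2`` reads per bp.
    """
    weights = np.asarray(promoter_weights, dtype=float)
    if weights.size != len(catalog):
        raise ValueError("one promoter weight per catalog gene required")
    if np.any(weights < 0) or plasmid_weight < 0:
        raise ValueError("weights must be non-negative")
    rng = (config.rng("chip") if seed is None
           else np.random.default_rng(seed))
    frag = config.frag_len_bp
    glen = genome_length(catalog)
    plen = config.plasmid_len_bp

    promoters = catalog["tss"].to_numpy()
    all_w = np.append(weights, plasmid_weight)
    if all_w.sum() <= 0:
        raise ValueError("all weights are zero")
    counts = rng.multinomial(n_reads, all_w / all_w.sum())

    starts = {
        "chrI": {s: np.zeros(glen, dtype=np.int64) for s in ("+", "-")},
        "plasmid": {s: np.zeros(plen, dtype=np.int64) for s in ("+", "-")},
    }
    truncated = 0

    def _drop(contig: str, length: int, centers: np.ndarray) -> None:
        nonlocal truncated
        left = np.rint(centers - frag / 2).astype(np.int64)
        bad = (left < 0) | (left > length - frag)
        truncated += int(bad.sum())
        left = np.clip(left, 0, length - frag)
        plus = rng.random(left.size) < 0.5
        np.add.at(starts[contig]["+"], left[plus], 1)
        np.add.at(starts[contig]["-"], left[~plus] + frag - 1, 1)

    for point, k in zip(promoters, counts[:-1]):
        if k:
            _drop("chrI", glen, point + rng.normal(0.0, 25.0, k))
    if counts[-1]:
        _drop("plasmid", plen, plen / 2 + rng.normal(0.0, 25.0, counts[-1]))

    if config.background_rate > 0:
        lam = config.background_rate / 2.0
        for contig, length in (("chrI", glen), ("plasmid", plen)):
            for s in ("+", "-"):
                starts[contig][s] += rng.poisson(lam, length)

    if truncated:
        logger.info("gen_chip_tracks: %d fragments clipped at contig edges",
                    truncated)
    return ReadStartTrack(starts, plasmid_contig="plasmid")


def gen_spikein_counts(true_mrna_per_cell, cells, spike_ratio_constant: float,
                       depth: int, seed: int = 0,
                       conditions=None) -> pd.DataFrame:
    """Two-species read counts for spike-in calibrated total-mRNA samples.

    Per sample, reads split multinomially between S. cerevisiae and the
    S. paradoxus spike-in with expected ratio (true_mrna_per_cell *
    cells) : spike_ratio_constant — the spike contribution is constant
    because the mixing OD ratio is fixed across samples.
    """
    true_vals = np.asarray(true_mrna_per_cell, dtype=float)
    cells_arr = np.asarray(cells, dtype=float)
    if true_vals.shape != cells_arr.shape:
        raise ValueError("true_mrna_per_cell and cells must align")
    if np.any(true_vals <= 0) or np.any(cells_arr <= 0):
        raise ValueError("true values and cell counts must be positive")
    if spike_ratio_constant <= 0 or depth <= 0:
        raise ValueError("spike_ratio_constant and depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (tv, nc) in enumerate(zip(true_vals, cells_arr)):
        cer_mass = tv * nc
        p = cer_mass / (cer_mass + spike_ratio_constant)
        cer = int(rng.binomial(depth, p))
        rows.append({
            "sample_id": f"s{i:02d}",
            "condition": (conditions[i] if conditions is not None else "SC"),
            "cer_reads": cer,
            "par_reads": depth - cer,
            "cells": nc,
            "true_mrna_per_cell": tv,
        })
    return pd.DataFrame(rows)
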