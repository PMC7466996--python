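# Methods

## The dead-time initiation model

Initiation attempts at a promoter are a homogeneous Poisson process with
rate *a* (attempts/s). An attempt succeeds if and only if at least the
dead time τ has elapsed since the *previous successful* initiation; the
clock restarts only on success (a non-paralyzable dead time — rejected
attempts do not extend the blocked interval). The first attempt of a run
always succeeds, a boundary convention that is negligible for the run
lengths used anywhere in the package. Successful initiations then form a
renewal process with inter-event gaps distributed as τ + Exp(a), giving
the closed-form long-run rate r(a) = a/(1 + aτ) with supremum 1/τ.

The event-level simulator (`simulate_initiation`) draws attempt gaps in
bounded chunks and applies the greedy dead-time filter with a
searchsorted scan, so memory stays flat while runs of 10⁸ attempts
remain feasible. Its Monte-Carlo standard error is estimated from the
empirical success-gap moments (var(N(T)) ≈ T·var(gap)/mean(gap)³). The
closed form and the simulator are implemented independently and
cross-checked in the tests across a·τ from 0.01 to 100; the analytic
form is what the synthetic-data generator uses (fast, deterministic),
keeping fixture generation separate from the model under test.

An optional two-state (telegraph) promoter gates attempts by ON/OFF
switching at rates k_on, k_off; attempts are kept only during ON
periods and then dead-time filtered. No closed form is exposed for this
variant; the tests only assert that bursting thins the effective rate at
equal attempt rate.

The clearance constants are the literature values for yeast RNA
polymerase II: a ~35 bp footprint and ~2 kb/min elongation, whose direct
quotient is 1.05 s (`clearance_time` returns this literal quotient; the
rounded "~1.2 s" figure sometimes quoted for the same constants is not
reproduced by division, and we do not attempt to reconcile it).

## The synthetic burden study

`SimConfig` fixes the study conditions; every generator is a pure
function of the config and seed.

* **Gene catalog.** Attempt rates are log-normal, ln a ~ N(−3.0, 1.5²)
  (attempts/s): the median gene attempts ~0.05/s while the upper tail
  reaches a·τ of order 5–10, inside the saturating regime — the spread a
  yeast-like abundance spectrum needs for the burden signature to have
  somewhere to come from. mRNA decay rates are log-normal around a
  20-minute half-life (sd 0.3 in ln-space). 20% of genes are flagged
  TATA, sampled from the top attempt-rate quartile; TATA status is a
  high-rate/bursty proxy only — no separate bursting kinetics enter the
  library generator. Genes are tiled on one chromosome (1.5 kb bodies
  every 3 kb, alternating strands); the 3 kb spacing keeps the
  ChIP signal regions (TSS−500 bp..TTS) of neighboring genes disjoint so
  per-gene promoter means are not cross-contaminated.
* **Burden library.** Copy numbers {0, 2, 5, 10, 15, 20}. Capacity
  factor g(c) = 1 + 0.0375·c (free parameter; 1.75 at 20 copies, in line
  with the ~75% total-mRNA increase measured in strongly burdened
  cells). Per-gene abundance is r_i(c)/decay_i with r_i(c) =
  g·a_i/(1+g·a_i·τ), times multiplicative log-normal noise (sd 0.1
  log2-units, a typical replicate spread for yeast expression
  profiling; no particular noise model is canonical here). Growth is
  1 − 0.015·c and size 1 + 0.025·c (−30% growth, +50% size at 20
  copies). Configs whose maximal copy number implies non-positive growth
  are refused.
* **Mutant compendium.** Three labeled classes in roughly equal thirds:
  *capacity* mutants scale all attempt rates by g ~ U(0.4, 0.9), their
  signature the mean-centered analytic log2 fold change (which *rises*
  with abundance for g < 1: saturated genes are buffered, so δ > 0 — the
  mirror image of the burden's δ < 0); *slow-growth* mutants share one
  growth-program vector scaled by their growth deficit; *null* mutants
  are noise. The program vector is orthogonalized against log10
  wild-type abundance so that slow growth alone carries no
  expression-dependent bias by construction — without this, a single
  finite-n chance correlation would give every slow mutant the same
  spurious δ.
* **ChIP tracks.** Fragments of length 120 bp are centered on promoter
  points (Gaussian jitter, sd 25 bp) with per-promoter intensity
  proportional to the supplied weights, plus one plasmid locus; each
  fragment is sequenced from one random end. A + read start is the
  fragment's left edge; a − read start is the 5′ end of the reverse
  read, i.e. the rightmost covered base (so the modal +/− offset is
  frag_len − 1, and the fragment-length estimate lands within the ±5 bp
  band used in the tests). Uniform Poisson background is added at
  0.002 reads/bp split across strands.
* **Spike-in counts.** Reads split binomially between species with odds
  (true mRNA per cell × cells) : spike constant, the spike mass being
  constant across samples because the mixing OD ratio is fixed.
* **Competition series.** Logistic dynamics: the WT log2-odds gains the
  true advantage per generation; observation noise is added on the
  log2-odds scale.

What the generator does **not** emulate: compositional sampling noise of
sequencing counts, gene-gene correlation structure, batch effects,
mapping ambiguity, or any regulatory feedback. Passing tests therefore
demonstrate that the estimators recover the model's structure under
realistic magnitudes and noise, not that real libraries are free of
those complications.

## Estimators and numerical choices

* **E_g** is the per-gene OLS slope of log2 expression on relative
  growth rate (closed-form slope and residual-based SE; genes with fewer
  than 3 finite samples are dropped and logged). Mean-normalization per
  condition shifts rows additively in log space and leaves slopes
  untouched.
* **δ** is the OLS slope of the relative expression change on log10
  wild-type abundance, with its SEM, for all genes and the TATA strata.
  The relative change is log2(strain/WT) after within-sample sum
  normalization, so a uniform global scale-up reads as exactly zero.
  Regressions are unweighted and untrimmed. The abundance axis should be
  measured independently of the two samples forming the contrast: using
  the WT sample itself puts its noise on both axes with opposite signs,
  biasing δ by roughly −σ²·log10(2)/var(x) (about −1.5 SEM at n = 2000),
  which is why the synthetic analyses use the generator's noise-free WT
  abundance (as the original analyses use an external abundance
  reference).
* **Correlation plane.** Per-mutant Pearson correlations with the burden
  E_g profile and the external growth response; when several
  condition-level profiles are supplied the per-profile correlations are
  averaged arithmetically. Pairwise-complete genes only; fewer than 3
  shared genes is an error, not a NaN.
* **Enrichment** uses the exact hypergeometric tail P(X ≥ k) and
  Benjamini–Hochberg adjustment across groups (no procedure is canonical
  for this analysis; BH is the field default). Ranking ties in
  top/bottom sets break lexicographically by gene id.
* **Competition fitness** fits log2 *odds* of the WT frequency — exactly
  linear in generations under constant selection, unlike log frequency;
  the fitted slope is taken directly as the WT per-generation advantage
  (no further division), and the competing strain's advantage is its
  negation, with % of WT division rate = 100·(1 + advantage). Boundary
  frequencies (0 or 1) are excluded and logged.
* **Scaled epistasis** ε̃ = (wxy − wx·wy)/|w̃xy − wx·wy| with w̃xy =
  min(wx, wy) for positive deviations (appropriate when single effects
  are small) and w̃xy = 0 (synthetic-lethal bound) for negative ones, so
  ε̃ = −1 at wxy = 0 and +1 at full buffering. The multiplicative
  boundary is detected with a 1e-12 relative tolerance (0.9·0.8 is not
  exactly 0.72 in floating point); values outside [−1, 1] — possible
  when wxy exceeds min(wx, wy) — are clamped and logged; min(wx, wy) =
  wx·wy with positive deviation has no defined scale and raises.
* **ChIP.** Cross-correlation scores are raw dot products between +
  starts and left-shifted − starts, summed over contigs, ties to the
  smallest shift. Extension is by diff-array accumulation; boundary
  truncation is logged. Normalization scales to 10⁶ reads; the
  background mean is genome-wide (not per-contig) over the signal
  complement, with plasmid positions in neither signal nor background
  (their coverage is still background-subtracted); negatives clip to 0.
  Occupancy uses raw read counts, pre-normalization. Overlapping signal
  intervals are merged for the partition while per-gene means use each
  gene's own interval.
* **Spike-in.** (cer/par)/cells per sample; depth-invariant by
  construction. Group summaries report mean ± sd/√n (missing for single
  replicates). A MAD-based flag marks samples whose spike reads deviate
  >3 MADs from the batch; the OD ratio is metadata only.

## The critical-size growth model

The verbal size-optimality argument is formalized here as a piecewise
model, and labeled as this package's formalization: the cell keeps a
fixed ribosomal proteome fraction φ, so its ribosome count is R(P) =
φ·P/κ for protein content P (κ converts protein content to ribosome
units, default 12); transcripts bind at most ρ ribosomes each (default
8), capping translating ribosomes at C = m·ρ for m transcripts (default
35,000). Growth is μ_opt (default 0.4/h) while R(P) ≤ C and
μ_opt·C/R(P) beyond, making the curve continuous, non-increasing, and
linear in m through the critical content P* = C·κ/φ. The defaults store
the often-quoted literature scales (200,000 ribosomes, 35,000
transcripts, "~8 ribosomes per mRNA") as documented values; the quoted
ratio 8 is not the literal quotient 5.7 and is deliberately not
re-derived.

## Problem sizes

The shipped analyses use 2000-gene catalogs (200 genes, 10⁵ reads for
ChIP), 60-mutant compendia, 20-timepoint competitions with 200
Monte-Carlo replicates, 10⁵-read spike-in samples, and initiation runs
of 10⁴–10⁵·τ (3·10⁴·τ at a·τ = 1000) — sizes at which every recovery
check resolves its effect at 3σ while the whole suite and the
acceptance script each run in seconds.

## Known limitations

* The dead time is strictly non-paralyzable; a paralyzable variant is
  intentionally not implemented.
* No polymerase traffic, elongation pausing, or decay dynamics: the
  model concerns initiation only.
* The telegraph promoter has no analytic reference in the package;
  conclusions about bursting rest on simulation.
* The capacity slope per burden copy is a free parameter — no
  quantitative copy-to-capacity mapping is available to calibrate it.
* The GFP-trend lowess uses span 0.3 with 2 robustness iterations; only
  the smoother family, not its parameters, is canonical.
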