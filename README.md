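# burdenlab

Tools for asking whether transcription initiation is a limiting step in
protein production, built around protein-burden experiments in budding
yeast: strains carrying 0–20 tandem copies of a strong-promoter reporter
grow progressively slower, get progressively larger, and shift their
relative gene expression in a characteristic way — highly expressed and
TATA-containing (bursty) genes fail to scale up with the rest of the
transcriptome.

The mechanistic core is a dead-time model of initiation. A promoter
receives stochastic initiation *attempts* at rate *a*; after each
successful initiation the polymerase must elongate its own footprint
(~35 bp at ~2 kb/min) away from the start site, imposing a clearance dead
time τ ≈ 1 s during which further attempts fail. The realized initiation
rate is

    r(a) = a / (1 + a·τ),   saturating at 1/τ.

When burdened cells raise their overall transcription capacity by a
factor *g* (all attempt rates scaled by *g*), lowly expressed genes gain
close to *g*-fold while genes near saturation barely move — reproducing
the burden expression signature without any gene-specific regulation.

## What is in the package

| module | contents |
| --- | --- |
| `burdenlab.initiation` | dead-time simulator, its renewal closed form, clearance-time constants, capacity fold change, critical-cell-size growth model |
| `burdenlab.synth` | synthetic study generator: gene catalog, burden library, deletion-mutant signature compendium, competition series, ChIP read tracks, spike-in counts |
| `burdenlab.expression` | mean/log2 normalization, growth-rate response E_g, compendium correlations, expression-dependent bias δ, top/bottom responder sets, hypergeometric enrichment, GFP-library ratio trend |
| `burdenlab.fitness` | competition-assay fitness (log2-odds slope), burden cost per copy, scaled epistasis ε̃ ∈ [−1, 1] |
| `burdenlab.chip` | fragment-length estimation, read extension, background subtraction, promoter-averaged binding, plasmid occupancy |
| `burdenlab.spikein` | two-species spike-in calibration of total mRNA per cell |
| `burdenlab.io` / `burdenlab.cli` | TSV/BED/bedGraph/GMT/YAML plumbing and the `burdenlab` command |

## Worked example

Simulate the initiation process at a promoter attempting twice per
second with a 1.05 s dead time, and compare with the closed form:

```python
from burdenlab.initiation import (InitiationParams, analytic_effective_rate,
                                  simulate_initiation)

p = InitiationParams(attempt_rate=2.0, dead_time=1.05)
sim = simulate_initiation(p, duration_s=50_000, seed=1)
print(f"analytic rate: {analytic_effective_rate(p):.4f} /s")
print(f"simulated rate: {sim.effective_rate:.4f} /s "
      f"({sim.n_success} successes of {sim.n_attempts} attempts)")
```

```
analytic rate: 0.6452 /s
simulated rate: 0.6464 /s (32318 successes of 100416 attempts)
```

Only about a third of attempts succeed at a·τ ≈ 2 — this promoter is
deep in the saturating regime. Now generate a full burden library and
measure the expression-dependent bias δ (slope of the relative
expression change, 20 copies vs wild type, against log10 wild-type
abundance):

```python
import burdenlab.synth as synth
import burdenlab.expression as ex

cfg = synth.SimConfig(seed=1)          # 2000 genes, copies 0..20, tau=1.05 s
catalog = synth.gen_gene_catalog(cfg)
expr, strains = synth.gen_burden_library(catalog, cfg)
change = ex.relative_change_vs_wt(expr, "copy00", "copy20")
print(ex.expression_bias(change, synth.wt_abundance(catalog, cfg),
                         catalog.set_index("gene_id")["is_tata"]).round(4))
```

```
           delta     sem  n_genes
subset
all      -0.1470  0.0058     2000
TATA     -0.3915  0.0340      400
non-TATA -0.0927  0.0071     1600
```

δ is strongly negative (−0.147 log2-units per abundance decade, 25× its
SEM): relative expression falls with wild-type abundance, because
highly expressed genes cannot follow the global scale-up. The bias is
~4-fold stronger in the TATA (high-attempt-rate) subset. Setting the
dead time to zero in the generator abolishes δ entirely.

A command-line interface mirrors the library, e.g.
`burdenlab simulate library --seed 1 --outdir out/` followed by
`burdenlab eg --expr out/expression.tsv --strains out/strains.tsv --out eg.tsv`;
see `burdenlab --help`.

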