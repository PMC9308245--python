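# ewasviz

Scriptable exploration of epigenome-wide association study (EWAS) results
across many traits.

## The problem

A multi-trait EWAS — say, screening the internal load of dozens of chemical
compounds against genome-wide DNA methylation — produces one result table
per trait, each with hundreds of thousands of CpG probes. Deciding which
trait, and then which probe, deserves deeper inspection is an exploratory
task: it needs ranked summaries, annotated plots, and per-probe deep dives,
not another regression engine. `ewasviz` provides the computational layer
for that workflow as a library plus CLI, so every step of an exploration is
a replayable script.

The upstream screening itself (normalisation, cell-type adjustment, the
per-probe regressions) is deliberately out of scope: `ewasviz` starts from
the result files such a pipeline writes.

## Core quantities and methods

**β-value.** Methylation at a CpG is the proportion
β = M / (M + U) of methylated (M) to total (M + U) probe intensity,
a value in [0, 1] per individual.

**Delta methylation.** Δ = max(β) − min(β) across individuals at one CpG:
the observed methylation range, a practical effect-size measure for probe
triage (result files may carry it signed by effect direction).

**Trait screening.** Every result file in a folder is summarised (probe
count, minimum p, maximum |Δ|, top probe) behind a fingerprint-keyed cache,
after a p-value floor filter (artefactually small p near the IEEE 754
lower bound), multimodal-probe exclusion, and optional minimum-n filtering.

**Scagnostics.** Each trait's strongest scatter (trait value vs methylation
at its top probe) is characterised by the nine graph-theoretic scatterplot
diagnostics — outlying, skewed, clumpy, sparse, striated, convex, skinny,
stringy, monotonic — computed from the Euclidean minimum spanning tree,
convex hull and alpha hull of the normalised point cloud. Traits can be
ordered by any of these, by p, or by Δ.

**Enriched Manhattan / volcano data.** One point per probe with
y = −log10(p); x is the probe's global array position (ordinal rank by
chromosome and position) for the Manhattan view, or signed Δ for the
volcano view. Dots carry a chromosome colour key, a diameter encoding the
probe's prior-finding count from a local EWAS-catalog snapshot
(size ∝ √count), annotation text, and an EWAS Data Hub hyperlink.

**Per-probe deep dives.** Sex-stratified trait–methylation records with
OLS trend fits and pointwise 95% confidence bands; DMR-window methylation
profiles (up to k probes either side of a centre CpG, never crossing a
chromosome boundary, ordinal x axis); per-probe SD; genome-wide
correlation profiling (pairwise-complete Pearson or Spearman against every
other probe, ranked by |r|); and merged trait + methylation export for
external pathway/network tools.

**Synthetic cohorts.** A deterministic generator emulates the full input
universe — β matrix (logit-normal with spiked trait effects), log-normal
traits, annotation, result files computed by actually regressing the
generated matrix, multimodal list, catalog counts, `config.yml` — so every
feature is testable without any download.

## Worked example

```
$ ewasviz simulate --out demo --seed 7
wrote dataset under demo (300 probes x 200 individuals, 2 traits)
spiked: trait_1 ~ cg00000100 (effect 1.0 logit units)
spiked: trait_2 ~ cg00000200 (effect 1.0 logit units)

$ ewasviz summarize --config demo/config.yml --out demo/summary.csv
$ head -3 demo/summary.csv   # columns truncated for width
trait_name,n_probes,min_p,max_abs_delta,top_probe_id,...,monotonic
trait_2,294,2.271322239e-99,0.9255204511,cg00000200,...,0.6593603753
trait_1,294,2.021905298e-39,0.9255204511,cg00000100,...,0.715488232
```

The summary is ordered by minimum p. For both traits the screening found
the planted probe (`top_probe_id` equals the spiked CpG), six probes were
removed by the multimodal filter (300 → 294), and the monotonic scagnostic
(squared Spearman correlation of the top-probe scatter) is ≈ 0.66–0.72 —
exactly what a 1.0 logit-unit effect against noise SD 0.3 should produce.

```
$ ewasviz manhattan --config demo/config.yml --trait trait_1 --top-pct 5 \
    --out-prefix demo/mh
$ head -3 demo/mh.csv
probe_id,x,y,chromosome,color,size,catalog_count,hover
cg00000006,6,1.346572306,1,#1f77b4,4,0,cg00000006 GENE2 (5'UTR) chr1:1767427 p=0.045 Δ=0.288
cg00000020,20,1.434808706,1,#1f77b4,13.29516003,3,cg00000020 GENE7 (TSS200) chr1:8415994 p=0.0367 Δ=-0.276
```

Each row is one dot: `x` the global array position, `y` = −log10(p),
`size` grows with the probe's catalog count (4 → 13.3 between counts 0
and 3 here). `volcano` emits the same rows with signed Δ as `x`.

```
$ ewasviz correlate --config demo/config.yml --probe cg00000100 --top-n 3 \
    --out demo/corr.csv
$ cat demo/corr.csv
probe_id,corr_coeff,n_pairs,gene_symbol,feature,chromosome,position
cg00000210,-0.1999282576,194,GENE70,Body,3,7299649
cg00000056,-0.1923387447,190,GENE19,5'UTR,1,27804415
cg00000171,0.1861285923,190,,TSS1500,2,31391177
```

No other probe was generated to co-vary with `cg00000100`, so its
strongest genome-wide correlates sit at |r| ≈ 0.2 — baseline noise level
for n ≈ 190 pairs. The remaining subcommands (`trait-plot`, `profile`,
`export`) produce the per-probe deep-dive tables; add `--png` to any plot
command for a static rendering.

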