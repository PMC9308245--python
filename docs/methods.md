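# Methods

## Data contract

All inputs are delimited text with an explicit dialect (separator, decimal
mark, encoding, column names — configurable because result files often
come out of locale-sensitive R or spreadsheet exports; defaults are
comma/point/UTF-8 with columns `probeID`, `P_VAL`, `Beta`, `DeltaMeth`).

Validation at load is strict where a violation would silently corrupt
downstream statistics, lenient where it would merely lose a row:

* p-values must lie in (0, 1]; offending rows are **dropped and counted**
  in the load report rather than clamped — a p of exactly 0 or above 1 is
  evidence of an upstream numeric problem, and clamping would hide it.
* β-matrix entries outside [0, 1] are coerced to missing (a β-value is a
  proportion by definition) and counted.
* Duplicate probe or individual ids in the β matrix are a hard error: they
  break the join key of the whole toolkit.
* `DeltaMeth` may be negative when the producing pipeline orients the
  range by effect direction; this is flagged, not rejected, and summaries
  always use |Δ|.
* Annotation rows with a chromosome outside 1–22/X/Y are dropped with a
  warning; sex codes map through the configured mapping, with anything
  unmapped becoming `unknown`.

## Summary index and cache

One summary per result file: surviving probe count, minimum p, maximum
|Δ|, top probe (smallest p, ties by probe id), optional scagnostics. The
cache is JSON lines keyed by a source fingerprint of (file size,
mtime in ns, SHA-256 of the leading 64 KiB). A fingerprint mismatch
invalidates only that trait's entry, so touching one file re-reads one
file. JSON lines rather than a binary store keeps the cache diffable and
language-neutral. Cached and cold-rebuilt indices are field-identical by
construction (the cache stores exactly the summary dataclass).

## Filters

* **p-floor** (default 1e-300): regression engines can emit p-values at
  the edge of IEEE 754 double range; these are numeric artefacts, not
  strong evidence. 1e-300 sits safely above the denormal range while
  excluding nothing a realistic cohort can produce legitimately.
* **min-n** (default off): requires an `n` column in the result file;
  when absent the filter is inert and logs a warning instead of guessing.
* **multimodal exclusion** (default on): probes on the configured list are
  removed; multimodal β distributions are typically genotype-driven.
* **top-percent**: keeps ceil(pct/100 · N) smallest-p rows — the ceiling
  guarantees a non-empty selection for any positive percentage — with ties
  at the cut broken by (p, probe id) for determinism. Applied *before*
  the annotation join in the plot builders, so the percentage refers to
  the statistical ranking, not to annotation coverage.

## Scagnostics

Computed on the trait-vs-methylation scatter of each trait's top probe —
the scatter a screening process has "for free". Pipeline: drop incomplete
pairs; min-max normalise both axes to the unit square (hence invariance
to translation and per-axis scaling); deduplicate; hex-bin to at most 250
centroids when larger (binning is deterministic; the seed parameter is
accepted for interface stability). The Euclidean MST is computed over the
complete distance graph; convex hull via Qhull; the alpha hull is the
union of Delaunay triangles with circumradius ≤ α.

Conventions (all module constants):

* outlier cut = q75 + 1.5·IQR of MST edge lengths; outlying vertices
  (every incident edge above the cut) contribute their edge length to
  `outlying` and are pruned before the shape measures;
* α = 90th percentile of MST edge lengths;
* `sparse` = q90 of edge lengths (unit square ⇒ already ≤ √2, clipped to 1);
* `skewed` = (q90 − q50)/(q90 − q10), defined as 0 when q90 = q10;
* `clumpy` uses the runt statistic: for each MST edge, cut the tree on
  strictly shorter edges, take the smaller component around the edge's
  endpoints, score runt_size · (1 − longest runt edge / edge length);
  clumpy = 2·max/n. The runt-size weighting keeps singleton runts (which
  are outliers, not clumps) from saturating the measure;
* `striated` = fraction of vertices of MST degree 2 whose edge pair has
  cos θ < −0.75;
* `convex` = alpha area / hull area, `skinny` = 1 − √(4π·area)/perimeter
  of the alpha shape; a degenerate (collinear) cloud has hull area 0 and
  is defined as convex 0, skinny 1 rather than raising;
* `stringy` = MST diameter (longest weighted path) / total MST length;
* `monotonic` = squared Spearman correlation with average ranks for ties,
  computed on the **original** points, so it equals the closed form
  exactly regardless of binning.

Fewer than 3 complete points or a zero-variance axis yields an absent
profile with a logged reason.

## Plot data products

Global array position is the rank after sorting by (chromosome in the
order 1..22, X, Y; position; probe id) — a bijection onto 1..N. Dot
diameter is s_min + (s_max − s_min)·√count/√count_max with s_min for
count 0; the square root keeps heavily catalogued probes from dominating.
Probes lacking annotation are dropped from plots (they have no x
coordinate) but kept in tables, with counts logged. Data Hub links are
built from a configurable URL template with a `{probe_id}` placeholder —
no network access at build time.

## Deep-dive views

* **Trend fits**: ordinary least squares of methylation on trait per
  stratum (all / female / male), with the t-based pointwise 95% band for
  the mean response over the stratum's observed trait range. OLS was
  chosen as the default smoother because it is exactly recoverable on
  linear fixtures and its CI calibration is testable by simulation;
  strata with fewer than 3 points or constant trait get no fit.
* **DMR window**: up to k probes either side of the centre by global
  rank, truncated (and flagged) at chromosome boundaries — array-adjacent
  probes on different chromosomes are biologically unrelated. The x axis
  is ordinal: real base-pair gaps are not represented. The window is a
  visualisation region, not a called DMR.
* **Colour scale**: linear red→blue over the trait range (red = low);
  a constant trait maps everyone to the midpoint colour.
* **Correlation profile**: the query probe against every other probe,
  pairwise-complete, requiring ≥ min_overlap (default 10) shared
  individuals; Pearson by default with Spearman selectable; ranked by
  |r| (so strong negative correlates surface), ties by probe id.
* **Violin summaries** are emitted as five-number + KDE-grid tables per
  stratum so any plotting layer can render them.

## Synthetic cohorts

The generator draws per-probe baselines uniform on [−3, 3] logit units,
adds effect·standardised-trait for spiked pairs plus N(0, noise_sd), and
inverse-logits into (0, 1) — no clamping artefacts. Traits are log-normal
(concentration-like biomarkers); sex is ~1:1; ~2% of probes get a
genotype-like three-component mixture and populate the multimodal list;
catalog counts are zero-inflated Poisson (80% zero). Result files come
from actually regressing each probe on each trait (slope, two-sided p,
signed Δ), so they are consistent with the matrix by construction. A p
underflowing double range is set to 1e-300 to respect the (0, 1]
contract. Defaults (200 individuals, 300 probes, effect 1.0, noise SD
0.3, 2% missing) describe a small but realistically powered screening
study: the spiked probe should top its trait's ranking essentially always.

What the generator does **not** emulate: batch effects, cell-type
composition, array chemistry (type I/II probes), genomic autocorrelation
of methylation, or correlated traits. Passing tests therefore demonstrate
correctness of the computations, not robustness to those real-data
complications.

## Problem sizes

Tests run on cohorts of 40–200 individuals and 30–300 probes; the
recovery check uses 20 seeds at n = 200 and the CI calibration 100
replicates at n = 100 — sizes at which every oracle (brute-force MST,
exhaustive correlation scan, permutation p-values) is itself cheap to
compute, keeping the dual-route checks honest.

## Known limitations

* The scagnostics constants (outlier cut, α percentile, bin cap) follow
  the common convention but are conventions; rankings, not absolute
  values, are the intended use.
* `corrwith`-based scanning materialises the individuals × probes
  transpose; for EPIC-scale matrices (~850k probes) a chunked scan would
  be needed.
* The min-n filter depends on an optional `n` column that many pipelines
  do not write.
* Sex strata are limited to female/male/unknown as provided by the trait
  table; no other stratifiers are built in.
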