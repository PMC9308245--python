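"""Deterministic synthetic EWAS dataset generator.

Emulates the complete input universe of the toolkit — a beta matrix, a
trait table with sex, probe annotation, per-trait result files, a
multimodal-probe list, a catalog-count table and a ``config.yml`` — as an
internally consistent mini-cohort, so every module is testable without
any download.

The generative model: each probe has a baseline methylation level on the
logit scale; for spiked (trait, probe) pairs the standardised trait is
added with a chosen effect size, plus Gaussian noise, and the inverse
logit maps back into [0, 1] without clamping artefacts.  Traits are
log-normal (concentration-like, as for chemical-exposure biomarkers).  A
small fraction of probes is generated bimodally (a genotype-like
three-component mixture) and listed as multimodal.  Result files are
produced by actually regressing each probe's beta on the trait, so the
p-values, slopes and delta-methylation ranges in the result files are
consistent with the matrix.  Catalog counts are zero-inflated Poisson:
most probes have no prior findings, a few are heavily reported.

Everything derives from one integer seed; a fixed seed yields a
byte-identical directory tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

_FLOAT_FMT = "%.10g"


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort.

    Defaults describe a small but realistic screening study: 200
    individuals, 300 CpG probes over three chromosomes, two
    concentration-like traits, one spiked association per trait with an
    effect of 1.0 logit units against probe-level noise of SD 0.3.
    """

    n_individuals: int = 200
    n_probes: int = 300
    n_traits: int = 2
    chromosomes: tuple[str, ...] = ("1", "2", "3")
    spiked_associations: list[tuple[str, str, float]] | None = None
    noise_sd: float = 0.3
    missing_rate: float = 0.02
    multimodal_fraction: float = 0.02
    seed: int = 0

    probe_ids: list[str] = field(init=False)
    trait_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        self.probe_ids = [f"cg{i:08d}" for i in range(1, self.n_probes + 1)]
        self.trait_names = [f"trait_{i}" for i in range(1, self.n_traits + 1)]
        if self.spiked_associations is None:
            # one spike per trait, on well-separated probes
            step = max(1, self.n_probes // (self.n_traits + 1))
            self.spiked_associations = [
                (self.trait_names[i], self.probe_ids[(i + 1) * step - 1], 1.0)
                for i in range(self.n_traits)]
        for trait, probe, _ in self.spiked_associations:
            if trait not in self.trait_names:
                raise ValueError(f"spiked trait {trait!r} not in universe")
            if probe not in self.probe_ids:
                raise ValueError(f"spiked probe {probe!r} not in universe")


def truth_table(spec: SimulationSpec) -> list[tuple[str, str, float]]:
    """Ground-truth spiked (trait, probe, effect) triples for recovery tests."""
    return list(spec.spiked_associations or [])


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _make_annotation(spec: SimulationSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_probes
    chroms = np.sort(rng.integers(0, len(spec.chromosomes), size=n))
    positions = np.empty(n, dtype=int)
    for c in range(len(spec.chromosomes)):
        mask = chroms == c
        k = int(mask.sum())
        pos = np.sort(rng.choice(np.arange(10_000, 50_000_000), size=k,
                                 replace=False))
        positions[mask] = pos
    features = rng.choice(["TSS200", "TSS1500", "5'UTR", "Body", "3'UTR",
                           "IGR"], size=n)
    genes = np.array([f"GENE{1 + i // 3}" for i in range(n)])
    has_gene = rng.random(n) > 0.15  # some probes are intergenic, unannotated
    return pd.DataFrame({
        "probeID": spec.probe_ids,
        "chromosome": [spec.chromosomes[c] for c in chroms],
        "position": positions,
        "gene.symbol": np.where(has_gene, genes, ""),
        "feature": features,
    })


def _regress(trait: np.ndarray, beta_row: np.ndarray) -> tuple[float, float]:
    """Slope and two-sided p of beta ~ trait over complete pairs."""
    ok = ~(np.isnan(trait) | np.isnan(beta_row))
    x, y = trait[ok], beta_row[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    fit = stats.linregress(x, y)
    p = float(fit.pvalue)
    if p <= 0.0:  # guard against underflow below double range
        p = 1e-300
    return float(fit.slope), p


def generate_dataset(spec: SimulationSpec, out_dir: str | Path) -> dict:
    """Write the full synthetic dataset under ``out_dir``.

    Layout: ``results/<trait>.csv`` per trait, plus ``beta_matrix.csv``,
    ``traits.csv``, ``annotation.csv``, ``multimodal_probes.txt``,
    ``catalog_counts.csv`` and a ``config.yml`` wiring them together.
    Returns a dict of the written paths plus the ground-truth spike list.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "results").mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    individuals = [f"I{i:04d}" for i in range(1, spec.n_individuals + 1)]
    sex_codes = rng.choice([1, 2], size=spec.n_individuals)

    # concentration-like traits: log-normal
    trait_vals = {t: np.exp(rng.normal(0.0, 1.0, size=spec.n_individuals))
                  for t in spec.trait_names}

    # multimodal probes: genotype-like 3-component mixture on the logit scale
    n_multi = max(1, int(round(spec.multimodal_fraction * spec.n_probes)))
    spiked_probes = {p for _, p, _ in spec.spiked_associations}
    candidates = [p for p in spec.probe_ids if p not in spiked_probes]
    multimodal = sorted(rng.choice(candidates, size=n_multi, replace=False))

    baseline = rng.uniform(-3.0, 3.0, size=spec.n_probes)
    logit = (baseline[:, None]
             + rng.normal(0.0, spec.noise_sd,
                          size=(spec.n_probes, spec.n_individuals)))
    for trait, probe, effect in spec.spiked_associations:
        i = spec.probe_ids.index(probe)
        vals = trait_vals[trait]
        z = (vals - vals.mean()) / vals.std()
        logit[i] += effect * z
    multi_idx = [spec.probe_ids.index(p) for p in multimodal]
    genotype = rng.choice([-2.0, 0.0, 2.0], size=(len(multi_idx),
                                                  spec.n_individuals),
                          p=[0.25, 0.5, 0.25])
    logit[multi_idx] += genotype

    beta = _logistic(logit)
    if spec.missing_rate > 0:
        mask = rng.random(beta.shape) < spec.missing_rate
        beta[mask] = np.nan

    beta_df = pd.DataFrame(beta, index=pd.Index(spec.probe_ids,
                                                name="probeID"),
                           columns=individuals)
    beta_path = out_dir / "beta_matrix.csv"
    beta_df.to_csv(beta_path, float_format=_FLOAT_FMT)

    traits_df = pd.DataFrame({"ID": individuals, "sex": sex_codes})
    for t in spec.trait_names:
        traits_df[t] = trait_vals[t]
    traits_path = out_dir / "traits.csv"
    traits_df.to_csv(traits_path, index=False, float_format=_FLOAT_FMT)

    annotation = _make_annotation(spec, rng)
    annotation_path = out_dir / "annotation.csv"
    annotation.to_csv(annotation_path, index=False)

    # per-trait result files from actual regressions on the generated matrix
    result_paths = {}
    for t in spec.trait_names:
        vals = trait_vals[t]
        slopes = np.empty(spec.n_probes)
        pvals = np.empty(spec.n_probes)
        deltas = np.empty(spec.n_probes)
        for i in range(spec.n_probes):
            slopes[i], pvals[i] = _regress(vals, beta[i])
            row = beta[i]
            row = row[~np.isnan(row)]
            span = float(row.max() - row.min()) if row.size else np.nan
            deltas[i] = np.copysign(span, slopes[i] if slopes[i] != 0 else 1.0)
        res = pd.DataFrame({"probeID": spec.probe_ids, "P_VAL": pvals,
                            "Beta": slopes, "DeltaMeth": deltas})
        path = out_dir / "results" / f"{t}.csv"
        res.to_csv(path, index=False, float_format=_FLOAT_FMT)
        result_paths[t] = path

    multimodal_path = out_dir / "multimodal_probes.txt"
    multimodal_path.write_text("\n".join(multimodal) + "\n", encoding="utf-8")

    # zero-inflated Poisson prior-finding counts; only nonzero rows listed
    reported = rng.random(spec.n_probes) < 0.2
    counts = np.where(reported, 1 + rng.poisson(2.0, size=spec.n_probes), 0)
    catalog = pd.DataFrame({"probeID": spec.probe_ids, "count": counts})
    catalog = catalog[catalog["count"] > 0]
    catalog_path = out_dir / "catalog_counts.csv"
    catalog.to_csv(catalog_path, index=False)

    config = {
        "paths": {
            "results_dir": "results",
            "beta_matrix": "beta_matrix.csv",
            "traits": "traits.csv",
            "annotation": "annotation.csv",
            "multimodal": "multimodal_probes.txt",
            "catalog": "catalog_counts.csv",
            "cache": "summary_cache.jsonl",
        },
        "dialect": {"sep": ",", "decimal": ".", "probe_id_col": "probeID"},
        "sex_mapping": {"1": "female", "2": "male"},
        "filters": {"p_floor": 1.0e-300, "min_n": 0,
                    "exclude_multimodal": True, "top_percent": 100.0},
        "sizing": {"s_min": 4.0, "s_max": 16.0},
        "correlation": {"method": "pearson", "min_overlap": 10, "top_n": 20},
        "log_level": "INFO",
    }
    config_path = out_dir / "config.yml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True),
                           encoding="utf-8")

    return {
        "config": config_path,
        "beta_matrix": beta_path,
        "traits": traits_path,
        "annotation": annotation_path,
        "multimodal": multimodal_path,
        "catalog": catalog_path,
        "results": result_paths,
        "truth": truth_table(spec),
    }
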