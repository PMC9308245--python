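"""Enriched Manhattan and volcano data products.

Both plots place -log10(p) on the y axis.  The Manhattan x axis is the
probe's ordinal rank on the array after sorting by chromosome then
position (the "global array position" — real base-pair distances are not
preserved); the volcano x axis is the signed delta-methylation effect.
Enrichment means each dot additionally carries its chromosome colour key,
a diameter encoding the number of prior findings for the probe in a local
catalog snapshot, and hover/annotation text (gene symbol, genomic
feature, coordinates), plus a per-probe hyperlink into the EWAS Data Hub.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ewasviz.io_model import CHROMOSOMES, CatalogCounts, EwasResultTable
from ewasviz.screening import top_percent_probes

logger = logging.getLogger("ewasviz")

DEFAULT_HUB_URL = "https://ngdc.cncb.ac.cn/ewas/datahub/probe/{probe_id}"

#: cyclic categorical palette keyed by chromosome order (matplotlib tab10)
CHROMOSOME_PALETTE = ("#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
                      "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")


@dataclass
class SizingRule:
    """Dot-diameter encoding of catalog counts.

    size = s_min + (s_max - s_min) * sqrt(count) / sqrt(count_max); the
    square root keeps heavily reported probes from dominating the plot,
    and a zero count always maps to s_min.
    """

    s_min: float = 4.0
    s_max: float = 16.0

    def sizes(self, counts: pd.Series) -> pd.Series:
        if not (self.s_max >= self.s_min > 0):
            raise ValueError("require s_max >= s_min > 0")
        count_max = int(counts.max()) if len(counts) else 0
        if count_max <= 0:
            return pd.Series(self.s_min, index=counts.index)
        scale = (self.s_max - self.s_min) / np.sqrt(count_max)
        return self.s_min + scale * np.sqrt(counts.astype(float))


def chromosome_color(chromosome: str) -> str:
    idx = CHROMOSOMES.index(str(chromosome))
    return CHROMOSOME_PALETTE[idx % len(CHROMOSOME_PALETTE)]


def assign_global_positions(annotation: pd.DataFrame) -> pd.DataFrame:
    """Rank probes 1..N by (chromosome 1..22,X,Y; position; probe id).

    The returned frame is sorted in rank order with a
    ``global_array_position`` column; the rank is a bijection onto 1..N
    and strictly increases with position within each chromosome.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    df = annotation.copy()
    chrom_rank = {c: i for i, c in enumerate(CHROMOSOMES)}
    df["_chrom_rank"] = df["chromosome"].map(chrom_rank)
    df = df.sort_values(["_chrom_rank", "position", "probe_id"],
                        kind="mergesort").drop(columns="_chrom_rank")
    df = df.reset_index(drop=True)
    df["global_array_position"] = np.arange(1, len(df) + 1)
    return df


def _hover_text(row: pd.Series) -> str:
    gene = row.get("gene_symbol")
    feature = row.get("feature")
    gene = gene if isinstance(gene, str) and gene else "?"
    feature = feature if isinstance(feature, str) and feature else "?"
    return (f"{row['probe_id']} {gene} ({feature}) "
            f"chr{row['chromosome']}:{row['position']} "
            f"p={row['p_value']:.3g} Δ={row['delta_meth']:.3g}")


def _build_points(results: EwasResultTable,
                  annotation: pd.DataFrame,
                  catalog: CatalogCounts | None,
                  top_pct: float,
                  sizing: SizingRule,
                  x_from: str) -> pd.DataFrame:
    """Shared Manhattan/volcano assembly: filter, join, size, annotate."""
    if "global_array_position" not in annotation.columns:
        annotation = assign_global_positions(annotation)
    selected = top_percent_probes(results, top_pct)
    merged = selected.data.merge(annotation, on="probe_id", how="left")
    unannotated = merged["global_array_position"].isna()
    if unannotated.any():
        logger.warning("trait %s: %d probes lack annotation and are dropped "
                       "from the plot", results.trait_name,
                       int(unannotated.sum()))
    merged = merged[~unannotated]
    if merged.empty:
        logger.warning("trait %s: no annotated probes survive; empty plot",
                       results.trait_name)
        cols = ["probe_id", "x", "y", "chromosome", "color", "size",
                "catalog_count", "hover"]
        return pd.DataFrame(columns=cols)

    catalog = catalog or CatalogCounts()
    counts = catalog.as_series(merged["probe_id"])
    counts.index = merged.index
    x = (merged["global_array_position"].astype(float)
         if x_from == "rank" else merged["delta_meth"].astype(float))
    out = pd.DataFrame({
        "probe_id": merged["probe_id"],
        "x": x,
        "y": -np.log10(merged["p_value"].astype(float)),
        "chromosome": merged["chromosome"],
        "color": merged["chromosome"].map(chromosome_color),
        "size": sizing.sizes(counts),
        "catalog_count": counts,
        "hover": merged.apply(_hover_text, axis=1),
    }).reset_index(drop=True)
    return out


def build_manhattan(results: EwasResultTable,
                    annotation: pd.DataFrame,
                    catalog: CatalogCounts | None = None,
                    top_pct: float = 100.0,
                    sizing: SizingRule | None = None) -> pd.DataFrame:
    """One enriched Manhattan point per surviving annotated probe.

    x = global array position, y = -log10(p); the top-percent filter is
    applied before the annotation join, and unannotated probes are dropped
    with a logged count.
    """
    return _build_points(results, annotation, catalog, top_pct,
                         sizing or SizingRule(), x_from="rank")


def build_volcano(results: EwasResultTable,
                  annotation: pd.DataFrame,
                  catalog: CatalogCounts | None = None,
                  top_pct: float = 100.0,
                  sizing: SizingRule | None = None) -> pd.DataFrame:
    """Enriched volcano points: x = signed delta methylation, y = -log10(p).

    Negative deltas (hypo-methylation) sit left of zero, positive right.
    """
    return _build_points(results, annotation, catalog, top_pct,
                         sizing or SizingRule(), x_from="delta")


def probe_detail(probe_id: str,
                 results: EwasResultTable,
                 annotation: pd.DataFrame,
                 catalog: CatalogCounts | None = None,
                 hub_url_template: str = DEFAULT_HUB_URL) -> dict:
    """Annotated detail record for one probe, for the table tied to plots.

    Raises KeyError for a probe absent from the result table; a probe
    missing from the annotation yields a record with chromosome/position
    set to None rather than an exception.
    """
    rows = results.data[results.data["probe_id"] == probe_id]
    if rows.empty:
        raise KeyError(f"probe {probe_id!r} not found in results for "
                       f"{results.trait_name!r}")
    row = rows.iloc[0]
    ann = annotation[annotation["probe_id"] == probe_id]
    catalog = catalog or CatalogCounts()
    detail = {
        "probe_id": probe_id,
        "trait_name": results.trait_name,
        "p_value": float(row["p_value"]),
        "beta": float(row["beta"]),
        "delta_meth": float(row["delta_meth"]),
        "catalog_count": catalog.get(probe_id),
        "hub_url": hub_url_template.format(probe_id=probe_id),
        "chromosome": None,
        "position": None,
        "gene_symbol": None,
        "feature": None,
    }
    if not ann.empty:
        arow = ann.iloc[0]
        detail["chromosome"] = str(arow["chromosome"])
        detail["position"] = int(arow["position"])
        gene = arow.get("gene_symbol")
        feat = arow.get("feature")
        detail["gene_symbol"] = gene if isinstance(gene, str) else None
        detail["feature"] = feat if isinstance(feat, str) else None
    else:
        logger.warning("probe %s has no annotation; coordinates unavailable",
                       probe_id)
    return detail
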