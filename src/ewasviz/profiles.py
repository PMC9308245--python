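"""Per-probe deep-dive products.

Once a probe is selected from a Manhattan or volcano plot the questions
become local: how does methylation at this CpG relate to the trait (and
does the relationship differ by sex), what do the neighbouring CpGs on
the array do across individuals (the DMR-window profile), how variable is
the probe (its SD, comparable across cohorts), and which probes anywhere
on the epigenome co-vary with it (the correlation profile).  This module
computes the data behind each of those views plus the merged trait +
methylation export used to hand a window to external pathway/network
tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ewasviz.io_model import BetaMatrix, EwasResultTable, TraitTable

logger = logging.getLogger("ewasviz")

STRATA = ("all", "female", "male")


# ---------------------------------------------------------------------------
# trait-methylation scatter with per-stratum trends
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """OLS fit of methylation on trait for one stratum with a 95% CI band.

    The band is the pointwise t-based confidence interval of the mean
    response over a grid spanning the stratum's observed trait range.
    """

    stratum: str
    n: int
    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple[float, float]
    grid: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    ci_low: np.ndarray = field(repr=False)
    ci_high: np.ndarray = field(repr=False)


def _ols_trend(x: np.ndarray, y: np.ndarray, stratum: str,
               n_grid: int = 50) -> TrendFit | None:
    n = len(x)
    if n < 3 or np.ptp(x) == 0:
        return None
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    slope_se = np.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(0.975, dof)
    grid = np.linspace(x.min(), x.max(), n_grid)
    predicted = intercept + slope * grid
    se_mean = np.sqrt(s2 * (1.0 / n + (grid - x.mean()) ** 2 / sxx))
    return TrendFit(stratum=stratum, n=n, slope=float(slope),
                    intercept=float(intercept), slope_se=float(slope_se),
                    slope_ci=(float(slope - tcrit * slope_se),
                              float(slope + tcrit * slope_se)),
                    grid=grid, predicted=predicted,
                    ci_low=predicted - tcrit * se_mean,
                    ci_high=predicted + tcrit * se_mean)


def trait_methylation(probe_id: str, trait_name: str,
                      betas: BetaMatrix, traits: TraitTable,
                      ) -> tuple[pd.DataFrame, dict[str, TrendFit]]:
    """Joined trait/methylation records plus trend fits for all/female/male.

    Records keep only individuals present in both tables with both values
    non-missing.  Each stratum with at least 3 points and non-constant
    trait gets an OLS trend of methylation on trait with a pointwise 95%
    confidence band.
    """
    meth = betas.probe_vector(probe_id)
    tvals = traits.trait_values(trait_name)
    records = pd.DataFrame({
        "individual_id": traits.individual_ids,
        "sex": traits.data["sex"].to_numpy(),
        "trait_value": tvals.to_numpy(),
    }).set_index("individual_id")
    records = records.join(meth.to_frame("methylation"), how="inner")
    records = records.dropna(subset=["trait_value", "methylation"])
    records = records.reset_index()
    if records.empty:
        raise ValueError(f"no individuals share probe {probe_id!r} and "
                         f"trait {trait_name!r}")

    fits: dict[str, TrendFit] = {}
    for stratum in STRATA:
        sub = (records if stratum == "all"
               else records[records["sex"] == stratum])
        fit = _ols_trend(sub["trait_value"].to_numpy(),
                         sub["methylation"].to_numpy(), stratum)
        if fit is not None:
            fits[stratum] = fit
        else:
            logger.info("stratum %s: <3 points or constant trait, no fit",
                        stratum)
    return records, fits


def violin_summary(records: pd.DataFrame, value_col: str = "trait_value",
                   n_grid: int = 64) -> pd.DataFrame:
    """Per-stratum distribution summary for violin-style rendering.

    One row per stratum with the five-number summary plus a kernel
    density estimate evaluated on an evenly spaced grid (NaN-filled when
    the stratum is too small or degenerate for a KDE).
    """
    rows = []
    for stratum in STRATA:
        sub = (records if stratum == "all"
               else records[records["sex"] == stratum])
        vals = sub[value_col].dropna().to_numpy()
        if vals.size == 0:
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        row = {"stratum": stratum, "n": vals.size, "min": q[0], "q25": q[1],
               "median": q[2], "q75": q[3], "max": q[4]}
        grid = np.linspace(q[0], q[4], n_grid)
        if vals.size >= 3 and np.ptp(vals) > 0:
            density = stats.gaussian_kde(vals)(grid)
        else:
            density = np.full(n_grid, np.nan)
        row["grid"] = grid.tolist()
        row["density"] = density.tolist()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMR window
# ---------------------------------------------------------------------------

@dataclass
class ProfileWindow:
    """A run of neighbouring CpGs around a centre probe, one chromosome.

    ``probes`` is annotation rows ordered by global array position (at
    most 2k+1 of them); ``methylation`` the matching beta sub-matrix; the
    x axis of any rendering is ordinal — real base-pair distances are not
    represented.  The window is a visualisation region, not a called DMR.
    """

    center_probe: str
    k: int
    probes: pd.DataFrame
    methylation: pd.DataFrame
    trait_values: pd.Series
    truncated_left: bool
    truncated_right: bool
    skipped_probes: list[str] = field(default_factory=list)


def dmr_window(center: str, k: int, annotation: pd.DataFrame,
               betas: BetaMatrix, traits: TraitTable,
               trait_name: str) -> ProfileWindow:
    """Window of up to k probes either side of the centre, same chromosome.

    Neighbours are taken by global array position and never cross a
    chromosome boundary; hitting a boundary sets the corresponding
    truncation flag.  Window probes missing from the beta matrix are
    skipped and recorded.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if "global_array_position" not in annotation.columns:
        from ewasviz.plotdata import assign_global_positions
        annotation = assign_global_positions(annotation)
    hit = annotation[annotation["probe_id"] == center]
    if hit.empty:
        raise KeyError(f"center probe {center!r} is not annotated")
    if center not in betas.probe_ids:
        raise KeyError(f"center probe {center!r} not in beta matrix")
    chrom = hit.iloc[0]["chromosome"]
    chrom_probes = (annotation[annotation["chromosome"] == chrom]
                    .sort_values("global_array_position")
                    .reset_index(drop=True))
    idx = int(chrom_probes.index[chrom_probes["probe_id"] == center][0])
    lo = max(0, idx - k)
    hi = min(len(chrom_probes) - 1, idx + k)
    window = chrom_probes.iloc[lo:hi + 1]

    present = window["probe_id"].isin(betas.probe_ids)
    skipped = window.loc[~present, "probe_id"].tolist()
    if skipped:
        logger.warning("window around %s: %d probes absent from beta matrix "
                       "skipped", center, len(skipped))
    window = window[present].reset_index(drop=True)
    meth = betas.values.loc[window["probe_id"]]
    return ProfileWindow(
        center_probe=center, k=k, probes=window, methylation=meth,
        trait_values=traits.trait_values(trait_name),
        truncated_left=idx - k < 0,
        truncated_right=idx + k > len(chrom_probes) - 1,
        skipped_probes=skipped,
    )


def trait_color_scale(trait_values: pd.Series) -> dict[str, str]:
    """Linear red-to-blue colour per individual: red = low, blue = high.

    A constant trait maps everyone to the scale midpoint; missing values
    are left out of the mapping.
    """
    vals = trait_values.dropna()
    if vals.empty:
        raise ValueError("no non-missing trait values to colour")
    lo, hi = float(vals.min()), float(vals.max())
    span = hi - lo

    def to_hex(t: float) -> str:
        r = int(round(255 * (1 - t)))
        b = int(round(255 * t))
        return f"#{r:02x}00{b:02x}"

    if span == 0:
        mid = to_hex(0.5)
        return {str(i): mid for i in vals.index}
    return {str(i): to_hex((float(v) - lo) / span) for i, v in vals.items()}


# ---------------------------------------------------------------------------
# per-probe SD and correlation profile
# ---------------------------------------------------------------------------

def probe_sd(probe_id: str, betas: BetaMatrix) -> float:
    """Sample SD (n-1 denominator) of a probe's beta values; NaN if n < 2.

    A probe's SD is comparable across cohorts even without the trait, so
    it serves as a replication check for a candidate probe.
    """
    vals = betas.probe_vector(probe_id).dropna().to_numpy()
    if vals.size < 2:
        return float("nan")
    return float(np.std(vals, ddof=1))


def correlation_profile(probe_id: str, betas: BetaMatrix,
                        top_n: int = 20, method: str = "pearson",
                        min_overlap: int = 10,
                        annotation: pd.DataFrame | None = None,
                        absolute: bool = True) -> pd.DataFrame:
    """Rank every other probe by correlation with the query probe.

    Correlations use pairwise-complete individuals; probes sharing fewer
    than ``min_overlap`` individuals with the query are silently excluded
    (with a logged count).  Ranking is by |corr| descending (signed
    ranking with ``absolute=False``), ties by probe id.  Annotation
    columns are joined onto the top ``top_n`` hits when provided.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    query = betas.probe_vector(probe_id)

    wide = betas.values.T  # individuals x probes
    others = wide.drop(columns=[probe_id])
    overlap = others.notna().mul(query.notna(), axis=0).sum(axis=0)
    eligible = overlap[overlap >= min_overlap].index
    excluded = len(others.columns) - len(eligible)
    if excluded:
        logger.info("correlation profile %s: %d probes below min_overlap=%d "
                    "excluded", probe_id, excluded, min_overlap)
    corr = others[eligible].corrwith(query, method=method)
    corr = corr.dropna()

    hits = pd.DataFrame({
        "probe_id": corr.index,
        "corr_coeff": corr.to_numpy(),
        "n_pairs": overlap.loc[corr.index].to_numpy(dtype=int),
    })
    sort_key = hits["corr_coeff"].abs() if absolute else hits["corr_coeff"]
    hits = (hits.assign(_key=-sort_key)
            .sort_values(["_key", "probe_id"], kind="mergesort")
            .drop(columns="_key")
            .head(top_n)
            .reset_index(drop=True))
    if annotation is not None:
        cols = [c for c in ("probe_id", "gene_symbol", "feature",
                            "chromosome", "position") if c in annotation.columns]
        hits = hits.merge(annotation[cols], on="probe_id", how="left")
    return hits


# ---------------------------------------------------------------------------
# merged export
# ---------------------------------------------------------------------------

def export_merged(window: ProfileWindow, traits: TraitTable,
                  out_path, trait_name: str | None = None,
                  results: EwasResultTable | None = None) -> pd.DataFrame:
    """Write the window's merged individual-level data for external tools.

    The main sheet has one row per individual — id, sex, trait value,
    then one beta column per window probe (individuals missing the trait
    keep their row with an empty trait cell).  A companion
    ``<stem>_probes.csv`` sheet lists gene symbol, p-value and delta
    methylation per probe for pathway-tool import.  Returns the main
    frame.
    """
    from pathlib import Path

    out_path = Path(out_path)
    tvals = window.trait_values
    trait_col = trait_name or (tvals.name or "trait")
    individuals = window.methylation.columns
    main = pd.DataFrame({
        "individual_id": individuals,
        "sex": traits.data["sex"].reindex(individuals).to_numpy(),
        trait_col: tvals.reindex(individuals).to_numpy(),
    })
    for probe in window.probes["probe_id"]:
        main[probe] = window.methylation.loc[probe].reindex(individuals).to_numpy()
    main.to_csv(out_path, index=False)

    probe_sheet = window.probes[["probe_id", "chromosome", "position",
                                 "gene_symbol", "feature"]].copy()
    if results is not None:
        probe_sheet = probe_sheet.merge(
            results.data[["probe_id", "p_value", "delta_meth"]],
            on="probe_id", how="left")
    sheet_path = out_path.with_name(out_path.stem + "_probes.csv")
    probe_sheet.to_csv(sheet_path, index=False)
    return main
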