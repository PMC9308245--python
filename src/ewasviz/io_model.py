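"""On-disk data contract and validated in-memory types.

EWAS screening pipelines emit one result file per trait: a table of CpG
probes with the regression p-value (``P_VAL``), the regression coefficient
(``Beta``) and the observed methylation range across individuals
(``DeltaMeth``).  Alongside these live a probe-by-individual matrix of
methylation beta-values, a per-individual trait table (the join key for
everything), a probe annotation table, an optional multimodal-probe
exclusion list and an optional catalog of prior findings per probe.

This module loads and validates all of those, defines the two scalar
formulas of the methylation domain (the beta-value and the delta
methylation range), and maintains a cached per-trait summary index so that
folders with hundreds of result files do not have to be re-parsed on every
run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ewasviz")

#: canonical chromosome order used for global array positions
CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

_FINGERPRINT_BYTES = 64 * 1024  # content digest covers the first 64 KiB


# ---------------------------------------------------------------------------
# dialect / load reports
# ---------------------------------------------------------------------------

@dataclass
class CsvDialect:
    """CSV conventions for all tabular inputs.

    Result files frequently come out of spreadsheet or locale-sensitive R
    exports, so separator and decimal mark are explicit rather than sniffed.
    """

    sep: str = ","
    decimal: str = "."
    encoding: str = "utf-8"
    probe_id_col: str = "probeID"
    p_col: str = "P_VAL"
    beta_col: str = "Beta"
    delta_col: str = "DeltaMeth"


@dataclass
class LoadReport:
    """Outcome of one load: rows read, rows rejected, coercions, notes."""

    path: str = ""
    rows_read: int = 0
    rows_rejected: int = 0
    reject_reasons: dict[str, int] = field(default_factory=dict)
    coerced_missing: int = 0
    signed_delta: bool = False
    warnings: list[str] = field(default_factory=list)

    def reject(self, reason: str, n: int = 1) -> None:
        self.rows_rejected += n
        self.reject_reasons[reason] = self.reject_reasons.get(reason, 0) + n

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning("%s: %s", self.path, message)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EwasResultTable:
    """Per-trait EWAS screening output.

    ``data`` holds one row per probe with columns ``probe_id``, ``p_value``,
    ``beta`` and ``delta_meth``.  Every ``p_value`` lies in (0, 1];
    offending rows are rejected at load.  ``delta_meth`` may be signed when
    the producing pipeline orients the methylation range by effect
    direction (negative = hypo-methylated).
    """

    trait_name: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def probe_ids(self) -> pd.Series:
        return self.data["probe_id"]

    def top_probe(self) -> str:
        """Probe with the smallest p-value; ties broken by probe id."""
        if self.data.empty:
            raise ValueError(f"result table for {self.trait_name!r} is empty")
        order = self.data.sort_values(["p_value", "probe_id"], kind="mergesort")
        return str(order.iloc[0]["probe_id"])


@dataclass
class BetaMatrix:
    """Probe-by-individual methylation beta-values in [0, 1], NaN = missing."""

    values: pd.DataFrame  # index: probe ids, columns: individual ids

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def individual_ids(self) -> pd.Index:
        return self.values.columns

    def probe_vector(self, probe_id: str) -> pd.Series:
        if probe_id not in self.values.index:
            raise KeyError(f"probe {probe_id!r} not in beta matrix")
        return self.values.loc[probe_id]


@dataclass
class TraitTable:
    """Per-individual sex and numeric trait values.

    ``data`` is indexed by individual id with a ``sex`` column (values in
    {female, male, unknown} after config mapping) plus one numeric column
    per trait.
    """

    data: pd.DataFrame

    @property
    def individual_ids(self) -> pd.Index:
        return self.data.index

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "sex"]

    def trait_values(self, trait_name: str) -> pd.Series:
        if trait_name not in self.data.columns or trait_name == "sex":
            raise KeyError(f"trait {trait_name!r} not in trait table")
        return self.data[trait_name]


class CatalogCounts:
    """Per-probe count of prior findings; probes not listed count as 0."""

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        self._counts: dict[str, int] = {}
        for probe, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative catalog count for {probe!r}")
            self._counts[str(probe)] = n

    def get(self, probe_id: str) -> int:
        return self._counts.get(probe_id, 0)

    def __len__(self) -> int:
        return len(self._counts)

    def as_series(self, probe_ids: Iterable[str]) -> pd.Series:
        ids = list(probe_ids)
        return pd.Series([self.get(p) for p in ids], index=ids, dtype=int)


@dataclass
class TraitSummary:
    """Aggregated descriptive metrics for one trait's result file."""

    trait_name: str
    n_probes: int
    min_p: float
    max_abs_delta: float
    top_probe_id: str
    scagnostics: dict[str, float] | None = None
    source_fingerprint: str = ""


# ---------------------------------------------------------------------------
# scalar formulas
# ---------------------------------------------------------------------------

def beta_value(meth_intensity: float, unmeth_intensity: float) -> float:
    """Methylation proportion: methylated / (methylated + unmethylated).

    Returns NaN when both intensities are zero (no signal at the probe).
    Accepts array inputs elementwise.
    """
    m = np.asarray(meth_intensity, dtype=float)
    u = np.asarray(unmeth_intensity, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def delta_methylation(betas: Iterable[float]) -> float:
    """Methylation range max(beta) - min(beta), ignoring missing values.

    The range across individuals at one CpG; NaN when every value is
    missing.  Always non-negative by construction.
    """
    arr = np.asarray(list(betas) if not isinstance(betas, np.ndarray) else betas,
                     dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmax(arr) - np.nanmin(arr))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, dialect: CsvDialect, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal,
                       encoding=dialect.encoding, **kwargs)


def read_ewas_results(path: str | Path,
                      dialect: CsvDialect | None = None,
                      ) -> tuple[EwasResultTable, LoadReport]:
    """Load one per-trait result file.

    The trait name is the file stem.  Rows with a p-value outside (0, 1]
    or non-numeric are rejected and counted; a signed delta column is
    flagged in the report rather than rejected.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    report = LoadReport(path=str(path))
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_csv(path, dialect)
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"{path}: empty result file")
    for col in (dialect.probe_id_col, dialect.p_col, dialect.beta_col,
                dialect.delta_col):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if raw.empty:
        raise ValueError(f"{path}: result file has a header but no rows")

    df = pd.DataFrame({
        "probe_id": raw[dialect.probe_id_col].astype(str),
        "p_value": pd.to_numeric(raw[dialect.p_col], errors="coerce"),
        "beta": pd.to_numeric(raw[dialect.beta_col], errors="coerce"),
        "delta_meth": pd.to_numeric(raw[dialect.delta_col], errors="coerce"),
    })
    report.rows_read = len(df)

    bad_p = df["p_value"].isna() | (df["p_value"] <= 0) | (df["p_value"] > 1)
    if bad_p.any():
        report.reject("p_value outside (0, 1]", int(bad_p.sum()))
        df = df[~bad_p]

    dup = df["probe_id"].duplicated(keep="first")
    if dup.any():
        report.reject("duplicate probe_id", int(dup.sum()))
        df = df[~dup]

    if (df["delta_meth"] < 0).any():
        report.signed_delta = True
        report.warn("delta_meth carries signed values (effect-oriented range)")

    table = EwasResultTable(trait_name=path.stem, data=df.reset_index(drop=True))
    return table, report


def read_beta_matrix(path: str | Path,
                     dialect: CsvDialect | None = None,
                     ) -> tuple[BetaMatrix, LoadReport]:
    """Load the probe x individual beta matrix.

    Entries outside [0, 1] are not trusted (a beta-value is a proportion)
    and are coerced to missing, with the coercion counted.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    report = LoadReport(path=str(path))
    with path.open(encoding=dialect.encoding) as fh:
        header = fh.readline().rstrip("\n").split(dialect.sep)[1:]
    seen = pd.Index(header)
    if seen.duplicated().any():
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate individual ids {dups}")
    raw = _read_csv(path, dialect, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe ids {dups}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    out_of_range = (values < 0) | (values > 1)
    n_bad = int(out_of_range.sum().sum())
    if n_bad:
        values = values.mask(out_of_range)
        report.coerced_missing = n_bad
        report.warn(f"{n_bad} entries outside [0, 1] set to missing")
    report.rows_read = len(values)
    return BetaMatrix(values=values), report


def read_trait_table(path: str | Path,
                     sex_mapping: Mapping[str, str] | None = None,
                     dialect: CsvDialect | None = None,
                     id_col: str = "ID",
                     sex_col: str = "sex",
                     ) -> tuple[TraitTable, LoadReport]:
    """Load the per-individual trait table and normalise the sex coding.

    ``sex_mapping`` maps raw codes (as strings) to {female, male, unknown};
    unmapped codes become ``unknown`` with a warning.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    report = LoadReport(path=str(path))
    raw = _read_csv(path, dialect)
    if id_col not in raw.columns:
        raise ValueError(f"{path}: missing individual id column {id_col!r}")
    raw[id_col] = raw[id_col].astype(str)
    if raw[id_col].duplicated().any():
        raise ValueError(f"{path}: duplicate individual ids")
    raw = raw.set_index(id_col)
    report.rows_read = len(raw)

    mapping = {str(k): v for k, v in (sex_mapping or {}).items()}
    valid = {"female", "male", "unknown"}
    if sex_col in raw.columns:
        codes = raw[sex_col].astype(str)
        mapped = codes.map(lambda c: mapping.get(c, c if c in valid else None))
        unknown_mask = mapped.isna()
        if unknown_mask.any():
            bad = sorted(codes[unknown_mask].unique().tolist())
            report.warn(f"unmapped sex codes {bad} set to 'unknown'")
            mapped = mapped.fillna("unknown")
        raw[sex_col] = mapped
    else:
        report.warn(f"no {sex_col!r} column; all individuals set to 'unknown'")
        raw.insert(0, sex_col, "unknown")

    for col in raw.columns:
        if col != sex_col:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    if sex_col != "sex":
        raw = raw.rename(columns={sex_col: "sex"})
    return TraitTable(data=raw), report


def read_annotation(path: str | Path,
                    dialect: CsvDialect | None = None,
                    ) -> tuple[pd.DataFrame, LoadReport]:
    """Load probe annotation (chromosome, position, gene symbol, feature).

    Rows with a chromosome outside 1..22/X/Y are rejected with a warning.
    The returned frame carries no global positions yet; see
    :func:`ewasviz.plotdata.assign_global_positions`.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    report = LoadReport(path=str(path))
    raw = _read_csv(path, dialect)
    col_map = {dialect.probe_id_col: "probe_id", "gene.symbol": "gene_symbol"}
    raw = raw.rename(columns=col_map)
    required = {"probe_id", "chromosome", "position"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    raw["probe_id"] = raw["probe_id"].astype(str)
    raw["chromosome"] = (raw["chromosome"].astype(str)
                         .str.replace("^chr", "", regex=True))
    report.rows_read = len(raw)
    bad = ~raw["chromosome"].isin(CHROMOSOMES)
    if bad.any():
        report.reject("chromosome outside 1..22/X/Y", int(bad.sum()))
        report.warn(f"{int(bad.sum())} rows with unrecognised chromosome dropped")
        raw = raw[~bad]
    raw["position"] = pd.to_numeric(raw["position"], errors="coerce").astype("Int64")
    for col in ("gene_symbol", "feature"):
        if col not in raw.columns:
            raw[col] = pd.NA
    return raw.reset_index(drop=True), report


def read_multimodal_list(path: str | Path) -> set[str]:
    """Read the multimodal-probe exclusion list: one probe id per line."""
    text = Path(path).read_text(encoding="utf-8")
    return {line.strip() for line in text.splitlines() if line.strip()}


def read_catalog_counts(path: str | Path,
                        dialect: CsvDialect | None = None) -> CatalogCounts:
    """Read per-probe prior-finding counts (probes absent count as 0)."""
    dialect = dialect or CsvDialect()
    raw = _read_csv(path, dialect)
    if dialect.probe_id_col in raw.columns:
        probe_col = dialect.probe_id_col
    else:
        probe_col = raw.columns[0]
    count_col = "count" if "count" in raw.columns else raw.columns[1]
    return CatalogCounts(dict(zip(raw[probe_col].astype(str),
                                  raw[count_col].astype(int))))


# ---------------------------------------------------------------------------
# summary index with cache
# ---------------------------------------------------------------------------

def _fingerprint(path: Path) -> str:
    stat = path.stat()
    digest = hashlib.sha256(path.open("rb").read(_FINGERPRINT_BYTES)).hexdigest()
    return f"{stat.st_size}:{stat.st_mtime_ns}:{digest}"


def _summarize_one(path: Path, filters, multimodal: set[str],
                   dialect: CsvDialect,
                   betas: BetaMatrix | None,
                   traits: TraitTable | None) -> TraitSummary | None:
    from ewasviz.screening import apply_probe_filters  # avoid import cycle

    try:
        table, _ = read_ewas_results(path, dialect)
    except (ValueError, pd.errors.ParserError) as exc:
        logger.warning("skipping unparseable result file %s: %s", path, exc)
        return None
    filtered, _ = apply_probe_filters(table, filters, multimodal)
    if filtered.data.empty:
        logger.warning("trait %s: no probes survive filtering", table.trait_name)
        return TraitSummary(trait_name=table.trait_name, n_probes=0,
                            min_p=float("nan"), max_abs_delta=float("nan"),
                            top_probe_id="", source_fingerprint=_fingerprint(path))
    scag = None
    if betas is not None and traits is not None:
        from ewasviz.scagnostics import scagnostics_for_trait
        profile = scagnostics_for_trait(table.trait_name, filtered, betas, traits)
        scag = profile.as_dict() if profile is not None else None
    return TraitSummary(
        trait_name=table.trait_name,
        n_probes=len(filtered),
        min_p=float(filtered.data["p_value"].min()),
        max_abs_delta=float(filtered.data["delta_meth"].abs().max()),
        top_probe_id=filtered.top_probe(),
        scagnostics=scag,
        source_fingerprint=_fingerprint(path),
    )


def build_summary_index(results_dir: str | Path,
                        filters=None,
                        cache_path: str | Path | None = None,
                        multimodal: set[str] | None = None,
                        dialect: CsvDialect | None = None,
                        betas: BetaMatrix | None = None,
                        traits: TraitTable | None = None,
                        ) -> list[TraitSummary]:
    """Build (or refresh) the per-trait summary index for a results folder.

    Every ``*.csv`` file in ``results_dir`` is summarised after probe
    filtering: number of surviving probes, minimum p-value, maximum
    absolute delta methylation, top probe, and (when a beta matrix and
    trait table are supplied) the nine scagnostics of the top-probe
    scatter.  Summaries are persisted to ``cache_path`` as JSON lines
    keyed by a source fingerprint (file size, mtime, content digest of the
    leading 64 KiB); an unchanged file is served from the cache without
    re-reading, a changed file invalidates only its own entry.
    """
    from ewasviz.screening import FilterConfig

    filters = filters if filters is not None else FilterConfig()
    multimodal = multimodal or set()
    dialect = dialect or CsvDialect()
    results_dir = Path(results_dir)
    files = sorted(results_dir.glob("*.csv"))
    if not files:
        raise ValueError(f"no result files (*.csv) found in {results_dir}")

    cached: dict[str, dict] = {}
    if cache_path is not None and Path(cache_path).exists():
        for line in Path(cache_path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                entry = json.loads(line)
                cached[entry["trait_name"]] = entry

    summaries: list[TraitSummary] = []
    for path in files:
        trait = path.stem
        fp = _fingerprint(path)
        hit = cached.get(trait)
        if hit is not None and hit["source_fingerprint"] == fp:
            summaries.append(TraitSummary(**hit))
            continue
        summary = _summarize_one(path, filters, multimodal, dialect, betas, traits)
        if summary is not None:
            summaries.append(summary)

    if cache_path is not None:
        lines = [json.dumps(asdict(s), sort_keys=True) for s in summaries]
        Path(cache_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return summaries


def summaries_to_frame(summaries: list[TraitSummary]) -> pd.DataFrame:
    """Tidy one-row-per-trait frame with scagnostics expanded to columns."""
    from ewasviz.scagnostics import MEASURE_NAMES

    rows = []
    for s in summaries:
        row = {"trait_name": s.trait_name, "n_probes": s.n_probes,
               "min_p": s.min_p, "max_abs_delta": s.max_abs_delta,
               "top_probe_id": s.top_probe_id}
        for name in MEASURE_NAMES:
            row[name] = (s.scagnostics or {}).get(name, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
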