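"""Probe- and trait-level filtering and ranking.

Three probe filters precede any visualisation or ranking step: a p-value
floor (regression engines occasionally emit p-values at the lower edge of
IEEE 754 double range, which are artefacts of the numeric pipeline rather
than evidence), a minimum case count, and removal of probes on a
predefined multimodal list (multi-modal beta distributions are usually
genotype-driven and uninformative for trait association).  A top-percent
selector then limits plots to the strongest signals, and traits themselves
can be ordered by any summary measure for triage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from ewasviz.io_model import EwasResultTable, TraitSummary

logger = logging.getLogger("ewasviz")

#: summary keys order_traits accepts besides the nine scagnostics
_BASE_ORDER_KEYS = ("min_p", "max_abs_delta")


@dataclass
class FilterConfig:
    """Probe-filter thresholds.

    p_floor
        Reject p-values below this bound.  Defaults to 1e-300, safely
        above the denormal range of IEEE 754 doubles where p-values stop
        being meaningful.
    min_n
        Minimum per-model case count; 0 disables.  Requires an ``n``
        column in the result file — when absent the filter is inert and a
        warning is logged.
    exclude_multimodal
        Drop probes on the multimodal exclusion list.
    top_percent
        Default top-percent selection for plot builders, in (0, 100].
    """

    p_floor: float = 1e-300
    min_n: int = 0
    exclude_multimodal: bool = True
    top_percent: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_floor < 1.0):
            raise ValueError("p_floor must lie in (0, 1)")
        if not (0.0 < self.top_percent <= 100.0):
            raise ValueError("top_percent must lie in (0, 100]")
        if self.min_n < 0:
            raise ValueError("min_n must be >= 0")


def apply_probe_filters(table: EwasResultTable,
                        cfg: FilterConfig,
                        multimodal: set[str] | None = None,
                        ) -> tuple[EwasResultTable, dict[str, int]]:
    """Apply the p-floor, min-n and multimodal filters to one result table.

    Returns the filtered table plus a report counting removals per rule.
    An empty survivor set is legal and flagged in the report.
    """
    multimodal = multimodal or set()
    df = table.data
    report = {"input_rows": len(df), "p_floor": 0, "min_n": 0, "multimodal": 0}

    below_floor = df["p_value"] < cfg.p_floor
    report["p_floor"] = int(below_floor.sum())
    df = df[~below_floor]

    if cfg.min_n > 0:
        if "n" in df.columns:
            small = df["n"] < cfg.min_n
            report["min_n"] = int(small.sum())
            df = df[~small]
        else:
            logger.warning("trait %s: min_n filter requested but result file "
                           "has no 'n' column; filter inert", table.trait_name)

    if cfg.exclude_multimodal and multimodal:
        mm = df["probe_id"].isin(multimodal)
        report["multimodal"] = int(mm.sum())
        df = df[~mm]

    report["output_rows"] = len(df)
    if len(df) == 0:
        report["empty_output"] = 1
        logger.warning("trait %s: all probes removed by filters",
                       table.trait_name)
    return EwasResultTable(table.trait_name, df.reset_index(drop=True)), report


def top_percent_probes(table: EwasResultTable, pct: float) -> EwasResultTable:
    """Keep the ceil(pct/100 * N) probes with the smallest p-values.

    Ties at the cut are broken by (p_value, probe_id) so the selection is
    deterministic; the ceiling guarantees a non-empty result for any
    pct > 0.  Surviving rows keep their input order.
    """
    if not (0.0 < pct <= 100.0):
        raise ValueError("pct must lie in (0, 100]")
    df = table.data
    n = len(df)
    if n == 0:
        return EwasResultTable(table.trait_name, df.copy())
    k = math.ceil(pct / 100.0 * n)
    ranked = df.sort_values(["p_value", "probe_id"], kind="mergesort")
    keep = set(ranked.index[:k])
    out = df[df.index.isin(keep)].reset_index(drop=True)
    return EwasResultTable(table.trait_name, out)


def order_traits(summaries: list[TraitSummary], key: str) -> list[TraitSummary]:
    """Order trait summaries for triage.

    ``min_p`` sorts ascending (strongest association first); every other
    key — ``max_abs_delta`` or one of the nine scagnostics — sorts
    descending.  Ties break alphabetically by trait name; traits lacking
    the requested scagnostic sort last with a warning.
    """
    from ewasviz.scagnostics import MEASURE_NAMES

    valid = _BASE_ORDER_KEYS + tuple(MEASURE_NAMES)
    if key not in valid:
        raise ValueError(f"unknown ordering key {key!r}; valid keys: "
                         f"{', '.join(valid)}")
    if not summaries:
        raise ValueError("no trait summaries to order")

    def value_of(s: TraitSummary) -> float | None:
        if key == "min_p":
            return s.min_p
        if key == "max_abs_delta":
            return s.max_abs_delta
        if s.scagnostics is None or key not in s.scagnostics:
            return None
        return s.scagnostics[key]

    missing = [s for s in summaries if value_of(s) is None
               or math.isnan(value_of(s))]
    present = [s for s in summaries if s not in missing]
    if missing:
        logger.warning("%d traits lack measure %r; sorted last",
                       len(missing), key)
    ascending = key == "min_p"
    present.sort(key=lambda s: ((1 if ascending else -1) * value_of(s),
                                s.trait_name))
    missing.sort(key=lambda s: s.trait_name)
    return present + missing
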