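"""Turnaround-time summaries: district banding and before/after comparisons.

A turnaround record splits a sample's journey into the *pre-analytic*
component (clinic dispatch, courier transport, batching — dominated by the
assignment distance) and the *laboratory-to-result* (LTR) component, from
registration on the laboratory information system to result authorization.
District performance is reported as the fraction of records whose LTR time
meets a threshold (default 48 h), banded into contiguous percentage bands
for choropleth-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Contiguous band edges on the percent-within-threshold scale.  A fraction
#: f (percent) falls in [0,35), [35,85), [85,95) or [95,100].
DEFAULT_BAND_EDGES: tuple[float, ...] = (35.0, 85.0, 95.0)

DEFAULT_BAND_LABELS: tuple[str, ...] = ("<35%", "35-85%", "85-95%", "95-100%")

TAT_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "facility_id",
    "district_id",
    "pre_analytic_h",
    "ltr_h",
    "total_h",
)


def band_label(
    percent_within: float,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
    labels: Sequence[str] | None = None,
) -> str:
    """Band for a percent-within-threshold value under contiguous edges."""
    edges = list(band_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError(f"band edges must be strictly increasing, got {edges}")
    if labels is None:
        labels = (
            DEFAULT_BAND_LABELS
            if tuple(edges) == DEFAULT_BAND_EDGES
            else [f"band{k}" for k in range(len(edges) + 1)]
        )
    k = int(np.searchsorted(edges, percent_within, side="right"))
    return labels[k]


def summarize_tat(
    records: pd.DataFrame,
    threshold_h: float = 48.0,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
    districts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-district fraction of LTR times within a threshold, with bands.

    ``districts`` optionally fixes the set of districts to report; any of
    them absent from the records appear with ``n = 0`` and no band.

    Returns columns ``district_id, n, fraction_within, percent_within, band``.
    """
    if len(records) == 0:
        raise ValidationError("no turnaround records to summarize")
    grouped = records.groupby("district_id")["ltr_h"].agg(
        n="size", within=lambda s: float((s <= threshold_h).sum())
    )
    if districts is not None:
        grouped = grouped.reindex([str(d) for d in districts])
    grouped = grouped.sort_index()
    rows = []
    for district_id, row in grouped.iterrows():
        n = 0 if pd.isna(row["n"]) else int(row["n"])
        if n == 0:
            rows.append((district_id, 0, np.nan, np.nan, None))
            continue
        frac = row["within"] / n
        rows.append((district_id, n, frac, 100.0 * frac, band_label(100.0 * frac, band_edges)))
    return pd.DataFrame(
        rows, columns=["district_id", "n", "fraction_within", "percent_within", "band"]
    )


def national_fraction_within(records: pd.DataFrame, threshold_h: float = 48.0) -> float:
    """Record-weighted national fraction of LTR times within the threshold."""
    if len(records) == 0:
        raise ValidationError("no turnaround records")
    return float((records["ltr_h"] <= threshold_h).mean())


@dataclass(frozen=True)
class BeforeAfter:
    """Paired district TAT summary for two simulation arms."""

    district_id: str
    n_before: int
    n_after: int
    median_pre_before_h: float
    median_pre_after_h: float
    median_total_before_h: float
    median_total_after_h: float
    fraction_within_before: float
    fraction_within_after: float

    @property
    def delta_median_pre_h(self) -> float:
        return self.median_pre_after_h - self.median_pre_before_h

    @property
    def delta_median_total_h(self) -> float:
        return self.median_total_after_h - self.median_total_before_h


def before_after(
    records_before: pd.DataFrame,
    records_after: pd.DataFrame,
    district: str,
    threshold_h: float = 48.0,
) -> BeforeAfter:
    """Paired medians and threshold fractions for one district, two arms."""
    before = records_before[records_before["district_id"] == str(district)]
    after = records_after[records_after["district_id"] == str(district)]
    if len(before) == 0 or len(after) == 0:
        raise ValidationError(
            f"district {district!r} absent from the "
            f"{'before' if len(before) == 0 else 'after'} record set"
        )
    return BeforeAfter(
        district_id=str(district),
        n_before=len(before),
        n_after=len(after),
        median_pre_before_h=float(before["pre_analytic_h"].median()),
        median_pre_after_h=float(after["pre_analytic_h"].median()),
        median_total_before_h=float(before["total_h"].median()),
        median_total_after_h=float(after["total_h"].median()),
        fraction_within_before=float((before["ltr_h"] <= threshold_h).mean()),
        fraction_within_after=float((after["ltr_h"] <= threshold_h).mean()),
    )
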