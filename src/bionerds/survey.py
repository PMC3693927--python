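"""Corpus-level resource-usage analytics.

Given per-document resource lists and document metadata (journal,
year), this module computes:

* yearly **relative usage** — documents mentioning a resource divided
  by the total documents that year (or raw mention counts);
* the **variation statistic** sigma-delta, the sum over consecutive
  years of absolute changes in a resource's (normalised) frequency;
* **Gaussian random-walk bounds** — an envelope ``k*mu ± 2*sigma*sqrt(k)``
  fitted to pooled year-over-year changes, against which observed
  trajectories are compared: a trajectory escaping the envelope is
  changing faster than drift alone explains (a flat ``± 2*sigma``
  variant is available);
* **long-tail** summaries (fraction of resources mentioned once /
  fewer than N times, share of all mentions held by the top K);
* **cross-journal overlap** of resource name sets and the mention share
  of the shared names.

Survey-level grouping case-folds names on top of the document-level
normalisation, mirroring the limited variant aggregation applied when
pooling across a corpus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .doc_resolution import normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "UsageSeries",
    "VariationStat",
    "RandomWalkBounds",
    "survey_key",
    "relative_usage",
    "usage_table",
    "sigma_delta",
    "random_walk_bounds",
    "trajectory_exceeds",
    "long_tail_stats",
    "journal_overlap",
    "normalized_frequencies",
]


def survey_key(name: str) -> str:
    """Survey-level grouping key: normalised and case-folded."""
    return normalize_name(name).casefold()


@dataclass
class UsageSeries:
    resource: str
    journal: str | None
    level: str  # "document" | "mention"
    counts_by_year: dict[int, int] = field(default_factory=dict)
    relative_by_year: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VariationStat:
    resource: str
    sigma_delta: float


@dataclass
class RandomWalkBounds:
    mean_step: float
    sd_step: float
    upper: dict[int, float]
    lower: dict[int, float]


def relative_usage(
    doc_lists: Mapping[str, Mapping[str, int]],
    metadata: pd.DataFrame,
    resource: str,
    level: str = "document",
    journal: str | None = None,
) -> UsageSeries:
    """Yearly usage of one resource.

    ``doc_lists`` maps doc_id -> {resource name -> mention count} (the
    document-level lists produced by the pipeline).  At document level
    the count per year is the number of documents mentioning the
    resource and the relative value divides by the total number of
    documents that year; at mention level counts are summed mentions.
    Documents without a year are excluded with a warning.
    """
    if level not in ("document", "mention"):
        raise ValueError(f"unknown level: {level!r}")
    key = survey_key(resource)
    meta = metadata
    if journal is not None:
        meta = meta[meta["journal"] == journal]
    missing = meta["year"].isna()
    if missing.any():
        logger.warning("%d documents without year excluded", int(missing.sum()))
        meta = meta[~missing]

    totals: dict[int, int] = {}
    counts: dict[int, int] = {}
    for doc_id, year in zip(meta["doc_id"], meta["year"]):
        year = int(year)
        totals[year] = totals.get(year, 0) + 1
        names = doc_lists.get(doc_id, {})
        hits = sum(c for n, c in names.items() if survey_key(n) == key)
        if hits:
            counts[year] = counts.get(year, 0) + (1 if level == "document" else hits)

    series = UsageSeries(resource=resource, journal=journal, level=level)
    for year in sorted(totals):
        series.counts_by_year[year] = counts.get(year, 0)
        if level == "document":
            series.relative_by_year[year] = counts.get(year, 0) / totals[year]
    return series


def usage_table(
    doc_lists: Mapping[str, Mapping[str, int]],
    metadata: pd.DataFrame,
    level: str = "document",
    journal: str | None = None,
) -> pd.DataFrame:
    """Tidy (resource, year, count) table over all resources."""
    meta = metadata
    if journal is not None:
        meta = meta[meta["journal"] == journal]
    meta = meta[~meta["year"].isna()]
    rows: dict[tuple[str, int], int] = {}
    for doc_id, year in zip(meta["doc_id"], meta["year"]):
        year = int(year)
        for name, count in doc_lists.get(doc_id, {}).items():
            k = (survey_key(name), year)
            rows[k] = rows.get(k, 0) + (1 if level == "document" else count)
    return pd.DataFrame(
        [(r, y, c) for (r, y), c in sorted(rows.items())],
        columns=["resource", "year", "count"],
    )


def sigma_delta(
    series: Mapping[int, float], year_range: tuple[int, int], resource: str = ""
) -> VariationStat:
    """Sum of absolute year-over-year changes across ``year_range``
    (inclusive endpoints); missing years count as 0."""
    first, last = year_range
    if last - first < 1:
        raise ValueError("year_range must span at least 2 years")
    total = sum(
        abs(series.get(y + 1, 0.0) - series.get(y, 0.0))
        for y in range(first, last)
    )
    return VariationStat(resource=resource, sigma_delta=total)


def random_walk_bounds(
    normalized_changes: Sequence[float],
    horizon: int,
    cumulative: bool = True,
) -> RandomWalkBounds:
    """95% envelope of a Gaussian random walk fitted to pooled changes.

    The step mean and standard deviation are the sample statistics of
    ``normalized_changes`` (year-over-year changes of usage normalised
    to a Year-0 baseline, pooled over resources).  At step k the bounds
    are ``k*mu ± 2*sigma*sqrt(k)`` — the cumulative variance of a
    random walk — or ``k*mu ± 2*sigma`` with ``cumulative=False``.
    """
    if len(normalized_changes) < 2:
        raise ValueError("need at least 2 change observations")
    mu = float(np.mean(normalized_changes))
    sd = float(np.std(normalized_changes, ddof=1))
    upper: dict[int, float] = {}
    lower: dict[int, float] = {}
    for k in range(horizon + 1):
        half = 2.0 * sd * (math.sqrt(k) if cumulative else (1.0 if k else 0.0))
        upper[k] = k * mu + half
        lower[k] = k * mu - half
    return RandomWalkBounds(mean_step=mu, sd_step=sd, upper=upper, lower=lower)


def trajectory_exceeds(
    trajectory: Mapping[int, float] | Sequence[float],
    bounds: RandomWalkBounds,
) -> bool:
    """True iff the trajectory escapes the envelope at any step."""
    items = (
        trajectory.items()
        if isinstance(trajectory, Mapping)
        else enumerate(trajectory)
    )
    for k, v in items:
        if k in bounds.upper and not (bounds.lower[k] <= v <= bounds.upper[k]):
            return True
    return False


def long_tail_stats(
    mention_counts: Mapping[str, int] | Sequence[int],
    below_n: int = 6,
    top_k: int = 100,
) -> dict[str, float]:
    """Long-tail summary of a resource mention-count table."""
    counts = sorted(
        mention_counts.values() if isinstance(mention_counts, Mapping)
        else mention_counts,
        reverse=True,
    )
    if not counts:
        raise ValueError("empty count table")
    n = len(counts)
    total = sum(counts)
    return {
        "fraction_once": sum(1 for c in counts if c == 1) / n,
        "fraction_below_n": sum(1 for c in counts if c < below_n) / n,
        "top_k_share": sum(counts[:top_k]) / total if total else 0.0,
    }


def journal_overlap(
    names_a: Iterable[str],
    names_b: Iterable[str],
    mention_counts: Mapping[str, int],
) -> dict[str, float]:
    """Union/intersection statistics of two journals' resource name sets.

    ``mention_counts`` holds total mentions per (survey-key) name.
    Reports the Jaccard fraction of shared names and the intersection's
    share of each journal's mentions and of all mentions.
    """
    a = {survey_key(n) for n in names_a}
    b = {survey_key(n) for n in names_b}
    counts = {survey_key(n): c for n, c in mention_counts.items()}
    inter, union = a & b, a | b

    def share(names: set[str]) -> float:
        denom = sum(counts.get(n, 0) for n in names)
        return (
            sum(counts.get(n, 0) for n in inter) / denom if denom else 0.0
        )

    return {
        "jaccard": len(inter) / len(union) if union else 0.0,
        "intersection_share_a": share(a),
        "intersection_share_b": share(b),
        "intersection_share_total": share(union),
    }


def normalized_frequencies(
    table: pd.DataFrame, top_n: int = 50
) -> pd.DataFrame:
    """Per-year frequencies of the top-N resources, each year's counts
    divided by that year's total over the top-N set.

    ``table`` is the tidy (resource, year, count) frame from
    :func:`usage_table`.
    """
    totals = table.groupby("resource")["count"].sum()
    top = set(totals.sort_values(ascending=False).head(top_n).index)
    sub = table[table["resource"].isin(top)].copy()
    year_totals = sub.groupby("year")["count"].transform("sum")
    sub["normalized"] = sub["count"] / year_totals
    return sub.reset_index(drop=True)
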