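"""Pearson correlation of per-taxon contributions against environmental
metadata, and taxon-vs-taxon association.

Metadata from pooled surveys is heterogeneous, so missing values are
handled pairwise-complete with a minimum pair count (default 5); columns or
pairs below that, or with zero variance, report ``insufficient`` rather
than a coefficient.  Raw r values are reported with a display filter
(|r| > 0.25 by default) and no p-values or multiple-testing correction —
the output is a screening view, not an inference.

Seasonal time points are correlated through a cosine encoding of the
calendar month (``month_cos = cos(2*pi*month/12)``, maximal mid-winter),
with the raw month retained for grouped summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contribution import INSUFFICIENT, ContributionProfile

__all__ = [
    "CorrelationResult",
    "pearson",
    "taxon_metadata_matrix",
    "taxon_vs_taxon",
    "grouped_analysis",
]

logger = logging.getLogger(__name__)

MIN_PAIRS = 5


def pearson(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    min_pairs: int = MIN_PAIRS,
) -> float | str:
    """Sample Pearson correlation on pairwise-complete observations.

    Pairs where either value is missing (NaN) are dropped.  Returns
    ``INSUFFICIENT`` when fewer than ``min_pairs`` complete pairs remain or
    either vector is constant over them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    if len(xs) < min_pairs:
        return INSUFFICIENT
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return INSUFFICIENT
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return INSUFFICIENT
    return float((xc * yc).sum() / denom)


@dataclass(frozen=True)
class CorrelationResult:
    """Long-form correlation table with a display filter.

    ``table`` holds every computable (x, y) pair: columns ``x_name``,
    ``y_name``, ``r``, ``n_pairs``.  ``report`` applies the |r| display
    threshold; ``matrix`` pivots to wide form.
    """

    table: pd.DataFrame
    r_report: float = 0.25

    def __post_init__(self) -> None:
        if len(self.table) and (self.table["r"].abs() > 1 + 1e-12).any():
            raise ValueError("|r| > 1 in correlation table")

    def report(self, r_report: float | None = None) -> pd.DataFrame:
        cut = self.r_report if r_report is None else r_report
        return self.table[self.table["r"].abs() > cut].reset_index(drop=True)

    def matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="x_name", columns="y_name", values="r")

    def to_tsv(self, path: str | Path, wide_path: str | Path | None = None) -> None:
        out = self.table.copy()
        out["r"] = out["r"].round(9)
        out.to_csv(path, sep="\t", index=False)
        if wide_path is not None:
            self.matrix().round(9).to_csv(wide_path, sep="\t")


def _month_cosine(metadata: pd.DataFrame) -> pd.DataFrame:
    if "month" in metadata.columns and "month_cos" not in metadata.columns:
        metadata = metadata.copy()
        metadata["month_cos"] = np.cos(
            2 * np.pi * metadata["month"].astype(float) / 12.0
        )
    return metadata


def taxon_metadata_matrix(
    profile: ContributionProfile,
    metadata: pd.DataFrame,
    r_report: float = 0.25,
    min_pairs: int = MIN_PAIRS,
) -> CorrelationResult:
    """Correlate every numeric metadata column against every taxon's D_t.

    ``metadata`` must be indexed by, or carry a column of, sample ids.
    Numeric columns are auto-detected; a ``month`` column also contributes
    its cosine encoding.  Insufficient cells (too few pairs, constant
    column) are omitted from the table.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    metadata = _month_cosine(metadata)
    shared = [s for s in profile.samples if s in metadata.index]
    if not shared:
        raise ValueError("metadata and profile share no samples")
    meta = metadata.loc[shared].select_dtypes(include="number")
    D = profile.D.loc[shared]
    rows = []
    for col in meta.columns:
        for taxon in D.columns:
            r = pearson(meta[col].to_numpy(), D[taxon].to_numpy(), min_pairs)
            if r == INSUFFICIENT:
                continue
            n = int(
                (~(meta[col].isna() | D[taxon].isna())).sum()
            )
            rows.append((col, taxon, r, n))
    table = pd.DataFrame(rows, columns=["x_name", "y_name", "r", "n_pairs"])
    return CorrelationResult(table=table, r_report=r_report)


def taxon_vs_taxon(
    profile: ContributionProfile,
    r_report: float = 0.25,
    min_pairs: int = MIN_PAIRS,
) -> CorrelationResult:
    """Pairwise Pearson correlation between taxa D_t columns (no diagonal)."""
    D = profile.D
    rows = []
    taxa = list(D.columns)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            r = pearson(D[a].to_numpy(), D[b].to_numpy(), min_pairs)
            if r == INSUFFICIENT:
                continue
            rows.append((a, b, r, len(D)))
    table = pd.DataFrame(rows, columns=["x_name", "y_name", "r", "n_pairs"])
    return CorrelationResult(table=table, r_report=r_report)


def grouped_analysis(
    profile: ContributionProfile,
    metadata: pd.DataFrame,
    study_col: str = "study",
    r_report: float = 0.25,
    min_pairs: int = MIN_PAIRS,
) -> dict[str, CorrelationResult]:
    """Per-study taxon-metadata correlations.

    Samples are grouped by ``study_col``; each group is analysed
    independently, which removes between-study methodological variation.
    Groups with fewer than ``min_pairs`` retained samples are skipped with
    a logged notice.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    if study_col not in metadata.columns:
        raise ValueError(f"metadata lacks study column {study_col!r}")
    out: dict[str, CorrelationResult] = {}
    for study, grp in metadata.groupby(study_col, sort=True):
        shared = [s for s in profile.samples if s in grp.index]
        if len(shared) < min_pairs:
            logger.info(
                "study %s skipped: %d retained samples < %d",
                study,
                len(shared),
                min_pairs,
            )
            continue
        sub = ContributionProfile(
            counts=profile.counts.loc[shared],
            category=profile.category,
            min_hits=profile.min_hits,
        )
        out[str(study)] = taxon_metadata_matrix(
            sub, grp.drop(columns=[study_col]), r_report=r_report, min_pairs=min_pairs
        )
    return out
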