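"""Per-taxon marker-gene contribution statistics.

The central metagenome statistic is the per-taxon cobalamin gene
contribution D_t: the fraction of a sample's combined marker-gene hits
(pooled over the eleven cob/cbi markers) attributed to taxon t, so that
sum_t D_t = 1 including the Unclassified fraction.  Samples with fewer than
``min_hits`` (default 10) combined hits are excluded to avoid small-sample
bias; the same rule applies per gene for single-gene frequency profiles and
to the ribosomal-marker profiles used as a community-abundance baseline.

The pooled definition (hits summed across genes, normalized by the grand
total) is the default; an unweighted mean of per-gene profiles is available
behind ``method="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FamilyCatalog
from .screen import HitTable, UNCLASSIFIED

__all__ = [
    "INSUFFICIENT",
    "ContributionProfile",
    "gene_counts",
    "gene_frequency_profile",
    "sample_contribution",
    "build_profile",
    "profile_from_counts",
    "overrepresentation",
    "aggregate_study",
    "export_profile",
]

#: Sentinel returned when a denominator falls below the minimum hit count.
INSUFFICIENT = "insufficient"

#: Default minimum number of hits for a proportion to be reported.
MIN_HITS = 10


def gene_counts(table: HitTable, genes: Iterable[str] | None = None) -> pd.DataFrame:
    """Gene x taxon hit-count matrix for one sample."""
    rows = table.rows
    if genes is not None:
        rows = rows[rows["gene_label"].isin(set(genes))]
    if len(rows) == 0:
        return pd.DataFrame(dtype=int)
    return (
        rows.groupby(["gene_label", "taxon_label"], sort=True)
        .size()
        .unstack(fill_value=0)
    )


def gene_frequency_profile(
    table: HitTable, gene_label: str, min_hits: int = MIN_HITS
) -> dict[str, float] | str:
    """Taxon frequency profile of a single marker gene in one sample.

    Returns ``INSUFFICIENT`` when the gene has fewer than ``min_hits`` hits.
    """
    rows = table.rows[table.rows["gene_label"] == gene_label]
    n = len(rows)
    if n < min_hits:
        return INSUFFICIENT
    counts = rows.groupby("taxon_label", sort=True).size()
    return {taxon: count / n for taxon, count in counts.items()}


def sample_contribution(
    table: HitTable,
    genes: Iterable[str],
    min_hits: int = MIN_HITS,
    method: str = "pooled",
) -> dict[str, float] | str:
    """Combined per-taxon contribution D_t for one sample.

    ``method="pooled"`` (default): D_t = sum_g h(g, t) / N with
    N = sum_g sum_t h(g, t); returns ``INSUFFICIENT`` when N < min_hits.
    ``method="mean"``: unweighted mean of the per-gene frequency profiles of
    genes that individually pass the min-hits rule (renormalized so the
    result sums to 1); ``INSUFFICIENT`` when no gene qualifies.
    """
    genes = list(genes)
    if method == "pooled":
        counts = gene_counts(table, genes)
        total = int(counts.to_numpy().sum()) if counts.size else 0
        if total < min_hits:
            return INSUFFICIENT
        per_taxon = counts.sum(axis=0)
        return {taxon: count / total for taxon, count in per_taxon.items()}
    if method == "mean":
        profiles = [
            p
            for g in genes
            if (p := gene_frequency_profile(table, g, min_hits=min_hits))
            != INSUFFICIENT
        ]
        if not profiles:
            return INSUFFICIENT
        taxa = sorted({t for p in profiles for t in p})
        mean = {t: float(np.mean([p.get(t, 0.0) for p in profiles])) for t in taxa}
        norm = sum(mean.values())
        return {t: v / norm for t, v in mean.items()}
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ContributionProfile:
    """Sample x taxon contribution matrix with per-sample totals.

    ``counts`` holds the raw pooled hit counts (samples x taxa, ints) of the
    retained samples only (every retained sample has >= ``min_hits`` hits);
    ``D`` derives the row-normalized proportions, which therefore sum to 1.
    """

    counts: pd.DataFrame
    category: str = "cobalamin"
    min_hits: int = MIN_HITS

    def __post_init__(self) -> None:
        totals = self.counts.sum(axis=1)
        if (totals < self.min_hits).any():
            bad = list(totals.index[totals < self.min_hits])
            raise ValueError(f"under-sampled rows retained: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_total(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def D(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def pooled(self) -> pd.Series:
        """Study-wide D_t: column sums over all retained samples, normalized."""
        totals = self.counts.sum(axis=0)
        return totals / totals.sum()


def build_profile(
    tables: Sequence[HitTable],
    catalog: FamilyCatalog,
    category: str = "cobalamin",
    min_hits: int = MIN_HITS,
) -> ContributionProfile:
    """Pool each sample's hits over the markers of ``category``.

    Samples whose combined hit count is below ``min_hits`` are dropped
    (recorded only through their absence); taxa are the sorted union over
    retained samples, always including ``Unclassified``.
    """
    genes = set(catalog.labels(category))
    per_sample: dict[str, pd.Series] = {}
    for table in tables:
        rows = table.rows[table.rows["gene_label"].isin(genes)]
        if len(rows) < min_hits:
            continue
        per_sample[table.sample_id] = rows.groupby("taxon_label", sort=True).size()
    taxa = sorted(set().union(*[s.index for s in per_sample.values()], {UNCLASSIFIED}))
    counts = pd.DataFrame(0, index=list(per_sample), columns=taxa, dtype=int)
    for sid, series in per_sample.items():
        counts.loc[sid, series.index] = series.values
    counts.index.name = "sample_id"
    return ContributionProfile(counts=counts, category=category, min_hits=min_hits)


def profile_from_counts(
    counts: pd.DataFrame,
    category: str = "cobalamin",
    min_hits: int = MIN_HITS,
) -> ContributionProfile:
    """Build a profile directly from a samples x taxa count matrix.

    Rows below ``min_hits`` total are dropped, mirroring
    :func:`build_profile`.
    """
    counts = counts.astype(int)
    keep = counts.sum(axis=1) >= min_hits
    counts = counts.loc[keep]
    if UNCLASSIFIED not in counts.columns:
        counts[UNCLASSIFIED] = 0
    counts = counts[sorted(counts.columns)]
    counts.index.name = "sample_id"
    return ContributionProfile(counts=counts, category=category, min_hits=min_hits)


def overrepresentation(
    cob: ContributionProfile,
    ribo: ContributionProfile,
    taxon: str | None = None,
) -> pd.DataFrame:
    """Ratio of cobalamin to ribosomal contribution per taxon.

    A ratio > 1 means the taxon contributes more of the cobalamin marker
    pool than its community abundance (ribosomal marker share) predicts.
    Returns one row per shared sample plus a ``pooled`` row; the ratio is
    missing (NaN) wherever the ribosomal share is zero.
    """
    shared = [s for s in cob.samples if s in set(ribo.samples)]
    if not shared:
        raise ValueError("profiles share no retained samples")
    taxa = (
        [taxon]
        if taxon is not None
        else sorted(set(cob.taxa) & set(ribo.taxa))
    )
    d_cob = cob.D.loc[shared].reindex(columns=taxa, fill_value=0.0)
    d_ribo = ribo.D.loc[shared].reindex(columns=taxa, fill_value=0.0)
    ratio = d_cob / d_ribo.where(d_ribo > 0)
    pooled_cob = cob.pooled().reindex(taxa, fill_value=0.0)
    pooled_ribo = ribo.pooled().reindex(taxa, fill_value=0.0)
    pooled = pooled_cob / pooled_ribo.where(pooled_ribo > 0)
    ratio.loc["pooled"] = pooled
    ratio.index.name = "sample_id"
    return ratio


def aggregate_study(
    tables: Sequence[HitTable],
    parents: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pooled per-taxon hit counts over samples, sorted by descending count.

    All tables must share one reporting rank (species level for a
    most-abundant-contributors table).  ``parents`` optionally maps each
    label to a parent rank name for display.
    """
    ranks = {t.rank for t in tables}
    if len(ranks) > 1:
        raise ValueError(f"tables mix reporting ranks: {sorted(ranks)}")
    counts: dict[str, int] = {}
    for t in tables:
        for taxon, c in t.rows.groupby("taxon_label").size().items():
            counts[taxon] = counts.get(taxon, 0) + int(c)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.DataFrame(rows, columns=["label", "count"])
    if parents is not None:
        out.insert(1, "parent", out["label"].map(lambda l: parents.get(l, "")))
    return out


def export_profile(
    profile: ContributionProfile,
    wide_path: str | Path,
    long_path: str | Path | None = None,
    min_display_fraction: float = 0.0,
) -> None:
    """Write the D matrix as wide (and optionally long) TSV.

    Taxa whose maximum share across samples falls below
    ``min_display_fraction`` are collapsed into an ``Other`` column at
    export time only; the underlying arithmetic is never collapsed.
    """
    D = profile.D
    if min_display_fraction > 0:
        minor = [
            t
            for t in D.columns
            if D[t].max() < min_display_fraction and t != UNCLASSIFIED
        ]
        if minor:
            other = D[minor].sum(axis=1)
            D = D.drop(columns=minor)
            D["Other"] = other
    D = D.round(9)
    D.to_csv(wide_path, sep="\t")
    if long_path is not None:
        long = (
            D.rename_axis(index="sample_id", columns="taxon")
            .stack()
            .rename("D")
            .reset_index()
        )
        long.to_csv(long_path, sep="\t", index=False)
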