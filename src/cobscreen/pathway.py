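"""Genome-level cobalamin pathway profiling.

Builds genome x family presence/absence matrices from annotation tables,
computes per-enzyme conservation scores (the fraction of genomes in the
supplied set possessing each enzyme), classifies each genome's biosynthesis
route from the route-diagnostic gene sets, and applies the indicator-gene
completeness heuristic: a genome encoding cbiA/cobB, cbiC/cobH or cobT very
likely encodes the complete pathway.

The conservation score is computed over whatever genome set the caller
supplies; restricting to e.g. archaeal genomes is the caller's filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .catalog import FamilyCatalog

__all__ = [
    "PresenceAbsenceMatrix",
    "RouteCall",
    "build_presence_absence",
    "conservation_scores",
    "classify_route",
    "route_calls",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Boolean genome x gene-family matrix."""

    table: pd.DataFrame  # index: genome ids; columns: gene labels; dtype bool

    def __post_init__(self) -> None:
        if not self.table.dtypes.map(lambda d: d == bool).all():
            raise ValueError("presence/absence cells must be boolean")

    @property
    def genomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def families(self) -> list[str]:
        return list(self.table.columns)

    def row(self, genome_id: str) -> pd.Series:
        return self.table.loc[genome_id]

    def to_wide_tsv(self, path: str | Path) -> None:
        out = self.table.astype(int)
        out.index.name = "genome_id"
        out.to_csv(path, sep="\t")

    def to_long_tsv(self, path: str | Path) -> None:
        long = (
            self.table.astype(int)
            .rename_axis(index="genome_id", columns="family")
            .stack()
            .rename("present")
            .reset_index()
        )
        long.to_csv(path, sep="\t", index=False)


def build_presence_absence(
    annotation: pd.DataFrame, catalog: FamilyCatalog
) -> PresenceAbsenceMatrix:
    """Mark family f present in genome g iff g has >= 1 gene labelled f.

    Annotation rows need ``genome_id`` and ``gene_label`` columns; empty
    labels are decoys.  Labels the catalog does not know (neither a member
    nor a route/indicator gene) are logged and ignored.  Genomes whose genes
    are all decoys still appear as all-false rows.
    """
    known = catalog.known_pathway_labels
    # Column order: catalog members first, then the extra genome-annotation
    # labels (route markers, indicators) in sorted order.
    member_labels = [l for l in catalog.labels() if l in known]
    extra = sorted(known - set(member_labels))
    columns = member_labels + extra

    genomes = list(pd.unique(annotation["genome_id"])) if len(annotation) else []
    mat = pd.DataFrame(False, index=genomes, columns=columns, dtype=bool)
    labelled = annotation[annotation["gene_label"].fillna("") != ""]
    unknown = sorted(set(labelled["gene_label"]) - known)
    if unknown:
        logger.warning("ignoring unknown gene labels: %s", ", ".join(unknown))
    labelled = labelled[labelled["gene_label"].isin(known)]
    for gid, lab in zip(labelled["genome_id"], labelled["gene_label"]):
        mat.loc[gid, lab] = True
    return PresenceAbsenceMatrix(table=mat)


def conservation_scores(matrix: PresenceAbsenceMatrix) -> pd.Series:
    """Fraction of genomes possessing each family, per column.

    Raises for an empty genome set (the proportion is undefined).
    """
    n = len(matrix.genomes)
    if n == 0:
        raise ValueError("conservation score undefined for zero genomes")
    return matrix.table.sum(axis=0) / n


@dataclass(frozen=True)
class RouteCall:
    """Route classification for one genome.

    ``route`` is ``anaerobic`` / ``aerobic`` / ``ambiguous`` / ``none``
    based on counts of route-diagnostic genes; ``complete_likely`` is true
    when at least one completeness-indicator gene is present.
    """

    genome_id: str
    route: str
    n_anaerobic_specific: int
    n_aerobic_specific: int
    complete_likely: bool


def classify_route(
    row: Mapping[str, bool] | pd.Series,
    catalog: FamilyCatalog,
    genome_id: str = "",
) -> RouteCall:
    """Classify one genome's biosynthesis route from its presence vector.

    With a = number of anaerobic-specific genes present (CbiX, CbiG, CbiD)
    and b = number of aerobic-specific genes present (CobG, CobF, CobN/S/T
    chelatase subunits): route = anaerobic if a >= 2 and a > b; aerobic if
    b >= 2 and b > a; none if a = b = 0; ambiguous otherwise.  A single
    diagnostic gene is treated as insufficient evidence so that one
    annotation dropout cannot flip a call.
    """
    present = {str(k) for k, v in dict(row).items() if bool(v)}
    a = len(present & catalog.route_markers["anaerobic_specific"])
    b = len(present & catalog.route_markers["aerobic_specific"])
    if a >= 2 and a > b:
        route = "anaerobic"
    elif b >= 2 and b > a:
        route = "aerobic"
    elif a == 0 and b == 0:
        route = "none"
    else:
        route = "ambiguous"
    complete = bool(present & catalog.completeness_indicators)
    return RouteCall(
        genome_id=genome_id,
        route=route,
        n_anaerobic_specific=a,
        n_aerobic_specific=b,
        complete_likely=complete,
    )


def route_calls(matrix: PresenceAbsenceMatrix, catalog: FamilyCatalog) -> pd.DataFrame:
    """Classify every genome in the matrix; one row per genome."""
    calls = [
        classify_route(matrix.row(g), catalog, genome_id=g) for g in matrix.genomes
    ]
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "route": c.route,
                "n_anaerobic_specific": c.n_anaerobic_specific,
                "n_aerobic_specific": c.n_aerobic_specific,
                "complete_likely": c.complete_likely,
            }
            for c in calls
        ],
        columns=[
            "genome_id",
            "route",
            "n_anaerobic_specific",
            "n_aerobic_specific",
            "complete_likely",
        ],
    )
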