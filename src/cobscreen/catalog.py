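"""Curated marker-family catalog for cobalamin (vitamin B12) biosynthesis screening.

The catalog ties profile-HMM family accessions (TIGRFAM / Pfam) to pathway
gene labels and metadata used throughout the pipeline:

* eleven cobalamin (cob/cbi) marker families spanning the biosynthesis
  pathway from uroporphyrinogen III to the finished cofactor, and
* three universally conserved ribosomal-protein families that serve as a
  community-abundance baseline.

Gene labels use the dual aerobic/anaerobic nomenclature joined by an
underscore (``cbiA_cobB``) wherever the two routes share a homologous
enzyme.  Route-diagnostic gene sets (aerobic: CobG, CobF, CobNST; anaerobic:
CbiX, CbiG, CbiD) and the pathway-completeness indicator genes
(cbiA/cobB, cbiC/cobH, cobT) are carried alongside the member list because
genome-level route classification reads the full annotation label set, not
only the eleven metagenome markers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "MarkerFamily",
    "FamilyCatalog",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "strip_version",
    "CATEGORIES",
    "STAGES",
    "ROUTES",
    "AEROBIC_SPECIFIC",
    "ANAEROBIC_SPECIFIC",
    "COMPLETENESS_INDICATORS",
]

CATEGORIES = ("cobalamin", "ribosomal")
STAGES = ("early", "late", "not_applicable")
ROUTES = ("shared", "aerobic_specific", "anaerobic_specific", "not_applicable")

#: Genes diagnostic of the aerobic (late cobalt insertion) route.  The
#: CobN/CobS/CobT cobaltochelatase subunits are distinct enzymes from the
#: TIGR00317 cobalamin-synthase marker labelled plain ``cobS``, hence the
#: ``_chelatase`` suffix.
AEROBIC_SPECIFIC = frozenset(
    {"cobG", "cobF", "cobN", "cobS_chelatase", "cobT_chelatase"}
)

#: Genes diagnostic of the anaerobic (early cobalt insertion) route.
ANAEROBIC_SPECIFIC = frozenset({"cbiX", "cbiG", "cbiD"})

#: Indicator genes: a genome encoding any one of these very likely encodes
#: (and expresses) the complete cobalamin synthesis pathway.
COMPLETENESS_INDICATORS = frozenset({"cbiA_cobB", "cbiC_cobH", "cobT"})

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(accession: str) -> str:
    """Drop a trailing minor-version suffix (``PF02570.10`` -> ``PF02570``)."""
    return _VERSION_RE.sub("", accession)


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog definitions."""


@dataclass(frozen=True)
class MarkerFamily:
    """One profile-HMM family in the catalog.

    Parameters
    ----------
    accession:
        TIGRFAM or Pfam accession, e.g. ``"TIGR01469"`` or ``"PF02570"``.
        Version suffixes are stripped on construction.
    gene_label:
        Pathway gene name, e.g. ``"cbiC_cobH"``.
    category:
        ``"cobalamin"`` or ``"ribosomal"``.
    stage:
        ``"early"`` (uroporphyrinogen III -> cobyrinic acid a,c-diamide),
        ``"late"`` (onwards to the finished cofactor) or
        ``"not_applicable"``.
    route:
        Route specificity of the family; the eleven metagenome markers are
        all ``"shared"`` between the aerobic and anaerobic routes.
    """

    accession: str
    gene_label: str
    category: str
    stage: str = "not_applicable"
    route: str = "shared"

    def __post_init__(self) -> None:
        object.__setattr__(self, "accession", strip_version(self.accession))
        if self.category not in CATEGORIES:
            raise CatalogError(f"unknown category {self.category!r}")
        if self.stage not in STAGES:
            raise CatalogError(f"unknown stage {self.stage!r}")
        if self.route not in ROUTES:
            raise CatalogError(f"unknown route {self.route!r}")
        if self.category == "ribosomal" and (
            self.stage != "not_applicable" or self.route != "not_applicable"
        ):
            raise CatalogError(
                f"{self.accession}: ribosomal families carry no pathway "
                "stage or route"
            )


# The default marker set: eleven cobalamin pathway families plus three
# ribosomal-protein families used as phylogenetic (community abundance)
# markers.
_DEFAULT_MEMBERS = (
    MarkerFamily("TIGR01469", "cobA_cysG", "cobalamin", "early", "shared"),
    MarkerFamily("TIGR01467", "cobI_cbiL", "cobalamin", "early", "shared"),
    MarkerFamily("TIGR01466", "cobJ_cbiH", "cobalamin", "early", "shared"),
    MarkerFamily("TIGR01465", "cobM_cbiF", "cobalamin", "early", "shared"),
    MarkerFamily("TIGR02469", "cbiT_cobL", "cobalamin", "early", "shared"),
    MarkerFamily("TIGR02467", "cbiE_cobL", "cobalamin", "early", "shared"),
    MarkerFamily("PF02570", "cbiC_cobH", "cobalamin", "early", "shared"),
    MarkerFamily("TIGR00379", "cbiA_cobB", "cobalamin", "late", "shared"),
    MarkerFamily("TIGR00380", "cbiB_cobD", "cobalamin", "late", "shared"),
    MarkerFamily("TIGR00313", "cbiP_cobQ", "cobalamin", "late", "shared"),
    MarkerFamily("TIGR00317", "cobS", "cobalamin", "late", "shared"),
    MarkerFamily(
        "PF00164", "Ribosomal_S12_S23", "ribosomal", "not_applicable", "not_applicable"
    ),
    MarkerFamily(
        "PF00828", "Ribosomal_L18e", "ribosomal", "not_applicable", "not_applicable"
    ),
    MarkerFamily(
        "PF00380", "Ribosomal_S9", "ribosomal", "not_applicable", "not_applicable"
    ),
)


@dataclass(frozen=True)
class FamilyCatalog:
    """An ordered, validated collection of :class:`MarkerFamily` entries."""

    members: tuple[MarkerFamily, ...]
    route_markers: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {
            "aerobic_specific": AEROBIC_SPECIFIC,
            "anaerobic_specific": ANAEROBIC_SPECIFIC,
        }
    )
    completeness_indicators: frozenset[str] = COMPLETENESS_INDICATORS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.accession in seen:
                raise CatalogError(f"duplicate accession {m.accession!r}")
            seen.add(m.accession)
        if self.route_markers["aerobic_specific"] & self.route_markers[
            "anaerobic_specific"
        ]:
            raise CatalogError("aerobic/anaerobic route marker sets overlap")

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def by_accession(self, accession: str) -> MarkerFamily:
        acc = strip_version(accession)
        for m in self.members:
            if m.accession == acc:
                return m
        raise KeyError(accession)

    def gene_label(self, accession: str) -> str:
        return self.by_accession(accession).gene_label

    def __contains__(self, accession: str) -> bool:
        try:
            self.by_accession(accession)
            return True
        except KeyError:
            return False

    def labels(self, category: str | None = None) -> tuple[str, ...]:
        return tuple(
            m.gene_label
            for m in self.members
            if category is None or m.category == category
        )

    @property
    def cobalamin_labels(self) -> tuple[str, ...]:
        return self.labels("cobalamin")

    @property
    def ribosomal_labels(self) -> tuple[str, ...]:
        return self.labels("ribosomal")

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(m.accession for m in self.members)

    def label_category(self) -> dict[str, str]:
        """Mapping gene_label -> category for catalog members."""
        return {m.gene_label: m.category for m in self.members}

    @property
    def known_pathway_labels(self) -> frozenset[str]:
        """All gene labels the genome-level analyses understand.

        Catalog member labels plus the route-diagnostic and
        completeness-indicator genes, which are genome-annotation labels
        rather than metagenome screening markers.
        """
        extra: set[str] = set(self.completeness_indicators)
        for s in self.route_markers.values():
            extra |= s
        return frozenset(self.labels()) | frozenset(extra)


_CATALOG_COLUMNS = ("accession", "gene_label", "category", "stage", "route")


def default_catalog() -> FamilyCatalog:
    """The packaged 11 cobalamin + 3 ribosomal marker catalog."""
    return FamilyCatalog(members=_DEFAULT_MEMBERS)


def load_catalog(source: str | Path = "default") -> FamilyCatalog:
    """Load a catalog from a TSV file, or return the packaged default.

    The file format is a tab-separated table with header columns
    ``accession  gene_label  category  stage  route``; blank lines and
    ``#`` comment lines are permitted.
    """
    if source == "default":
        return default_catalog()
    path = Path(source)
    members: list[MarkerFamily] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if tuple(header) != _CATALOG_COLUMNS:
                    raise CatalogError(
                        f"{path}:{lineno}: expected header "
                        f"{' '.join(_CATALOG_COLUMNS)!r}, got {line!r}"
                    )
                continue
            if len(fields) != len(_CATALOG_COLUMNS):
                raise CatalogError(
                    f"{path}:{lineno}: expected {len(_CATALOG_COLUMNS)} "
                    f"columns, got {len(fields)}: {line!r}"
                )
            try:
                members.append(MarkerFamily(*[f.strip() for f in fields]))
            except CatalogError as exc:
                raise CatalogError(f"{path}:{lineno}: {exc}") from exc
    if not members:
        raise CatalogError(f"{path}: no catalog entries found")
    return FamilyCatalog(members=tuple(members))


def write_catalog(catalog: FamilyCatalog, path: str | Path) -> None:
    """Write a catalog to TSV in the format :func:`load_catalog` reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for m in catalog.members:
            fh.write(
                "\t".join((m.accession, m.gene_label, m.category, m.stage, m.route))
                + "\n"
            )
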