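"""Metagenome marker-gene screening.

Consumes the standard text outputs of an upstream homology search —
``hmmsearch`` per-sequence tables ("tblout", optionally the per-domain
"domtblout" dialect) for the marker-family scan and BLAST tabular output
(``-outfmt 6``) for taxonomic assignment — applies the screening E-value
threshold (1e-6, boundary inclusive), resolves a single best marker family
per ORF, and assigns a taxon per ORF from its top BLAST match via a flat
taxonomy index.

Running FragGeneScan / HMMER / BLAST themselves is out of scope: ORF
identifiers are opaque strings and this module only reads their outputs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import FamilyCatalog, strip_version

__all__ = [
    "RANKS",
    "E_VALUE_MAX",
    "HmmHit",
    "BlastHit",
    "TaxonomyIndex",
    "HitTable",
    "ScreenParseError",
    "parse_hmm_tblout",
    "parse_hmm_domtblout",
    "parse_blast_outfmt6",
    "filter_hits",
    "best_family_per_orf",
    "assign_taxonomy",
    "build_hit_table",
]

#: Canonical taxonomic ranks of the lineage strings in a taxonomy index.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Screening threshold: hits with E-value <= this pass (boundary inclusive).
E_VALUE_MAX = 1e-6

UNCLASSIFIED = "Unclassified"

BLAST6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class ScreenParseError(ValueError):
    """Raised when a homology-search output file cannot be parsed."""


@dataclass(frozen=True)
class HmmHit:
    orf_id: str
    family_accession: str
    evalue: float
    bitscore: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError(f"{self.orf_id}: E-value must be positive")


@dataclass(frozen=True)
class BlastHit:
    orf_id: str
    subject_id: str
    evalue: float
    bitscore: float
    file_rank: int

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError(f"{self.orf_id}: E-value must be positive")


def _parse_hmm_table(
    path: str | Path,
    sample_id: str,
    evalue_col: int,
    min_cols: int,
    qname_col: int = 2,
) -> list[HmmHit]:
    qacc_col = qname_col + 1
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < min_cols:
                raise ScreenParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, "
                    f"got {len(fields)}"
                )
            acc = fields[qacc_col] if fields[qacc_col] != "-" else fields[qname_col]
            try:
                evalue = float(fields[evalue_col])
                score = float(fields[evalue_col + 1])
            except ValueError as exc:
                raise ScreenParseError(
                    f"{path}:{lineno}: non-numeric E-value/score: {exc}"
                ) from exc
            hits.append(
                HmmHit(
                    orf_id=fields[0],
                    family_accession=acc,
                    evalue=evalue,
                    bitscore=score,
                    sample_id=sample_id,
                )
            )
    return hits


def parse_hmm_tblout(path: str | Path, sample_id: str = "") -> list[HmmHit]:
    """Parse hmmsearch per-sequence tabular output ("tblout").

    One hit per data line; '#' header/comment lines are skipped.  The
    full-sequence E-value (column 5) and score (column 6) are used.  The
    family accession comes from the query accession column, falling back to
    the query name when the accession field is "-".
    """
    return _parse_hmm_table(path, sample_id, evalue_col=4, min_cols=18)


def parse_hmm_domtblout(path: str | Path, sample_id: str = "") -> list[HmmHit]:
    """Parse the hmmsearch per-domain dialect ("domtblout").

    The full-sequence E-value (column 7) governs filtering, matching the
    tblout semantics; multiple domain rows for one ORF collapse later in
    :func:`best_family_per_orf`.
    """
    return _parse_hmm_table(path, sample_id, evalue_col=6, min_cols=22, qname_col=3)


def parse_blast_outfmt6(path: str | Path) -> list[BlastHit]:
    """Parse BLAST tabular output (``-outfmt 6``, 12 tab-separated columns).

    ``file_rank`` records each row's 0-based position in the file; it is the
    final tie-break when E-value and bit score are equal (BLAST lists better
    hits first).
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        rank = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ScreenParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ScreenParseError(
                    f"{path}:{lineno}: non-numeric E-value/bitscore: {exc}"
                ) from exc
            hits.append(
                BlastHit(
                    orf_id=fields[0],
                    subject_id=fields[1],
                    evalue=evalue,
                    bitscore=bitscore,
                    file_rank=rank,
                )
            )
            rank += 1
    return hits


def filter_hits(hits: Iterable[HmmHit], e_max: float = E_VALUE_MAX) -> list[HmmHit]:
    """Retain hits with E-value <= ``e_max`` (boundary inclusive), in order."""
    if not e_max > 0:
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.evalue <= e_max]


def best_family_per_orf(
    hits: Iterable[HmmHit], catalog: FamilyCatalog
) -> dict[str, str]:
    """Resolve one catalog gene label per ORF from (filtered) HMM hits.

    Per ORF the winning hit has the smallest E-value; ties go to the larger
    bit score, then the lexicographically smallest (version-stripped)
    accession.  Hits to families outside the catalog are dropped, so an ORF
    never counts in two marker categories.
    """
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        acc = strip_version(h.family_accession)
        if acc not in catalog:
            continue
        key = (h.evalue, -h.bitscore, acc)
        if h.orf_id not in best or key < best[h.orf_id]:
            best[h.orf_id] = key
    return {orf: catalog.gene_label(key[2]) for orf, key in best.items()}


class TaxonomyIndex:
    """Flat mapping subject_id -> ranked lineage.

    Lineages are tuples aligned to :data:`RANKS`; shorter lineages simply
    lack the trailing ranks.  Lookups are total: an unknown subject yields
    the sentinel ``Unclassified`` at every rank.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages = {k: tuple(v) for k, v in lineages.items()}

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._lineages

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyIndex":
        """Read a two-column TSV: subject_id, semicolon-joined lineage."""
        lineages: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ScreenParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                lineages[parts[0]] = tuple(
                    name.strip() for name in parts[1].split(";")
                )
        return cls(lineages)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for subject in sorted(self._lineages):
                fh.write(f"{subject}\t{';'.join(self._lineages[subject])}\n")

    def lineage(self, subject_id: str) -> tuple[str, ...]:
        return self._lineages.get(subject_id, ())

    def name_at_rank(
        self,
        subject_id: str,
        rank: str = "phylum",
        split_proteobacteria: bool = False,
    ) -> str:
        """Lineage name at ``rank``, or ``Unclassified``.

        With ``split_proteobacteria`` and rank ``phylum``, proteobacterial
        subjects report their class instead (Alphaproteobacteria, ...),
        mirroring the mixed phylum/class reporting convention common in
        marine surveys.
        """
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}")
        lineage = self.lineage(subject_id)
        i = RANKS.index(rank)
        if i >= len(lineage) or not lineage[i]:
            return UNCLASSIFIED
        name = lineage[i]
        if (
            split_proteobacteria
            and rank == "phylum"
            and name == "Proteobacteria"
            and len(lineage) > i + 1
            and lineage[i + 1]
        ):
            return lineage[i + 1]
        return name


def assign_taxonomy(
    blast_hits: Iterable[BlastHit],
    index: TaxonomyIndex,
    rank: str = "phylum",
    e_max: float = E_VALUE_MAX,
    split_proteobacteria: bool = False,
) -> str:
    """Taxon label for one ORF from its top BLAST match.

    Among hits with E-value <= ``e_max`` the top hit has the smallest
    E-value; ties go to the larger bit score, then the earliest file
    position.  Returns ``Unclassified`` when no hit passes, the subject is
    unknown, or the lineage lacks the requested rank.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    passing = [h for h in blast_hits if h.evalue <= e_max]
    if not passing:
        return UNCLASSIFIED
    top = min(passing, key=lambda h: (h.evalue, -h.bitscore, h.file_rank))
    return index.name_at_rank(
        top.subject_id, rank=rank, split_proteobacteria=split_proteobacteria
    )


@dataclass(frozen=True)
class HitTable:
    """Per-sample classified marker hits: one row per surviving ORF."""

    sample_id: str
    rows: pd.DataFrame  # columns: orf_id, gene_label, taxon_label
    rank: str = "phylum"

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out.insert(0, "sample_id", self.sample_id)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, rank: str = "phylum") -> "HitTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        sample_id = df["sample_id"].iloc[0] if len(df) else Path(path).stem
        return cls(
            sample_id=sample_id,
            rows=df[["orf_id", "gene_label", "taxon_label"]].reset_index(drop=True),
            rank=rank,
        )


def build_hit_table(
    sample_id: str,
    hmm_paths: Sequence[str | Path] | str | Path,
    blast_paths: Sequence[str | Path] | str | Path,
    catalog: FamilyCatalog,
    index: TaxonomyIndex,
    rank: str = "phylum",
    e_max: float = E_VALUE_MAX,
    split_proteobacteria: bool = False,
    dialect: str = "tblout",
) -> HitTable:
    """Compose parsing, filtering, family resolution and taxonomy for a sample.

    An ORF that survives the HMM screen but has no BLAST evidence is kept
    with taxon ``Unclassified``.  Rows are ordered by orf_id, so repeated
    runs export byte-identical tables.
    """
    if isinstance(hmm_paths, (str, Path)):
        hmm_paths = [hmm_paths]
    if isinstance(blast_paths, (str, Path)):
        blast_paths = [blast_paths]
    parser = parse_hmm_tblout if dialect == "tblout" else parse_hmm_domtblout
    hmm_hits: list[HmmHit] = []
    for p in hmm_paths:
        hmm_hits.extend(parser(p, sample_id=sample_id))
    families = best_family_per_orf(filter_hits(hmm_hits, e_max=e_max), catalog)

    by_orf: dict[str, list[BlastHit]] = defaultdict(list)
    for p in blast_paths:
        for h in parse_blast_outfmt6(p):
            by_orf[h.orf_id].append(h)

    rows = []
    for orf_id in sorted(families):
        taxon = assign_taxonomy(
            by_orf.get(orf_id, ()),
            index,
            rank=rank,
            e_max=e_max,
            split_proteobacteria=split_proteobacteria,
        )
        rows.append((orf_id, families[orf_id], taxon))
    return HitTable(
        sample_id=sample_id,
        rows=pd.DataFrame(rows, columns=["orf_id", "gene_label", "taxon_label"]),
        rank=rank,
    )
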