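"""Detection of co-located cobalamin pathway gene clusters and cross-genome
synteny conservation.

Ammonia-oxidizing archaeal genomes carry their cob/cbi genes in two compact
clusters — a six-gene cluster for the early pathway (uroporphyrinogen III to
cobyrinic acid a,c-diamide) and a four-gene cluster for the late steps — with
conserved gene order across genomes.  This module finds such runs in an
annotation table and groups mutually syntenic clusters across genomes.

Distances between pathway genes are measured in intervening gene count (not
base pairs), which is robust to differing annotation density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GeneRecord",
    "SyntenyCluster",
    "ANNOTATION_COLUMNS",
    "records_to_frame",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_annotation_gff3",
    "find_clusters",
    "synteny_score",
    "conserved_clusters",
    "clusters_to_frame",
    "write_clusters",
]

ANNOTATION_COLUMNS = (
    "genome_id",
    "replicon_id",
    "locus_tag",
    "start",
    "end",
    "strand",
    "gene_label",
)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 1-based inclusive coordinates on a replicon.

    ``gene_label`` is a catalog pathway label, or ``""`` for genes outside
    the pathway (decoys).
    """

    genome_id: str
    replicon_id: str
    locus_tag: str
    start: int
    end: int
    strand: str
    gene_label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")


def records_to_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=list(ANNOTATION_COLUMNS))
    df["gene_label"] = df["gene_label"].fillna("")
    return df


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a flat annotation table (columns = :data:`ANNOTATION_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_label": "string"})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    df["gene_label"] = df["gene_label"].fillna("").astype(str)
    return df[list(ANNOTATION_COLUMNS)]


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotation_gff3(
    path: str | Path,
    genome_id: str | None = None,
    family_attribute: str = "tigrfam_pfam",
) -> pd.DataFrame:
    """Read CDS features from a GFF3 file into an annotation table.

    The pathway gene label is taken from ``family_attribute`` (default
    ``tigrfam_pfam``); CDS features without that attribute are decoys.
    Locus tags come from the ``locus_tag`` attribute, falling back to ``ID``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows: list[GeneRecord] = []
    gid = genome_id if genome_id is not None else Path(path).stem
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        locus = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [feat.id])[0]
        label = (feat.attributes.get(family_attribute) or [""])[0]
        rows.append(
            GeneRecord(
                genome_id=gid,
                replicon_id=feat.seqid,
                locus_tag=locus,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                gene_label=label,
            )
        )
    return records_to_frame(rows)


@dataclass(frozen=True)
class SyntenyCluster:
    """A genomic run of co-located pathway genes (length >= 2)."""

    genome_id: str
    replicon_id: str
    ordered_labels: tuple[str, ...]
    member_locus_tags: tuple[str, ...]
    span: tuple[int, int]
    n_intervening: int

    def __len__(self) -> int:
        return len(self.ordered_labels)


def _canonical_sort(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation.sort_values(
        ["genome_id", "replicon_id", "start", "end", "locus_tag"],
        kind="mergesort",
    ).reset_index(drop=True)


def find_clusters(
    annotation: pd.DataFrame,
    pathway_labels: Iterable[str],
    max_gap: int = 2,
) -> list[SyntenyCluster]:
    """Find maximal runs of pathway genes separated by <= ``max_gap`` decoys.

    Genes are ordered per replicon by start coordinate (ties by end then
    locus tag, so the result is invariant to input row order).  Runs of
    length >= 2 are returned sorted by descending length, then by
    (genome_id, replicon_id, span start).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    labels = set(pathway_labels)
    out: list[SyntenyCluster] = []
    df = _canonical_sort(annotation)
    for (gid, rid), grp in df.groupby(["genome_id", "replicon_id"], sort=True):
        is_path = grp["gene_label"].isin(labels).to_numpy()
        idx = np.flatnonzero(is_path)
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][-1] - 1 <= max_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < 2:
                continue
            members = grp.iloc[run]
            out.append(
                SyntenyCluster(
                    genome_id=gid,
                    replicon_id=rid,
                    ordered_labels=tuple(members["gene_label"]),
                    member_locus_tags=tuple(members["locus_tag"]),
                    span=(int(members["start"].min()), int(members["end"].max())),
                    n_intervening=int(run[-1] - run[0] + 1 - len(run)),
                )
            )
    out.sort(key=lambda c: (-len(c), c.genome_id, c.replicon_id, c.span[0]))
    return out


def synteny_score(a: SyntenyCluster | Sequence[str], b: SyntenyCluster | Sequence[str]) -> float:
    """Order-aware similarity of two clusters, in [0, 1].

    score = J * O, where J is the Jaccard index of the label sets and O is
    the fraction of label pairs shared by both clusters whose relative order
    agrees.  O is defined as 1 when one or zero labels are shared, so the
    score is symmetric by construction.  Repeated labels are compared at
    their first occurrence.
    """
    la = tuple(a.ordered_labels if isinstance(a, SyntenyCluster) else a)
    lb = tuple(b.ordered_labels if isinstance(b, SyntenyCluster) else b)
    if not la or not lb:
        raise ValueError("clusters must be non-empty")
    sa, sb = set(la), set(lb)
    union = sa | sb
    shared = sa & sb
    jaccard = len(shared) / len(union)
    if len(shared) <= 1:
        return jaccard
    pos_a = {lab: i for i, lab in reversed(list(enumerate(la)))}
    pos_b = {lab: i for i, lab in reversed(list(enumerate(lb)))}
    agree = total = 0
    for x, y in combinations(sorted(shared), 2):
        total += 1
        if (pos_a[x] < pos_a[y]) == (pos_b[x] < pos_b[y]):
            agree += 1
    return jaccard * agree / total


@dataclass(frozen=True)
class ClusterFamily:
    """A group of mutually syntenic clusters spanning several genomes."""

    members: tuple[SyntenyCluster, ...]
    consensus_labels: tuple[str, ...]

    @property
    def genomes(self) -> tuple[str, ...]:
        return tuple(sorted({c.genome_id for c in self.members}))


def conserved_clusters(
    clusters: Sequence[SyntenyCluster],
    min_genomes: int = 2,
    min_score: float = 0.5,
) -> list[ClusterFamily]:
    """Group clusters by single linkage over synteny-score edges.

    Two clusters are linked when ``synteny_score >= min_score``; connected
    components spanning at least ``min_genomes`` distinct genomes are
    reported.  The consensus label order is that of the group's longest
    member (ties broken by lexicographically smallest genome_id, then
    replicon and span start).
    """
    if min_genomes < 2:
        raise ValueError("min_genomes must be >= 2")
    if not 0 <= min_score <= 1:
        raise ValueError("min_score must be within [0, 1]")
    n = len(clusters)
    if n == 0:
        return []
    ii, jj = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if synteny_score(clusters[i], clusters[j]) >= min_score:
                ii.append(i)
                jj.append(j)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    families: list[ClusterFamily] = []
    for comp in range(n_comp):
        members = [clusters[i] for i in np.flatnonzero(labels == comp)]
        genomes = {c.genome_id for c in members}
        if len(genomes) < min_genomes:
            continue
        rep = min(
            members,
            key=lambda c: (-len(c), c.genome_id, c.replicon_id, c.span[0]),
        )
        members.sort(key=lambda c: (c.genome_id, c.replicon_id, c.span[0]))
        families.append(
            ClusterFamily(members=tuple(members), consensus_labels=rep.ordered_labels)
        )
    families.sort(key=lambda f: (-len(f.members[0]), f.members[0].genome_id))
    return families


def clusters_to_frame(clusters: Sequence[SyntenyCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "replicon_id": c.replicon_id,
                "n_genes": len(c),
                "ordered_labels": ",".join(c.ordered_labels),
                "member_locus_tags": ",".join(c.member_locus_tags),
                "span_start": c.span[0],
                "span_end": c.span[1],
                "n_intervening": c.n_intervening,
            }
            for c in clusters
        ],
        columns=[
            "genome_id",
            "replicon_id",
            "n_genes",
            "ordered_labels",
            "member_locus_tags",
            "span_start",
            "span_end",
            "n_intervening",
        ],
    )


def write_clusters(clusters: Sequence[SyntenyCluster], tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    clusters_to_frame(clusters).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {
                "genome_id": c.genome_id,
                "replicon_id": c.replicon_id,
                "ordered_labels": list(c.ordered_labels),
                "member_locus_tags": list(c.member_locus_tags),
                "span": list(c.span),
                "n_intervening": c.n_intervening,
            }
            for c in clusters
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
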