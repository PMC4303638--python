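"""Synthetic fixture generation with recorded ground truth.

Everything downstream of the external search tools is testable without any
real metagenome: this module writes format-compatible inputs — genome
annotation tables with planted cob/cbi gene clusters, hmmsearch "tblout"
files, BLAST ``-outfmt 6`` files, a taxonomy index and per-sample metadata
— together with a truth record of every draw.

The metagenome generator emulates the statistical structure of a marine
survey, not its sequences: per-sample, per-marker-gene hit totals are
Poisson, allocated multinomially across taxa; taxon proportions respond to
covariates (depth, temperature, nitrate, season) either through a softmax
link over taxa or through a mixture of "ecotype" components (softmax over
components, Dirichlet noise around each component's centre profile);
E-values straddle the 1e-6 screening threshold; a configurable fraction of
ORFs is taxonomically misassigned (``p_wrong``) or left without usable
BLAST evidence (``p_unc``).  ORF identifiers encode only the sample and a
serial number, never the true taxon.

Fixing the seed fixes every output byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FamilyCatalog, default_catalog
from .screen import TaxonomyIndex, UNCLASSIFIED
from .synteny import GeneRecord, records_to_frame

__all__ = [
    "GenomeArchetype",
    "default_archetypes",
    "generate_genomes",
    "EcotypeSpec",
    "SamplingDesign",
    "SampleTruth",
    "OrfTruth",
    "SyntheticBundle",
    "generate_metagenome_hits",
    "default_taxonomy_index",
    "demo_design",
    "noiseless_design",
    "ecotype_design",
    "planted_correlation_counts",
    "DEFAULT_TAXA",
]

DEFAULT_TAXA = (
    "Thaumarchaeota",
    "Cyanobacteria",
    "Proteobacteria",
    "Bacteroidetes",
    UNCLASSIFIED,
)

# Reference subjects backing BLAST-based taxonomy: subject_id, 7-rank
# lineage.  Subject ids are deliberately opaque.
_REFERENCE = {
    "Thaumarchaeota": (
        ("S0001", "Archaea;Thaumarchaeota;Nitrososphaeria;Nitrosopumilales;Nitrosopumilaceae;Nitrosopumilus;Nitrosopumilus maritimus SCM1"),
        ("S0002", "Archaea;Thaumarchaeota;Nitrososphaeria;Nitrosopumilales;Nitrosopumilaceae;Nitrosopumilus;Candidatus Nitrosopumilus salaria"),
    ),
    "Cyanobacteria": (
        ("S0003", "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Prochlorococcaceae;Prochlorococcus;Prochlorococcus marinus str. MIT 9301"),
        ("S0004", "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Prochlorococcaceae;Prochlorococcus;Prochlorococcus marinus str. AS9601"),
    ),
    "Proteobacteria": (
        ("S0005", "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Rhodobacterales bacterium;Rhodobacterales bacterium HTCC2255"),
        ("S0006", "Bacteria;Proteobacteria;Gammaproteobacteria;Oceanospirillales;Oceanospirillaceae;Neptuniibacter;Neptuniibacter caesariensis"),
    ),
    "Bacteroidetes": (
        ("S0007", "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Polaribacter;Polaribacter sp. MED152"),
    ),
}

# Accessions as they appear in third-party hit files (Pfam accessions carry
# a minor version there).
_WRITTEN_ACCESSION = {"PF02570": "PF02570.10"}


def default_taxonomy_index() -> TaxonomyIndex:
    """Taxonomy index over the packaged reference subjects."""
    lineages = {
        sid: tuple(lin.split(";"))
        for entries in _REFERENCE.values()
        for sid, lin in entries
    }
    return TaxonomyIndex(lineages)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeArchetype:
    """Blueprint for one synthetic genome.

    ``clusters`` are ordered gene-label runs planted consecutively (zero
    intervening decoys); remaining ``present_families`` are scattered as
    singletons well away from any other pathway gene.  ``decoy_gene_count``
    is the total number of unlabelled genes.
    """

    name: str
    present_families: tuple[str, ...]
    clusters: tuple[tuple[str, ...], ...] = ()
    decoy_gene_count: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        present = set(self.present_families)
        for cluster in self.clusters:
            missing = set(cluster) - present
            if missing:
                raise ValueError(
                    f"{self.name}: clustered genes missing from "
                    f"present_families: {sorted(missing)}"
                )


_EARLY_CLUSTER = ("cobA_cysG", "cbiX", "cobI_cbiL", "cbiG", "cbiD", "cobJ_cbiH")
_LATE_CLUSTER = ("cbiA_cobB", "cbiB_cobD", "cbiP_cobQ", "cobS")


def default_archetypes() -> list[GenomeArchetype]:
    """The packaged fixture genomes: anaerobic producer (with the dual
    6-gene early and 4-gene late clusters), aerobic producer, non-producer.
    """
    anaerobic = GenomeArchetype(
        name="anaerobic_producer",
        present_families=_EARLY_CLUSTER
        + _LATE_CLUSTER
        + ("cobM_cbiF", "cbiT_cobL", "cbiE_cobL", "cbiC_cobH"),
        clusters=(_EARLY_CLUSTER, _LATE_CLUSTER),
        decoy_gene_count=55,
    )
    aerobic = GenomeArchetype(
        name="aerobic_producer",
        present_families=(
            "cobG",
            "cobF",
            "cobN",
            "cobT",
            "cobA_cysG",
            "cobI_cbiL",
            "cbiC_cobH",
            "cobM_cbiF",
        ),
        clusters=(("cobG", "cobF", "cobN"),),
        decoy_gene_count=45,
    )
    non_producer = GenomeArchetype(
        name="non_producer",
        present_families=(),
        clusters=(),
        decoy_gene_count=30,
    )
    return [anaerobic, aerobic, non_producer]


# Decoys placed between planted clusters (keeps the 6- and 4-gene clusters
# well apart at any reasonable gap tolerance) and around scattered
# singletons.
_CLUSTER_SEPARATION = 22
_SINGLETON_SEPARATION = 5


def generate_genomes(
    archetypes: Sequence[GenomeArchetype],
    seed: int | None,
) -> tuple[pd.DataFrame, dict]:
    """Realize archetypes into an annotation table plus a truth record.

    Coordinates are 1-based, strictly increasing and non-overlapping per
    replicon; the truth lists each planted cluster's labels, locus tags and
    span.  A seed is mandatory: fixture generation must be reproducible.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible genome fixtures")
    records: list[GeneRecord] = []
    truth: dict[str, dict] = {}
    for a_idx, arch in enumerate(archetypes):
        rng = np.random.default_rng(
            arch.seed if arch.seed is not None else [int(seed), a_idx]
        )
        clustered = {g for c in arch.clusters for g in c}
        singles = [g for g in arch.present_families if g not in clustered]

        # Token stream: None marks a decoy position.
        tokens: list[tuple[str | None, int | None]] = []  # (label, cluster index)
        budget = arch.decoy_gene_count
        segments: list[tuple[list[str], int | None]] = [
            (list(c), ci) for ci, c in enumerate(arch.clusters)
        ] + [([g], None) for g in singles]
        need = 0
        for i in range(len(segments) - 1):
            sep = (
                _CLUSTER_SEPARATION
                if segments[i][1] is not None and segments[i + 1][1] is not None
                else _SINGLETON_SEPARATION
            )
            need += sep
        if budget < need:
            raise ValueError(
                f"{arch.name}: decoy_gene_count={budget} cannot separate the "
                f"planted segments (need >= {need})"
            )
        for i, (labels, ci) in enumerate(segments):
            tokens.extend((lab, ci) for lab in labels)
            if i < len(segments) - 1:
                sep = (
                    _CLUSTER_SEPARATION
                    if ci is not None and segments[i + 1][1] is not None
                    else _SINGLETON_SEPARATION
                )
                tokens.extend([(None, None)] * sep)
                budget -= sep
        tokens.extend([(None, None)] * budget)

        pos = 1
        cluster_members: dict[int, list[tuple[str, str, int, int]]] = {}
        for serial, (label, ci) in enumerate(tokens):
            length = int(rng.integers(200, 600)) * 3
            start, end = pos, pos + length - 1
            pos = end + 1 + int(rng.integers(20, 200))
            locus = f"{arch.name}_{serial:04d}"
            records.append(
                GeneRecord(
                    genome_id=arch.name,
                    replicon_id=f"{arch.name}_chr",
                    locus_tag=locus,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    gene_label=label or "",
                )
            )
            if ci is not None:
                cluster_members.setdefault(ci, []).append((label, locus, start, end))
        truth[arch.name] = {
            "present_families": sorted(arch.present_families),
            "clusters": [
                {
                    "labels": [m[0] for m in cluster_members[ci]],
                    "locus_tags": [m[1] for m in cluster_members[ci]],
                    "span": [
                        min(m[2] for m in cluster_members[ci]),
                        max(m[3] for m in cluster_members[ci]),
                    ],
                }
                for ci in sorted(cluster_members)
            ],
        }
    return records_to_frame(records), truth


# ---------------------------------------------------------------------------
# Metagenome sampling design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EcotypeSpec:
    """One mixture component: a centre profile plus covariate link.

    ``center`` maps taxa to relative weights (normalized internally);
    ``link`` maps covariate names to softmax coefficients on standardized
    covariates (the month covariate enters via its cosine encoding).
    """

    name: str
    center: Mapping[str, float]
    intercept: float = 0.0
    link: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SamplingDesign:
    """Full description of a synthetic metagenome study.

    Covariate specs are tuples: ``("uniform", lo, hi)``, ``("normal", mu,
    sd)``, ``("months",)`` (integer 1..12, linked via cos(2*pi*month/12))
    or ``("constant", v)``.  Exactly one of ``links`` (softmax over taxa)
    or ``ecotypes`` (softmax over components) shapes the taxon proportions;
    with neither, proportions are uniform.
    """

    taxa: tuple[str, ...] = DEFAULT_TAXA
    n_samples: int = 60
    covariates: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "depth": ("uniform", 5.0, 1000.0),
            "temperature": ("normal", 12.0, 6.0),
            "nitrate": ("uniform", 0.0, 35.0),
            "month": ("months",),
        }
    )
    links: Mapping[str, Mapping[str, float]] | None = None
    intercepts: Mapping[str, float] = field(default_factory=dict)
    ecotypes: tuple[EcotypeSpec, ...] | None = None
    ecotype_assignment: str = "softmax"  # or "balanced"
    concentration: float = 150.0
    per_gene_means: Mapping[str, float] = field(default_factory=dict)
    p_wrong: float = 0.0
    p_unc: float = 0.0
    decoy_fraction: float = 0.0
    true_log10e: tuple[float, float] = (-30.0, -3.0)
    decoy_log10e: tuple[float, float] = (-5.0, 2.0)
    undersampled: int = 0
    studies: tuple[str, ...] = ("study_A",)
    rank: str = "phylum"

    def validate(self, catalog: FamilyCatalog | None = None) -> None:
        if not self.taxa:
            raise ValueError("design needs at least one taxon")
        for p, name in (
            (self.p_wrong, "p_wrong"),
            (self.p_unc, "p_unc"),
            (self.decoy_fraction, "decoy_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.links is not None and self.ecotypes is not None:
            raise ValueError("specify taxa links or ecotype components, not both")
        link_maps: list[Mapping[str, float]] = []
        if self.links is not None:
            link_maps.extend(self.links.values())
        if self.ecotypes is not None:
            link_maps.extend(e.link for e in self.ecotypes)
            for e in self.ecotypes:
                bad = set(e.center) - set(self.taxa)
                if bad:
                    raise ValueError(f"ecotype {e.name}: unknown taxa {sorted(bad)}")
                if any(v < 0 for v in e.center.values()):
                    raise ValueError(f"ecotype {e.name}: negative centre weight")
        for lm in link_maps:
            for cov, coef in lm.items():
                if cov not in self.covariates:
                    raise ValueError(f"link references unknown covariate {cov!r}")
                if not math.isfinite(coef):
                    raise ValueError(f"non-finite link coefficient for {cov!r}")
        if not self.per_gene_means:
            raise ValueError("design needs per-gene expected hit totals")
        if any(m < 0 for m in self.per_gene_means.values()):
            raise ValueError("per-gene means must be nonnegative")
        if self.undersampled > self.n_samples:
            raise ValueError("more under-sampled samples than samples")
        if self.ecotype_assignment not in ("softmax", "balanced"):
            raise ValueError("ecotype_assignment must be 'softmax' or 'balanced'")
        if catalog is not None:
            unknown = set(self.per_gene_means) - set(catalog.labels())
            if unknown:
                raise ValueError(f"per-gene means for non-catalog genes: {sorted(unknown)}")


def _draw_covariate(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "normal":
        return float(rng.normal(spec[1], spec[2]))
    if kind == "months":
        return int(rng.integers(1, 13))
    if kind == "constant":
        return float(spec[1])
    raise ValueError(f"unknown covariate kind {kind!r}")


def _standardize(name: str, value: float, spec: tuple) -> float:
    kind = spec[0]
    if kind == "uniform":
        mid = (spec[1] + spec[2]) / 2.0
        half = (spec[2] - spec[1]) / 2.0
        return (value - mid) / half if half else 0.0
    if kind == "normal":
        return (value - spec[1]) / spec[2] if spec[2] else 0.0
    if kind == "months":
        return math.cos(2.0 * math.pi * value / 12.0)
    return 0.0


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Metagenome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfTruth:
    orf_id: str
    gene_label: str
    taxon: str
    species: str | None
    evalue: float
    passes_filter: bool
    blast_taxon: str


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one synthetic sample."""

    sample_id: str
    covariates: dict[str, float]
    true_proportions: dict[str, float]
    total_hits_per_gene: dict[str, int]
    seed: int
    ecotype: str | None = None
    study: str = "study_A"
    orfs: tuple[OrfTruth, ...] = ()

    def allocated_counts(self) -> dict[str, int]:
        """Hits allocated per taxon (before any downstream filtering)."""
        out: dict[str, int] = {}
        for o in self.orfs:
            out[o.taxon] = out.get(o.taxon, 0) + 1
        return out

    def expected_table_counts(self, e_max: float = 1e-6) -> dict[str, int]:
        """Per-taxon counts the screening pipeline should report exactly."""
        out: dict[str, int] = {}
        for o in self.orfs:
            if o.evalue <= e_max:
                out[o.blast_taxon] = out.get(o.blast_taxon, 0) + 1
        return out


@dataclass(frozen=True)
class SyntheticBundle:
    """Paths and truth of one generated study."""

    outdir: Path
    hmm_paths: dict[str, Path]
    blast_paths: dict[str, Path]
    metadata_path: Path
    taxonomy_path: Path
    truth_path: Path
    truths: tuple[SampleTruth, ...]
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.truths]


_TBLOUT_HEADER = (
    "#                                                               "
    "--- full sequence ---- --- best 1 domain ---- --- domain number estimation ----\n"
    "# target name        accession  query name           accession  "
    "  E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc "
    "description of target\n"
    "#------------------- ---------- -------------------- ---------- "
    "--------- ------ ----- --------- ------ -----   --- --- --- --- --- --- --- --- "
    "---------------------\n"
)


def generate_metagenome_hits(
    design: SamplingDesign,
    seed: int | None,
    outdir: str | Path,
    catalog: FamilyCatalog | None = None,
) -> SyntheticBundle:
    """Write a complete synthetic study bundle under ``outdir``.

    Per sample: per-gene totals are Poisson draws around the design means
    (under-sampled samples instead receive a fixed sub-threshold total of
    1-9 hits, so the downstream n<10 filter removes exactly these samples);
    taxa are allocated multinomially from the sample's link-derived
    proportions; every ORF gets one hmmsearch tblout row and (unless
    unclassifiable) BLAST rows whose top hit maps to the true taxon with
    probability 1 - p_wrong.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible fixtures")
    catalog = catalog or default_catalog()
    design.validate(catalog)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    label_to_acc = {m.gene_label: m.accession for m in catalog}
    index = default_taxonomy_index()
    taxonomy_path = outdir / "taxonomy.tsv"
    index.to_tsv(taxonomy_path)

    taxa = list(design.taxa)
    genes = sorted(design.per_gene_means)
    species_of = {
        t: list(_REFERENCE.get(t, ())) for t in taxa if t != UNCLASSIFIED
    }
    for t, entries in species_of.items():
        if not entries:
            raise ValueError(f"no reference subjects for taxon {t!r}")

    hmm_paths: dict[str, Path] = {}
    blast_paths: dict[str, Path] = {}
    truths: list[SampleTruth] = []
    meta_rows: list[dict] = []
    unk_serial = 0

    n = design.n_samples
    for i in range(n):
        sid = f"SMP{i:03d}"
        rng = np.random.default_rng([int(seed), 7, i])
        covs = {
            name: _draw_covariate(spec, rng)
            for name, spec in design.covariates.items()
        }
        z = {
            name: _standardize(name, covs[name], design.covariates[name])
            for name in design.covariates
        }

        ecotype_name: str | None = None
        if design.ecotypes is not None:
            if design.ecotype_assignment == "balanced":
                comp = i % len(design.ecotypes)
            else:
                scores = np.array(
                    [
                        e.intercept
                        + sum(coef * z[cov] for cov, coef in e.link.items())
                        for e in design.ecotypes
                    ]
                )
                comp = int(rng.choice(len(design.ecotypes), p=_softmax(scores)))
            spec = design.ecotypes[comp]
            ecotype_name = spec.name
            center = np.array(
                [max(spec.center.get(t, 0.0), 1e-3) for t in taxa], dtype=float
            )
            center /= center.sum()
            p = rng.dirichlet(center * design.concentration)
        elif design.links is not None:
            scores = np.array(
                [
                    design.intercepts.get(t, 0.0)
                    + sum(
                        coef * z[cov]
                        for cov, coef in design.links.get(t, {}).items()
                    )
                    for t in taxa
                ]
            )
            p = _softmax(scores)
        else:
            p = np.full(len(taxa), 1.0 / len(taxa))

        undersampled = i >= n - design.undersampled
        totals: dict[str, int] = {}
        if undersampled:
            total = int(rng.integers(1, 10))
            weights = np.array([design.per_gene_means[g] for g in genes], float)
            weights /= weights.sum()
            alloc = rng.multinomial(total, weights)
            totals = {g: int(c) for g, c in zip(genes, alloc)}
        else:
            totals = {
                g: int(rng.poisson(design.per_gene_means[g])) for g in genes
            }

        # Allocate each gene's hits across taxa, then shuffle so ORF serial
        # numbers carry no information about gene or taxon.
        pairs: list[tuple[str, str]] = []
        for g in genes:
            counts = rng.multinomial(totals[g], p)
            for t, c in zip(taxa, counts):
                pairs.extend([(g, t)] * int(c))
        order = rng.permutation(len(pairs))
        pairs = [pairs[j] for j in order]

        m = len(pairs)
        decoy_law = rng.random(m) < design.decoy_fraction
        lo_t, hi_t = design.true_log10e
        lo_d, hi_d = design.decoy_log10e
        log10e = np.where(
            decoy_law,
            rng.uniform(lo_d, hi_d, size=m),
            rng.uniform(lo_t, hi_t, size=m),
        )
        unc_draw = rng.random(m) < design.p_unc
        wrong_draw = rng.random(m) < design.p_wrong

        hmm_lines: list[str] = []
        blast_lines: list[str] = []
        orfs: list[OrfTruth] = []
        for j, (g, t) in enumerate(pairs):
            orf = f"{sid}_orf{j:05d}"
            evalue = float(f"{10.0 ** log10e[j]:.2e}")
            score = max(round(25.0 - 2.0 * log10e[j] + rng.normal(0, 2), 1), 2.0)
            acc = label_to_acc[g]
            written_acc = _WRITTEN_ACCESSION.get(acc, acc)
            hmm_lines.append(
                f"{orf} - {g} {written_acc} {evalue:.2e} {score:.1f} 0.1 "
                f"{evalue:.2e} {score:.1f} 0.1 1.0 1 0 0 1 1 1 1 -\n"
            )

            unclassified = (t == UNCLASSIFIED) or unc_draw[j]
            species: str | None = None
            blast_taxon = UNCLASSIFIED
            if unclassified:
                if rng.random() < 0.7:
                    unk_serial += 1
                    subject = f"UNK{unk_serial:06d}"
                    be = 10.0 ** rng.uniform(-40, -10)
                    bs = max(round(60.0 - 2.0 * math.log10(be) + rng.normal(0, 3), 1), 25.0)
                    blast_lines.append(_blast_row(orf, subject, be, bs, rng))
            else:
                if wrong_draw[j]:
                    others = [x for x in taxa if x not in (t, UNCLASSIFIED)]
                    pick_taxon = others[int(rng.integers(len(others)))]
                else:
                    pick_taxon = t
                entries = species_of[pick_taxon]
                sidx = int(rng.integers(len(entries)))
                subject, lineage = entries[sidx]
                species = lineage.split(";")[-1]
                blast_taxon = index.name_at_rank(subject, rank=design.rank)
                be = 10.0 ** rng.uniform(-40, -10)
                bs = max(round(60.0 - 2.0 * math.log10(be) + rng.normal(0, 3), 1), 25.0)
                blast_lines.append(_blast_row(orf, subject, be, bs, rng))
                if rng.random() < 0.5:
                    # A worse secondary hit, possibly to another taxon.
                    all_entries = [e for v in species_of.values() for e in v]
                    s2, _ = all_entries[int(rng.integers(len(all_entries)))]
                    be2 = be * 10.0 ** rng.uniform(2, 6)
                    bs2 = max(round(bs - rng.uniform(10, 40), 1), 20.0)
                    blast_lines.append(_blast_row(orf, s2, be2, bs2, rng))
            orfs.append(
                OrfTruth(
                    orf_id=orf,
                    gene_label=g,
                    taxon=t,
                    species=species,
                    evalue=evalue,
                    passes_filter=evalue <= 1e-6,
                    blast_taxon=blast_taxon,
                )
            )

        hmm_path = outdir / f"{sid}.tblout"
        with open(hmm_path, "w") as fh:
            fh.write(_TBLOUT_HEADER)
            fh.writelines(hmm_lines)
            fh.write("#\n# Program:         hmmsearch\n")
        blast_path = outdir / f"{sid}.blast.tsv"
        with open(blast_path, "w") as fh:
            fh.writelines(blast_lines)
        hmm_paths[sid] = hmm_path
        blast_paths[sid] = blast_path

        study = design.studies[i * len(design.studies) // n]
        meta_rows.append(
            {
                "sample_id": sid,
                **{
                    k: (int(v) if design.covariates[k][0] == "months" else round(v, 4))
                    for k, v in covs.items()
                },
                "study": study,
            }
        )
        truths.append(
            SampleTruth(
                sample_id=sid,
                covariates=covs,
                true_proportions={t: float(pp) for t, pp in zip(taxa, p)},
                total_hits_per_gene=totals,
                seed=int(seed),
                ecotype=ecotype_name,
                study=study,
                orfs=tuple(orfs),
            )
        )

    metadata_path = outdir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)

    truth_path = outdir / "truth.json"
    summary = [
        {
            "sample_id": t.sample_id,
            "study": t.study,
            "ecotype": t.ecotype,
            "covariates": {k: float(v) for k, v in t.covariates.items()},
            "true_proportions": t.true_proportions,
            "total_hits_per_gene": t.total_hits_per_gene,
            "allocated_counts": t.allocated_counts(),
            "expected_table_counts": t.expected_table_counts(),
        }
        for t in truths
    ]
    with open(truth_path, "w") as fh:
        json.dump({"seed": int(seed), "samples": summary}, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return SyntheticBundle(
        outdir=outdir,
        hmm_paths=hmm_paths,
        blast_paths=blast_paths,
        metadata_path=metadata_path,
        taxonomy_path=taxonomy_path,
        truth_path=truth_path,
        truths=tuple(truths),
        seed=int(seed),
    )


def _blast_row(
    orf: str, subject: str, evalue: float, bitscore: float, rng: np.random.Generator
) -> str:
    pident = round(float(rng.uniform(60, 99)), 1)
    length = int(rng.integers(60, 250))
    mismatch = int(round(length * (100 - pident) / 100))
    return (
        f"{orf}\t{subject}\t{pident:.1f}\t{length}\t{mismatch}\t0\t1\t{length}"
        f"\t1\t{length}\t{evalue:.2e}\t{bitscore:.1f}\n"
    )


# ---------------------------------------------------------------------------
# Canned designs
# ---------------------------------------------------------------------------


def demo_design(n_samples: int = 60) -> SamplingDesign:
    """The documented default study: three ecotypes shaped by depth,
    nitrate, temperature and season; a mutually exclusive
    Thaumarchaeota/Cyanobacteria pair (they dominate disjoint components);
    an Unclassified fraction; E-values straddling the screening threshold;
    two under-sampled samples.
    """
    catalog = default_catalog()
    means = {g: 20.0 for g in catalog.cobalamin_labels}
    means.update({g: 40.0 for g in catalog.ribosomal_labels})
    ecotypes = (
        EcotypeSpec(
            name="T",
            center={
                "Thaumarchaeota": 0.72,
                "Proteobacteria": 0.13,
                "Cyanobacteria": 0.02,
                "Bacteroidetes": 0.05,
                UNCLASSIFIED: 0.08,
            },
            link={"depth": 2.5, "nitrate": 1.5, "month": 1.0},
        ),
        EcotypeSpec(
            name="C",
            center={
                "Thaumarchaeota": 0.01,
                "Proteobacteria": 0.25,
                "Cyanobacteria": 0.55,
                "Bacteroidetes": 0.09,
                UNCLASSIFIED: 0.10,
            },
            link={"depth": -2.0, "temperature": 1.5, "month": -1.0},
        ),
        EcotypeSpec(
            name="P",
            center={
                "Thaumarchaeota": 0.05,
                "Proteobacteria": 0.60,
                "Cyanobacteria": 0.14,
                "Bacteroidetes": 0.11,
                UNCLASSIFIED: 0.10,
            },
            intercept=0.3,
        ),
    )
    return SamplingDesign(
        n_samples=n_samples,
        ecotypes=ecotypes,
        per_gene_means=means,
        p_wrong=0.02,
        p_unc=0.05,
        decoy_fraction=0.08,
        true_log10e=(-30.0, -3.0),
        undersampled=2,
        studies=("MILOCO_like", "channel_L4_like", "polar_like"),
    )


def noiseless_design(
    n_samples: int = 4,
    hits_per_sample: float = 10_000.0,
    undersampled: int = 2,
    ecotypes: tuple[EcotypeSpec, ...] | None = None,
) -> SamplingDesign:
    """A loss-free configuration: no misassignment, no unclassifiable ORFs,
    all E-values below the screening threshold.  Downstream per-taxon counts
    must equal the generator's allocations exactly.
    """
    catalog = default_catalog()
    per_gene = hits_per_sample / 11.0
    means = {g: per_gene for g in catalog.cobalamin_labels}
    means.update({g: per_gene for g in catalog.ribosomal_labels})
    taxa = tuple(t for t in DEFAULT_TAXA if t != UNCLASSIFIED)
    if ecotypes is None:
        ecotypes = (
            EcotypeSpec(name="T", center={"Thaumarchaeota": 0.65, "Proteobacteria": 0.2, "Cyanobacteria": 0.05, "Bacteroidetes": 0.1}),
            EcotypeSpec(name="P", center={"Thaumarchaeota": 0.1, "Proteobacteria": 0.6, "Cyanobacteria": 0.2, "Bacteroidetes": 0.1}),
        )
    return SamplingDesign(
        taxa=taxa,
        n_samples=n_samples + undersampled,
        ecotypes=ecotypes,
        ecotype_assignment="balanced",
        per_gene_means=means,
        p_wrong=0.0,
        p_unc=0.0,
        decoy_fraction=0.0,
        true_log10e=(-30.0, -7.0),
        undersampled=undersampled,
    )


def ecotype_design(
    n_per_ecotype: int = 20,
    hits_per_sample: float = 400.0,
    concentration: float = 200.0,
) -> SamplingDesign:
    """Three well-separated ecotypes (pairwise centre separation > 0.4 in
    L1), balanced membership, for cluster-recovery checks.
    """
    base = demo_design(n_samples=3 * n_per_ecotype)
    catalog = default_catalog()
    per_gene = hits_per_sample / 11.0
    means = {g: per_gene for g in catalog.cobalamin_labels}
    means.update({g: per_gene for g in catalog.ribosomal_labels})
    return SamplingDesign(
        n_samples=3 * n_per_ecotype,
        ecotypes=base.ecotypes,
        ecotype_assignment="balanced",
        concentration=concentration,
        per_gene_means=means,
        p_wrong=0.0,
        p_unc=0.0,
        decoy_fraction=0.0,
        true_log10e=(-30.0, -7.0),
        undersampled=0,
    )


def planted_correlation_counts(
    seed: int,
    r_true: float,
    n_samples: int = 200,
    hits_per_sample: int = 400,
    taxon: str = "Thaumarchaeota",
    covariate: str = "depth",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Plant an exact empirical covariate-taxon correlation.

    Constructs a latent proportion vector for ``taxon`` whose sample
    Pearson correlation with the drawn covariate equals ``r_true`` exactly
    (Gram-Schmidt on a noise vector), splits the remaining mass over the
    other default taxa in fixed ratio, and draws multinomial hit counts.
    Any departure of the recovered correlation from ``r_true`` is therefore
    attributable to the counting pipeline, not to sampling of the planted
    link itself.

    Returns (metadata, counts, truth proportion of ``taxon``).
    """
    if not -1.0 < r_true < 1.0:
        raise ValueError("r_true must be in (-1, 1)")
    rng = np.random.default_rng([int(seed), 11])
    x = rng.uniform(5.0, 1000.0, size=n_samples)
    eps = rng.normal(size=n_samples)
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)
    ec = eps - eps.mean()
    ec -= (ec @ xn) * xn
    en = ec / np.linalg.norm(ec)
    y = r_true * xn + math.sqrt(1.0 - r_true**2) * en
    # Affine map into (0.05, 0.95); preserves the exact correlation.
    y = 0.5 + 0.45 * y / np.abs(y).max()

    others = [t for t in DEFAULT_TAXA if t != taxon]
    rest_weights = np.array([3.0, 4.0, 2.0, 1.0])[: len(others)]
    rest_weights = rest_weights / rest_weights.sum()
    taxa = [taxon] + others
    counts = np.empty((n_samples, len(taxa)), dtype=int)
    for i in range(n_samples):
        p = np.concatenate(([y[i]], (1.0 - y[i]) * rest_weights))
        counts[i] = rng.multinomial(hits_per_sample, p)
    sample_ids = [f"SMP{i:03d}" for i in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    counts_df.index.name = "sample_id"
    metadata = pd.DataFrame({"sample_id": sample_ids, covariate: x}).set_index(
        "sample_id"
    )
    truth = pd.Series(y, index=sample_ids, name=taxon)
    return metadata, counts_df, truth
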