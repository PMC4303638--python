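"""End-to-end pipeline driver, configuration and run provenance.

A run executes: marker screening (per-sample hit tables) -> contribution
profiles (cobalamin and ribosomal) -> ecotype clustering -> metadata and
taxon-taxon correlations, writing every intermediate and final table plus a
machine-readable run manifest (config echo, version, per-stage row counts,
output checksums).  Identical config and inputs produce byte-identical
output bundles; the manifest contains no timestamps for that reason.

The filters along the way (E-value threshold, n<10 sample rule) silently
drop data, so stage boundaries log row counts in and out.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .catalog import load_catalog
from .contribution import (
    ContributionProfile,
    build_profile,
    export_profile,
    overrepresentation,
)
from .correlate import grouped_analysis, taxon_metadata_matrix, taxon_vs_taxon
from .ecotypes import assign_ecotypes, manhattan_distance_matrix, to_newick
from .screen import HitTable, TaxonomyIndex, build_hit_table
from .simulate import SyntheticBundle, demo_design, generate_metagenome_hits

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run.

    ``samples`` maps sample_id -> {"hmm": path, "blast": path}.  Thresholds
    default to the screening conventions used throughout the package.
    """

    samples: dict[str, dict[str, str]]
    metadata: str
    taxonomy: str
    outdir: str
    catalog: str = "default"
    e_max: float = 1e-6
    min_hits: int = 10
    r_report: float = 0.25
    max_gap: int = 2
    dominance: float = 0.50
    co_dominance: float = 0.25
    min_pairs: int = 5
    k: int | str = "auto"
    rank: str = "phylum"
    split_proteobacteria: bool = False
    study_col: str = "study"
    seed: int = 0

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        if not 0 < self.e_max:
            raise ValueError("e_max must be positive")
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if not 0 <= self.r_report <= 1:
            raise ValueError("r_report must be within [0, 1]")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not 0 <= self.co_dominance <= self.dominance <= 1:
            raise ValueError("need 0 <= co_dominance <= dominance <= 1")
        for sid, paths in self.samples.items():
            for key in ("hmm", "blast"):
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(f"{sid}: missing {key} file {paths[key]}")
        for p in (self.metadata, self.taxonomy):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    cob_profile: ContributionProfile | None
    ribo_profile: ContributionProfile | None
    hit_tables: dict[str, HitTable]


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full metagenome analysis described by ``config``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "complete": False,
    }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        info = stage("catalog")
        catalog = load_catalog(config.catalog)
        taxonomy = TaxonomyIndex.from_tsv(config.taxonomy)
        info["families"] = len(catalog)
        info["taxonomy_subjects"] = len(taxonomy)

        info = stage("screen")
        tables: dict[str, HitTable] = {}
        tables_dir = outdir / "hit_tables"
        tables_dir.mkdir(exist_ok=True)
        n_rows = 0
        for sid in sorted(config.samples):
            paths = config.samples[sid]
            table = build_hit_table(
                sid,
                paths["hmm"],
                paths["blast"],
                catalog,
                taxonomy,
                rank=config.rank,
                e_max=config.e_max,
                split_proteobacteria=config.split_proteobacteria,
            )
            table.to_tsv(tables_dir / f"{sid}.tsv")
            tables[sid] = table
            n_rows += len(table)
        info["samples"] = len(tables)
        info["rows"] = n_rows

        info = stage("contribution")
        cob = build_profile(
            list(tables.values()), catalog, "cobalamin", min_hits=config.min_hits
        )
        ribo = build_profile(
            list(tables.values()), catalog, "ribosomal", min_hits=config.min_hits
        )
        export_profile(cob, outdir / "cob_profile_wide.tsv", outdir / "cob_profile_long.tsv")
        export_profile(ribo, outdir / "ribo_profile_wide.tsv", outdir / "ribo_profile_long.tsv")
        cob.n_total.rename("n_total").to_csv(outdir / "cob_n_total.tsv", sep="\t")
        info["retained_cobalamin_samples"] = len(cob.samples)
        info["retained_ribosomal_samples"] = len(ribo.samples)
        info["dropped_samples"] = len(tables) - len(cob.samples)
        if len(cob.samples) == 0:
            logger.warning("no sample reached %d cobalamin hits; downstream "
                           "stages skipped", config.min_hits)
        try:
            over = overrepresentation(cob, ribo)
            over.round(9).to_csv(outdir / "overrepresentation.tsv", sep="\t")
        except ValueError:
            logger.info("no shared retained samples; overrepresentation skipped")

        info = stage("ecotypes")
        if len(cob.samples) >= 3:
            assignments, dend = assign_ecotypes(
                cob,
                k=config.k,
                dominance=config.dominance,
                co_dominance=config.co_dominance,
            )
            assignments.to_csv(outdir / "ecotypes.tsv", sep="\t", index=False)
            dend.merge_table().round(9).to_csv(outdir / "dendrogram.tsv", sep="\t", index=False)
            (outdir / "dendrogram.nwk").write_text(to_newick(dend) + "\n")
            dist = manhattan_distance_matrix(cob)
            order = dend.leaf_order()
            cob.D.loc[order].round(9).to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
            info["clusters"] = int(assignments["cluster_id"].nunique())
        else:
            logger.info("fewer than 3 retained samples; clustering skipped")
            info["clusters"] = 0

        info = stage("correlation")
        metadata = pd.read_csv(config.metadata, sep="\t")
        if len(cob.samples) >= config.min_pairs:
            result = taxon_metadata_matrix(
                cob, metadata, r_report=config.r_report, min_pairs=config.min_pairs
            )
            result.to_tsv(
                outdir / "taxon_metadata_r.tsv", outdir / "taxon_metadata_r_wide.tsv"
            )
            result.report().to_csv(outdir / "taxon_metadata_report.tsv", sep="\t", index=False)
            tvt = taxon_vs_taxon(cob, r_report=config.r_report, min_pairs=config.min_pairs)
            tvt.to_tsv(outdir / "taxon_vs_taxon_r.tsv")
            info["metadata_pairs"] = len(result.table)
            info["taxon_pairs"] = len(tvt.table)
            if config.study_col in metadata.columns:
                per_study = grouped_analysis(
                    cob,
                    metadata,
                    study_col=config.study_col,
                    r_report=config.r_report,
                    min_pairs=config.min_pairs,
                )
                for study, res in per_study.items():
                    sdir = outdir / "per_study" / study
                    sdir.mkdir(parents=True, exist_ok=True)
                    res.to_tsv(sdir / "taxon_metadata_r.tsv")
                info["studies"] = len(per_study)
        else:
            logger.info("too few retained samples; correlations skipped")
            info["metadata_pairs"] = 0
    except Exception as exc:
        failed_stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed_stage
        _write_manifest(outdir, manifest)
        raise PipelineError(f"stage {failed_stage!r} failed: {exc}") from exc

    manifest["complete"] = True
    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    _write_manifest(outdir, manifest)
    return RunResult(
        outdir=outdir,
        manifest=manifest,
        cob_profile=cob if len(cob.samples) else None,
        ribo_profile=ribo if len(ribo.samples) else None,
        hit_tables=tables,
    )


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass(frozen=True)
class DemoBundle:
    bundle: SyntheticBundle
    config: PipelineConfig
    config_path: Path
    digest: dict
    digest_path: Path


def make_demo(seed: int, outdir: str | Path, n_samples: int = 60) -> DemoBundle:
    """Generate the documented default synthetic study plus a run config.

    Sixty samples from three planted ecotypes (Thaumarchaeota-, Cyanobacteria-
    and Proteobacteria-dominated) with depth/nitrate/temperature/season
    links, a mutually exclusive Thaumarchaeota-Cyanobacteria pair, an
    Unclassified fraction, E-values on both sides of the screening
    threshold, and two under-sampled samples.  A digest of headline
    expectations is written for downstream checks.
    """
    outdir = Path(outdir)
    data_dir = outdir / "inputs"
    design = demo_design(n_samples=n_samples)
    bundle = generate_metagenome_hits(design, seed=seed, outdir=data_dir)
    config = PipelineConfig(
        samples={
            sid: {
                "hmm": str(bundle.hmm_paths[sid]),
                "blast": str(bundle.blast_paths[sid]),
            }
            for sid in bundle.sample_ids
        },
        metadata=str(bundle.metadata_path),
        taxonomy=str(bundle.taxonomy_path),
        outdir=str(outdir / "results"),
        seed=seed,
    )
    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    ecotype_names = sorted({t.ecotype for t in bundle.truths if t.ecotype})
    digest = {
        "seed": int(seed),
        "n_samples": design.n_samples,
        "n_undersampled": design.undersampled,
        "planted_ecotypes": len(design.ecotypes or ()),
        "ecotype_names": ecotype_names,
        "either_or_pair": ["Thaumarchaeota", "Cyanobacteria"],
        "total_orfs": int(sum(len(t.orfs) for t in bundle.truths)),
        "input_sha256": {
            p.name: _sha256(p)
            for p in sorted(data_dir.iterdir())
            if p.is_file()
        },
    }
    digest_path = outdir / "digest.json"
    with open(digest_path, "w") as fh:
        json.dump(digest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return DemoBundle(
        bundle=bundle,
        config=config,
        config_path=config_path,
        digest=digest,
        digest_path=digest_path,
    )
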