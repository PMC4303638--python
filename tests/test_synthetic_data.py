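import math

import numpy as np
import pandas as pd
import pytest

from cobscreen.simulate import (
    GenomeArchetype,
    SamplingDesign,
    default_archetypes,
    default_taxonomy_index,
    generate_genomes,
    generate_metagenome_hits,
    planted_correlation_counts,
)


def _small_design(**kw):
    base = dict(
        n_samples=4,
        per_gene_means={"cbiA_cobB": 30.0, "cobS": 20.0},
        taxa=("Thaumarchaeota", "Proteobacteria"),
    )
    base.update(kw)
    return SamplingDesign(**base)


def test_genome_generation_is_deterministic():
    a1, t1 = generate_genomes(default_archetypes(), seed=5)
    a2, t2 = generate_genomes(default_archetypes(), seed=5)
    pd.testing.assert_frame_equal(a1, a2)
    assert t1 == t2
    a3, _ = generate_genomes(default_archetypes(), seed=6)
    assert not a1.equals(a3)


def test_genome_coordinates_valid(genome_fixture):
    annotation, _ = genome_fixture
    for _, grp in annotation.groupby(["genome_id", "replicon_id"]):
        grp = grp.sort_values("start")
        assert (grp["start"] >= 1).all()
        assert (grp["end"] >= grp["start"]).all()
        # strictly increasing, non-overlapping
        assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()


def test_empty_archetype_yields_only_decoys():
    arch = GenomeArchetype(name="empty", present_families=(), decoy_gene_count=5)
    annotation, truth = generate_genomes([arch], seed=1)
    assert len(annotation) == 5
    assert (annotation["gene_label"] == "").all()
    assert truth["empty"]["clusters"] == []


def test_clustered_gene_must_be_present():
    with pytest.raises(ValueError, match="missing from"):
        GenomeArchetype(
            name="bad", present_families=("cbiX",), clusters=(("cbiX", "cbiG"),)
        )


def test_seed_is_mandatory(tmp_path):
    with pytest.raises(ValueError, match="seed"):
        generate_genomes(default_archetypes(), seed=None)
    with pytest.raises(ValueError, match="seed"):
        generate_metagenome_hits(_small_design(), seed=None, outdir=tmp_path)


def test_design_validation_rejects_bad_inputs():
    with pytest.raises(ValueError, match="p_wrong"):
        _small_design(p_wrong=1.5).validate()
    with pytest.raises(ValueError, match="unknown covariate"):
        _small_design(
            links={"Thaumarchaeota": {"salinity": 1.0}}
        ).validate()
    with pytest.raises(ValueError, match="non-finite"):
        _small_design(
            links={"Thaumarchaeota": {"depth": float("nan")}}
        ).validate()


def test_metagenome_bundle_is_byte_identical_across_runs(tmp_path):
    d = _small_design()
    b1 = generate_metagenome_hits(d, seed=9, outdir=tmp_path / "a")
    b2 = generate_metagenome_hits(d, seed=9, outdir=tmp_path / "b")
    for sid in b1.hmm_paths:
        assert b1.hmm_paths[sid].read_bytes() == b2.hmm_paths[sid].read_bytes()
        assert b1.blast_paths[sid].read_bytes() == b2.blast_paths[sid].read_bytes()
    assert b1.metadata_path.read_bytes() == b2.metadata_path.read_bytes()
    assert b1.truth_path.read_bytes() == b2.truth_path.read_bytes()


def test_allocations_sum_to_per_gene_totals(tmp_path):
    bundle = generate_metagenome_hits(_small_design(), seed=2, outdir=tmp_path)
    for truth in bundle.truths:
        per_gene = {}
        for o in truth.orfs:
            per_gene[o.gene_label] = per_gene.get(o.gene_label, 0) + 1
        for g, total in truth.total_hits_per_gene.items():
            assert per_gene.get(g, 0) == total
        p = truth.true_proportions
        assert math.isclose(sum(p.values()), 1.0, abs_tol=1e-9)


def test_misassignment_rate_matches_p_wrong(tmp_path):
    p_wrong = 0.1
    design = _small_design(
        n_samples=1,
        per_gene_means={"cbiA_cobB": 6000.0, "cobS": 6000.0},
        p_wrong=p_wrong,
    )
    bundle = generate_metagenome_hits(design, seed=13, outdir=tmp_path)
    orfs = [o for t in bundle.truths for o in t.orfs if o.blast_taxon != "Unclassified"]
    assert len(orfs) >= 10_000
    wrong = sum(o.blast_taxon != o.taxon for o in orfs)
    rate = wrong / len(orfs)
    se = math.sqrt(p_wrong * (1 - p_wrong) / len(orfs))
    assert abs(rate - p_wrong) < 3 * se


def test_either_or_pair_anticorrelated_in_truth(demo):
    """Brute-force Pearson on the planted proportions of the mutually
    exclusive pair is negative."""
    t = np.array([s.true_proportions["Thaumarchaeota"] for s in demo.bundle.truths])
    c = np.array([s.true_proportions["Cyanobacteria"] for s in demo.bundle.truths])
    r = np.corrcoef(t, c)[0, 1]
    assert r < 0


def test_depth_link_recovered_against_truth_oracle(tmp_path):
    """A monotone depth effect planted through the softmax-over-taxa link is
    recovered from the generated counts within 0.1 of the Pearson r computed
    directly on the truth proportions."""
    design = SamplingDesign(
        n_samples=200,
        taxa=("Thaumarchaeota", "Proteobacteria", "Cyanobacteria"),
        links={"Thaumarchaeota": {"depth": 2.0}, "Cyanobacteria": {"depth": -1.0}},
        per_gene_means={"cbiA_cobB": 30.0, "cobS": 30.0},
    )
    bundle = generate_metagenome_hits(design, seed=21, outdir=tmp_path)
    depth = np.array([t.covariates["depth"] for t in bundle.truths])
    truth_p = np.array(
        [t.true_proportions["Thaumarchaeota"] for t in bundle.truths]
    )
    observed = np.array(
        [
            t.expected_table_counts().get("Thaumarchaeota", 0)
            / max(sum(t.expected_table_counts().values()), 1)
            for t in bundle.truths
        ]
    )
    r_oracle = np.corrcoef(depth, truth_p)[0, 1]
    r_recovered = np.corrcoef(depth, observed)[0, 1]
    assert r_oracle > 0.5  # the link is genuinely monotone and strong
    assert abs(r_recovered - r_oracle) < 0.1


def test_undersampled_samples_stay_below_threshold(demo):
    truths = demo.bundle.truths
    totals = [sum(t.total_hits_per_gene.values()) for t in truths]
    assert sum(total < 10 for total in totals) == 2
    # and they are the designated trailing samples
    assert totals[-1] < 10 and totals[-2] < 10


def test_orf_ids_encode_only_sample_and_serial(noiseless_bundle):
    for truth in noiseless_bundle.truths:
        for o in truth.orfs:
            sid, serial = o.orf_id.rsplit("_orf", maxsplit=1)
            assert sid == truth.sample_id
            assert serial.isdigit()
            assert o.taxon not in o.orf_id


def test_taxonomy_index_covers_reference_taxa():
    index = default_taxonomy_index()
    assert index.name_at_rank("S0001", "phylum") == "Thaumarchaeota"
    assert index.name_at_rank("S0006", "phylum") == "Proteobacteria"
    assert (
        index.name_at_rank("S0006", "phylum", split_proteobacteria=True)
        == "Gammaproteobacteria"
    )
    assert index.name_at_rank("NOPE", "phylum") == "Unclassified"


def test_planted_correlation_is_exact():
    metadata, counts, truth = planted_correlation_counts(
        seed=5, r_true=0.5, n_samples=100, hits_per_sample=300
    )
    x = metadata["depth"].to_numpy()
    r = np.corrcoef(x, truth.to_numpy())[0, 1]
    assert abs(r - 0.5) < 1e-12
    assert counts.to_numpy().sum(axis=1).min() == 300
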