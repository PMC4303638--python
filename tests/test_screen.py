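import pytest

from cobscreen.screen import (
    BlastHit,
    HmmHit,
    ScreenParseError,
    TaxonomyIndex,
    assign_taxonomy,
    best_family_per_orf,
    build_hit_table,
    filter_hits,
    parse_blast_outfmt6,
    parse_hmm_domtblout,
    parse_hmm_tblout,
)

TBLOUT = """# comment line
# another
orf1 - cbiA_cobB TIGR00379 1e-20 88.1 0.1 1e-20 88.1 0.1 1.0 1 0 0 1 1 1 1 -
orf2 - cbiC_cobH PF02570.10 3.5e-08 41.0 0.0 3.5e-08 41.0 0.0 1.0 1 0 0 1 1 1 1 -
orf3 - cobS TIGR00317 2e-03 12.2 0.0 2e-03 12.2 0.0 1.0 1 0 0 1 1 1 1 -
"""


def test_tblout_parsing(tmp_path):
    path = tmp_path / "s.tblout"
    path.write_text(TBLOUT)
    hits = parse_hmm_tblout(path, sample_id="s")
    assert len(hits) == 3
    assert hits[0].evalue == 1e-20
    assert hits[0].family_accession == "TIGR00379"
    assert hits[1].family_accession == "PF02570.10"
    assert hits[2].bitscore == 12.2


def test_tblout_accession_fallback_to_query_name(tmp_path):
    path = tmp_path / "s.tblout"
    path.write_text(
        "orf1 - TIGR00379 - 1e-20 88.1 0.1 1e-20 88.1 0.1 1.0 1 0 0 1 1 1 1 -\n"
    )
    (hit,) = parse_hmm_tblout(path)
    assert hit.family_accession == "TIGR00379"


def test_tblout_parse_error_names_line(tmp_path):
    path = tmp_path / "bad.tblout"
    path.write_text(
        "orf1 - g TIGR00379 1e-20 88.1 0.1 1e-20 88.1 0.1 1.0 1 0 0 1 1 1 1 -\n"
        "orf2 - g TIGR00379 oops 88.1 0.1 1e-20 88.1 0.1 1.0 1 0 0 1 1 1 1 -\n"
    )
    with pytest.raises(ScreenParseError, match=r":2"):
        parse_hmm_tblout(path)


def test_domtblout_dialect(tmp_path):
    path = tmp_path / "s.domtblout"
    path.write_text(
        "orf1 - 210 cbiA_cobB TIGR00379 310 4.2e-19 85.0 0.1 1 1 "
        "5e-20 4.8e-19 84.1 0.1 3 300 5 205 4 206 0.9 -\n"
    )
    (hit,) = parse_hmm_domtblout(path)
    assert hit.family_accession == "TIGR00379"
    assert hit.evalue == 4.2e-19


def test_filter_boundary_inclusive():
    hits = [
        HmmHit(f"o{i}", "TIGR00379", e, 10.0) for i, e in enumerate([1e-7, 1e-6, 1e-5])
    ]
    kept = filter_hits(hits)
    assert [h.evalue for h in kept] == [1e-7, 1e-6]
    assert filter_hits([]) == []
    low = [HmmHit("o", "TIGR00379", 1e-30, 5.0)]
    assert filter_hits(low) == low


def test_best_family_resolution(catalog):
    # smaller E-value wins
    hits = [
        HmmHit("orf", "TIGR00379", 1e-10, 50.0),
        HmmHit("orf", "TIGR00380", 1e-8, 80.0),
    ]
    assert best_family_per_orf(hits, catalog) == {"orf": "cbiA_cobB"}
    # exact tie -> lexicographically smallest accession (PF02570 < TIGR00313)
    tie = [
        HmmHit("orf", "TIGR00313", 1e-9, 44.0),
        HmmHit("orf", "PF02570.10", 1e-9, 44.0),
    ]
    assert best_family_per_orf(tie, catalog) == {"orf": "cbiC_cobH"}
    # non-catalog accessions dropped entirely
    assert best_family_per_orf([HmmHit("orf", "PF99999", 1e-30, 99.0)], catalog) == {}


@pytest.fixture()
def index():
    return TaxonomyIndex(
        {
            "s1": ("Archaea", "Thaumarchaeota", "Nitrososphaeria"),
            "s2": ("Bacteria", "Proteobacteria", "Alphaproteobacteria"),
            "s3": ("Bacteria",),
        }
    )


def test_assign_taxonomy_top_hit(index):
    hits = [
        BlastHit("o", "s2", 1e-5, 60.0, 0),
        BlastHit("o", "s1", 1e-20, 90.0, 1),
    ]
    assert assign_taxonomy(hits, index, rank="phylum") == "Thaumarchaeota"
    # nothing under threshold
    assert assign_taxonomy([BlastHit("o", "s1", 1e-5, 60.0, 0)], index) == "Unclassified"
    # tie on evalue and bitscore -> earliest file position
    tie = [
        BlastHit("o", "s2", 1e-9, 60.0, 0),
        BlastHit("o", "s1", 1e-9, 60.0, 1),
    ]
    assert assign_taxonomy(tie, index) == "Proteobacteria"
    # unknown subject and truncated lineage are Unclassified
    assert assign_taxonomy([BlastHit("o", "zz", 1e-9, 60.0, 0)], index) == "Unclassified"
    assert assign_taxonomy([BlastHit("o", "s3", 1e-9, 60.0, 0)], index) == "Unclassified"


def test_taxonomy_index_roundtrip(tmp_path, index):
    path = tmp_path / "tax.tsv"
    index.to_tsv(path)
    again = TaxonomyIndex.from_tsv(path)
    assert again.lineage("s1") == index.lineage("s1")
    assert len(again) == len(index)


def test_blast_parser_records_file_rank(tmp_path):
    path = tmp_path / "b.tsv"
    path.write_text(
        "o1\ts1\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-30\t120.0\n"
        "o1\ts2\t80.0\t100\t20\t0\t1\t100\t1\t100\t1e-10\t80.0\n"
    )
    hits = parse_blast_outfmt6(path)
    assert [h.file_rank for h in hits] == [0, 1]
    assert hits[0].subject_id == "s1"


def test_noiseless_sample_counts_equal_truth(noiseless_bundle, catalog):
    """With no decoy E-values, no misassignment and no unclassifiable ORFs,
    the screening pipeline reproduces the generator's allocations exactly."""
    from cobscreen.screen import TaxonomyIndex

    index = TaxonomyIndex.from_tsv(noiseless_bundle.taxonomy_path)
    for truth in noiseless_bundle.truths:
        table = build_hit_table(
            truth.sample_id,
            noiseless_bundle.hmm_paths[truth.sample_id],
            noiseless_bundle.blast_paths[truth.sample_id],
            catalog,
            index,
        )
        # full recall: every generated ORF survives
        assert len(table) == len(truth.orfs)
        observed = table.rows.groupby("taxon_label").size().to_dict()
        assert observed == truth.allocated_counts()


def test_parsed_hits_match_generator_truth(noiseless_bundle, catalog):
    for truth in noiseless_bundle.truths:
        hits = parse_hmm_tblout(
            noiseless_bundle.hmm_paths[truth.sample_id], truth.sample_id
        )
        parsed = {
            (h.orf_id, catalog.gene_label(h.family_accession), h.evalue) for h in hits
        }
        expected = {(o.orf_id, o.gene_label, o.evalue) for o in truth.orfs}
        assert parsed == expected


def test_all_superthreshold_sample_is_empty(tmp_path, catalog, index):
    path = tmp_path / "s.tblout"
    path.write_text(
        "orf1 - cbiA_cobB TIGR00379 1e-3 8.0 0.1 1e-3 8.0 0.1 1.0 1 0 0 1 1 1 1 -\n"
    )
    blast = tmp_path / "s.blast"
    blast.write_text("")
    table = build_hit_table("s", path, blast, catalog, index)
    assert len(table) == 0


def test_hit_table_export_deterministic(tmp_path, noiseless_bundle, catalog):
    index = TaxonomyIndex.from_tsv(noiseless_bundle.taxonomy_path)
    truth = noiseless_bundle.truths[0]
    args = (
        truth.sample_id,
        noiseless_bundle.hmm_paths[truth.sample_id],
        noiseless_bundle.blast_paths[truth.sample_id],
        catalog,
        index,
    )
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    build_hit_table(*args).to_tsv(p1)
    build_hit_table(*args).to_tsv(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_missing_blast_evidence_is_unclassified(tmp_path, catalog, index):
    path = tmp_path / "s.tblout"
    path.write_text(
        "orf9 - cbiA_cobB TIGR00379 1e-20 80.0 0.1 1e-20 80.0 0.1 1.0 1 0 0 1 1 1 1 -\n"
    )
    blast = tmp_path / "s.blast"
    blast.write_text("")
    table = build_hit_table("s", path, blast, catalog, index)
    assert list(table.rows["taxon_label"]) == ["Unclassified"]
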