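import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cobscreen.contribution import INSUFFICIENT, profile_from_counts
from cobscreen.correlate import (
    grouped_analysis,
    pearson,
    taxon_metadata_matrix,
    taxon_vs_taxon,
)
from cobscreen.simulate import planted_correlation_counts


def test_pearson_exact_lines():
    assert pearson([1, 2, 3], [2, 4, 6], min_pairs=3) == pytest.approx(1.0)
    assert pearson([1, 2, 3], [3, 2, 1], min_pairs=3) == pytest.approx(-1.0)


def test_pearson_matches_closed_form():
    rng = np.random.default_rng(2)
    for _ in range(200):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert abs(r - oracle) < 1e-12


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(min_value=0.1, max_value=100),
    b=st.floats(min_value=-100, max_value=100),
)
def test_pearson_affine_invariance(a, b):
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r = pearson(x, y)
    assert pearson(a * x + b, y) == pytest.approx(r, abs=1e-9)
    assert pearson(-a * x + b, y) == pytest.approx(-r, abs=1e-9)


def test_pearson_insufficient_cases():
    assert pearson([1, 2, 3], [1, 2, 3], min_pairs=5) == INSUFFICIENT
    assert pearson([1.0] * 10, list(range(10))) == INSUFFICIENT
    # pairwise-complete: NaNs drop pairs
    x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
    y = [2.0, 4.0, 6.0, 8.0, np.nan, 12.0]
    assert pearson(x, y, min_pairs=4) == pytest.approx(1.0)
    assert pearson(x, y, min_pairs=5) == INSUFFICIENT


def test_planted_depth_link_sign_and_magnitude():
    metadata, counts, _ = planted_correlation_counts(
        seed=5, r_true=0.6, n_samples=200, hits_per_sample=400
    )
    profile = profile_from_counts(counts)
    result = taxon_metadata_matrix(profile, metadata.reset_index(), r_report=0.25)
    row = result.table.query("x_name == 'depth' and y_name == 'Thaumarchaeota'")
    assert len(row) == 1
    r = float(row["r"].iloc[0])
    assert r > 0
    assert abs(r - 0.6) < 0.1


def test_constant_metadata_column_omitted():
    metadata, counts, _ = planted_correlation_counts(seed=1, n_samples=50, r_true=0.4)
    metadata = metadata.copy()
    metadata["flat"] = 3.14
    profile = profile_from_counts(counts)
    result = taxon_metadata_matrix(profile, metadata.reset_index())
    assert "flat" not in set(result.table["x_name"])


def test_report_filter_at_zero_equals_full_table():
    metadata, counts, _ = planted_correlation_counts(seed=2, n_samples=60, r_true=0.4)
    profile = profile_from_counts(counts)
    result = taxon_metadata_matrix(profile, metadata.reset_index(), r_report=0.0)
    nonzero = result.table[result.table["r"] != 0.0]
    pd.testing.assert_frame_equal(
        result.report().reset_index(drop=True), nonzero.reset_index(drop=True)
    )


def test_month_cosine_encoding_added():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(
        rng.integers(10, 100, size=(24, 2)),
        index=[f"s{i}" for i in range(24)],
        columns=["T", "P"],
    )
    metadata = pd.DataFrame(
        {"sample_id": counts.index, "month": list(range(1, 13)) * 2}
    )
    result = taxon_metadata_matrix(profile_from_counts(counts), metadata)
    assert {"month", "month_cos"} <= set(result.table["x_name"])


def test_complementary_taxa_perfectly_anticorrelated():
    rng = np.random.default_rng(0)
    a = rng.integers(10, 90, size=30)
    counts = pd.DataFrame({"A": a, "B": 100 - a}, index=[f"s{i}" for i in range(30)])
    result = taxon_vs_taxon(profile_from_counts(counts))
    row = result.table.query("x_name == 'A' and y_name == 'B'")
    assert float(row["r"].iloc[0]) == pytest.approx(-1.0)


def test_either_or_pair_negative_downstream(demo):
    """The planted mutually exclusive pair comes out negatively correlated
    in the pipeline's own taxon-vs-taxon view."""
    from cobscreen.contribution import build_profile
    from cobscreen.screen import TaxonomyIndex, build_hit_table
    from cobscreen.catalog import default_catalog

    catalog = default_catalog()
    bundle = demo.bundle
    index = TaxonomyIndex.from_tsv(bundle.taxonomy_path)
    tables = [
        build_hit_table(
            t.sample_id,
            bundle.hmm_paths[t.sample_id],
            bundle.blast_paths[t.sample_id],
            catalog,
            index,
        )
        for t in bundle.truths
    ]
    profile = build_profile(tables, catalog, "cobalamin")
    result = taxon_vs_taxon(profile)
    row = result.table.query(
        "x_name == 'Cyanobacteria' and y_name == 'Thaumarchaeota'"
    )
    assert float(row["r"].iloc[0]) < 0


def test_independent_minor_taxa_within_permutation_band():
    """Two minor taxa driven by independent latent signals (the closure
    constraint couples large shares unavoidably, so independence is only
    observable for small ones): their |r| stays within the upper tail of
    the permutation null."""
    rng = np.random.default_rng(12)
    n = 500
    wa = 0.05 * np.exp(0.5 * rng.normal(size=n))
    wc = 0.05 * np.exp(0.5 * rng.normal(size=n))
    weights = np.column_stack(
        [wa, np.full(n, 0.3), wc, np.full(n, 0.3), np.full(n, 0.3)]
    )
    p = weights / weights.sum(axis=1, keepdims=True)
    counts = pd.DataFrame(
        np.array([rng.multinomial(300, row) for row in p]),
        index=[f"s{i}" for i in range(n)],
        columns=list("ABCDE"),
    )
    D = profile_from_counts(counts).D
    x, y = D["A"].to_numpy(), D["C"].to_numpy()
    observed = abs(pearson(x, y))
    null = [abs(pearson(x, rng.permutation(y))) for _ in range(199)]
    assert observed <= np.quantile(null, 0.995) + 0.05


def test_grouped_analysis_identical_studies_agree():
    metadata, counts, _ = planted_correlation_counts(seed=9, n_samples=80, r_true=0.5)
    meta = metadata.reset_index()
    meta["study"] = ["one"] * 40 + ["two"] * 40
    # make the two studies literally identical
    counts.iloc[40:] = counts.iloc[:40].to_numpy()
    meta.loc[40:, "depth"] = meta.loc[:39, "depth"].to_numpy()
    profile = profile_from_counts(counts)
    per_study = grouped_analysis(profile, meta)
    assert set(per_study) == {"one", "two"}
    pd.testing.assert_frame_equal(
        per_study["one"].table, per_study["two"].table
    )


def test_grouped_analysis_skips_small_groups(caplog):
    metadata, counts, _ = planted_correlation_counts(seed=4, n_samples=20, r_true=0.5)
    meta = metadata.reset_index()
    meta["study"] = ["big"] * 17 + ["tiny"] * 3
    profile = profile_from_counts(counts)
    with caplog.at_level("INFO"):
        per_study = grouped_analysis(profile, meta)
    assert set(per_study) == {"big"}
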