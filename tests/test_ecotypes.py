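import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cobscreen.contribution import profile_from_counts
from cobscreen.ecotypes import (
    assign_ecotypes,
    cut_clusters,
    label_ecotype,
    manhattan_distance_matrix,
    to_newick,
    ward_linkage,
)


def ward_d_reference(dist):
    """Naive O(n^3) Lance-Williams ward.D agglomeration (independent of the
    package implementation): merge the closest pair, update distances with
    d(k, ij) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)] / (n_i+n_j+n_k).
    """
    n = dist.shape[0]
    active = {i: 1 for i in range(n)}  # id -> size
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = active[i], active[j]
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k]
            dki = d[tuple(sorted((k, i)))]
            dkj = d[tuple(sorted((k, j)))]
            dij = h
            d[tuple(sorted((k, new)))] = (
                (ni + nk) * dki + (nj + nk) * dkj - nk * dij
            ) / (ni + nj + nk)
        for k in list(d):
            if i in k or j in k:
                del d[k]
        del active[i], active[j]
        active[new] = ni + nj
        merges.append((i, j, h))
    return merges


def _random_profile(n, t, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(10, 200, size=(n, t))
    return profile_from_counts(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n)],
            columns=[f"T{j}" for j in range(t)],
        )
    )


def test_manhattan_examples():
    D = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]], index=list("abc"))
    dist = manhattan_distance_matrix(D)
    assert dist.loc["a", "b"] == pytest.approx(2.0)
    assert dist.loc["a", "c"] == 0.0
    assert np.allclose(dist, dist.T)
    assert np.diag(dist).sum() == 0.0


def test_manhattan_matches_bruteforce():
    profile = _random_profile(10, 4, seed=4)
    D = profile.D
    dist = manhattan_distance_matrix(profile)
    for i in D.index:
        for j in D.index:
            brute = float(np.abs(D.loc[i] - D.loc[j]).sum())
            assert abs(dist.loc[i, j] - brute) < 1e-12


def test_manhattan_needs_two_samples():
    D = pd.DataFrame([[1.0, 0.0]], index=["a"])
    with pytest.raises(ValueError, match=">= 2"):
        manhattan_distance_matrix(D)


def test_ward_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_two_points_merge_at_their_distance():
    dend = ward_linkage(np.array([[0.0, 3.0], [3.0, 0.0]]))
    assert dend.merges.shape[0] == 1
    assert dend.merges[0, 2] == pytest.approx(3.0)


def test_separated_pairs_merge_first():
    # two tight pairs far apart
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    dist = np.abs(pts[:, None] - pts[None, :])
    dend = ward_linkage(dist)
    first_two = {frozenset(map(int, row[:2])) for row in dend.merges[:2]}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_ward_matches_reference_lance_williams(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    X = rng.random((n, 3))
    dist = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
    dend = ward_linkage(dist, variant="ward.D")
    ref = ward_d_reference(dist)
    for row, (i, j, h) in zip(dend.merges, ref):
        assert {int(row[0]), int(row[1])} == {i, j}
        assert row[2] == pytest.approx(h, rel=1e-9)


def test_cut_extremes_and_range():
    profile = _random_profile(8, 3, seed=7)
    dist = manhattan_distance_matrix(profile)
    dend = ward_linkage(dist)
    assert len(np.unique(cut_clusters(dend, k=1))) == 1
    assert len(np.unique(cut_clusters(dend, k=8))) == 8
    with pytest.raises(ValueError, match="within"):
        cut_clusters(dend, k=9)


def test_auto_k_recovers_planted_ecotypes(tmp_path, catalog):
    from cobscreen.contribution import build_profile
    from cobscreen.screen import TaxonomyIndex, build_hit_table
    from cobscreen.simulate import ecotype_design, generate_metagenome_hits

    bundle = generate_metagenome_hits(
        ecotype_design(n_per_ecotype=12), seed=31, outdir=tmp_path
    )
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
    assignments, _ = assign_ecotypes(profile, k="auto")
    truth_labels = {t.sample_id: t.ecotype for t in bundle.truths}
    truth = [truth_labels[s] for s in assignments["sample_id"]]
    assert adjusted_rand_score(truth, assignments["cluster_id"]) == pytest.approx(1.0)
    assert assignments["cluster_id"].nunique() == 3


def test_partition_robust_to_sample_order():
    profile = _random_profile(20, 4, seed=9)
    dist = manhattan_distance_matrix(profile)
    ids = cut_clusters(ward_linkage(dist), k=3)
    perm = np.random.default_rng(1).permutation(20)
    shuffled = profile_from_counts(profile.counts.iloc[perm])
    dist2 = manhattan_distance_matrix(shuffled)
    ids2 = cut_clusters(ward_linkage(dist2), k=3)
    # align by sample id and compare partitions up to relabeling
    order = {s: i for i, s in enumerate(shuffled.samples)}
    ids2_aligned = [ids2[order[s]] for s in profile.samples]
    assert adjusted_rand_score(ids, ids2_aligned) == pytest.approx(1.0)


def test_ecotype_labels():
    taxa = ["Thaumarchaeota", "Proteobacteria", "Cyanobacteria", "Bacteroidetes"]
    dominant = pd.DataFrame([[0.8, 0.15, 0.03, 0.02]], columns=taxa)
    assert label_ecotype(dominant) == "T"
    co = pd.DataFrame([[0.05, 0.45, 0.35, 0.15]], columns=taxa)
    assert label_ecotype(co) == "P+C"
    flat = pd.DataFrame([[0.24, 0.24, 0.24, 0.28]], columns=taxa)
    assert label_ecotype(flat, co_dominance=0.30) == "mixed"
    # unmapped taxon falls back to its first letter
    bact = pd.DataFrame([[0.1, 0.2, 0.1, 0.6]], columns=taxa)
    assert label_ecotype(bact) == "B"


def test_newick_export_parses_with_dendropy():
    import dendropy

    profile = _random_profile(6, 3, seed=5)
    dend = ward_linkage(manhattan_distance_matrix(profile))
    tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
    assert len(tree.leaf_nodes()) == 6
    leaf_labels = {l.taxon.label for l in tree.leaf_nodes()}
    assert leaf_labels == set(profile.samples)
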