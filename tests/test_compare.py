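"""Cross-virome comparison: mapping fractions, presence/absence profiles,
Bray-Curtis identities, and agglomerative clustering."""

import numpy as np
import pytest

from viromenet.assignment import UNKNOWN, ContigAnnotation
from viromenet.compare import (
    DissimilarityMatrix,
    ViromeProfile,
    bray_curtis,
    cluster_viromes,
    cross_mapping_matrix,
    pairwise_bray_curtis,
    presence_absence,
    profiles_to_frame,
)


# ---------------------------------------------------------------------------
# cross-mapping
# ---------------------------------------------------------------------------

def _reads_from(contigs, n, rl, rng):
    reads = []
    keys = sorted(contigs)
    for i in range(n):
        cid = keys[rng.integers(0, len(keys))]
        seq = contigs[cid]
        start = int(rng.integers(0, len(seq) - rl + 1))
        reads.append((f"r{i}", seq[start : start + rl]))
    return reads


def test_cross_mapping_closure_and_disjoint(rng):
    set_a = {f"a{i}": "".join(rng.choice(list("ACGT"), 800)) for i in range(3)}
    set_b = {f"b{i}": "".join(rng.choice(list("ACGT"), 800)) for i in range(3)}
    reads_a = _reads_from(set_a, 300, 100, rng)
    mat = cross_mapping_matrix({"A": reads_a}, {"A": set_a, "B": set_b})
    assert mat.loc["A", "A"] == 1.0  # reads generated within own contigs
    assert mat.loc["A", "B"] == 0.0  # no shared read-length substring


def test_cross_mapping_mixture_recovers_half(rng):
    set_a = {f"a{i}": "".join(rng.choice(list("ACGT"), 2000)) for i in range(2)}
    set_b = {f"b{i}": "".join(rng.choice(list("ACGT"), 2000)) for i in range(2)}
    n = 4000
    mixed = _reads_from(set_a, n // 2, 120, rng) + _reads_from(set_b, n // 2, 120, rng)
    mat = cross_mapping_matrix({"mix": mixed}, {"A": set_a})
    se = np.sqrt(0.25 / n)
    assert abs(mat.loc["mix", "A"] - 0.5) < 3 * se


def test_cross_mapping_is_directional_not_symmetrized(rng):
    # contigs of B contain A's contigs as substrings but not vice versa, so
    # A-reads map to B while B-reads largely fail on A
    core = "".join(rng.choice(list("ACGT"), 1000))
    set_a = {"a0": core}
    set_b = {"b0": "".join(rng.choice(list("ACGT"), 1000)) + core}
    reads_a = _reads_from(set_a, 200, 100, rng)
    reads_b = _reads_from(set_b, 200, 100, rng)
    mat = cross_mapping_matrix({"A": reads_a, "B": reads_b}, {"A": set_a, "B": set_b})
    assert mat.loc["A", "B"] == 1.0
    assert mat.loc["B", "A"] < 1.0


def test_empty_read_set_reported_missing(rng):
    set_a = {"a0": "".join(rng.choice(list("ACGT"), 500))}
    with pytest.warns(UserWarning):
        mat = cross_mapping_matrix({"A": [], "B": _reads_from(set_a, 10, 100, rng)},
                                   {"A": set_a})
    assert np.isnan(mat.loc["A", "A"])
    assert mat.loc["B", "A"] == 1.0


# ---------------------------------------------------------------------------
# presence/absence
# ---------------------------------------------------------------------------

def test_presence_absence_rank_filter_and_dedup(taxonomy):
    annotations = {
        "v1": {
            "c1": ContigAnnotation("gokuv_s1", "direct"),
            "c2": ContigAnnotation("gokuv_s1", "propagated"),
            "c3": ContigAnnotation("caudo", "direct"),  # above species: excluded
            "c4": ContigAnnotation(UNKNOWN, "none"),
        },
        "v2": {},
    }
    profiles = presence_absence(annotations, taxonomy, rank="species")
    by_id = {p.virome_id: p.species_present for p in profiles}
    assert by_id["v1"] == {"gokuv_s1"}
    assert by_id["v2"] == frozenset()


def test_presence_absence_matches_lineage_scan(rng, taxonomy):
    taxa = sorted(taxonomy.nodes)
    ann = {
        f"c{i}": ContigAnnotation(taxa[rng.integers(0, len(taxa))], "direct")
        for i in range(60)
    }
    (profile,) = presence_absence({"v": ann}, taxonomy, rank="family")
    expected = {
        a.taxon_id for a in ann.values() if taxonomy.rank(a.taxon_id) == "family"
    }
    assert profile.species_present == expected


def test_profiles_frame_export(taxonomy):
    profiles = [ViromeProfile("v1", frozenset({"gokuv_s1", "circv_s1"}))]
    frame = profiles_to_frame(profiles)
    assert list(frame["taxon_id"]) == ["circv_s1", "gokuv_s1"]


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_identities():
    p = [ViromeProfile("a", frozenset({"x", "y"})), ViromeProfile("b", frozenset({"x", "y"}))]
    assert bray_curtis(p).values[0, 1] == 0.0  # identical -> 0
    q = [ViromeProfile("a", frozenset({"x"})), ViromeProfile("b", frozenset({"y"}))]
    assert bray_curtis(q).values[0, 1] == 1.0  # disjoint -> 1
    # a=2 shared, b=1, c=1 -> 2/6
    r = [ViromeProfile("a", frozenset({"s1", "s2", "s3"})),
         ViromeProfile("b", frozenset({"s1", "s2", "s4"}))]
    assert bray_curtis(r).values[0, 1] == pytest.approx(1 / 3)


def test_bray_curtis_below_one_when_any_species_shared(rng):
    for _ in range(50):
        universe = [f"s{i}" for i in range(20)]
        x = {s for s in universe if rng.random() < 0.4}
        y = {s for s in universe if rng.random() < 0.4}
        d = pairwise_bray_curtis(x, y)
        if x & y:
            assert d < 1.0
        assert 0.0 <= d <= 1.0


def test_bray_curtis_equals_sorensen_and_scipy(rng):
    """Independent routes: the Sorensen formula 1 - 2a/(|X|+|Y|) and
    scipy's braycurtis on 0/1 vectors."""
    from scipy.spatial.distance import braycurtis

    universe = [f"s{i}" for i in range(30)]
    for _ in range(100):
        x = {s for s in universe if rng.random() < 0.5}
        y = {s for s in universe if rng.random() < 0.5}
        if not x and not y:
            continue
        d = pairwise_bray_curtis(x, y)
        sorensen = 1 - 2 * len(x & y) / (len(x) + len(y))
        assert d == pytest.approx(sorensen)
        vx = np.array([s in x for s in universe], dtype=float)
        vy = np.array([s in y for s in universe], dtype=float)
        assert d == pytest.approx(braycurtis(vx, vy))


def test_both_empty_profiles_give_zero_with_warning():
    p = [ViromeProfile("a", frozenset()), ViromeProfile("b", frozenset())]
    with pytest.warns(UserWarning):
        mat = bray_curtis(p)
    assert mat.values[0, 1] == 0.0
    with pytest.raises(ValueError):
        bray_curtis(p[:1])


def test_matrix_validation():
    with pytest.raises(ValueError):
        DissimilarityMatrix(("a", "b"), np.array([[0.0, 0.3], [0.4, 0.0]]))
    with pytest.raises(ValueError):
        DissimilarityMatrix(("a", "b"), np.array([[0.1, 0.3], [0.3, 0.0]]))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _matrix(ids, entries):
    n = len(ids)
    v = np.zeros((n, n))
    for (i, j), d in entries.items():
        v[i, j] = v[j, i] = d
    return DissimilarityMatrix(tuple(ids), v)


def test_first_merge_is_minimum_distance_pair():
    mat = _matrix(["A", "B", "C"], {(0, 1): 0.2, (0, 2): 0.9, (1, 2): 0.9})
    newick, merges = cluster_viromes(mat)
    assert merges[0]["members"] == ["A", "B"]
    assert merges[0]["height"] == pytest.approx(0.2)
    # remaining leaf C joins the {A,B} cluster at its own height 0.9
    assert newick == "(C:0.9,(A:0.2,B:0.2):0.7);"


def test_two_virome_dendrogram():
    mat = _matrix(["GS", "SS"], {(0, 1): 0.3})
    newick, merges = cluster_viromes(mat)
    assert len(merges) == 1
    assert newick == "(GS:0.3,SS:0.3);"


def test_newick_readable_with_correct_leaves():
    import dendropy

    mat = _matrix(["v1", "v2", "v3", "v4"],
                  {(0, 1): 0.1, (0, 2): 0.5, (0, 3): 0.8, (1, 2): 0.6,
                   (1, 3): 0.7, (2, 3): 0.2})
    newick, _ = cluster_viromes(mat)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"v1", "v2", "v3", "v4"}


@pytest.mark.parametrize("linkage", ["complete", "single", "average"])
def test_merges_match_scipy_linkage(rng, linkage):
    """Independent oracle: scipy's hierarchical clustering on random
    continuous dissimilarities (ties have probability zero)."""
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    for _ in range(20):
        n = int(rng.integers(3, 9))
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.uniform(0.05, 1.0, len(iu[0]))
        v = v + v.T
        mat = DissimilarityMatrix(tuple(f"v{i}" for i in range(n)), v)
        _, merges = cluster_viromes(mat, linkage=linkage)
        z = scipy_linkage(squareform(v), method=linkage)
        assert [m["height"] for m in merges] == pytest.approx(list(z[:, 2]))
        # merged leaf sets agree step by step
        scipy_members = {i: {i} for i in range(n)}
        for step, row in enumerate(z):
            a, b = int(row[0]), int(row[1])
            scipy_members[n + step] = scipy_members[a] | scipy_members[b]
            got = {int(m[1:]) for m in merges[step]["members"]}
            assert got == scipy_members[n + step]


def test_cluster_requires_valid_input():
    mat = _matrix(["a", "b"], {(0, 1): 0.5})
    with pytest.raises(ValueError):
        cluster_viromes(mat, linkage="ward")
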