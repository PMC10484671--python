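"""Distances, complete-linkage trees, threshold cuts, ASC naming.

The independent oracle used here recomputes everything from scratch:
a textbook dynamic-programming Levenshtein and a direct agglomeration that
repeatedly merges the closest cluster pair (max-linkage over raw distances,
ties by smallest leaf pair).  It shares no code with the package path.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ascgenotype import (
    ASCReference,
    AscGenotypeError,
    DistanceMatrix,
    KeyTable,
    assign_asc_names,
    build_tree,
    cluster_reference,
    compare_clusterings,
    cut_tree,
    evaluate_cut_thresholds,
    normalized_levenshtein,
    pairwise_distances,
    translate_call,
)
from ascgenotype.errors import TranslationError

from conftest import make_ref


# ---------------------------------------------------------------- oracles

def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(nm) edit-distance table."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_partition(seqs: list[str], similarity: float) -> list[set[int]]:
    """Complete-linkage agglomeration run directly on raw distances.

    Merge the globally closest cluster pair (linkage = max pairwise leaf
    distance, ties by smallest leaf indices) while the merge height stays
    <= 1 - similarity; return the resulting partition of leaf indices.
    """
    n = len(seqs)
    d = [[dp_levenshtein(seqs[i], seqs[j]) / max(len(seqs[i]), len(seqs[j]))
          for j in range(n)] for i in range(n)]
    clusters = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            h = max(d[i][j] for i in clusters[x] for j in clusters[y])
            key = (h, min(clusters[x] | clusters[y]),
                   max(min(clusters[x]), min(clusters[y])))
            if best is None or key < best[0]:
                best = (key, x, y)
        (h, *_), x, y = best
        if h > 1 - similarity + 1e-9:
            break
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return clusters


def as_partition(labels: np.ndarray) -> set[frozenset[int]]:
    return {
        frozenset(np.flatnonzero(labels == lab)) for lab in np.unique(labels)
    }


def random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    return [
        "".join(rng.choice(list("ACGT"), size=rng.integers(5, 15)))
        for _ in range(n)
    ]


# ------------------------------------------------------------- distances

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("AAAA", "AA", 0.5),  # edit distance 2 over max length 4
    ],
)
def test_normalized_levenshtein_examples(a, b, expected):
    assert normalized_levenshtein(a, b) == pytest.approx(expected)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        normalized_levenshtein("", "ACGT")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=12),
    st.text(alphabet="ACGT", min_size=1, max_size=12),
)
def test_normalized_levenshtein_matches_dp_oracle(a, b):
    expected = dp_levenshtein(a, b) / max(len(a), len(b))
    assert normalized_levenshtein(a, b) == pytest.approx(expected)


def test_pairwise_matrix_matches_bruteforce():
    rng = np.random.default_rng(3)
    seqs = random_sequences(rng, 8)
    ref = make_ref({f"A{i}*01": s for i, s in enumerate(seqs)}, gapped=False)
    D = pairwise_distances(ref)
    assert D.labels == ref.names  # input order preserved
    for i in range(8):
        for j in range(8):
            expected = (
                0.0 if i == j
                else dp_levenshtein(seqs[i], seqs[j])
                / max(len(seqs[i]), len(seqs[j]))
            )
            assert D.values[i, j] == pytest.approx(expected)


def test_identical_sequences_zero_offdiagonal():
    ref = make_ref({"A*01": "ACGT", "B*01": "ACGT", "C*01": "ACGT"},
                   gapped=False)
    D = pairwise_distances(ref)
    assert np.all(D.values == 0)


def test_single_sequence_rejected():
    ref = make_ref({"A*01": "ACGT"})
    with pytest.raises(AscGenotypeError):
        pairwise_distances(ref)


# ------------------------------------------------------------------ trees

def toy_matrix():
    """4 leaves: {a,b} at 0.02, c at 0.10 from both, d at 0.30 from all."""
    m = np.array(
        [
            [0.00, 0.02, 0.10, 0.30],
            [0.02, 0.00, 0.10, 0.30],
            [0.10, 0.10, 0.00, 0.30],
            [0.30, 0.30, 0.30, 0.00],
        ]
    )
    return DistanceMatrix(labels=["a", "b", "c", "d"], values=m)


def test_two_leaf_tree():
    D = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 0.3], [0.3, 0]]))
    tree = build_tree(D)
    assert tree.merges == [(0, 1, 0.3)]


def test_four_leaf_toy_merge_heights():
    tree = build_tree(toy_matrix())
    assert [h for (_, _, h) in tree.merges] == pytest.approx([0.02, 0.10, 0.30])


def test_cophenetic_dominates_pairwise():
    D = toy_matrix()
    coph = build_tree(D).cophenetic()
    assert np.all(coph >= D.values - 1e-12)


def test_invalid_matrix_rejected():
    bad = np.array([[0, 0.2], [0.3, 0]])
    with pytest.raises(AscGenotypeError):
        DistanceMatrix(labels=["a", "b"], values=bad)


def test_newick_contains_all_leaves():
    nwk = build_tree(toy_matrix()).to_newick()
    assert nwk.endswith(";")
    for leaf in "abcd":
        assert leaf in nwk


# ------------------------------------------------------------------- cuts

def test_cut_toy_at_95():
    tree = build_tree(toy_matrix())
    labels = cut_tree(tree, 0.95)
    assert as_partition(labels) == {
        frozenset({0, 1}), frozenset({2}), frozenset({3})
    }


def test_cut_at_full_similarity_gives_singletons():
    ref = make_ref({"A*01": "ACGT", "B*01": "ACGA", "C*01": "TTTT"},
                   gapped=False)
    tree = build_tree(pairwise_distances(ref))
    assert len(set(cut_tree(tree, 1.0))) == 3


def test_invalid_similarity_rejected():
    tree = build_tree(toy_matrix())
    with pytest.raises(ValueError):
        cut_tree(tree, 0.0)


@pytest.mark.parametrize("seed", range(30))
def test_cuts_match_bruteforce_oracle_on_random_sets(seed):
    """Exhaustive agreement with the independent agglomeration oracle."""
    rng = np.random.default_rng(seed)
    seqs = random_sequences(rng, int(rng.integers(3, 9)))
    ref = make_ref({f"A{i}*01": s for i, s in enumerate(seqs)}, gapped=False)
    tree = build_tree(pairwise_distances(ref))
    for sim in (0.5, 0.75, 0.9, 0.95, 1.0):
        got = as_partition(cut_tree(tree, sim))
        expected = {frozenset(c) for c in oracle_partition(seqs, sim)}
        assert got == expected, f"seed={seed} sim={sim}"


@pytest.mark.parametrize("seed", range(10))
def test_agrees_with_scipy_on_tie_free_matrices(seed):
    """Library cross-check: on matrices with all-distinct distances (no
    tie-breaking involved), the tree and its cuts match scipy's complete
    linkage exactly."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 10))
    condensed = rng.permutation(np.linspace(0.05, 0.95, n * (n - 1) // 2))
    D = DistanceMatrix(
        labels=[f"L{i}" for i in range(n)], values=squareform(condensed)
    )
    tree = build_tree(D)
    Z = linkage(condensed, method="complete")
    assert tree.to_linkage()[:, 2] == pytest.approx(Z[:, 2])
    for sim in (0.3, 0.6, 0.9):
        ours = as_partition(cut_tree(tree, sim))
        scipys = as_partition(
            fcluster(Z, t=1 - sim + 1e-9, criterion="distance")
        )
        assert ours == scipys


def test_max_intracluster_dissimilarity_bounded_by_cut():
    rng = np.random.default_rng(11)
    for _ in range(20):
        seqs = random_sequences(rng, 7)
        ref = make_ref({f"A{i}*01": s for i, s in enumerate(seqs)},
                       gapped=False)
        D = pairwise_distances(ref)
        tree = build_tree(D)
        for sim in (0.6, 0.8, 0.95):
            labels = cut_tree(tree, sim)
            for lab in np.unique(labels):
                idx = np.flatnonzero(labels == lab)
                for i, j in itertools.combinations(idx, 2):
                    assert D.values[i, j] <= 1 - sim + 1e-9


def test_family_cut_coarsens_asc_cut(toy_germline):
    from ascgenotype import collapse_identical
    unique, _ = collapse_identical(toy_germline)
    tree = build_tree(pairwise_distances(unique))
    fam = cut_tree(tree, 0.75)
    asc = cut_tree(tree, 0.95)
    for lab in np.unique(asc):
        assert len(np.unique(fam[asc == lab])) == 1


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(5)
    seqs = random_sequences(rng, 6)
    names = [f"A{i}*01" for i in range(6)]
    ref = make_ref(dict(zip(names, seqs)), gapped=False)
    perm = rng.permutation(6)
    ref_p = make_ref(
        {names[i]: seqs[i] for i in perm}, gapped=False
    )

    def named_partition(r):
        tree = build_tree(pairwise_distances(r))
        labels = cut_tree(tree, 0.8)
        return {
            frozenset(np.array(r.names)[labels == lab])
            for lab in np.unique(labels)
        }

    assert named_partition(ref) == named_partition(ref_p)


# ------------------------------------------------------------- ASC naming

def test_asc_name_format():
    ref = make_ref({"IGHV1-2*01": "AAAA"})
    asc = assign_asc_names(
        ref,
        family_labels=np.array([2]),
        cluster_labels=np.array([15]),
        amplicon="S1",
    )
    # indices are renumbered by policy: one family, one cluster
    assert asc.entries[0].asc_name == "IGHVS1F1-G1*01"


def test_single_sequence_reference(toy_cfg):
    ref = make_ref({"IGHV1-2*01": "AAAA"})
    asc = assign_asc_names(ref, np.array([1]), np.array([1]), amplicon="")
    assert asc.entries[0].asc_name == "IGHVF1-G1*01"


def test_name_components_match_indices(toy_asc):
    asc_ref, _, _, _ = toy_asc
    for e in asc_ref:
        assert e.asc_name == (
            f"IGHVS1F{e.family_index}-G{e.cluster_index}*{e.allele_number:02d}"
        )


def test_non_nested_partitions_rejected():
    ref = make_ref({"A*01": "AAAA", "B*01": "AAAT"})
    with pytest.raises(AscGenotypeError, match="refine"):
        assign_asc_names(ref, np.array([1, 2]), np.array([1, 1]))


def test_pinned_key_table_reproduced():
    ref = make_ref({"IGHV1-2*01": "AAAA", "IGHV1-2*02": "AAAT"})
    pinned = KeyTable({"IGHVS1F9-G42*07": ["IGHV1-2*01"],
                       "IGHVS1F9-G42*08": ["IGHV1-2*02"]})
    asc = assign_asc_names(
        ref, np.array([1, 1]), np.array([1, 1]), amplicon="S1", pinned=pinned
    )
    assert [e.asc_name for e in asc] == ["IGHVS1F9-G42*07", "IGHVS1F9-G42*08"]


def test_global_cluster_numbering_spans_families(toy_asc):
    asc_ref, _, _, _ = toy_asc
    clusters = sorted({e.cluster_index for e in asc_ref})
    assert clusters == list(range(1, len(clusters) + 1))
    assert asc_ref.n_families >= 2  # several families share the G-sequence


# ------------------------------------------------------- cut evaluation

def test_perfect_correspondence_gives_zero_metrics():
    # each gene's alleles ~99% similar, cross-gene far apart
    rng = np.random.default_rng(2)
    seqs = {}
    for g in range(3):
        base = "".join(rng.choice(list("ACGT"), size=100))
        seqs[f"IGHV{g + 1}-1*01"] = base
        seqs[f"IGHV{g + 1}-1*02"] = "T" + base[1:]
    ref = make_ref(seqs, gapped=False)
    ev = evaluate_cut_thresholds(ref, [0.95])
    row = ev.table.iloc[0]
    assert row["gene_split"] == 0.0
    assert row["cluster_mixed"] == 0.0


def test_shared_identical_allele_mixes_clusters():
    rng = np.random.default_rng(4)
    base = "".join(rng.choice(list("ACGT"), size=100))
    other = "".join(rng.choice(list("ACGT"), size=100))
    ref = make_ref(
        {"IGHV1-1*01": base, "IGHV2-1*01": other}, gapped=False
    )
    from ascgenotype import collapse_identical
    # a duplicated sequence under a second gene name
    ref2 = make_ref(
        {"IGHV1-1*01": base, "IGHV1-1D*01": base, "IGHV2-1*01": other},
        gapped=False,
    )
    unique, mapping = collapse_identical(ref2)
    for sim in (0.5, 0.95, 1.0):
        ev = evaluate_cut_thresholds(unique, [sim], collapse_mapping=mapping)
        assert ev.table.iloc[0]["cluster_mixed"] > 0


def test_grid_of_length_one():
    ref = make_ref({"A*01": "AAAA", "B*01": "TTTT"}, gapped=False)
    assert len(evaluate_cut_thresholds(ref, [0.9]).table) == 1
    with pytest.raises(ValueError):
        evaluate_cut_thresholds(ref, [])


# ------------------------------------------------- clustering comparison

def _cluster(seqs: dict[str, str]) -> ASCReference:
    ref = make_ref(seqs, gapped=False)
    asc, _ = cluster_reference(ref)
    return asc


def test_compare_identical_clusterings(toy_asc):
    asc_ref, _, _, _ = toy_asc
    report = compare_clusterings(asc_ref, asc_ref)
    assert report["merged"] == [] and report["dropped"] == []
    assert report["split"] == []
    assert len(report["unchanged"]) == asc_ref.n_clusters


def test_removed_cluster_reported_dropped():
    rng = np.random.default_rng(6)
    bases = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(3)]
    full = {f"IGHV{i + 1}-1*01": b for i, b in enumerate(bases)}
    a = _cluster(full)
    dropped_cluster = next(
        e.cluster_index for e in a if e.iuis_names[0] == "IGHV3-1*01"
    )
    b = _cluster({k: v for k, v in full.items() if k != "IGHV3-1*01"})
    report = compare_clusterings(a, b)
    assert report["dropped"] == [dropped_cluster]


def test_bridge_removal_merges_clusters():
    # A and C are distant; bridge B is close to both.  With the bridge,
    # complete linkage keeps {A,B} and {C} separate at the cut; without
    # any pair below the cut... construct instead: A-B close, B-C close,
    # A-C just over the cut.  Removing B leaves A and C in separate
    # clusters; adding sequences can merge.  Here we test the converse
    # direction the report is designed for: two a-clusters whose
    # sequences land in one b-cluster are reported merged.
    seqs = {
        "IGHV1-1*01": "A" * 50,
        "IGHV2-1*01": "A" * 46 + "TTTT",   # distance 4/50 = 0.08
    }
    a = _cluster(seqs)  # at 95%: two singleton clusters
    assert a.n_clusters == 2
    ref_b = make_ref(seqs, gapped=False)
    b_asc, _ = cluster_reference(ref_b, asc_similarity=0.90)  # now merged
    report = compare_clusterings(a, b_asc)
    assert report["merged"] == [(1, 2)]


def test_disjoint_references_rejected():
    a = _cluster({"A*01": "AAAA" * 10, "B*01": "TTTT" * 10})
    b = _cluster({"C*01": "GGGG" * 10, "D*01": "CCCC" * 10})
    with pytest.raises(AscGenotypeError):
        compare_clusterings(a, b)


# ------------------------------------------------------------ key table

def test_translate_both_directions(toy_asc):
    _, _, key, mapping = toy_asc
    merged_rep = next(k for k, v in mapping.items() if len(v) > 1)
    asc_name = key.iuis_to_asc[merged_rep]
    expanded = translate_call(asc_name, key, "asc_to_iuis")
    assert set(expanded.split(",")) == set(mapping[merged_rep])
    # round trip contains the original
    back = translate_call(expanded, key, "iuis_to_asc")
    assert back == asc_name  # both synonyms dedup to one ASC allele


def test_identical_sequences_share_one_asc_name(toy_asc):
    _, _, key, mapping = toy_asc
    merged = next(v for v in mapping.values() if len(v) > 1)
    assert len({key.iuis_to_asc[n] for n in merged}) == 1


def test_unknown_name_passthrough_and_strict(toy_asc):
    _, _, key, _ = toy_asc
    assert translate_call("IGHV9-99*99", key) == "IGHV9-99*99"
    with pytest.raises(TranslationError):
        translate_call("IGHV9-99*99", key, strict=True)


def test_key_table_tsv_round_trip(toy_asc, tmp_path):
    _, _, key, _ = toy_asc
    path = tmp_path / "key.tsv"
    key.write_tsv(path)
    loaded = KeyTable.read_tsv(path)
    assert loaded.asc_to_iuis == key.asc_to_iuis
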