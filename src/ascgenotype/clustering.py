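"""Allele similarity clustering and the ASC naming scheme.

Alleles of a germline reference set are clustered purely by sequence
similarity: pairwise normalized Levenshtein distances, complete-linkage
agglomeration, and cuts of the resulting tree at two similarity thresholds —
75% for allele *families* (the analogue of IUIS subgroups) and 95% for
*Allele Similarity Clusters* (ASCs, the analogue of genes).  Each unique
sequence is then renamed ``IGHV{S}F{f}-G{g}*{aa}``: family index, global
cluster index, and a two-digit allele number within the cluster.  A key
table records the mapping between ASC names and the IUIS names they absorb.

Complete linkage is implemented directly (naive O(n^3) agglomeration) so
that merge order is fully deterministic: among equally distant cluster
pairs, the pair whose smallest leaf labels come first is merged first.
Reference sets are a few hundred sequences, so the cubic loop is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import AscGenotypeError, TranslationError
from .germline import GermlineReference, natural_key

#: Similarity threshold defining allele families (IUIS-subgroup analogue).
FAMILY_SIMILARITY = 0.75
#: Similarity threshold defining Allele Similarity Clusters.
ASC_SIMILARITY = 0.95

_EPS = 1e-9  # float guard for inclusive height comparisons on rationals


def normalized_levenshtein(a: str, b: str) -> float:
    """Edit distance with unit costs, normalized by the longer length.

    Normalizing by ``max(len(a), len(b))`` bounds the dissimilarity in
    [0, 1], keeps it symmetric, and makes "x% similarity" = 1 - distance.
    Returns 0.0 iff the sequences are identical.
    """
    if not a or not b:
        raise ValueError("cannot compute distance of an empty sequence")
    if a == b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of normalized dissimilarities over labelled items."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise AscGenotypeError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise AscGenotypeError("distance matrix diagonal is not zero")
        if v.min() < 0 or v.max() > 1:
            raise AscGenotypeError("distances must lie in [0, 1]")
        self.values = v


def pairwise_distances(ref: GermlineReference) -> DistanceMatrix:
    """Normalized Levenshtein distances between all allele pairs.

    Distances are computed on ungapped sequences: the edit distance itself
    models indels, so IMGT gap characters are stripped first.
    """
    if len(ref) < 2:
        raise AscGenotypeError("need at least 2 sequences to cluster")
    seqs = [a.sequence for a in ref]
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = normalized_levenshtein(seqs[i], seqs[j])
    return DistanceMatrix(labels=ref.names, values=m)


@dataclass
class ClusterTree:
    """A complete-linkage dendrogram.

    ``merges`` lists (id_a, id_b, height) in merge order, with leaves
    numbered 0..n-1 and the k-th merge creating node n+k (scipy linkage
    convention).  Heights are non-decreasing under complete linkage.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-style linkage matrix (for dendrograms / cophenet)."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        rows = []
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[self.n_leaves + k] = size
            rows.append([a, b, h, size])
        return np.array(rows, dtype=float)

    def cophenetic(self) -> np.ndarray:
        """Matrix of heights at which each leaf pair first joins."""
        members = {i: [i] for i in range(self.n_leaves)}
        coph = np.zeros((self.n_leaves, self.n_leaves))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
            members[self.n_leaves + k] = members.pop(a) + members.pop(b)
        return coph

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: lab for i, lab in enumerate(self.leaf_labels)}
        node = self.n_leaves - 1
        for a, b, h in self.merges:
            node += 1
            la = h - height[a]
            lb = h - height[b]
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            height[node] = h
        return text[node] + ";" if self.merges else text[0] + ";"


def build_tree(D: DistanceMatrix) -> ClusterTree:
    """Agglomerate with complete linkage, deterministically.

    At each step the pair of active clusters with the smallest complete-
    linkage distance (max pairwise leaf distance) is merged; ties are broken
    in favour of the pair whose sorted smallest leaf indices are smallest.
    """
    n = len(D.labels)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    dm = D.values

    # cache complete-linkage distances between active clusters
    def clink(a: int, b: int) -> float:
        return max(dm[i, j] for i in active[a] for j in active[b])

    while len(active) > 1:
        best = None
        ids = sorted(active)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                d = clink(a, b)
                key = (d, min(min(active[a]), min(active[b])),
                       max(min(active[a]), min(active[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        key, a, b = best
        d = key[0]
        merges.append((a, b, d))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return ClusterTree(leaf_labels=list(D.labels), merges=merges)


def cut_tree(tree: ClusterTree, similarity: float) -> np.ndarray:
    """Cut the dendrogram at a similarity threshold.

    Leaves end up in the same cluster iff they were joined at height
    <= 1 - similarity (inclusive).  Cluster labels are integers 1..k,
    numbered by each cluster's smallest leaf index, so the labelling is
    deterministic and order-stable.
    """
    if not 0 < similarity <= 1:
        raise ValueError(f"similarity must be in (0, 1], got {similarity}")
    cut_height = 1.0 - similarity
    parent = list(range(tree.n_leaves))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members = {i: [i] for i in range(tree.n_leaves)}
    for k, (a, b, h) in enumerate(tree.merges):
        node = tree.n_leaves + k
        ma = members.pop(a)
        mb = members.pop(b)
        members[node] = ma + mb
        if h <= cut_height + _EPS:
            ra, rb = find(ma[0]), find(mb[0])
            parent[max(ra, rb)] = min(ra, rb)

    roots = sorted({find(i) for i in range(tree.n_leaves)})
    label_of_root = {r: i + 1 for i, r in enumerate(roots)}
    return np.array([label_of_root[find(i)] for i in range(tree.n_leaves)])


@dataclass(frozen=True)
class ASCAllele:
    """One unique sequence with its ASC identity."""

    asc_name: str
    family_index: int
    cluster_index: int
    allele_number: int
    iuis_names: tuple[str, ...]
    sequence: str


@dataclass
class ASCReference:
    """An ASC-annotated reference: names, key table, thresholds used."""

    entries: list[ASCAllele]
    amplicon_class: str = "S1"
    family_similarity: float = FAMILY_SIMILARITY
    asc_similarity: float = ASC_SIMILARITY

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def n_families(self) -> int:
        return len({e.family_index for e in self.entries})

    @property
    def n_clusters(self) -> int:
        return len({e.cluster_index for e in self.entries})

    @property
    def key_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "asc_name": [e.asc_name for e in self.entries],
                "iuis_names": [";".join(e.iuis_names) for e in self.entries],
                "sequence": [e.sequence for e in self.entries],
            }
        )

    def cluster_of(self, asc_name: str) -> str:
        """ASC (gene-level) part of an ASC allele name."""
        return asc_name.split("*")[0]


class KeyTable:
    """Bidirectional IUIS <-> ASC allele-name translation table."""

    def __init__(self, asc_to_iuis: Mapping[str, Sequence[str]]):
        self.asc_to_iuis: dict[str, list[str]] = {
            k: list(v) for k, v in asc_to_iuis.items()
        }
        self.iuis_to_asc: dict[str, str] = {}
        for asc, names in self.asc_to_iuis.items():
            for n in names:
                if n in self.iuis_to_asc:
                    raise AscGenotypeError(
                        f"IUIS name {n} maps to more than one ASC allele"
                    )
                self.iuis_to_asc[n] = asc

    @classmethod
    def from_reference(cls, ref: ASCReference) -> "KeyTable":
        return cls({e.asc_name: list(e.iuis_names) for e in ref})

    @classmethod
    def read_tsv(cls, path: str | Path) -> "KeyTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            {
                row["asc_name"]: row["iuis_names"].split(";")
                for _, row in df.iterrows()
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "asc_name": list(self.asc_to_iuis),
                "iuis_names": [
                    ";".join(v) for v in self.asc_to_iuis.values()
                ],
            }
        ).to_csv(path, sep="\t", index=False)


def translate_call(
    call: str,
    key_table: KeyTable,
    direction: str = "iuis_to_asc",
    strict: bool = False,
) -> str:
    """Translate a (possibly comma-separated) allele call between schemes.

    ``iuis_to_asc`` maps each name to its unique ASC allele and removes the
    duplicates this creates (identical sequences share one ASC name) —
    this deduplication is what shrinks multiple assignments.  ``asc_to_iuis``
    expands each ASC allele to all IUIS names it absorbed.  Unknown names
    pass through unchanged unless ``strict``.
    """
    names = [n.strip() for n in call.split(",") if n.strip()]
    out: list[str] = []
    for n in names:
        if direction == "iuis_to_asc":
            mapped = [key_table.iuis_to_asc.get(n)]
        elif direction == "asc_to_iuis":
            mapped = key_table.asc_to_iuis.get(n)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if mapped is None or mapped == [None]:
            if strict:
                raise TranslationError(f"unknown allele name {n!r}")
            mapped = [n]
        for m in mapped:
            if m not in out:
                out.append(m)
    return ",".join(out)


def _check_nesting(
    family_labels: np.ndarray, cluster_labels: np.ndarray
) -> None:
    for c in np.unique(cluster_labels):
        fams = np.unique(family_labels[cluster_labels == c])
        if len(fams) > 1:
            raise AscGenotypeError(
                f"cluster {c} spans families {fams.tolist()}: the ASC "
                "partition must refine the family partition"
            )


def _locus_prefix(names: Iterable[str]) -> str:
    first = next(iter(names), "IGHV")
    prefix = ""
    for ch in first:
        if ch.isdigit():
            break
        prefix += ch
    return prefix or "IGHV"


def assign_asc_names(
    ref: GermlineReference,
    family_labels: np.ndarray,
    cluster_labels: np.ndarray,
    amplicon: str | None = None,
    collapse_mapping: Mapping[str, Sequence[str]] | None = None,
    pinned: KeyTable | None = None,
) -> ASCReference:
    """Rename unique sequences under the ASC scheme.

    Families get indices F1..Fm and clusters global indices G1..Gn, both
    ordered by the natural-sort-smallest member IUIS name; allele numbers
    run 01.. within each cluster in the same order.  The resulting name is
    ``{locus}{amplicon}F{f}-G{g}*{aa}``.  Published numbering can be pinned
    by supplying an existing key table, which overrides the policy.

    ``collapse_mapping`` (from ``collapse_identical``) supplies the merged
    IUIS synonyms carried by each retained representative.
    """
    family_labels = np.asarray(family_labels)
    cluster_labels = np.asarray(cluster_labels)
    _check_nesting(family_labels, cluster_labels)
    names = ref.names
    if amplicon is None:
        amplicon = ref.amplicon_class if ref.amplicon_class != "custom" else ""
    locus = _locus_prefix(names)

    def smallest_member(label: int, labels: np.ndarray) -> str:
        members = [names[i] for i in range(len(names)) if labels[i] == label]
        return min(members, key=natural_key)

    fam_order = sorted(
        np.unique(family_labels),
        key=lambda f: natural_key(smallest_member(f, family_labels)),
    )
    fam_index = {f: i + 1 for i, f in enumerate(fam_order)}
    clus_order = sorted(
        np.unique(cluster_labels),
        key=lambda c: natural_key(smallest_member(c, cluster_labels)),
    )
    clus_index = {c: i + 1 for i, c in enumerate(clus_order)}

    if pinned is not None:
        seq_to_pinned = {}
        for e_asc, iuis in pinned.asc_to_iuis.items():
            for n in iuis:
                seq_to_pinned[n] = e_asc

    entries = []
    for c in clus_order:
        idx = [i for i in range(len(names)) if cluster_labels[i] == c]
        idx.sort(key=lambda i: natural_key(names[i]))
        for num, i in enumerate(idx, start=1):
            iuis = (
                tuple(collapse_mapping.get(names[i], [names[i]]))
                if collapse_mapping
                else (names[i],)
            )
            f = fam_index[family_labels[i]]
            g = clus_index[c]
            asc_name = f"{locus}{amplicon}F{f}-G{g}*{num:02d}"
            if pinned is not None:
                pin = {seq_to_pinned.get(n) for n in iuis} - {None}
                if len(pin) > 1:
                    raise AscGenotypeError(
                        f"key-table conflict: {iuis} pinned to {sorted(pin)}"
                    )
                if pin:
                    asc_name = pin.pop()
            entries.append(
                ASCAllele(
                    asc_name=asc_name,
                    family_index=f,
                    cluster_index=g,
                    allele_number=num,
                    iuis_names=iuis,
                    sequence=ref.alleles[i].sequence,
                )
            )
    return ASCReference(
        entries=entries,
        amplicon_class=amplicon or "custom",
    )


def cluster_reference(
    ref: GermlineReference,
    family_similarity: float = FAMILY_SIMILARITY,
    asc_similarity: float = ASC_SIMILARITY,
    collapse_mapping: Mapping[str, Sequence[str]] | None = None,
    amplicon: str | None = None,
) -> tuple[ASCReference, ClusterTree]:
    """Distance -> tree -> 75%/95% cuts -> ASC names, in one call."""
    D = pairwise_distances(ref)
    tree = build_tree(D)
    fam = cut_tree(tree, family_similarity)
    asc = cut_tree(tree, asc_similarity)
    ref_out = assign_asc_names(
        ref, fam, asc, amplicon=amplicon, collapse_mapping=collapse_mapping
    )
    ref_out.family_similarity = family_similarity
    ref_out.asc_similarity = asc_similarity
    return ref_out, tree


@dataclass
class CutEvaluation:
    """Gene/cluster correspondence metrics over a similarity grid.

    At each threshold: ``gene_split`` is the fraction of IUIS genes whose
    alleles land in more than one cluster; ``cluster_mixed`` the fraction of
    clusters containing alleles of more than one gene.  The trade-off
    between the two guides the choice of the ASC threshold.
    """

    table: pd.DataFrame  # columns: similarity, gene_split, cluster_mixed

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def evaluate_cut_thresholds(
    ref: GermlineReference,
    grid: Sequence[float],
    collapse_mapping: Mapping[str, Sequence[str]] | None = None,
) -> CutEvaluation:
    """Compute both correspondence metrics at each similarity in ``grid``."""
    if len(grid) == 0:
        raise ValueError("empty similarity grid")
    D = pairwise_distances(ref)
    tree = build_tree(D)

    # genes carried by each unique sequence (several, if names were merged)
    genes_per_seq: list[set[str]] = []
    for a in ref:
        merged = (
            collapse_mapping.get(a.iuis_name, [a.iuis_name])
            if collapse_mapping
            else [a.iuis_name]
        )
        genes_per_seq.append({n.split("*")[0] for n in merged})

    rows = []
    for s in grid:
        labels = cut_tree(tree, s)
        gene_clusters: dict[str, set[int]] = {}
        cluster_genes: dict[int, set[str]] = {}
        for i, genes in enumerate(genes_per_seq):
            for g in genes:
                gene_clusters.setdefault(g, set()).add(labels[i])
            cluster_genes.setdefault(labels[i], set()).update(genes)
        n_genes = len(gene_clusters)
        n_clusters = len(cluster_genes)
        rows.append(
            {
                "similarity": s,
                "gene_split": sum(
                    1 for cl in gene_clusters.values() if len(cl) > 1
                )
                / n_genes,
                "cluster_mixed": sum(
                    1 for gs in cluster_genes.values() if len(gs) > 1
                )
                / n_clusters,
            }
        )
    return CutEvaluation(table=pd.DataFrame(rows))


def compare_clusterings(a: ASCReference, b: ASCReference) -> dict[str, list]:
    """Classify each cluster of ``a`` by its image in re-clustering ``b``.

    ``b`` is typically built from a reduced reference (sequences removed).
    A cluster of ``a`` is *dropped* if none of its sequences survive,
    *split* if its survivors spread over several ``b`` clusters, part of a
    *merged* group if its ``b`` cluster also contains survivors of another
    ``a`` cluster, else *unchanged*.
    """
    seq_to_a = {e.sequence.upper(): e.cluster_index for e in a}
    seq_to_b = {e.sequence.upper(): e.cluster_index for e in b}
    common = set(seq_to_a) & set(seq_to_b)
    if not common:
        raise AscGenotypeError("the two references share no sequences")

    a_clusters = sorted({e.cluster_index for e in a})
    a_image: dict[int, set[int]] = {c: set() for c in a_clusters}
    b_sources: dict[int, set[int]] = {}
    for s in common:
        ca, cb = seq_to_a[s], seq_to_b[s]
        a_image[ca].add(cb)
        b_sources.setdefault(cb, set()).add(ca)

    dropped = [c for c in a_clusters if not a_image[c]]
    split = [c for c in a_clusters if len(a_image[c]) > 1]
    merged = sorted(
        tuple(sorted(srcs))
        for srcs in b_sources.values()
        if len(srcs) > 1
    )
    merged_members = {c for grp in merged for c in grp}
    unchanged = [
        c
        for c in a_clusters
        if c not in dropped
        and c not in split
        and c not in merged_members
    ]
    return {
        "merged": merged,
        "dropped": dropped,
        "split": split,
        "unchanged": unchanged,
    }
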