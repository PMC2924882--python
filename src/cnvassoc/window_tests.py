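"""Window-based CNV-pattern testing: complete-linkage clustering and the
"first class node" minimum P value.

For each candidate SNP, the copy-number vectors of all samples over a window
of n SNPs (default 41) centred on the site are clustered agglomeratively with
complete linkage under Euclidean distance. Every non-root node of the
dendrogram (leaves included) defines a 2x2 table — cases/controls inside vs
outside the node — tested exactly as at the site level; the most significant
node is the first class node and its P value is the window's P value.

The dendrogram depends only on the copy-number vectors, never on the labels,
so it is computed once per window and re-scored under label permutations.
Duplicate vectors (overwhelmingly the all-diploid vector) are collapsed into
weighted leaves before clustering; zero-distance merges happen first under
complete linkage, so the memberships of nodes separating distinct patterns
are unchanged by the collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SnpMap
from .contingency import pvalues_by_k

__all__ = [
    "CnWindow",
    "Dendrogram",
    "WindowResult",
    "extract_window",
    "euclidean",
    "complete_linkage",
    "node_p",
    "first_class_p",
    "evaluate_window",
]


@dataclass
class CnWindow:
    """Copy-number vectors of all samples over one window of SNPs."""

    center: str
    snp_cols: np.ndarray  # column indices into the cohort CN matrix
    vectors: np.ndarray  # (n_samples, window span)
    truncated: bool = False
    imputed: int = 0  # masked entries imputed as CN2 for distance purposes

    @property
    def span(self) -> int:
        return self.vectors.shape[1]


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over (possibly collapsed) leaves.

    Node ids: leaves are 0..n_leaves-1 in first-occurrence order of their
    pattern; internal nodes follow in merge order. ``members[v]`` is the set
    of original sample indices under node v.
    """

    n_samples: int
    n_leaves: int
    merges: list  # (left id, right id, height), in merge order
    members: list  # per node id, ndarray of sample indices

    @property
    def n_nodes(self) -> int:
        return self.n_leaves + len(self.merges)

    @property
    def root(self) -> int:
        return self.n_nodes - 1 if self.n_leaves > 1 else 0


@dataclass
class WindowResult:
    center: str
    first_class_p: float
    node: int
    node_size: int
    cases_in_node: int
    controls_in_node: int
    span: int


def extract_window(
    cn_matrix: np.ndarray, snp_map: SnpMap, center: str, n: int = 41
) -> CnWindow:
    """The (n-1)/2 SNPs each side of the centre on the same chromosome.

    Windows are truncated (and flagged) at chromosome ends rather than
    skipped, so candidate sites near ends stay testable. Masked copy numbers
    (negative entries) are imputed as diploid for distance purposes.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("window size must be a positive odd integer")
    j = snp_map.index_of(center)
    chrom_cols = snp_map.chrom_indices(snp_map.chrom[j])
    pos_in_chrom = int(np.flatnonzero(chrom_cols == j)[0])
    half = (n - 1) // 2
    lo = max(0, pos_in_chrom - half)
    hi = min(len(chrom_cols), pos_in_chrom + half + 1)
    cols = chrom_cols[lo:hi]
    vectors = np.asarray(cn_matrix[:, cols], dtype=np.int16)
    imputed = int(np.sum(vectors < 0))
    if imputed:
        vectors = np.where(vectors < 0, 2, vectors)
    return CnWindow(
        center=str(center),
        snp_cols=cols,
        vectors=vectors,
        truncated=len(cols) < n,
        imputed=imputed,
    )


def euclidean(u, v) -> float:
    """Euclidean distance between two copy-number vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def _collapse(vectors: np.ndarray):
    """Group identical rows; groups ordered by first occurrence."""
    groups: dict[bytes, list] = {}
    order: list[bytes] = []
    arr = np.ascontiguousarray(vectors)
    for i in range(arr.shape[0]):
        key = arr[i].tobytes()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    members = [np.asarray(groups[k], dtype=np.int64) for k in order]
    reps = np.stack([vectors[m[0]] for m in members])
    return reps, members


def complete_linkage(
    vectors: np.ndarray, collapse_duplicates: bool = True
) -> Dendrogram:
    """Agglomerative complete-linkage clustering of copy-number vectors.

    Cluster-cluster distance is the maximum pairwise member distance; each
    step merges the minimum-distance pair. Ties are broken deterministically:
    the pair whose union has the lowest smallest sample index wins, then the
    lower remaining smallest index. With ``collapse_duplicates`` identical
    vectors become one weighted leaf (their zero-height merges are implicit).
    """
    vectors = np.asarray(vectors)
    if vectors.ndim != 2 or vectors.shape[0] < 1:
        raise ValueError("need a 2-D (samples x span) array")
    n_samples = vectors.shape[0]
    if collapse_duplicates:
        reps, leaf_members = _collapse(vectors)
    else:
        reps = vectors.astype(float)
        leaf_members = [np.asarray([i]) for i in range(n_samples)]
    L = reps.shape[0]
    members: list[np.ndarray] = list(leaf_members)
    if L == 1:
        return Dendrogram(n_samples=n_samples, n_leaves=1, merges=[], members=members)
    diff = reps[:, None, :].astype(float) - reps[None, :, :].astype(float)
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    active = list(range(L))
    cluster_of = {i: i for i in range(L)}  # active slot -> node id
    min_idx = {i: int(members[i].min()) for i in range(L)}
    merges: list[tuple[int, int, float]] = []
    D = dist.copy()
    alive = np.ones(L, dtype=bool)
    while alive.sum() > 1:
        sub = np.where(alive[:, None] & alive[None, :], D, np.inf)
        d = sub.min()
        ii, jj = np.where(sub <= d)
        # deterministic tie-break on sample indices of the union
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            key = tuple(sorted((min_idx[a], min_idx[b])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        if min_idx[a] > min_idx[b]:
            a, b = b, a
        left, right = cluster_of[a], cluster_of[b]
        new_id = len(members)
        merged = np.sort(np.concatenate([members[left], members[right]]))
        members.append(merged)
        merges.append((left, right, float(d)))
        # Lance-Williams complete-linkage update into slot a
        D[a, :] = np.maximum(D[a, :], D[b, :])
        D[:, a] = D[a, :]
        D[a, a] = np.inf
        alive[b] = False
        cluster_of[a] = new_id
        min_idx[a] = min(min_idx[a], min_idx[b])
    return Dendrogram(
        n_samples=n_samples, n_leaves=L, merges=merges, members=members
    )


def node_p(member_indices, labels, cache: dict | None = None) -> float:
    """Case-control imbalance P of one node: in-node vs out-of-node table.

    Chi-squared when all expected counts reach 5, Fisher otherwise (shared
    convention with the site level). The margins depend only on the node size,
    so an optional cache keyed by size makes repeated evaluation cheap.
    """
    labels = np.asarray(labels, dtype=bool)
    member_indices = np.asarray(member_indices)
    m = int(member_indices.size)
    N = int(labels.size)
    n_case = int(labels.sum())
    if cache is None:
        cache = {}
    if m not in cache:
        cache[m] = pvalues_by_k(m, n_case, N)[0]
    k = int(labels[member_indices].sum())
    return float(cache[m][k])


def first_class_p(dendrogram: Dendrogram, labels) -> WindowResult:
    """Minimum node P over every non-root node (leaves included).

    Ties prefer the smaller node, then the lower node id: the root's two
    children always produce identical tables (complementary rows), so a
    carrier cluster sitting directly under the root ties with its complement,
    and the smaller of the two is the CNV-pattern cluster itself. A
    degenerate dendrogram (a single sample) reports P = 1.
    """
    labels = np.asarray(labels, dtype=bool)
    N = dendrogram.n_samples
    if N < 2 or dendrogram.n_nodes < 2:
        return WindowResult(
            center="", first_class_p=1.0, node=0,
            node_size=N, cases_in_node=int(labels.sum()),
            controls_in_node=int(N - labels.sum()), span=0,
        )
    cache: dict = {}
    best = None
    for v in range(dendrogram.n_nodes):
        if v == dendrogram.root:
            continue
        mem = dendrogram.members[v]
        if mem.size == N:
            continue  # improper node: all samples
        p = node_p(mem, labels, cache)
        key = (p, mem.size, v)
        if best is None or key < best[0]:
            best = (key, v, mem)
    _, v, mem = best
    k = int(labels[mem].sum())
    return WindowResult(
        center="",
        first_class_p=float(best[0][0]),
        node=v,
        node_size=int(mem.size),
        cases_in_node=k,
        controls_in_node=int(mem.size - k),
        span=0,
    )


def evaluate_window(
    cn_matrix: np.ndarray,
    snp_map: SnpMap,
    center: str,
    labels,
    n: int = 41,
    collapse_duplicates: bool = True,
) -> tuple[WindowResult, Dendrogram]:
    """Extract, cluster and score one candidate window."""
    win = extract_window(cn_matrix, snp_map, center, n)
    dend = complete_linkage(win.vectors, collapse_duplicates)
    res = first_class_p(dend, labels)
    res.center = win.center
    res.span = win.span
    return res, dend
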