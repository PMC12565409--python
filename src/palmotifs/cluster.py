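"""Motif comparison, hierarchical clustering, shared motifs and screening.

Motifs from many homolog families are compared with an alignment-aware
distance (best ungapped overlap over all offsets and both orientations,
mean per-column total-variation plus a length-mismatch penalty), merged
by average-linkage agglomeration, and cut into clusters.  Clusters with
fewer than five members are dropped.  Each surviving cluster is
summarised by a *shared motif* — the medoid-anchored average of its
aligned members — and screened: if any member sits farther from the
shared motif than the match threshold, the whole cluster is discarded
as inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .matrix import (
    FrequencyMatrix,
    MotifRecord,
    reverse_complement,
    total_variation_columns,
)

DEFAULT_MIN_OVERLAP = 5
DEFAULT_LENGTH_PENALTY = 0.5  # lambda, weight of the non-overlap fraction
DEFAULT_MIN_MEMBERS = 5


@dataclass(frozen=True)
class MotifAlignment:
    """Best ungapped superposition of motif B onto motif A.

    ``offset`` is the column of A that B's column 0 aligns to (negative
    when B overhangs A's left edge); ``orientation`` says whether B was
    reverse-complemented first.
    """

    offset: int
    orientation: str  # "same" or "revcomp"
    overlap: int
    distance: float


@dataclass
class Cluster:
    id: str
    member_ids: list[str]
    shared_motif: MotifRecord
    retained: bool = True
    motif_type: object = None  # filled by conservation typing
    distance_to_shared: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusterSet:
    """Clustering outcome: the merge tree, clusters, and leftovers."""

    linkage_matrix: np.ndarray
    motif_ids: list[str]
    clusters: list[Cluster]
    cutoff: float
    unclustered: list[str] = field(default_factory=list)

    @property
    def retained_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.retained]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.motif_ids[node.id]}:{length:.6f}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return rec(tree, tree.dist) + ";"


def motif_distance(
    a: FrequencyMatrix,
    b: FrequencyMatrix,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    length_penalty: float = DEFAULT_LENGTH_PENALTY,
) -> MotifAlignment:
    """Alignment-minimised distance between two PWMs.

    Over every offset with at least ``min_overlap`` overlapping columns
    and both orientations of ``b``, computes the mean per-column
    total-variation distance on the overlap plus
    ``length_penalty * (1 - overlap / max(W_a, W_b))``, and returns the
    minimising alignment.  Symmetric; zero for identical motifs (and for
    a motif against its own reverse complement).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    wa, wb = a.width, b.width
    if wa < min_overlap or wb < min_overlap:
        raise ValueError(
            f"motif widths ({wa}, {wb}) must both be >= min_overlap={min_overlap}"
        )
    wmax = max(wa, wb)
    best: MotifAlignment | None = None
    for orientation, bm in (("same", b), ("revcomp", reverse_complement(b))):
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(wa, offset + wb)
            overlap = a_hi - a_lo
            if overlap < min_overlap:
                continue
            b_lo = a_lo - offset
            tv = total_variation_columns(
                a.probs[:, a_lo:a_hi], bm.probs[:, b_lo:b_lo + overlap]
            ).mean()
            dist = float(tv + length_penalty * (1.0 - overlap / wmax))
            if best is None or dist < best.distance - 1e-12:
                best = MotifAlignment(offset, orientation, overlap, dist)
    assert best is not None
    return best


def _pairwise_distances(
    motifs: list[MotifRecord], min_overlap: int, length_penalty: float
) -> np.ndarray:
    n = len(motifs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = motif_distance(
                motifs[i].matrix, motifs[j].matrix, min_overlap, length_penalty
            ).distance
            dm[i, j] = dm[j, i] = d
    return dm


def cluster_motifs(
    motifs: list[MotifRecord],
    cutoff: float,
    min_members: int = DEFAULT_MIN_MEMBERS,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    length_penalty: float = DEFAULT_LENGTH_PENALTY,
    linkage_method: str = "average",
) -> ClusterSet:
    """Average-linkage clustering of motifs, cut at ``cutoff``.

    Groups with fewer than ``min_members`` members are removed (their
    motifs reported as unclustered).  Deterministic for a given input:
    motifs are ordered lexicographically by id before clustering.
    """
    if len(motifs) < 2:
        raise ValueError("clustering needs at least 2 motifs")
    motifs = sorted(motifs, key=lambda m: m.id)
    ids = [m.id for m in motifs]
    dm = _pairwise_distances(motifs, min_overlap, length_penalty)
    condensed = dm[np.triu_indices(len(motifs), k=1)]
    z = hierarchy.linkage(condensed, method=linkage_method)
    labels = hierarchy.fcluster(z, t=cutoff, criterion="distance")
    by_label: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(idx)
    clusters: list[Cluster] = []
    unclustered: list[str] = []
    # stable cluster order: by lexicographically smallest member id
    groups = sorted(by_label.values(), key=lambda g: ids[g[0]])
    cnum = 0
    for group in groups:
        if len(group) < min_members:
            unclustered.extend(ids[i] for i in group)
            continue
        cnum += 1
        members = [motifs[i] for i in group]
        shared = shared_motif(members, min_overlap, length_penalty)
        shared.id = f"cluster_{cnum}"
        clusters.append(
            Cluster(
                id=f"cluster_{cnum}",
                member_ids=[m.id for m in members],
                shared_motif=shared,
            )
        )
    return ClusterSet(
        linkage_matrix=z, motif_ids=ids, clusters=clusters,
        cutoff=cutoff, unclustered=unclustered,
    )


def shared_motif(
    cluster_members: list[MotifRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    length_penalty: float = DEFAULT_LENGTH_PENALTY,
) -> MotifRecord:
    """Consensus PWM of a cluster: medoid-anchored aligned average.

    The medoid (member minimising summed distance to the rest, ties to
    the lexicographically first id) anchors the coordinate frame; every
    member is superposed via its best alignment, columns covered by at
    least half the members are averaged and renormalised.
    """
    if len(cluster_members) < 2:
        raise ValueError("shared motif needs at least 2 members")
    members = cluster_members
    n = len(members)
    dm = _pairwise_distances(members, min_overlap, length_penalty)
    sums = dm.sum(axis=1)
    order = sorted(range(n), key=lambda i: (sums[i], members[i].id))
    medoid = members[order[0]]
    placements: list[tuple[int, np.ndarray]] = []
    for m in members:
        aln = motif_distance(medoid.matrix, m.matrix, min_overlap, length_penalty)
        mat = m.matrix if aln.orientation == "same" else reverse_complement(m.matrix)
        placements.append((aln.offset, mat.probs))
    lo = min(off for off, _ in placements)
    hi = max(off + p.shape[1] for off, p in placements)
    span = hi - lo
    acc = np.zeros((4, span))
    cov = np.zeros(span)
    for off, p in placements:
        s = off - lo
        acc[:, s:s + p.shape[1]] += p
        cov[s:s + p.shape[1]] += 1
    keep = cov >= n / 2.0
    # longest contiguous covered stretch
    best_run = (0, 0)
    run_start = None
    for j in range(span + 1):
        if j < span and keep[j]:
            if run_start is None:
                run_start = j
        elif run_start is not None:
            if j - run_start > best_run[1] - best_run[0]:
                best_run = (run_start, j)
            run_start = None
    a, b = best_run
    probs = acc[:, a:b] / cov[a:b]
    probs = probs / probs.sum(axis=0, keepdims=True)
    nsites = sum(m.nsites for m in members)
    return MotifRecord(
        id="shared", matrix=FrequencyMatrix(probs=probs), nsites=nsites,
        coverage=1.0, source_set="shared",
    )


def screen_cluster(
    cluster: Cluster,
    members: list[MotifRecord],
    match_thresh: float,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    length_penalty: float = DEFAULT_LENGTH_PENALTY,
) -> bool:
    """Keep a cluster only if every member matches its shared motif.

    Each member's distance to the shared motif is recorded; the cluster
    is retained iff all distances are at most ``match_thresh``.
    """
    ok = True
    for m in members:
        d = motif_distance(
            cluster.shared_motif.matrix, m.matrix, min_overlap, length_penalty
        ).distance
        cluster.distance_to_shared[m.id] = d
        if d > match_thresh:
            ok = False
    cluster.retained = ok
    return ok


def screen_clusters(
    cluster_set: ClusterSet,
    motifs: list[MotifRecord],
    match_thresh: float,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    length_penalty: float = DEFAULT_LENGTH_PENALTY,
) -> ClusterSet:
    """Apply ``screen_cluster`` to every cluster in place."""
    by_id = {m.id: m for m in motifs}
    for c in cluster_set.clusters:
        screen_cluster(
            c, [by_id[i] for i in c.member_ids], match_thresh,
            min_overlap, length_penalty,
        )
    return cluster_set


def cluster_table(cluster_set: ClusterSet) -> pd.DataFrame:
    """Per-motif cluster assignment table."""
    rows = []
    for c in cluster_set.clusters:
        for mid in c.member_ids:
            rows.append(
                {
                    "motif_id": mid,
                    "cluster_id": c.id,
                    "retained": c.retained,
                    "distance_to_shared": round(c.distance_to_shared.get(mid, np.nan), 6),
                }
            )
    for mid in cluster_set.unclustered:
        rows.append(
            {"motif_id": mid, "cluster_id": "unclustered",
             "retained": False, "distance_to_shared": np.nan}
        )
    return pd.DataFrame(rows, columns=["motif_id", "cluster_id", "retained", "distance_to_shared"])


def plot_height_histogram(cluster_set: ClusterSet, path) -> None:
    """Merge-height histogram, the calibration aid for choosing the cutoff."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = cluster_set.linkage_matrix[:, 2]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(heights, bins=30, color="#4477aa")
    ax.axvline(cluster_set.cutoff, color="#cc3311", label=f"cutoff={cluster_set.cutoff}")
    ax.set_xlabel("merge height")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
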