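"""Hierarchical clustering of quantitative enrichment profiles.

Profiles are clustered with the uncentred Pearson correlation (a cosine-type
similarity that does not mean-centre the vectors) as similarity, using
complete linkage on the distance d = 1 - r. Clusters of distinct protein
enrichment are extracted by cutting the dendrogram at a similarity threshold
(r >= 0.80 by default) and labelled active / inactive / unenriched from the
median log2 fold change of their members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .quantify import round_half_up

__all__ = [
    "profile_matrix",
    "uncentred_pearson",
    "uncentred_distance_matrix",
    "hclust_complete",
    "extract_clusters",
    "label_clusters",
    "adhesome_coverage",
    "ClusterTree",
    "to_newick",
]


def profile_matrix(
    profiles: pd.DataFrame,
    floor: float | None = None,
    centre: bool = True,
) -> pd.DataFrame:
    """Feature matrix for enrichment-profile clustering.

    Per-replicate summed NSC values are log2-transformed after adding a
    pseudo-count ``floor`` (default: half the smallest positive value) and,
    by default, median-centred per protein. Centring makes the uncentred
    Pearson similarity compare enrichment direction rather than overall
    abundance: unenriched proteins become near-zero vectors while enriched
    proteins point along their condition axis.
    """
    m = profiles.to_numpy(dtype=float)
    if floor is None:
        positive = m[m > 0]
        if positive.size == 0:
            raise ValueError("profile matrix has no positive entries")
        floor = positive.min() / 2.0
    logm = pd.DataFrame(np.log2(m + floor), index=profiles.index, columns=profiles.columns)
    if centre:
        logm = logm.sub(logm.median(axis=1), axis=0)
    return logm


def uncentred_pearson(x, y) -> float:
    """Uncentred Pearson correlation r = sum(x*y) / sqrt(sum(x^2) sum(y^2)).

    Defined as 0 when either vector is all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float((x * y).sum() / (nx * ny))


def uncentred_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise distance 1 - r_uncentred between the rows of ``matrix``.

    Zero rows have r = 0 (distance 1) against everything, including each other.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("non-finite entries in profile matrix")
    norms = np.sqrt((m * m).sum(axis=1))
    safe = np.where(norms == 0.0, 1.0, norms)
    unit = m / safe[:, None]
    r = unit @ unit.T
    r[norms == 0.0, :] = 0.0
    r[:, norms == 0.0] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterTree:
    """Agglomerative merge tree over profile rows.

    ``linkage`` is a scipy linkage matrix; merge heights are distances
    d = 1 - r, so each internal node's similarity is 1 - height.
    """

    linkage: np.ndarray
    labels: list

    @property
    def node_similarities(self) -> np.ndarray:
        return 1.0 - self.linkage[:, 2]


def hclust_complete(matrix, labels=None) -> ClusterTree:
    """Complete-linkage agglomeration under uncentred-Pearson distance.

    Accepts a 2-D array or a DataFrame (index supplies leaf labels).
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index)
        matrix = matrix.to_numpy()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if labels is None:
        labels = list(range(m.shape[0]))
    d = uncentred_distance_matrix(m)
    condensed = d[np.triu_indices(len(d), k=1)]
    z = hierarchy.linkage(condensed, method="complete")
    return ClusterTree(linkage=z, labels=list(labels))


def extract_clusters(tree: ClusterTree, r_min: float = 0.80) -> list[set]:
    """Maximal subtrees whose node similarity is >= ``r_min``.

    Equivalent to cutting the dendrogram at distance 1 - r_min (inclusive).
    Singleton clusters are allowed. Returns a partition of the leaves.
    """
    if not (-1.0 < r_min <= 1.0):
        raise ValueError(f"r_min must be in (-1, 1], got {r_min}")
    flat = hierarchy.fcluster(tree.linkage, t=1.0 - r_min, criterion="distance")
    clusters: dict[int, set] = {}
    for leaf, cid in zip(tree.labels, flat):
        clusters.setdefault(int(cid), set()).add(leaf)
    return [clusters[cid] for cid in sorted(clusters)]


def label_clusters(
    clusters: list[set],
    log2fc: pd.Series,
    neutral_band: float = 0.58,
) -> pd.DataFrame:
    """Assign each cluster an enrichment label from its median log2 fold change.

    active if median > +neutral_band, inactive if < -neutral_band, else
    unenriched. The default band of 0.58 log2 units corresponds to the
    1.5-fold enrichment threshold used for overrepresentation filtering.

    Returns a protein-indexed DataFrame with ``cluster_id`` and ``label``.
    """
    rows = []
    for cid, members in enumerate(clusters):
        if not members:
            raise ValueError(f"empty cluster {cid}")
        med = float(np.median([log2fc[p] for p in members]))
        if med > neutral_band:
            lab = "active"
        elif med < -neutral_band:
            lab = "inactive"
        else:
            lab = "unenriched"
        for p in sorted(members, key=str):
            rows.append((p, cid, lab))
    out = pd.DataFrame(rows, columns=["protein", "cluster_id", "label"])
    return out.set_index("protein")


@dataclass(frozen=True)
class AdhesomeCoverage:
    n_inventory: int
    n_identified: int
    pct_identified: int
    n_state_specific: int
    pct_state_specific: int
    core_pct_by_label: dict


def adhesome_coverage(
    assignment: pd.DataFrame,
    identified: set,
    inventory: pd.DataFrame,
) -> AdhesomeCoverage:
    """Coverage of the literature-curated adhesome by the identified proteins.

    Parameters
    ----------
    assignment
        Output of :func:`label_clusters` (index protein, column ``label``).
    identified
        All proteins identified by MS.
    inventory
        Adhesome roster indexed by protein with a ``division`` column
        ({"core", "associated"}).

    State-specific members are identified adhesome components assigned to an
    active- or inactive-labelled cluster. ``core_pct_by_label`` gives, for
    each label, the percentage of that label's adhesome members that are core
    components.
    """
    if len(inventory) == 0:
        raise ValueError("empty adhesome inventory")
    inv = set(inventory.index)
    ident = set(identified) & inv
    n_inv, n_id = len(inv), len(ident)
    labels = assignment["label"]
    state = {p for p in ident if p in labels.index and labels[p] in ("active", "inactive")}
    core = set(inventory.index[inventory["division"] == "core"])
    core_pct = {}
    for lab in ("active", "inactive", "unenriched"):
        members = [p for p in ident if p in labels.index and labels[p] == lab]
        if members:
            core_pct[lab] = round_half_up(
                100.0 * sum(p in core for p in members) / len(members)
            )
        else:
            core_pct[lab] = None
    return AdhesomeCoverage(
        n_inventory=n_inv,
        n_identified=n_id,
        pct_identified=round_half_up(100.0 * n_id / n_inv),
        n_state_specific=len(state),
        pct_state_specific=round_half_up(100.0 * len(state) / n_id) if n_id else 0,
        core_pct_by_label=core_pct,
    )


def to_newick(tree: ClusterTree) -> str:
    """Serialize the merge tree as a Newick string with merge-distance branch
    lengths."""
    z = tree.linkage
    n = len(tree.labels)
    heights = {i: 0.0 for i in range(n)}

    def name(i: int) -> str:
        return str(tree.labels[i]).replace(" ", "_")

    nodes: dict[int, str] = {i: name(i) for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"
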