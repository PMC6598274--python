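"""Cross-genome comparison of guide-site availability.

A set of strain catalogs is reduced to a binary presence/absence matrix
over the *guide universe* — the union of distinct guide 20-mers seen in any
strain — and compared by fractional Hamming distance over that shared
universe.  Using one universe for every pair (rather than pairwise unions)
makes the distance a proper metric and matches row-wise Hamming on a single
binary table.  Strains are ordered for display by complete-linkage
hierarchical clustering of the distance matrix.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform


def build_presence_matrix(catalogs: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Strains x guide-universe binary matrix.

    ``catalogs`` maps strain label -> iterable of guide strings (duplicates
    within a strain collapse to presence).  Columns are the lexicographically
    sorted union of guides; rows keep the given strain order.
    """
    labels = list(catalogs)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate strain label")
    guide_sets = {label: set(guides) for label, guides in catalogs.items()}
    universe = sorted(set().union(*guide_sets.values())) if guide_sets else []
    data = np.zeros((len(labels), len(universe)), dtype=np.int8)
    col_index = {g: j for j, g in enumerate(universe)}
    for i, label in enumerate(labels):
        for g in guide_sets[label]:
            data[i, col_index[g]] = 1
    return pd.DataFrame(data, index=labels, columns=universe)


def hamming_distance(row_u: Sequence[int], row_v: Sequence[int]) -> float:
    """Fraction of positions at which two equal-length binary rows differ."""
    u = np.asarray(row_u)
    v = np.asarray(row_v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(u != v))


def distance_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise fractional Hamming distances between strain rows."""
    if len(presence) < 2:
        raise ValueError("need >= 2 strains")
    values = presence.to_numpy()
    n = len(presence)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = hamming_distance(values[i], values[j])
    return pd.DataFrame(out, index=presence.index, columns=presence.index)


def cluster_order(dist: pd.DataFrame) -> list[str]:
    """Dendrogram leaf order from complete-linkage agglomerative clustering.

    Fractional Hamming distances over a shared universe tie frequently (same
    denominator), so the merge loop is written out explicitly with a fixed
    tie rule — equal inter-cluster distances break toward the pair with the
    lower original indices — making the leaf order fully deterministic.
    (scipy's nn-chain linkage gives the same order whenever distances are
    tie-free; it does not pin tie behavior.)  The earlier-created cluster is
    placed on the left, matching dendrogram convention.
    """
    n = len(dist)
    if n < 2:
        raise ValueError("need >= 2 strains to cluster")
    squareform(dist.to_numpy(), checks=True)  # validates symmetry/zero diagonal
    d = dist.to_numpy().astype(float)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}  # cluster -> leaves
    children: dict[int, tuple[int, int]] = {}
    cdist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        _, a, b = min(
            (cdist[(x, y)], x, y)
            for k, x in enumerate(active)
            for y in active[k + 1 :]
        )
        children[next_id] = (a, b)
        members[next_id] = members[a] + members[b]
        active = [x for x in active if x not in (a, b)]
        for x in active:
            cdist[(x, next_id)] = max(
                cdist[(min(x, a), max(x, a))], cdist[(min(x, b), max(x, b))]
            )
        active.append(next_id)
        next_id += 1

    def leaves(cid: int) -> list[int]:
        if cid < n:
            return [cid]
        left, right = children[cid]
        return leaves(left) + leaves(right)

    return [dist.index[i] for i in leaves(active[0])]


def presence_summary(presence: pd.DataFrame) -> pd.DataFrame:
    """Per-strain guide counts and private (single-strain) guide counts."""
    col_sums = presence.sum(axis=0)
    private_cols = presence.columns[col_sums == 1]
    return pd.DataFrame(
        {
            "n_guides": presence.sum(axis=1),
            "n_private_guides": presence[private_cols].sum(axis=1)
            if len(private_cols)
            else 0,
        },
        index=presence.index,
    )


def write_distance_matrix(dist: pd.DataFrame, path: str | Path) -> None:
    dist.to_csv(path, sep="\t", float_format="%.6f", index_label="strain")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
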