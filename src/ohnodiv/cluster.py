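"""Hierarchical clustering of ohnolog pairs.

Two schemes:

* STRE-count profiles across non-WGH and outgroup species, using the
  correlation distance computed over pairwise-complete columns (missing =
  no ortholog), average/UPGMA linkage, and flat clusters from the
  inconsistency criterion (threshold 1.1, depth-2 windows).
* GO-slim indicator vectors per pair member (plus a metabolic-map indicator
  weighted 4 so map pairs co-cluster), Euclidean distance, Ward linkage.
"""

from __future__ import annotations

import warnings
from typing import List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .orthology import OhnologPair


def correlation_distance_matrix(profiles: pd.DataFrame, min_shared: int = 3) -> np.ndarray:
    """1 - Pearson r between rows over pairwise-complete columns.

    Rows sharing fewer than ``min_shared`` observed columns, or constant on
    the shared columns, get the neutral distance 1 (zero correlation).
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two rows")
    D = np.zeros((n, n))
    mask = np.isfinite(X)
    for i in range(n):
        for j in range(i + 1, n):
            shared = mask[i] & mask[j]
            d = 1.0
            if shared.sum() >= min_shared:
                xi, xj = X[i, shared], X[j, shared]
                if xi.std() > 0 and xj.std() > 0:
                    r = float(np.corrcoef(xi, xj)[0, 1])
                    d = float(np.clip(1.0 - r, 0.0, 2.0))
            D[i, j] = D[j, i] = d
    return D


def upgma(distance: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of a symmetric distance matrix.

    Returns a scipy-format linkage: one row (i, j, height, size) per merge.
    Inter-cluster distance is the size-weighted mean of member pairwise
    distances.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be a square matrix")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(D, checks=False), method="average")


def ward(vectors: np.ndarray) -> np.ndarray:
    """Ward linkage on Euclidean distances between observation vectors."""
    return hierarchy.linkage(np.asarray(vectors, dtype=float), method="ward")


def inconsistency(Z: np.ndarray, depth: int = 2, ddof: int = 1) -> np.ndarray:
    """Inconsistency coefficient of every merge.

    For each merge the statistic window holds the heights of the merges up
    to ``depth`` levels below it, itself included (depth 2: the merge and
    its non-singleton children).  The coefficient is (height - mean)/sd over
    the window, 0 where the sd is 0.  ``ddof=1`` (sample sd) matches the
    common library dialect; ``ddof=0`` is the population alternative.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1

    def window(node: int, level: int) -> List[float]:
        # node >= n indexes merge node - n
        if node < n or level == 0:
            return []
        row = Z[node - n]
        heights = [row[2]]
        for child in (int(row[0]), int(row[1])):
            heights.extend(window(child, level - 1))
        return heights

    coeff = np.zeros(n - 1)
    for k in range(n - 1):
        hs = np.array(window(k + n, depth))
        sd = hs.std(ddof=ddof) if hs.size > ddof else 0.0
        coeff[k] = 0.0 if sd == 0 else (Z[k, 2] - hs.mean()) / sd
    return coeff


def inconsistency_flat_clusters(
    Z: np.ndarray, t: float = 1.1, depth: int = 2, ddof: int = 1
) -> np.ndarray:
    """Flat clusters: maximal subtrees whose merges are all consistent.

    A merge node and its leaves form one flat cluster when no merge in its
    subtree (itself included) has an inconsistency coefficient above ``t``;
    leaves not covered by any such subtree become singleton clusters.
    Labels are 1-based consecutive integers over the leaves.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    coeff = inconsistency(Z, depth, ddof)
    ok = np.zeros(n - 1, dtype=bool)
    for k in range(n - 1):  # children precede parents in a linkage
        good = coeff[k] <= t
        for child in (int(Z[k, 0]), int(Z[k, 1])):
            if child >= n:
                good = good and ok[child - n]
        ok[k] = good
    labels = np.zeros(n, dtype=int)
    next_label = [0]

    def leaves(node: int) -> List[int]:
        if node < n:
            return [node]
        return leaves(int(Z[node - n, 0])) + leaves(int(Z[node - n, 1]))

    def assign(node: int):
        if node < n:
            next_label[0] += 1
            labels[node] = next_label[0]
            return
        k = node - n
        if ok[k]:
            next_label[0] += 1
            for leaf in leaves(node):
                labels[leaf] = next_label[0]
        else:
            assign(int(Z[k, 0]))
            assign(int(Z[k, 1]))

    assign(2 * n - 2)
    return labels


def flat_clusters_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut the tree into exactly ``k`` flat clusters (highest merges undone)."""
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def build_stre_profiles(
    pairs: Sequence[OhnologPair],
    stre_counts_by_species: Mapping[str, Mapping[str, float]],
    species: Sequence[str],
) -> pd.DataFrame:
    """Rows = ohnolog pairs, columns = species, cells = ortholog STRE counts.

    Only the designated (non-WGH + outgroup) species enter.  A species cell
    is the mean STRE count over that species' orthologs with promoter scans,
    and missing when the pair has no ortholog there.  Pairs with no ortholog
    in any listed species are dropped with a warning.
    """
    rows = {}
    for pair in pairs:
        cells = {}
        for sp in species:
            counts = stre_counts_by_species.get(sp, {})
            vals = [counts[g] for g in pair.orthologs.get(sp, ()) if g in counts]
            cells[sp] = float(np.mean(vals)) if vals else np.nan
        if all(np.isnan(v) for v in cells.values()):
            warnings.warn(f"pair {pair.pillar_id}: no ortholog in any profiled species")
            continue
        rows[pair.pillar_id] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(species))


def go_indicator_vectors(
    pairs: Sequence[OhnologPair],
    go_map: Mapping[str, Set[str]],
    terms: Sequence[str],
    metabolic_map_pairs: Set[str] = frozenset(),
    metabolic_weight: float = 4.0,
) -> pd.DataFrame:
    """Per-pair 0/1 vectors over (term x member) plus a weighted map indicator.

    The metabolic-map coordinate is ``metabolic_weight`` for pairs on the
    map and 0 otherwise; the large value forces map pairs together under
    Euclidean distances.
    """
    cols = [f"{t}|{m}" for t in terms for m in ("a", "b")] + ["metabolic_map"]
    rows = {}
    for pair in pairs:
        vec = []
        for t in terms:
            vec.append(1.0 if t in go_map.get(pair.member_a, ()) else 0.0)
            vec.append(1.0 if t in go_map.get(pair.member_b, ()) else 0.0)
        vec.append(metabolic_weight if pair.pillar_id in metabolic_map_pairs else 0.0)
        rows[pair.pillar_id] = vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def ward_go_clusters(
    pairs: Sequence[OhnologPair],
    go_map: Mapping[str, Set[str]],
    terms: Sequence[str],
    metabolic_map_pairs: Set[str] = frozenset(),
    metabolic_weight: float = 4.0,
    t: float = 1.1,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Ward-cluster pairs on GO indicator vectors; returns (Z, labels, vectors)."""
    vectors = go_indicator_vectors(pairs, go_map, terms, metabolic_map_pairs, metabolic_weight)
    Z = ward(vectors.to_numpy())
    labels = inconsistency_flat_clusters(Z, t=t)
    return Z, labels, vectors


def linkage_table(Z: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(Z, columns=["node_i", "node_j", "height", "size"])


def to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage as a Newick string with merge-height branch lengths."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2]

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        i, j = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = Z[node - n, 2]
        return "({}:{:g},{}:{:g})".format(
            render(i), h - height(i), render(j), h - height(j)
        )

    return render(2 * n - 2) + ";"
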