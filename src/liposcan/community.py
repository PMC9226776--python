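"""LPGM normalization and habitat comparison statistics.

Per-sample hit counts (lipolytic proteins per family, or per genus of
origin) are normalized to LPGM — Lipolytic hits Per Gigabase of assembled
metagenome per Million predicted genes:

    LPGM = count * (1e9 / assembly_size_bp) * (1e6 / gene_count)

so samples of different sequencing depth and gene density are comparable.
On the LPGM matrix the module computes Bray-Curtis dissimilarities,
agglomerative Ward clustering (the "ward.D" convention: Lance-Williams
update applied to the raw dissimilarities, no pre-squaring), the rank-based
ANOSIM permutation test for habitat structure, point-biserial
indicator-association analysis linking categories (genera) to habitats or
habitat combinations, and the habitat-genus bipartite association network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import rankdata

__all__ = [
    "SampleMetadata",
    "AnosimResult",
    "IndicatorAssociation",
    "lpgm_normalize",
    "log_transform",
    "bray_curtis",
    "ward_cluster",
    "dendrogram_to_newick",
    "anosim",
    "indicator_analysis",
    "bipartite_network",
]


@dataclass
class SampleMetadata:
    sample_id: str
    habitat: str
    assembly_size: float  # bp of assembled metagenome
    gene_count: float  # predicted genes

    def __post_init__(self) -> None:
        if self.assembly_size <= 0 or self.gene_count <= 0:
            raise ValueError(f"sample {self.sample_id!r}: sizes must be positive")
        if not self.habitat:
            raise ValueError(f"sample {self.sample_id!r}: empty habitat label")


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "habitat", "assembly_size", "gene_count"}
    if not need <= set(df.columns):
        raise ValueError(f"metadata TSV needs columns {sorted(need)}")
    return [
        SampleMetadata(str(r.sample_id), str(r.habitat), float(r.assembly_size), float(r.gene_count))
        for r in df.itertuples()
    ]


def lpgm_normalize(
    counts: pd.DataFrame, metadata: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Normalize a samples x categories count table to LPGM units.

    ``counts`` rows are samples, columns are categories (family or genus).
    Every sample row must have metadata; zero counts stay exactly zero.
    """
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in counts.index if s not in meta]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    factors = np.array(
        [(1e9 / meta[s].assembly_size) * (1e6 / meta[s].gene_count) for s in counts.index]
    )
    return counts.mul(factors, axis=0)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Heatmap transform log10(x + 1): monotone, maps 0 to 0."""
    return np.log10(matrix + 1.0)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y), in [0, 1].

    A pair of all-zero rows has an undefined quotient; the distance is
    defined as 0 with a warning.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    n = x.shape[0]
    d = np.zeros((n, n))
    zero_rows = ~x.any(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if zero_rows[i] and zero_rows[j]:
                warnings.warn("all-zero sample pair: Bray-Curtis defined as 0")
                continue
            d[i, j] = d[j, i] = _braycurtis(x[i], x[j])
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# Ward clustering ("ward.D": Lance-Williams on raw dissimilarities)


def ward_cluster(distance: pd.DataFrame) -> list[tuple[frozenset, frozenset, float]]:
    """Agglomerative Ward clustering, ward.D convention.

    The Lance-Williams Ward update
        d(k, i+j) = ((n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)) / (n_i+n_j+n_k)
    is applied to the dissimilarities as given (no squaring).  Ties are
    broken lexicographically on cluster labels (a cluster's label is its
    smallest member label), so the merge sequence is deterministic.

    Returns the merge list: (members_a, members_b, height) per merge.
    """
    labels = [str(s) for s in distance.index]
    n = len(labels)
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    mat = distance.to_numpy(dtype=float)
    clusters: list[frozenset] = [frozenset([a]) for a in labels]
    dist: dict[tuple[frozenset, frozenset], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset_pair(clusters[i], clusters[j])] = mat[i, j]
    sizes = {c: 1 for c in clusters}
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            key = frozenset_pair(a, b)
            h = dist[key]
            tag = (h, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or tag < best[0]:
                best = (tag, a, b)
        _, a, b = best
        h = dist[frozenset_pair(a, b)]
        merged = a | b
        merges.append((a, b, h))
        na, nb = sizes[a], sizes[b]
        new_clusters = [c for c in clusters if c not in (a, b)]
        for c in new_clusters:
            nc = sizes[c]
            dk = (
                (na + nc) * dist[frozenset_pair(a, c)]
                + (nb + nc) * dist[frozenset_pair(b, c)]
                - nc * h
            ) / (na + nb + nc)
            dist[frozenset_pair(merged, c)] = dk
        clusters = new_clusters + [merged]
        sizes[merged] = na + nb
    return merges


def frozenset_pair(a: frozenset, b: frozenset) -> frozenset:
    return frozenset([a, b])


def dendrogram_to_newick(merges: list[tuple[frozenset, frozenset, float]]) -> str:
    """Render a merge list as a Newick string with branch lengths from heights."""
    node_repr: dict[frozenset, str] = {}
    height: dict[frozenset, float] = {}
    for a, b, h in merges:
        for part in (a, b):
            if part not in node_repr:
                node_repr[part] = next(iter(part)) if len(part) == 1 else None
                height[part] = 0.0
        ra = node_repr[a]
        rb = node_repr[b]
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        merged = a | b
        node_repr[merged] = f"({ra}:{la:g},{rb}:{lb:g})"
        height[merged] = h
    root = merges[-1][0] | merges[-1][1]
    return node_repr[root] + ";"


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / denom


def anosim(
    distance: pd.DataFrame,
    groups: Sequence[str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: rank-based R with a permutation p-value.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (n(n-1)/4), ranks over all pairwise distances with midranks
    for ties.  p uses the add-one convention over seeded label permutations:
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations).
    """
    groups = np.asarray(groups)
    n = len(groups)
    if n != distance.shape[0]:
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with < 2 members: {small}")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    iu = np.triu_indices(n, k=1)
    dvec = distance.to_numpy(dtype=float)[iu]
    ranks = rankdata(dvec)
    denom = n * (n - 1) / 4.0
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, same, denom)

    rng = np.random.default_rng(seed)
    count_ge = 0
    gi = np.arange(n)
    for _ in range(n_permutations):
        perm = rng.permutation(gi)
        pg = groups[perm]
        same_p = pg[iu[0]] == pg[iu[1]]
        if _anosim_r(ranks, same_p, denom) >= r_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return AnosimResult(R=float(r_obs), p_value=float(p), n_permutations=n_permutations, seed=seed)


def anosim_exact(distance: pd.DataFrame, groups: Sequence[str]) -> tuple[float, float]:
    """R and exact p over all distinct label permutations (small n only)."""
    groups = np.asarray(groups)
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(distance.to_numpy(dtype=float)[iu])
    denom = n * (n - 1) / 4.0
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, same, denom)
    count_ge = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        pg = groups[list(perm)]
        same_p = pg[iu[0]] == pg[iu[1]]
        total += 1
        if _anosim_r(ranks, same_p, denom) >= r_obs - 1e-12:
            count_ge += 1
    return float(r_obs), count_ge / total


# ---------------------------------------------------------------------------
# Indicator (point-biserial) associations


@dataclass
class IndicatorAssociation:
    category: str
    habitats: tuple[str, ...]
    r: float
    p_value: float
    mean_lpgm: float


def indicator_analysis(
    matrix: pd.DataFrame,
    habitats: Sequence[str],
    max_subset_size: int = 3,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[IndicatorAssociation]:
    """Point-biserial indicator associations between categories and habitat subsets.

    For every category and every habitat subset (sizes 1..max_subset_size,
    never the full habitat set), r is the Pearson correlation between the
    category's abundance vector and the subset's 0/1 membership vector.
    Each category reports its best subset (maximum r); the permutation
    p-value (add-one convention) permutes the abundance vector.  Only
    positive, significant associations (r > 0, p <= alpha) are returned.
    A constant abundance vector has r defined as 0 and is never significant.
    """
    habitats = np.asarray([str(h) for h in habitats])
    if len(habitats) != matrix.shape[0]:
        raise ValueError("habitats length must match matrix rows")
    uniq, counts = np.unique(habitats, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every habitat needs >= 2 samples")
    subsets = []
    for size in range(1, min(max_subset_size, len(uniq) - 1) + 1):
        subsets.extend(itertools.combinations(sorted(uniq), size))
    # membership matrix: n_subsets x n_samples
    member = np.array([[h in s for h in habitats] for s in subsets], dtype=float)
    x = matrix.to_numpy(dtype=float)  # n_samples x n_categories
    n = x.shape[0]

    def best_r(values: np.ndarray) -> np.ndarray:
        """r of every category against every subset; returns (n_cat, n_subsets)."""
        xc = values - values.mean(axis=0, keepdims=True)
        mc = member - member.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc**2).sum(axis=0))
        sm = np.sqrt((mc**2).sum(axis=1))
        num = xc.T @ mc.T  # n_cat x n_subsets
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / np.outer(sx, sm)
        r[~np.isfinite(r)] = 0.0
        return r

    r_all = best_r(x)
    best_idx = r_all.argmax(axis=1)
    r_obs = r_all[np.arange(r_all.shape[0]), best_idx]

    rng = np.random.default_rng(seed)
    count_ge = np.zeros(r_all.shape[0])
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = best_r(x[perm])
        count_ge += r_perm.max(axis=1) >= r_obs - 1e-12
    p = (1 + count_ge) / (1 + n_permutations)

    mean_lpgm = x.mean(axis=0)
    out = []
    for ci, cat in enumerate(matrix.columns):
        if r_obs[ci] > 0 and p[ci] <= alpha:
            out.append(
                IndicatorAssociation(
                    category=str(cat),
                    habitats=tuple(subsets[best_idx[ci]]),
                    r=float(r_obs[ci]),
                    p_value=float(p[ci]),
                    mean_lpgm=float(mean_lpgm[ci]),
                )
            )
    return out


def bipartite_network(
    associations: Sequence[IndicatorAssociation],
    min_mean_lpgm: float = 0.5,
) -> nx.Graph:
    """Habitat-genus bipartite network from significant associations.

    Categories with mean LPGM below ``min_mean_lpgm`` are dropped.  Each
    category node carries an ``association`` flag: unique (1 habitat),
    pair (2) or multi (> 2).
    """
    g = nx.Graph()
    for assoc in associations:
        if assoc.mean_lpgm < min_mean_lpgm:
            continue
        k = len(assoc.habitats)
        flag = "unique" if k == 1 else "pair" if k == 2 else "multi"
        g.add_node(assoc.category, bipartite="category", association=flag,
                   mean_lpgm=assoc.mean_lpgm)
        for hab in assoc.habitats:
            g.add_node(hab, bipartite="habitat")
            g.add_edge(hab, assoc.category, weight=assoc.r)
    return g


def network_edge_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"habitat": a if g.nodes[a].get("bipartite") == "habitat" else b,
         "category": b if g.nodes[a].get("bipartite") == "habitat" else a,
         "r": data["weight"]}
        for a, b, data in g.edges(data=True)
    ]
    return pd.DataFrame(rows)
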