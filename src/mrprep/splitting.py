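"""Decompose predicted models into rigid, domain-like search models.

Multi-domain predictions often place their domains in relative orientations
that differ from the crystal, so molecular replacement works better when the
model is cut into rigid units placed independently.  Two routes are provided:

* **Coordinate clustering** — Calpha positions are clustered in space
  (agglomerative Ward by default, seeded k-means as an alternative) into a
  user-chosen number of groups.  The default sweep produces the 1-, 2- and
  3-cluster splits.
* **PAE partitioning** — the predicted-aligned-error matrix is turned into a
  weighted residue graph (edge where the symmetrized PAE is below a cutoff,
  weight increasing as the error shrinks) and partitioned by greedy
  modularity maximization; rigid units show up as low-error blocks.

Both routes post-process undersized groups by merging them into the nearest
remaining domain, and both are deterministic (ties broken by lower residue
index / lower domain id).  Domains may be discontiguous in sequence: a
spatial cluster is free to join sequence-distant regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import greedy_modularity_communities
from sklearn.cluster import AgglomerativeClustering, KMeans

from .model_io import PAEMatrix, PredictedModel

__all__ = [
    "DomainPartition",
    "CoordSplitParams",
    "PAESplitParams",
    "split_by_coordinates",
    "split_by_pae",
    "default_split_sweep",
    "enforce_min_domain",
    "extract_search_models",
]

REMOVED = "removed"


@dataclass
class CoordSplitParams:
    """Parameters of the coordinate-clustering split."""

    n_clusters: int = 1
    linkage: str = "ward"    # "ward" (deterministic default) or "kmeans"
    seed: int = 0            # used by kmeans only
    min_domain: int = 20     # smallest domain kept as its own search model

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.linkage not in ("ward", "kmeans"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.min_domain < 1:
            raise ValueError("min_domain must be >= 1")


@dataclass
class PAESplitParams:
    """Parameters of the PAE-graph split."""

    pae_power: float = 1.0    # edge weight = (1 / max(pae, floor)) ** power
    pae_floor: float = 0.25   # Angstrom; avoids infinite weight at PAE 0
    edge_cutoff: float = 10.0  # Angstrom; no edge above this symmetrized PAE
    resolution: float = 1.0   # modularity resolution
    min_domain: int = 20

    def __post_init__(self) -> None:
        if min(self.pae_power, self.pae_floor, self.edge_cutoff, self.resolution) <= 0:
            raise ValueError("PAE split parameters must be positive")
        if self.min_domain < 1:
            raise ValueError("min_domain must be >= 1")


@dataclass
class DomainPartition:
    """Disjoint groups of residue indices with method provenance.

    ``domains`` are sorted index lists (indices into model residue order),
    numbered by ascending first residue index.  ``labels`` has one entry per
    model residue: the domain id, or ``"removed"`` for residues outside the
    partition.
    """

    domains: list[list[int]]
    method: str
    params: dict = field(default_factory=dict)
    labels: list = field(default_factory=list)

    @classmethod
    def from_labels(cls, labels: Sequence, method: str, params: dict | None = None) -> "DomainPartition":
        """Build from per-residue labels; non-"removed" labels become domains."""
        groups: dict[object, list[int]] = {}
        for i, lab in enumerate(labels):
            if lab == REMOVED:
                continue
            groups.setdefault(lab, []).append(i)
        domains = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
        final = [REMOVED] * len(labels)
        for domain_id, domain in enumerate(domains):
            for i in domain:
                final[i] = domain_id
        return cls(domains=domains, method=method, params=params or {}, labels=final)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def sizes(self) -> list[int]:
        return [len(d) for d in self.domains]

    def n_removed(self) -> int:
        return sum(1 for lab in self.labels if lab == REMOVED)

    def validate(self, n_residues: int | None = None) -> None:
        seen: set[int] = set()
        for domain_id, domain in enumerate(self.domains):
            if not domain:
                raise ValueError(f"empty domain {domain_id}")
            if seen & set(domain):
                raise ValueError("domains are not disjoint")
            seen.update(domain)
        if n_residues is not None and len(self.labels) != n_residues:
            raise ValueError("labels length does not match residue count")
        for i, lab in enumerate(self.labels):
            if lab == REMOVED:
                if i in seen:
                    raise ValueError(f"residue {i} both removed and in a domain")
            elif i not in self.domains[lab]:
                raise ValueError(f"label of residue {i} disagrees with domains")
        if seen != {i for i, lab in enumerate(self.labels) if lab != REMOVED}:
            raise ValueError("domain union disagrees with labels")
        firsts = [d[0] for d in self.domains]
        if firsts != sorted(firsts):
            raise ValueError("domain ids not ordered by first residue index")


# ---------------------------------------------------------------------------
# coordinate clustering


def _calpha_info(model: PredictedModel) -> tuple[np.ndarray, list[int], list[int]]:
    """Coordinates of Calpha-bearing residues and the map back to all residues.

    Returns (coords of Calpha residues, their residue indices, and for every
    residue the index of its own or nearest preceding Calpha-bearing residue).
    """
    has_ca = model.has_calpha()
    coords_all = model.representative_coordinates()
    ca_indices = [i for i, h in enumerate(has_ca) if h]
    if not ca_indices:
        raise ValueError("no atoms: model has no Calpha atoms")
    anchor: list[int] = []
    last = ca_indices[0]
    for i, h in enumerate(has_ca):
        if h:
            last = i
        anchor.append(last)
    return coords_all[ca_indices], ca_indices, anchor


def split_by_coordinates(
    model: PredictedModel, params: CoordSplitParams | None = None
) -> DomainPartition:
    """Cluster Calpha positions into ``n_clusters`` spatial domains.

    Ward agglomerative clustering is the deterministic default; k-means uses
    the seed in ``params``.  Residues without a Calpha atom inherit the
    cluster of the nearest preceding Calpha-bearing residue.  Undersized
    clusters are merged by :func:`enforce_min_domain`.
    """
    params = params or CoordSplitParams()
    coords, ca_indices, anchor = _calpha_info(model)
    n = len(ca_indices)
    if params.n_clusters > n:
        raise ValueError(
            f"too many clusters: {params.n_clusters} requested, {n} Calpha residues"
        )
    if params.n_clusters == 1:
        raw = np.zeros(n, dtype=int)
    elif params.linkage == "ward":
        raw = AgglomerativeClustering(
            n_clusters=params.n_clusters, linkage="ward"
        ).fit_predict(coords)
    else:
        raw = KMeans(
            n_clusters=params.n_clusters, random_state=params.seed, n_init=10
        ).fit_predict(coords)

    by_ca = dict(zip(ca_indices, raw.tolist()))
    labels = [by_ca[anchor[i]] for i in range(model.n_residues)]
    partition = DomainPartition.from_labels(
        labels, method="coords", params=asdict(params)
    )
    return enforce_min_domain(partition, model, params.min_domain)


def default_split_sweep(model: PredictedModel) -> list[DomainPartition]:
    """Coordinate splits for 1, 2 and 3 clusters, in that order.

    This is the default preparation sweep: the whole model plus its two- and
    three-way spatial dissections, each set usable as independent search
    models.  Models with fewer residues than a cluster count are skipped with
    a warning.
    """
    n_ca = sum(model.has_calpha())
    sweep: list[DomainPartition] = []
    for k in (1, 2, 3):
        if k > n_ca:
            warnings.warn(
                f"sweep truncated: {n_ca} residues cannot form {k} clusters",
                stacklevel=2,
            )
            break
        sweep.append(split_by_coordinates(model, CoordSplitParams(n_clusters=k)))
    return sweep


# ---------------------------------------------------------------------------
# PAE graph partitioning


def _pae_communities(sym: np.ndarray, params: PAESplitParams) -> list[list[int]]:
    n = sym.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            s = sym[i, j]
            if s <= params.edge_cutoff:
                weight = (1.0 / max(s, params.pae_floor)) ** params.pae_power
                graph.add_edge(i, j, weight=weight)

    groups: list[list[int]] = []
    components = sorted(nx.connected_components(graph), key=min)
    for component in components:
        if len(component) == 1:
            groups.append(sorted(component))
            continue
        sub = graph.subgraph(component)
        communities = greedy_modularity_communities(
            sub, weight="weight", resolution=params.resolution
        )
        groups.extend(sorted(c) for c in sorted(communities, key=min))
    return groups


def split_by_pae(
    pae: PAEMatrix,
    params: PAESplitParams | None = None,
    model: PredictedModel | None = None,
) -> DomainPartition:
    """Partition residues into rigid units by parsing the PAE matrix.

    The matrix is symmetrized as s = (PAE + PAE^T) / 2; residues i, j are
    connected when s_ij <= edge_cutoff with weight (1/max(s, floor))^power,
    and the graph is split by deterministic greedy modularity maximization,
    each connected component independently.  When the accompanying model is
    supplied its residue count is checked against the matrix and undersized
    groups are merged through :func:`enforce_min_domain`; without a model
    they are merged into the group with the smallest mean symmetrized PAE.
    """
    params = params or PAESplitParams()
    if model is not None and model.n_residues != pae.size:
        raise ValueError(
            f"PAE/model length mismatch: {pae.size} != {model.n_residues}"
        )
    sym = pae.symmetrized()
    groups = _pae_communities(sym, params)
    labels = [0] * pae.size
    for group_id, group in enumerate(groups):
        for i in group:
            labels[i] = group_id
    partition = DomainPartition.from_labels(labels, method="pae", params=asdict(params))
    if model is not None:
        return enforce_min_domain(partition, model, params.min_domain)
    return _enforce_min_domain_pae(partition, sym, params.min_domain)


def _merge_smallest(
    partition: DomainPartition, min_domain: int, distance
) -> DomainPartition:
    """Repeatedly merge the smallest undersized domain into its nearest one.

    ``distance(a, b)`` gives the separation between domains a and b (index
    lists); ties go to the lower domain id.  Stops when every domain reaches
    ``min_domain`` or one domain remains.
    """
    domains = [list(d) for d in partition.domains]
    while len(domains) > 1:
        undersized = [
            (len(d), i) for i, d in enumerate(domains) if len(d) < min_domain
        ]
        if not undersized:
            break
        _, src = min(undersized)
        best = min(
            (distance(domains[src], d), i)
            for i, d in enumerate(domains)
            if i != src
        )[1]
        domains[best] = sorted(domains[best] + domains[src])
        del domains[src]
    labels: list = list(partition.labels)
    assigned = {i for d in domains for i in d}
    for i, lab in enumerate(labels):
        if lab != REMOVED and i not in assigned:
            labels[i] = REMOVED  # unreachable; defensive
    relabel = [REMOVED] * len(labels)
    order = sorted(range(len(domains)), key=lambda k: domains[k][0])
    for new_id, old in enumerate(order):
        for i in domains[old]:
            relabel[i] = new_id
    return DomainPartition.from_labels(relabel, partition.method, partition.params)


def enforce_min_domain(
    partition: DomainPartition, model: PredictedModel, min_domain: int
) -> DomainPartition:
    """Merge domains smaller than ``min_domain`` into the nearest by centroid.

    Nearness is Euclidean distance between domain Calpha centroids; ties go
    to the lower domain id.  Repeats until stable or one domain remains.
    """
    coords = model.representative_coordinates()

    def centroid_distance(a: list[int], b: list[int]) -> float:
        return float(np.linalg.norm(coords[a].mean(axis=0) - coords[b].mean(axis=0)))

    return _merge_smallest(partition, min_domain, centroid_distance)


def _enforce_min_domain_pae(
    partition: DomainPartition, sym: np.ndarray, min_domain: int
) -> DomainPartition:
    def mean_pae(a: list[int], b: list[int]) -> float:
        return float(sym[np.ix_(a, b)].mean())

    return _merge_smallest(partition, min_domain, mean_pae)


# ---------------------------------------------------------------------------
# search-model extraction


def extract_search_models(
    model: PredictedModel, partition: DomainPartition
) -> list[PredictedModel]:
    """One model per domain, atoms and B-column values carried over unchanged."""
    partition.validate(model.n_residues)
    return [model.subset(domain) for domain in partition.domains]
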