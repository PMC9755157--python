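"""Overlapping link communities over the full-study association network.

Communities are detected on *edges*: two edges sharing a node are as
similar as the Jaccard overlap of the inclusive neighbourhoods of their
non-shared endpoints, edges are agglomerated by single linkage, and the
dendrogram is cut at the height maximizing partition density

    D = (2/M) * sum_c m_c * (m_c - n_c + 1) / ((n_c - 1) * (n_c - 2))

where community c holds m_c edges over n_c nodes (single-edge communities
contribute 0).  Because edge communities overlap at nodes, an individual
can belong to several communities; its permutation 'group' is then the
union of those communities' members.  These groups define the strata of
the data-stream permutation null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .netbuild import AssociationMatrix


@dataclass
class LinkCommunityCover:
    """Edge-community assignment with node multi-membership."""

    edges: list  # list of (node, node), lexicographic order
    edge_community: np.ndarray  # community id per edge
    node_communities: dict  # node -> frozenset of community ids
    membership_fraction: dict  # node -> {community: share of interactions}
    partition_density: float
    linkage_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def n_communities(self) -> int:
        return len(set(self.edge_community.tolist()))

    def members(self, community) -> frozenset:
        out = set()
        for e, c in zip(self.edges, self.edge_community):
            if c == community:
                out.update(e)
        return frozenset(out)


@dataclass
class GroupAssignment:
    """Disjoint permutation strata derived from an (overlapping) cover.

    Overlapping structured communities are merged transitively, so a
    multi-community node and all members of its communities share one
    group; single-edge communities do not chain groups together (see
    :func:`assign_groups`).  Roster nodes without edges become flagged
    singleton groups.
    """

    group_of: dict  # node -> group id
    groups: dict  # group id -> frozenset of nodes
    singletons: frozenset = frozenset()


def _edge_list(weights: np.ndarray):
    ii, jj = np.nonzero(np.triu(weights, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def partition_density(edge_labels, edges) -> float:
    """Average over edges of normalized within-community edge density."""
    edge_labels = np.asarray(edge_labels)
    m_total = len(edges)
    if m_total == 0:
        return 0.0
    total = 0.0
    for c in np.unique(edge_labels):
        members = set()
        m_c = 0
        for e, lab in zip(edges, edge_labels):
            if lab == c:
                members.update(e)
                m_c += 1
        n_c = len(members)
        if n_c > 2:
            total += m_c * (m_c - n_c + 1) / ((n_c - 1) * (n_c - 2))
    return 2.0 * total / m_total


def _edge_similarity_matrix(weights: np.ndarray, edges, weighted: bool) -> np.ndarray:
    """Pairwise similarity for edges sharing a node; 0 for disjoint pairs."""
    n = weights.shape[0]
    binary = (weights > 0).astype(float)
    if weighted:
        # Tanimoto on rows with the self-affinity set to the mean edge weight
        vec = weights.copy()
        deg = binary.sum(axis=1)
        strength = weights.sum(axis=1)
        self_aff = np.divide(strength, deg, out=np.zeros(n), where=deg > 0)
        vec[np.arange(n), np.arange(n)] = self_aff
    else:
        vec = binary.copy()
        vec[np.arange(n), np.arange(n)] = 1.0  # inclusive neighbourhood

    m = len(edges)
    sim = np.zeros((m, m))
    incident = {}
    for e_idx, (i, j) in enumerate(edges):
        incident.setdefault(i, []).append(e_idx)
        incident.setdefault(j, []).append(e_idx)
    for _, edge_ids in incident.items():
        for x in range(len(edge_ids)):
            for y in range(x + 1, len(edge_ids)):
                e1, e2 = edge_ids[x], edge_ids[y]
                shared = set(edges[e1]) & set(edges[e2])
                if not shared:
                    continue
                k = shared.pop()
                a = [v for v in edges[e1] if v != k][0]
                b = [v for v in edges[e2] if v != k][0]
                va, vb = vec[a], vec[b]
                if weighted:
                    num = float(va @ vb)
                    den = float(va @ va + vb @ vb - va @ vb)
                else:
                    num = float(np.minimum(va, vb).sum())
                    den = float(np.maximum(va, vb).sum())
                s = num / den if den > 0 else 0.0
                sim[e1, e2] = max(sim[e1, e2], s)
                sim[e2, e1] = sim[e1, e2]
    return sim


def link_communities(
    network: AssociationMatrix, weighted: bool = False
) -> LinkCommunityCover:
    """Detect overlapping link communities; cut maximizes partition density.

    Ties between cuts of equal density are broken toward fewer communities.
    Edge order (and hence linkage input) is lexicographic, making the
    result deterministic.
    """
    w = network.weights
    edges = _edge_list(w)
    if not edges:
        raise ValueError("link communities undefined on an empty network")
    m = len(edges)
    if m == 1:
        labels = np.array([1])
        cover_links = None
    else:
        sim = _edge_similarity_matrix(w, edges, weighted)
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        cover_links = linkage(squareform(dist, checks=False), method="single")
        heights = np.unique(cover_links[:, 2])
        candidates = [np.arange(1, m + 1)]  # trivial cut: all singletons
        for h in heights:
            candidates.append(fcluster(cover_links, t=h, criterion="distance"))
        best = None
        for labs in candidates:
            d = partition_density(labs, edges)
            k = len(set(labs.tolist()))
            key = (d, -k)
            if best is None or key > best[0]:
                best = (key, labs)
        labels = best[1]

    node_comms: dict = {}
    for (i, j), lab in zip(edges, labels):
        a, b = network.roster[i], network.roster[j]
        node_comms.setdefault(a, set()).add(int(lab))
        node_comms.setdefault(b, set()).add(int(lab))
    node_comms = {v: frozenset(cs) for v, cs in node_comms.items()}

    cover = LinkCommunityCover(
        edges=[(network.roster[i], network.roster[j]) for i, j in edges],
        edge_community=np.asarray(labels, dtype=int),
        node_communities=node_comms,
        membership_fraction={},
        partition_density=partition_density(labels, edges),
        linkage_matrix=cover_links,
    )
    cover.membership_fraction = membership_fractions(cover, network)
    return cover


def membership_fractions(cover: LinkCommunityCover, network: AssociationMatrix) -> dict:
    """Share of each node's interaction weight allocated to each community.

    share(v, c) = sum of v's edge weights inside c / strength(v); shares per
    node sum to 1.  Zero-strength nodes get an empty mapping (undefined).
    """
    index = {v: i for i, v in enumerate(network.roster)}
    out: dict = {}
    for (a, b), c in zip(cover.edges, cover.edge_community):
        wab = network.weights[index[a], index[b]]
        for v in (a, b):
            out.setdefault(v, {}).setdefault(int(c), 0.0)
            out[v][int(c)] += wab
    shares = {}
    for v, per_c in out.items():
        strength = sum(per_c.values())
        if strength > 0:
            shares[v] = {c: wsum / strength for c, wsum in per_c.items()}
        else:
            shares[v] = {}
    return shares


def assign_groups(cover: LinkCommunityCover, roster) -> GroupAssignment:
    """Disjoint strata: transitive merge of communities sharing nodes.

    Single-edge communities carry no community structure (partition-density
    contribution 0) and typically hold the rare between-group contacts;
    counting them as shared membership would chain otherwise separate
    communities into one stratum.  They are therefore ignored for nodes
    that also belong to a structured (multi-edge) community; a node whose
    only memberships are single edges keeps them, so no node is orphaned.
    """
    comm_sizes: dict = {}
    for c in cover.edge_community.tolist():
        comm_sizes[c] = comm_sizes.get(c, 0) + 1
    trivial = {c for c, size in comm_sizes.items() if size == 1}

    def effective(cs):
        keep = frozenset(c for c in cs if c not in trivial)
        return keep if keep else frozenset(cs)

    node_comms = {v: effective(cs) for v, cs in cover.node_communities.items()}
    comm_ids = sorted({c for cs in node_comms.values() for c in cs})
    parent = {c: c for c in comm_ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(c1, c2):
        r1, r2 = find(c1), find(c2)
        if r1 != r2:
            parent[max(r1, r2)] = min(r1, r2)

    for v, cs in node_comms.items():
        cs = sorted(cs)
        for c in cs[1:]:
            union(cs[0], c)

    members: dict = {}
    for v, cs in node_comms.items():
        members.setdefault(find(sorted(cs)[0]), set()).add(v)

    group_of = {}
    groups = {}
    next_id = 0
    for root in sorted(members):
        groups[next_id] = frozenset(members[root])
        for v in members[root]:
            group_of[v] = next_id
        next_id += 1
    singletons = set()
    for v in roster:
        if v not in group_of:
            groups[next_id] = frozenset([v])
            group_of[v] = next_id
            singletons.add(v)
            next_id += 1
    return GroupAssignment(group_of=group_of, groups=groups, singletons=frozenset(singletons))


def detect_groups(
    events, roster, phase_config, weighted: bool = False
) -> tuple[LinkCommunityCover, GroupAssignment]:
    """Full-study network -> cover -> permutation strata, in one call."""
    from .netbuild import build_sri

    total_slots = sum(phase_config.n_slots(p) for p in range(phase_config.n_periods))
    net = build_sri(events, None, "all", roster, total_slots)
    # similarity acts on the binary structure unless weighted=True, but the
    # cover keeps SRI weights so membership fractions reflect interaction shares
    cover = link_communities(net, weighted=weighted)
    return cover, assign_groups(cover, roster)
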