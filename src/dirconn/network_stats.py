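"""Group-level permutation inference.

Two families of tests:

* Cluster-based permutation on per-source band power.  A two-sided paired
  t-test is run at every source; suprathreshold sources are grouped into
  adjacency-connected clusters separately for positive and negative t,
  each cluster scored by its summed t (its "mass"), and the family-wise
  null is the maximum |mass| over sign-flip permutations of the
  within-subject condition differences.

* A directed adaptation of the network-based statistic (NBS).  Links are
  ordered ROI pairs.  After a first-level t-test and p-threshold, the
  surviving links are grouped into weakly connected components (direction
  is ignored only for the connectedness search, never for the link set),
  each component scored by its number of links, and the family-wise null
  is the maximum component link count under a measure-appropriate
  permutation scheme:

  - paired variant (nMI, memory vs control): condition labels are swapped
    within subjects, equivalently the per-subject difference matrices are
    sign-flipped;
  - one-sample variant (logit dPLI vs 0 within one condition): each
    subject's matrix is randomly transposed, i.e. all of that subject's
    link directions are reversed.  Only the leading (positive-t)
    direction of each pair enters the observed component search.

  Permutations are drawn in antithetic pairs (each pattern together with
  its complement), a valid sampling of the same group that in addition
  makes the one-sample variant exactly equivariant under global
  transposition of its inputs.

Permutation p-values use the (1 + #exceedances) / (1 + n_perm) form, so
they are always in (0, 1].  Nodes of a significant component are typed
source (only outgoing links), sink (only incoming) or intermediate
(both).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# graph helpers


def weak_components(
    edges: Iterable[tuple[int, int]], nodes: Iterable[int] | None = None
) -> list[set[int]]:
    """Partition nodes into weakly connected components of a directed
    edge set (connectedness is judged ignoring link direction)."""
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from((int(a), int(b)) for a, b in edges)
    return [set(c) for c in nx.weakly_connected_components(g)]


def classify_nodes(links: Sequence[tuple]) -> dict[int, str]:
    """Type each node of a directed link set as source (only outgoing),
    sink (only incoming) or intermediate (both).  A self-loop gives its
    node both an incoming and an outgoing link."""
    outs: dict[int, int] = {}
    ins: dict[int, int] = {}
    for link in links:
        a, b = int(link[0]), int(link[1])
        outs[a] = outs.get(a, 0) + 1
        ins[b] = ins.get(b, 0) + 1
    types = {}
    for node in set(outs) | set(ins):
        has_out, has_in = node in outs, node in ins
        types[node] = (
            "intermediate" if (has_out and has_in) else "source" if has_out else "sink"
        )
    return types


@dataclass
class DirectedNetwork:
    """A weakly connected component of suprathreshold directed links.

    ``links`` are (src, dst, t) triples; ``node_types`` maps node ->
    source/sink/intermediate; ``p_value`` is the component-level
    family-wise permutation p (component measure: number of links).
    """

    links: list[tuple[int, int, float]]
    p_value: float
    measure: str = ""
    node_types: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_types:
            self.node_types = classify_nodes(self.links)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def nodes(self) -> set[int]:
        return {n for l in self.links for n in (l[0], l[1])}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degree(self, node: int) -> int:
        return sum(1 for l in self.links if node in (l[0], l[1]))

    def link_set(self) -> set[tuple[int, int]]:
        return {(l[0], l[1]) for l in self.links}

    def to_frame(self, abbrevs: Sequence[str] | None = None) -> pd.DataFrame:
        name = (lambda i: abbrevs[i]) if abbrevs is not None else (lambda i: i)
        return pd.DataFrame(
            [(name(a), name(b), t, self.measure, self.p_value) for a, b, t in self.links],
            columns=["src", "dst", "t", "measure", "component_p"],
        )


# ---------------------------------------------------------------------------
# first-level t helpers (vectorized across permutations)


def _t_from_moments(m: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """t statistics from per-link means and raw sums of squares.

    ``m`` may carry a leading permutation axis; ``ss`` is Σx² per link,
    invariant under sign flips.  Zero-variance links yield NaN.
    """
    var = (ss - n * m**2) / (n - 1)
    var = np.where(var > 0, var, np.nan)
    return m / np.sqrt(var / n)


def _antithetic_signs(rng: np.random.Generator, n_perm: int, n_subj: int) -> np.ndarray:
    """(n_perm, n_subj) array of ±1 drawn in antithetic pairs."""
    half = (n_perm + 1) // 2
    s = rng.integers(0, 2, size=(half, n_subj)) * 2 - 1
    return np.concatenate([s, -s], axis=0)[:n_perm]


def _max_component_links(edges: list[tuple[int, int]]) -> int:
    """Largest link count over weakly connected components of an edge set."""
    if len(edges) <= 1:
        return len(edges)
    comps = weak_components(edges)
    best = 0
    for comp in comps:
        k = sum(1 for a, b in edges if a in comp)
        best = max(best, k)
    return best


def _components_with_stats(
    edge_idx: np.ndarray, t_flat: np.ndarray, n_roi: int
) -> list[list[tuple[int, int, float]]]:
    """Group suprathreshold flat link indices into weakly connected
    components, returning each component's (src, dst, t) link list."""
    links = [(int(k // n_roi), int(k % n_roi), float(t_flat[k])) for k in edge_idx]
    out = []
    for comp in weak_components([(a, b) for a, b, _ in links]):
        out.append([l for l in links if l[0] in comp])
    return out


# ---------------------------------------------------------------------------
# directed NBS


def _nbs_core(
    t_obs: np.ndarray,
    t_perm: np.ndarray,
    n_subj: int,
    alpha_init: float,
    one_sided_positive: bool,
    measure: str,
) -> list[DirectedNetwork]:
    """Shared second level: threshold, component search, max-link null."""
    n_roi = t_obs.shape[0]
    t_crit = stats.t.isf(alpha_init / 2.0, df=n_subj - 1)

    def supra(tf: np.ndarray) -> list[np.ndarray]:
        """Suprathreshold flat indices per tail (one array per sign)."""
        with np.errstate(invalid="ignore"):
            if one_sided_positive:
                return [np.flatnonzero(tf > t_crit)]
            return [np.flatnonzero(tf > t_crit), np.flatnonzero(tf < -t_crit)]

    t_obs_flat = t_obs.ravel()
    obs_components: list[list[tuple[int, int, float]]] = []
    for idx in supra(t_obs_flat):
        obs_components.extend(_components_with_stats(idx, t_obs_flat, n_roi))

    n_perm = t_perm.shape[0]
    null_max = np.zeros(n_perm, dtype=int)
    for k in range(n_perm):
        best = 0
        for idx in supra(t_perm[k]):
            if idx.size:
                edges = [(int(j // n_roi), int(j % n_roi)) for j in idx]
                best = max(best, _max_component_links(edges))
        null_max[k] = best

    nets = []
    for links in obs_components:
        p = (1.0 + np.sum(null_max >= len(links))) / (1.0 + n_perm)
        nets.append(DirectedNetwork(links=links, p_value=float(p), measure=measure))
    nets.sort(key=lambda n: (n.p_value, -n.n_links))
    return nets


def _check_matrices(mats: np.ndarray, min_subjects: int = 3) -> np.ndarray:
    mats = np.asarray(mats, dtype=float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("expected a (n_subjects, n_roi, n_roi) stack")
    if mats.shape[0] < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects")
    return mats


def nbs_paired(
    mats_a: np.ndarray,
    mats_b: np.ndarray,
    alpha_init: float = 0.005,
    alpha_comp: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    measure: str = "nmi",
) -> list[DirectedNetwork]:
    """Directed NBS contrasting two conditions with a paired t-test.

    ``mats_a``/``mats_b`` are (n_subjects, n_roi, n_roi) logit-scale
    matrices (the diagonal may be meaningful, e.g. local phase-amplitude
    coupling, and is tested when finite).  Links with two-sided
    first-level p < alpha_init are kept per tail; components are searched
    within each tail and the null takes the max link count over both.
    Returns the components with family-wise p < alpha_comp.
    """
    a = _check_matrices(mats_a)
    b = _check_matrices(mats_b)
    if a.shape != b.shape:
        raise ValueError("condition stacks must have identical shapes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = (a - b).reshape(a.shape[0], -1)
    n_subj = d.shape[0]
    # NaN entries (undefined diagonals) and zero-variance links drop out as NaN t
    ss = np.nansum(d**2, axis=0)
    ss = np.where(np.all(np.isfinite(d), axis=0), ss, np.nan)
    t_obs = _t_from_moments(d.mean(axis=0), ss, n_subj).reshape(a.shape[1:])
    signs = _antithetic_signs(rng, n_perm, n_subj)
    m_perm = (signs @ np.nan_to_num(d)) / n_subj
    m_perm[:, ~np.isfinite(ss)] = np.nan
    t_perm = _t_from_moments(m_perm, ss[np.newaxis, :], n_subj)
    nets = _nbs_core(t_obs, t_perm, n_subj, alpha_init, False, measure)
    return [n for n in nets if n.p_value < alpha_comp]


def nbs_onesample_dpli(
    mats: np.ndarray,
    alpha_init: float = 0.005,
    alpha_comp: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    measure: str = "dpli",
) -> list[DirectedNetwork]:
    """Directed NBS for a consistent link direction within one condition.

    ``mats`` is a (n_subjects, n_roi, n_roi) stack of logit-scale dPLI
    matrices (anti-symmetric; diagonal NaN).  A one-sample t-test against
    0 is run per ordered link; only the leading direction (t > 0) of each
    pair survives at two-sided p < alpha_init.  The null reverses all
    link directions of randomly chosen subjects (matrix transposition)
    and records the maximum component link count.
    """
    m = _check_matrices(mats)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_subj, n_roi, _ = m.shape
    d = m.reshape(n_subj, -1)
    dt = np.transpose(m, (0, 2, 1)).reshape(n_subj, -1)
    finite = np.all(np.isfinite(d), axis=0)
    ss = np.where(finite, np.nansum(d**2, axis=0), np.nan)
    ss_t = np.where(
        np.all(np.isfinite(dt), axis=0), np.nansum(dt**2, axis=0), np.nan
    )
    t_obs = _t_from_moments(np.nan_to_num(d).mean(axis=0), ss, n_subj)
    t_obs = np.where(finite, t_obs, np.nan).reshape(n_roi, n_roi)

    keep = (_antithetic_signs(rng, n_perm, n_subj) + 1) // 2  # 1 = keep, 0 = transpose
    m_perm = (keep @ np.nan_to_num(d) + (1 - keep) @ np.nan_to_num(dt)) / n_subj
    ss_perm = keep @ np.nan_to_num(d**2) + (1 - keep) @ np.nan_to_num(dt**2)
    bad = ~(np.isfinite(ss) & np.isfinite(ss_t))
    m_perm[:, bad] = np.nan
    t_perm = _t_from_moments(m_perm, ss_perm, n_subj)
    nets = _nbs_core(
        t_obs, t_perm, n_subj, alpha_init, one_sided_positive=True, measure=measure
    )
    return [n for n in nets if n.p_value < alpha_comp]


def network_overlap(
    nets_a: Sequence[DirectedNetwork], nets_b: Sequence[DirectedNetwork]
) -> set[tuple[int, int]]:
    """Links present in significant networks of both analyses (e.g. the
    same directed lead found in both conditions)."""
    links_a = set().union(*(n.link_set() for n in nets_a)) if nets_a else set()
    links_b = set().union(*(n.link_set() for n in nets_b)) if nets_b else set()
    return links_a & links_b


# ---------------------------------------------------------------------------
# cluster-based permutation on source power


@dataclass
class ClusterResult:
    """A suprathreshold cluster of sources: members, summed t (mass),
    family-wise permutation p, and the peak |t| source."""

    members: np.ndarray
    mass: float
    p_value: float
    peak_t: float
    peak_index: int
    peak_coord: np.ndarray | None = None


def grid_adjacency(coords: np.ndarray, radius: float | None = None) -> sparse.csr_matrix:
    """Neighbourhood of a source grid: sources within ``radius`` are
    adjacent.  Default radius is 1.5x the median nearest-neighbour
    spacing of the grid."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    if radius is None:
        dists, _ = tree.query(coords, k=2)
        radius = 1.5 * float(np.median(dists[:, 1]))
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    n = coords.shape[0]
    if pairs.size == 0:
        return sparse.csr_matrix((n, n))
    row = np.concatenate([pairs[:, 0], pairs[:, 1]])
    col = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return sparse.csr_matrix((np.ones(row.size), (row, col)), shape=(n, n))


def form_clusters(
    t: np.ndarray, adjacency: sparse.spmatrix, t_crit: float
) -> list[tuple[np.ndarray, float]]:
    """Group suprathreshold sources into adjacency-connected clusters,
    separately for the positive and negative tails.

    Returns (member_indices, mass) per cluster, mass = Σt over members.
    """
    t = np.asarray(t, dtype=float)
    adjacency = sparse.csr_matrix(adjacency)
    clusters: list[tuple[np.ndarray, float]] = []
    for sign in (1.0, -1.0):
        with np.errstate(invalid="ignore"):
            idx = np.flatnonzero(sign * t > t_crit)
        if idx.size == 0:
            continue
        sub = adjacency[idx][:, idx]
        n_comp, labels = _cc(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            clusters.append((members, float(np.sum(t[members]))))
    return clusters


def cluster_perm_power(
    power_a: np.ndarray,
    power_b: np.ndarray,
    adjacency: sparse.spmatrix,
    alpha_init: float = 0.0005,
    alpha_cluster: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    coords: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Cluster-based permutation test of per-source power between two
    paired conditions.

    ``power_a``/``power_b`` are (n_subjects, n_sources) average power
    maps.  A two-sided paired t-test is thresholded at alpha_init,
    clusters are formed per tail with :func:`form_clusters`, and the null
    distribution is the maximum |cluster mass| over within-subject
    sign-flip permutations.  Returns clusters with p < alpha_cluster.
    """
    a = np.asarray(power_a, dtype=float)
    b = np.asarray(power_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("power maps must be equal-shape (n_subjects, n_sources)")
    n_subj, n_src = a.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = a - b
    ss = np.sum(d**2, axis=0)
    t_obs = _t_from_moments(d.mean(axis=0), ss, n_subj)
    t_crit = stats.t.isf(alpha_init / 2.0, df=n_subj - 1)

    observed = form_clusters(t_obs, adjacency, t_crit)
    signs = _antithetic_signs(rng, n_perm, n_subj)
    m_perm = (signs @ d) / n_subj
    t_perm = _t_from_moments(m_perm, ss[np.newaxis, :], n_subj)
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        cl = form_clusters(t_perm[k], adjacency, t_crit)
        if cl:
            null_max[k] = max(abs(mass) for _, mass in cl)

    results = []
    for members, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        if p < alpha_cluster:
            peak_local = members[np.argmax(np.abs(t_obs[members]))]
            results.append(
                ClusterResult(
                    members=members,
                    mass=mass,
                    p_value=float(p),
                    peak_t=float(t_obs[peak_local]),
                    peak_index=int(peak_local),
                    peak_coord=None if coords is None else np.asarray(coords)[peak_local],
                )
            )
    results.sort(key=lambda c: c.p_value)
    return results


# ---------------------------------------------------------------------------
# link-distance profile


def link_distances(
    networks: Sequence[DirectedNetwork], centroids: np.ndarray
) -> np.ndarray:
    """Euclidean centroid distance (mm) of every link in a network list."""
    centroids = np.asarray(centroids, dtype=float)
    d = [
        float(np.linalg.norm(centroids[a] - centroids[b]))
        for net in networks
        for a, b, _ in net.links
    ]
    return np.asarray(d)


def link_distance_anova(
    distance_groups: dict[str, np.ndarray], min_links: int = 2
) -> dict:
    """One-way ANOVA of link-distance profiles across connectivity types,
    with all pairwise post-hoc t-tests Šidák-adjusted
    (p_adj = 1 - (1 - p_raw)^m over the m pairwise comparisons).

    Groups with fewer than ``min_links`` distances are excluded (their
    names are reported under ``"excluded"``).
    """
    kept = {k: np.asarray(v, dtype=float) for k, v in distance_groups.items()}
    excluded = [k for k, v in kept.items() if v.size < min_links]
    kept = {k: v for k, v in kept.items() if v.size >= min_links}
    if len(kept) < 2:
        raise ValueError("need at least two connectivity types with >= 2 links each")
    names = list(kept)
    f_stat, p_val = stats.f_oneway(*kept.values())
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        t_stat, p_raw = stats.ttest_ind(kept[names[i]], kept[names[j]])
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "t": float(t_stat),
                "p_raw": float(p_raw),
                "p_sidak": float(sidak_adjust(p_raw, m)),
            }
        )
    return {
        "F": float(f_stat),
        "p": float(p_val),
        "df": (len(names) - 1, int(sum(v.size for v in kept.values()) - len(names))),
        "groups": {k: v for k, v in kept.items()},
        "posthoc": pd.DataFrame(rows),
        "excluded": excluded,
    }


def sidak_adjust(p_raw: float, m: int) -> float:
    """Dunn-Šidák correction for m comparisons: 1 - (1 - p)^m."""
    return 1.0 - (1.0 - p_raw) ** m
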