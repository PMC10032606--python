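"""Kinetic transition networks and transition disconnectivity graphs.

The workflow mirrors how energy landscapes of disordered peptides are mapped
from equilibrium trajectories:

1. frames are clustered in DRID feature space (centroid-based, cluster count
   selected by a knee-point analysis of the dispersion-versus-k curve);
2. transitions between clusters are counted at a lag time; symmetrised
   counts define stationary weights pi_i and free energies
   F_i = -kB T ln pi_i;
3. effective barriers between groups of minima are the max-flow/min-cut
   values of the capacitated count network (Ford-Fulkerson), converted to a
   free energy via F+ = -kB T ln(c_cut / N_total);
4. minima are merged in order of increasing pairwise min-cut barrier into an
   ultrametric tree (the transition disconnectivity graph, TRDG);
5. the roughness density rho_LB profiles branch splitting per free-energy
   interval, a measure of local landscape frustration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from . import constants

__all__ = [
    "ClusterModel",
    "TransitionNetwork",
    "DisconnectivityTree",
    "RoughnessProfile",
    "cluster_trajectories",
    "knee_point",
    "count_transitions",
    "mincut_barrier",
    "pairwise_mincut",
    "build_trdg",
    "annotate_states",
    "plot_trdg",
    "roughness_profile",
]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Partition of trajectory frames in feature space."""

    k: int
    centers: np.ndarray
    labels: np.ndarray  # per frame, values in [1, k]
    dispersion: dict  # k -> within-cluster dispersion (inertia)
    lengths: list  # frames per trajectory, in input order
    seed: int = 0

    def labels_per_trajectory(self) -> list[np.ndarray]:
        out, start = [], 0
        for n in self.lengths:
            out.append(self.labels[start:start + n])
            start += n
        return out


def knee_point(xs: np.ndarray, ys: np.ndarray) -> int:
    """Index of the knee of a decreasing curve by maximum distance-to-chord.

    Both axes are normalised to [0, 1] before measuring the perpendicular
    distance from the chord connecting the endpoints.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        return len(xs) - 1
    x = (xs - xs[0]) / (xs[-1] - xs[0])
    span = ys[0] - ys[-1]
    if abs(span) < 1e-15:
        return 0
    y = (ys - ys[-1]) / span
    # chord from (0, 1) to (1, 0): distance ~ |x + y - 1| / sqrt(2)
    d = np.abs(x + y - 1.0)
    return int(np.argmax(d))


def cluster_trajectories(trajs, k_range=range(2, 16), seed: int = 0,
                         features=None, topo=None, n_init: int = 10
                         ) -> ClusterModel:
    """Cluster frames of one or more trajectories in DRID space.

    ``trajs`` is a list of Trajectory objects (or raw frame stacks); their
    DRID features are computed with the given topology unless ``features``
    (a list of per-trajectory feature arrays) is supplied directly.  The
    cluster count is selected at the knee of the dispersion-versus-k curve.
    """
    from .order_params import drid_features

    if features is None:
        stacks = [t.coords if hasattr(t, "coords") else np.asarray(t)
                  for t in trajs]
        features = [drid_features(s, topo) for s in stacks]
    lengths = [len(f) for f in features]
    X = np.vstack(features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames to cluster")

    spread = float(np.max(np.ptp(X, axis=0)))
    if spread < 1e-12:
        warnings.warn("all frames identical in feature space; using k = 1")
        return ClusterModel(k=1, centers=X[:1].copy(),
                            labels=np.ones(len(X), dtype=int),
                            dispersion={1: 0.0}, lengths=lengths, seed=seed)

    k_values = [k for k in k_range if 1 <= k <= X.shape[0]]
    if not k_values:
        raise ValueError("k_range contains no feasible cluster counts")
    dispersion, models = {}, {}
    fitted = []
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        dispersion[k] = float(km.inertia_)
        models[k] = km
        fitted.append(k)
        if dispersion[k] <= 1e-9 * max(dispersion[fitted[0]], 1e-300):
            break  # exact partition found; larger k cannot improve
    # a (numerically) perfect partition short-circuits the knee analysis
    tol = 1e-9 * max(dispersion[fitted[0]], 1e-300)
    exact = [k for k in fitted if dispersion[k] <= tol]
    if exact:
        best_k = min(exact)
    else:
        best_k = fitted[knee_point(np.array(fitted),
                                   np.array([dispersion[k] for k in fitted]))]
    km = models[best_k]
    return ClusterModel(k=best_k, centers=km.cluster_centers_,
                        labels=km.labels_.astype(int) + 1,
                        dispersion=dispersion, lengths=lengths, seed=seed)


# ---------------------------------------------------------------------------
# transition network
# ---------------------------------------------------------------------------

@dataclass
class TransitionNetwork:
    """Counted transitions at a lag, with stationary weights and energies.

    ``counts`` are raw directed counts; ``sym_counts`` the detailed-balance
    symmetrisation (n_ij + n_ji)/2.  ``n_total`` is the total number of
    counted transitions (all ordered pairs), which normalises cut values
    into free energies.
    """

    states: np.ndarray  # sorted state ids
    counts: np.ndarray  # (k, k) raw directed counts at lag
    lag: int  # frames
    kbt: float  # kcal/mol
    dt_frame_ps: float | None = None  # physical time per frame

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def sym_counts(self) -> np.ndarray:
        return 0.5 * (self.counts + self.counts.T)

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    @property
    def pi(self) -> np.ndarray:
        s = self.sym_counts
        w = s.sum(axis=1)
        return w / w.sum()

    @property
    def free_energies(self) -> np.ndarray:
        """F_i = -kB T ln pi_i, kcal/mol."""
        with np.errstate(divide="ignore"):
            return -self.kbt * np.log(self.pi)

    @property
    def lag_ps(self) -> float | None:
        if self.dt_frame_ps is None:
            return None
        return self.lag * self.dt_frame_ps

    def index_of(self, state) -> int:
        idx = np.nonzero(self.states == state)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown state {state!r}")
        return int(idx[0])

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_states))
        s = self.sym_counts
        for i in range(self.n_states):
            for j in range(i + 1, self.n_states):
                if s[i, j] > 0:
                    g.add_edge(i, j)
        return nx.is_connected(g)

    def to_edge_list(self) -> list[tuple]:
        s = self.sym_counts
        return [(self.states[i], self.states[j], s[i, j])
                for i in range(self.n_states)
                for j in range(i + 1, self.n_states) if s[i, j] > 0]


def count_transitions(labels, lag: int = 1,
                      temperature: float = constants.DEFAULT_TEMPERATURE,
                      dt_frame_ps: float | None = None) -> TransitionNetwork:
    """Count i -> j hops at the given lag with sliding windows.

    ``labels`` is one label sequence or a list of sequences (one per
    trajectory); windows never span trajectory boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if labels is None:
        raise ValueError("labels must be non-empty")
    seqs = labels if isinstance(labels, (list, tuple)) and not np.isscalar(
        labels[0] if len(labels) else None) else None
    if seqs is None or (len(labels) and np.isscalar(labels[0])):
        seqs = [labels]
    seqs = [np.asarray(s) for s in seqs]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("labels must be non-empty")

    states = np.unique(np.concatenate(seqs))
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    counts = np.zeros((k, k))
    for seq in seqs:
        if len(seq) <= lag:
            continue
        a = seq[:-lag]
        b = seq[lag:]
        for x, y in zip(a, b):
            counts[index[x], index[y]] += 1.0
    return TransitionNetwork(states=states, counts=counts, lag=lag,
                             kbt=constants.kBT(temperature),
                             dt_frame_ps=dt_frame_ps)


# ---------------------------------------------------------------------------
# min-cut barriers
# ---------------------------------------------------------------------------

def _capacity_graph(net: TransitionNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_states))
    s = net.sym_counts
    for i in range(net.n_states):
        for j in range(i + 1, net.n_states):
            cap = s[i, j] + s[j, i]  # total transition count across the edge
            if cap > 0:
                g.add_edge(i, j, capacity=cap)
    return g


def mincut_barrier(net: TransitionNetwork, A, B) -> tuple[float, float]:
    """Effective barrier between node sets A and B by max-flow/min-cut.

    Edge capacities are the symmetrised transition counts; the barrier is
    F+ = -kB T ln(c_cut / N_total).  Disconnected sets give an infinite
    barrier (cut value 0).  Returns ``(barrier_kcal_mol, cut_value)``.
    """
    A = {net.index_of(a) for a in np.atleast_1d(A)}
    B = {net.index_of(b) for b in np.atleast_1d(B)}
    if not A or not B:
        raise ValueError("A and B must be non-empty")
    if A & B:
        raise ValueError("A and B must be disjoint")

    g = _capacity_graph(net)
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes)
    for i, j, data in g.edges(data=True):
        dg.add_edge(i, j, capacity=data["capacity"])
        dg.add_edge(j, i, capacity=data["capacity"])
    src, snk = "__source__", "__sink__"
    for a in A:
        dg.add_edge(src, a, capacity=float("inf"))
    for b in B:
        dg.add_edge(b, snk, capacity=float("inf"))
    cut_value, _ = nx.minimum_cut(dg, src, snk)
    if cut_value <= 0:
        return float("inf"), 0.0
    barrier = -net.kbt * np.log(cut_value / net.n_total)
    return float(barrier), float(cut_value)


def pairwise_mincut(net: TransitionNetwork) -> np.ndarray:
    """All-pairs min-cut values via a Gomory-Hu tree, shape (k, k).

    Disconnected pairs get cut value 0.
    """
    k = net.n_states
    cuts = np.zeros((k, k))
    g = _capacity_graph(net)
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        gh = nx.gomory_hu_tree(sub)
        for ia, a in enumerate(comp):
            for b in comp[ia + 1:]:
                path = nx.shortest_path(gh, a, b)
                cut = min(gh[u][v]["weight"]
                          for u, v in zip(path[:-1], path[1:]))
                cuts[a, b] = cuts[b, a] = cut
    return cuts


# ---------------------------------------------------------------------------
# disconnectivity tree
# ---------------------------------------------------------------------------

@dataclass
class DisconnectivityTree:
    """Ultrametric merge tree of free-energy minima (the TRDG).

    ``merges`` follows the scipy linkage convention: row m merges clusters
    ``merges[m, 0]`` and ``merges[m, 1]`` at barrier height ``merges[m, 2]``
    (kcal/mol).  Leaves carry state ids, free energies and fibril-overlap
    annotations: ``chi_min``/``chi_max`` are the lowest/highest member
    overlap and ``fibril_fraction`` the fraction of member frames with
    chi >= chi_c.
    """

    states: np.ndarray
    leaf_energies: np.ndarray  # F_i, kcal/mol
    merges: np.ndarray  # (k-1, 4) linkage matrix, heights in kcal/mol
    annotations: dict = field(default_factory=dict)  # state -> dict

    @property
    def n_leaves(self) -> int:
        return len(self.states)

    def merge_height(self, i: int, j: int) -> float:
        """Ultrametric barrier between leaves i and j (positional indices)."""
        n = self.n_leaves
        members = {k: {k} for k in range(n)}
        for m, row in enumerate(self.merges):
            a, b = int(row[0]), int(row[1])
            merged = members[a] | members[b]
            if i in merged and j in merged and not (
                    {i, j} <= members[a] or {i, j} <= members[b]):
                return float(row[2])
            members[n + m] = merged
        raise ValueError("leaves never merge (forest input?)")

    def to_json(self) -> str:
        payload = {
            "states": [s.item() if hasattr(s, "item") else s
                       for s in self.states],
            "leaf_energies_kcal_mol": self.leaf_energies.tolist(),
            "merges": self.merges.tolist(),
            "annotations": {str(k): v for k, v in self.annotations.items()},
        }
        return json.dumps(payload, indent=2)


def build_trdg(net: TransitionNetwork,
               annotations: dict | None = None) -> DisconnectivityTree:
    """Assemble the transition disconnectivity graph from a network.

    Minima are merged agglomeratively in order of increasing pairwise
    min-cut barrier (single linkage on the Gomory-Hu cut matrix), which
    yields an ultrametric tree.  ``annotations`` maps state id to a dict
    with (at least) ``chi_min``, ``chi_max`` and ``fibril_fraction``.
    """
    k = net.n_states
    F = net.free_energies
    if k == 1:
        return DisconnectivityTree(states=net.states, leaf_energies=F,
                                   merges=np.empty((0, 4)),
                                   annotations=annotations or {})
    cuts = pairwise_mincut(net)
    with np.errstate(divide="ignore"):
        barriers = -net.kbt * np.log(cuts / net.n_total)
    if not np.all(np.isfinite(barriers[~np.eye(k, dtype=bool)])):
        raise ValueError("network is disconnected; build per-component trees")
    iu = np.triu_indices(k, 1)
    # single linkage needs non-negative dissimilarities; shift and unshift
    condensed = barriers[iu]
    shift = min(0.0, float(condensed.min()))
    Z = linkage(condensed - shift, method="single")
    Z = Z.copy()
    Z[:, 2] += shift
    return DisconnectivityTree(states=net.states, leaf_energies=F,
                               merges=Z, annotations=annotations or {})


def plot_trdg(tree: DisconnectivityTree, path=None, color_key: str = "chi_min",
              ax=None):
    """Render the disconnectivity tree as vertical branches (vector output).

    Leaves are placed by recursive subtree ordering; branch colour encodes
    the ``color_key`` annotation (fibril overlap) when available.  Saves to
    ``path`` (format from the extension, e.g. .svg/.pdf) if given.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    n = tree.n_leaves
    # leaf ordering from the merge structure
    children = {n + m: (int(r[0]), int(r[1])) for m, r in enumerate(tree.merges)}

    def leaves_under(node):
        if node < n:
            return [node]
        a, b = children[node]
        return leaves_under(a) + leaves_under(b)

    order = leaves_under(n + len(tree.merges) - 1) if len(tree.merges) else [0]
    xpos = {leaf: i for i, leaf in enumerate(order)}

    if ax is None:
        fig, ax = plt.subplots(figsize=(max(4, 0.4 * n), 5))
    else:
        fig = ax.figure
    cmap = matplotlib.colormaps["coolwarm_r"]
    node_x = {}
    top = float(tree.merges[:, 2].max()) if len(tree.merges) else \
        float(tree.leaf_energies.max() + 1.0)
    for leaf in range(n):
        state = tree.states[leaf]
        key = state.item() if hasattr(state, "item") else state
        ann = tree.annotations.get(key, {})
        color = cmap(ann.get(color_key, 0.0))
        node_x[leaf] = xpos[leaf]
        ax.plot([xpos[leaf], xpos[leaf]],
                [tree.leaf_energies[leaf], top], color=color, lw=1.5,
                zorder=1)
    for m, row in enumerate(tree.merges):
        a, b = int(row[0]), int(row[1])
        xa = node_x[a] if a in node_x else np.mean(
            [xpos[l] for l in leaves_under(a)])
        xb = node_x[b] if b in node_x else np.mean(
            [xpos[l] for l in leaves_under(b)])
        ax.plot([xa, xb], [row[2], row[2]], color="0.3", lw=1.0, zorder=0)
        node_x[n + m] = 0.5 * (xa + xb)
    ax.set_xticks([])
    ax.set_ylabel("free energy (kcal/mol)")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax


def annotate_states(labels, chi_values: np.ndarray,
                    chi_c: float = 0.30) -> dict:
    """Per-state fibril-overlap annotations from frame labels and chi values.

    ``chi_min`` is the minimum member overlap (the conservative similarity
    shown on TRDG branches), ``chi_max`` the best member overlap, and
    ``fibril_fraction`` the fraction of member frames with chi >= chi_c.
    """
    labels = np.concatenate([np.asarray(s) for s in labels]) if isinstance(
        labels, (list, tuple)) else np.asarray(labels)
    chi_values = np.asarray(chi_values, dtype=float)
    if len(labels) != len(chi_values):
        raise ValueError("labels and chi values must align frame-by-frame")
    out = {}
    for state in np.unique(labels):
        member = chi_values[labels == state]
        out[state.item() if hasattr(state, "item") else state] = {
            "chi_min": float(member.min()),
            "chi_max": float(member.max()),
            "fibril_fraction": float(np.mean(member >= chi_c)),
            "population": int(len(member)),
        }
    return out


# ---------------------------------------------------------------------------
# roughness density
# ---------------------------------------------------------------------------

@dataclass
class RoughnessProfile:
    """Landscape roughness density versus free energy."""

    grid: np.ndarray  # bin edges, kcal/mol, strictly increasing
    rho: np.ndarray  # rho_LB per bin, 1/(minima * kcal/mol)
    fibril_fraction: np.ndarray  # per-bin fraction of fibril-like frames

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.grid[:-1] + self.grid[1:])


def _branches_alive(tree: DisconnectivityTree, level: float) -> int:
    """Number of distinct sub-basins at a free-energy level.

    A sub-basin is a cluster of leaves already born (leaf F <= level) and
    not yet merged with the rest (merge height > level).
    """
    n = tree.n_leaves
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members = {i: {i} for i in range(n)}
    for m, row in enumerate(tree.merges):
        a, b, h = int(row[0]), int(row[1]), row[2]
        members[n + m] = members[a] | members[b]
        if h <= level:
            ra, rb = find(min(members[a])), find(min(members[b]))
            if ra != rb:
                parent[ra] = rb
    alive_roots = set()
    for leaf in range(n):
        if tree.leaf_energies[leaf] <= level:
            alive_roots.add(find(leaf))
    return len(alive_roots)


def roughness_profile(tree: DisconnectivityTree, delta_f: float = 0.5,
                      chi_c: float = 0.30) -> RoughnessProfile:
    """Roughness density rho_LB on a uniform free-energy grid.

    Per bin (evaluated at the bin midpoint), rho_LB = (number of distinct
    branches alive - 1) / (total minima * delta_f).  The fibril-like
    fraction per bin averages the ``fibril_fraction`` annotation over the
    minima whose free energy falls in the bin, weighted by population
    (NaN where the bin holds no minima).
    """
    if delta_f <= 0:
        raise ValueError("bin width must be positive")
    if tree.n_leaves < 1:
        raise ValueError("tree must have at least one leaf")
    lo = float(tree.leaf_energies.min())
    hi = float(tree.merges[:, 2].max()) if len(tree.merges) else lo + delta_f
    n_bins = max(1, int(np.ceil((hi - lo) / delta_f + 1e-9)))
    grid = lo + delta_f * np.arange(n_bins + 1)

    rho = np.zeros(n_bins)
    frac = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mid = 0.5 * (grid[b] + grid[b + 1])
        alive = _branches_alive(tree, mid)
        rho[b] = max(alive - 1, 0) / (tree.n_leaves * delta_f)
        in_bin = [s for s, F in zip(tree.states, tree.leaf_energies)
                  if grid[b] <= F < grid[b + 1]]
        if in_bin and tree.annotations:
            weights, values = [], []
            for s in in_bin:
                key = s.item() if hasattr(s, "item") else s
                ann = tree.annotations.get(key)
                if ann is not None:
                    weights.append(ann.get("population", 1))
                    values.append(ann.get("fibril_fraction", np.nan))
            if values:
                frac[b] = float(np.average(values, weights=weights))
    return RoughnessProfile(grid=grid, rho=rho, fibril_fraction=frac)
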