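"""Protein phylogenetics: JTT model, ML distances, NJ, likelihood, bootstrap.

The substitution model is the empirical Jones-Taylor-Thornton (JTT)
exchangeability matrix with its published stationary frequencies, shipped as
a data file. The rate matrix is normalized to one expected substitution per
site per unit branch length; transition matrices come from the reversible
eigendecomposition, so Chapman-Kolmogorov holds to numerical precision.

Rates are uniform across sites. Gap columns are handled by pairwise deletion
for distances and as missing data for likelihoods.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .seqio import ProteinRecord

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {ch: i for i, ch in enumerate(AA_ORDER)}

_MAX_DISTANCE = 20.0


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# substitution model


@dataclass(frozen=True)
class JttModel:
    alphabet: str
    pi: np.ndarray
    rate_matrix: np.ndarray
    _evals: np.ndarray = field(repr=False)
    _right: np.ndarray = field(repr=False)  # D^{-1/2} U
    _left: np.ndarray = field(repr=False)  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1 for all t >= 0."""
        if t < 0:
            raise PhyloError(f"branch length must be nonnegative, got {t}")
        p = (self._right * np.exp(self._evals * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        return p


def _build_model(exchange_lower: list[float], freqs: list[float]) -> JttModel:
    n = 20
    s = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            s[i, j] = s[j, i] = exchange_lower[k]
            k += 1
    pi = np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    q = s * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # normalize to 1 expected substitution / site / unit time
    q /= -np.dot(pi, np.diag(q))
    # reversible eigendecomposition via symmetrization
    sq = np.sqrt(pi)
    sym = (q * sq[:, np.newaxis]) / sq[np.newaxis, :]
    evals, u = np.linalg.eigh((sym + sym.T) / 2.0)
    right = u / sq[:, np.newaxis]
    left = u.T * sq[np.newaxis, :]
    return JttModel(
        alphabet=AA_ORDER, pi=pi, rate_matrix=q, _evals=evals, _right=right, _left=left
    )


@lru_cache(maxsize=1)
def load_jtt() -> JttModel:
    with resources.files("clckit.data").joinpath("jtt.json").open() as fh:
        data = json.load(fh)
    assert data["alphabet"] == AA_ORDER
    return _build_model(data["exchangeabilities_lower_triangle"], data["frequencies"])


def encode_sequence(seq: ProteinRecord | str) -> np.ndarray:
    """Map residues to model indices; gaps and unknowns become -1 (missing)."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    return np.array([_AA_INDEX.get(ch, -1) for ch in s], dtype=np.int64)


# ---------------------------------------------------------------------------
# ML pairwise distances


def _pair_counts(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    mask = (ea >= 0) & (eb >= 0)
    if not mask.any():
        raise PhyloError("no shared ungapped columns between sequences")
    flat = ea[mask] * 20 + eb[mask]
    return np.bincount(flat, minlength=400).reshape(20, 20).astype(float)


def ml_distance_from_counts(counts: np.ndarray, model: JttModel) -> float:
    """Maximize sum_xy N_xy log(pi_x P_xy(t)) over t by bounded optimization."""
    off_diagonal = counts.sum() - np.trace(counts)
    if off_diagonal == 0:
        return 0.0
    nz = counts > 0
    log_pi = np.log(model.pi)[:, np.newaxis]

    def nll(t: float) -> float:
        p = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(p, 1e-300)) + log_pi
        return -float((counts[nz] * lp[nz]).sum())

    res = minimize_scalar(nll, bounds=(1e-8, _MAX_DISTANCE), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def ml_pairwise_distance(
    a: ProteinRecord | str, b: ProteinRecord | str, model: JttModel | None = None
) -> float:
    """Expected substitutions/site between two aligned sequences under JTT.

    Gap columns are dropped pairwise; identical sequences give exactly 0.
    """
    model = model or load_jtt()
    ea, eb = encode_sequence(a), encode_sequence(b)
    if len(ea) != len(eb):
        raise PhyloError("sequences must be aligned (equal length)")
    return ml_distance_from_counts(_pair_counts(ea, eb), model)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise PhyloError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise PhyloError("distances must be nonnegative")
        self.matrix = m

    @classmethod
    def from_alignment(
        cls, alignment: dict[str, str], model: JttModel | None = None
    ) -> "DistanceMatrix":
        model = model or load_jtt()
        labels = sorted(alignment)
        encoded = {lab: encode_sequence(alignment[lab]) for lab in labels}
        n = len(labels)
        m = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d = ml_distance_from_counts(
                _pair_counts(encoded[labels[i]], encoded[labels[j]]), model
            )
            m[i, j] = m[j, i] = d
        return cls(labels=labels, matrix=m)


# ---------------------------------------------------------------------------
# trees


class PhyloTree:
    """An unrooted tree: integer nodes, labelled leaves, branch lengths >= 0.

    ``support`` maps canonical splits (frozenset of leaf labels on the side
    not containing the alphabetically first leaf) to bootstrap percentages.
    """

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self.support: dict[frozenset[str], float] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        node = self._next_id
        self._next_id += 1
        self._adj[node] = {}
        if label is not None:
            self.labels[node] = label
        return node

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise PhyloError(f"branch length must be >= 0, got {length}")
        self._adj[u][v] = length
        self._adj[v][u] = length

    def set_length(self, u: int, v: int, length: float) -> None:
        if v not in self._adj[u]:
            raise PhyloError(f"no edge between {u} and {v}")
        self._adj[u][v] = length
        self._adj[v][u] = length

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        t.labels = dict(self.labels)
        t.support = dict(self.support)
        t._next_id = self._next_id
        return t

    # -- introspection ------------------------------------------------------

    def nodes(self) -> list[int]:
        return sorted(self._adj)

    def neighbors(self, u: int) -> dict[int, float]:
        return self._adj[u]

    def length(self, u: int, v: int) -> float:
        return self._adj[u][v]

    def leaves(self) -> list[int]:
        return sorted(n for n in self._adj if len(self._adj[n]) <= 1)

    def leaf_labels(self) -> list[str]:
        return sorted(self.labels[n] for n in self.leaves())

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in self._adj for v in self._adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if len(self._adj[u]) > 1 and len(self._adj[v]) > 1
        ]

    def _side_labels(self, u: int, away_from: int) -> frozenset[str]:
        """Leaf labels reachable from ``u`` without crossing ``away_from``."""
        seen = {away_from, u}
        stack = [u]
        out = []
        while stack:
            x = stack.pop()
            if x in self.labels:
                out.append(self.labels[x])
            for y in self._adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def canonical_split(self, u: int, v: int) -> frozenset[str]:
        """Canonical form of the split induced by edge (u, v)."""
        ref = min(self.leaf_labels())
        side = self._side_labels(u, v)
        return self._side_labels(v, u) if ref in side else side

    def splits(self) -> set[frozenset[str]]:
        """Canonical nontrivial splits, one per internal edge."""
        return {self.canonical_split(u, v) for u, v in self.internal_edges()}

    def path_length(self, label_a: str, label_b: str) -> float:
        by_label = {lab: n for n, lab in self.labels.items()}
        start, goal = by_label[label_a], by_label[label_b]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            x = stack.pop()
            if x == goal:
                return dist[x]
            for y, w in self._adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        raise PhyloError("tree is disconnected")

    # -- Newick -------------------------------------------------------------

    def to_newick(self, include_support: bool = False) -> str:
        leaves = self.leaves()
        if len(leaves) == 1:
            return f"{self.labels[leaves[0]]};"
        root = max(self._adj, key=lambda n: (len(self._adj[n]), -n))

        def render(node: int, parent: int | None) -> str:
            children = [n for n in sorted(self._adj[node]) if n != parent]
            if not children:
                name = self.labels.get(node, "")
                length = self._adj[node][parent]
                return f"{name}:{length:.10g}"
            inner = ",".join(render(c, node) for c in children)
            label = ""
            if include_support and parent is not None:
                split = self.canonical_split(node, parent)
                if split in self.support:
                    label = f"{self.support[split]:g}"
            if parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{self._adj[node][parent]:.10g}"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick")
        dt.is_rooted = False
        tree = cls()
        mapping: dict[int, int] = {}
        for node in dt.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else None
            mapping[id(node)] = tree.new_node(label)
        for node in dt.preorder_node_iter():
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else 0.0
                tree.add_edge(mapping[id(node.parent_node)], mapping[id(node)],
                              max(0.0, float(length)))
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        for node in list(self._adj):
            if len(self._adj[node]) == 2 and node not in self.labels:
                (a, la), (b, lb) = self._adj[node].items()
                del self._adj[a][node]
                del self._adj[b][node]
                del self._adj[node]
                self._adj[a][b] = la + lb
                self._adj[b][a] = la + lb


# ---------------------------------------------------------------------------
# neighbor joining


def build_nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic label-order tie-breaking.

    Negative branch-length estimates are clamped to zero.
    """
    n = len(d.labels)
    if n < 3:
        raise PhyloError(f"neighbor joining needs >= 3 taxa, got {n}")
    order = sorted(range(n), key=lambda i: d.labels[i])
    tree = PhyloTree()
    active: list[int] = []  # tree node ids
    dist: dict[tuple[int, int], float] = {}
    for i in order:
        active.append(tree.new_node(d.labels[i]))
    for a, i in enumerate(order):
        for b, j in enumerate(order):
            if a < b:
                dist[(active[a], active[b])] = float(d.matrix[i, j])

    def get(u: int, v: int) -> float:
        return dist[(u, v)] if (u, v) in dist else dist[(v, u)]

    while len(active) > 3:
        m = len(active)
        r = {u: sum(get(u, v) for v in active if v != u) for u in active}
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                u, v = active[a], active[b]
                q = (m - 2) * get(u, v) - r[u] - r[v]
                key = (q, u, v)
                if best is None or key < best:
                    best = key
        _, u, v = best
        duv = get(u, v)
        lu = 0.5 * duv + (r[u] - r[v]) / (2 * (m - 2))
        lv = duv - lu
        new = tree.new_node()
        tree.add_edge(u, new, max(0.0, lu))
        tree.add_edge(v, new, max(0.0, lv))
        for w in active:
            if w not in (u, v):
                dist[(new, w)] = 0.5 * (get(u, w) + get(v, w) - duv)
        active = [w for w in active if w not in (u, v)] + [new]

    (u, v, w) = active
    duv, duw, dvw = get(u, v), get(u, w), get(v, w)
    center = tree.new_node()
    tree.add_edge(u, center, max(0.0, 0.5 * (duv + duw - dvw)))
    tree.add_edge(v, center, max(0.0, 0.5 * (duv + dvw - duw)))
    tree.add_edge(w, center, max(0.0, 0.5 * (duw + dvw - duv)))
    return tree


# ---------------------------------------------------------------------------
# likelihood


def _encode_alignment(alignment: dict[str, str]) -> dict[str, np.ndarray]:
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise PhyloError("alignment sequences differ in length")
    return {lab: encode_sequence(s) for lab, s in alignment.items()}


def tree_log_likelihood(
    tree: PhyloTree, alignment: dict[str, str], model: JttModel | None = None
) -> float:
    """Felsenstein pruning log-likelihood, uniform rates, gaps = missing data.

    The likelihood is invariant to where the (virtual) root is placed because
    the model is reversible.
    """
    model = model or load_jtt()
    encoded = _encode_alignment(alignment)
    for node in tree.leaves():
        if tree.labels.get(node) not in encoded:
            raise PhyloError(f"leaf {tree.labels.get(node)!r} missing from alignment")
    nsites = len(next(iter(encoded.values())))

    def leaf_partial(node: int) -> np.ndarray:
        codes = encoded[tree.labels[node]]
        partial = np.zeros((20, nsites))
        observed = codes >= 0
        partial[:, ~observed] = 1.0
        partial[codes[observed], np.where(observed)[0]] = 1.0
        return partial

    def partial(node: int, parent: int | None) -> np.ndarray:
        children = [n for n in sorted(tree.neighbors(node)) if n != parent]
        if not children:
            return leaf_partial(node)
        out = leaf_partial(node) if node in tree.labels else np.ones((20, nsites))
        for child in children:
            p = model.transition_matrix(tree.length(node, child))
            out = out * (p @ partial(child, node))
        return out

    root = max(tree.nodes(), key=lambda n: (len(tree.neighbors(n)), -n))
    site_lik = model.pi @ partial(root, None)
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.log(site_lik).sum())


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: dict[str, str],
    model: JttModel | None = None,
    passes: int = 2,
) -> float:
    """Coordinate-wise branch-length optimization in place; returns final LL."""
    model = model or load_jtt()
    for _ in range(passes):
        for u, v in tree.edges():

            def nll(t: float) -> float:
                tree.set_length(u, v, t)
                return -tree_log_likelihood(tree, alignment, model)

            res = minimize_scalar(
                nll, bounds=(1e-9, _MAX_DISTANCE), method="bounded",
                options={"xatol": 1e-6},
            )
            tree.set_length(u, v, float(res.x))
    return tree_log_likelihood(tree, alignment, model)


def nni_neighbors(tree: PhyloTree, u: int, v: int) -> list[PhyloTree]:
    """The two NNI rearrangements around internal edge (u, v)."""
    nb_u = [n for n in sorted(tree.neighbors(u)) if n != v]
    nb_v = [n for n in sorted(tree.neighbors(v)) if n != u]
    if len(nb_u) < 2 or len(nb_v) < 2:
        raise PhyloError("NNI requires an internal edge")
    b = nb_u[1]
    out = []
    for c in nb_v[:2]:
        t = tree.copy()
        lb = t.length(u, b)
        lc = t.length(v, c)
        del t._adj[u][b], t._adj[b][u]
        del t._adj[v][c], t._adj[c][v]
        t.add_edge(u, c, lc)
        t.add_edge(v, b, lb)
        out.append(t)
    return out


def nni_search(
    tree: PhyloTree,
    alignment: dict[str, str],
    model: JttModel | None = None,
    max_rounds: int = 10,
) -> PhyloTree:
    """Greedy NNI hill-climb; accepts the best likelihood-improving move.

    Branch lengths are re-optimized coordinate-wise for every candidate, so
    the accepted log-likelihood sequence is non-decreasing. Deterministic.
    """
    model = model or load_jtt()
    current = tree.copy()
    current_ll = optimize_branch_lengths(current, alignment, model)
    for _ in range(max_rounds):
        best_ll, best_tree = current_ll, None
        for u, v in current.internal_edges():
            for candidate in nni_neighbors(current, u, v):
                ll = optimize_branch_lengths(candidate, alignment, model, passes=1)
                if ll > best_ll + 1e-9:
                    best_ll, best_tree = ll, candidate
        if best_tree is None:
            break
        current, current_ll = best_tree, best_ll
    return current


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    alignment: dict[str, str],
    model: JttModel | None = None,
    replicates: int = 100,
    seed: int = 0,
    reference_tree: PhyloTree | None = None,
) -> PhyloTree:
    """Site-resampling bootstrap; replicate trees are NJ on ML distances.

    Support for each internal split of the reference tree is the percentage
    of replicate trees containing it. Bit-reproducible for a fixed seed.
    """
    if replicates < 1:
        raise PhyloError("need at least one bootstrap replicate")
    model = model or load_jtt()
    if reference_tree is None:
        reference_tree = build_nj_tree(DistanceMatrix.from_alignment(alignment, model))
    rng = np.random.default_rng(seed)
    labels = sorted(alignment)
    encoded = np.stack([encode_sequence(alignment[lab]) for lab in labels])
    nsites = encoded.shape[1]
    ref_splits = reference_tree.splits()
    counts = {split: 0 for split in ref_splits}
    n = len(labels)
    for _ in range(replicates):
        cols = rng.integers(0, nsites, size=nsites)
        sample = encoded[:, cols]
        m = np.zeros((n, n))
        try:
            for i, j in itertools.combinations(range(n), 2):
                d = ml_distance_from_counts(_pair_counts(sample[i], sample[j]), model)
                m[i, j] = m[j, i] = d
            rep_splits = build_nj_tree(DistanceMatrix(labels, m)).splits()
        except PhyloError:
            continue  # degenerate resample (e.g. all-gap column draw)
        for split in ref_splits:
            if split in rep_splits:
                counts[split] += 1
    out = reference_tree.copy()
    out.support = {
        split: 100.0 * c / replicates for split, c in counts.items()
    }
    return out


# ---------------------------------------------------------------------------
# subgroup assignment


def assign_subgroup(
    tree: PhyloTree, anchors_i: set[str], anchors_ii: set[str]
) -> dict[str, str]:
    """Assign each leaf to subgroup I or II by the deepest separating split.

    Among all splits placing every subgroup-I anchor on one side and every
    subgroup-II anchor on the other, the most balanced one is used; each
    taxon takes the subgroup of the anchors sharing its side. If no
    separating split exists, non-anchor taxa are reported ``unassignable``.
    """
    anchors_i, anchors_ii = set(anchors_i), set(anchors_ii)
    if not anchors_i or not anchors_ii:
        raise PhyloError("both anchor sets must be non-empty")
    if anchors_i & anchors_ii:
        raise PhyloError("anchor sets overlap")
    leaf_set = set(tree.leaf_labels())
    missing = (anchors_i | anchors_ii) - leaf_set
    if missing:
        raise PhyloError(f"anchor labels absent from tree: {sorted(missing)}")

    best = None
    for u, v in tree.internal_edges():
        side = tree._side_labels(u, v)
        comp = leaf_set - side
        for s, c in ((side, comp), (comp, side)):
            if anchors_i <= s and anchors_ii <= c:
                balance = min(len(s), len(c))
                key = (balance, tuple(sorted(s)))
                if best is None or key > best[0]:
                    best = (key, s)
    call: dict[str, str] = {}
    for taxon in sorted(leaf_set):
        if taxon in anchors_i:
            call[taxon] = "I"
        elif taxon in anchors_ii:
            call[taxon] = "II"
        elif best is None:
            call[taxon] = "unassignable"
        else:
            call[taxon] = "I" if taxon in best[1] else "II"
    return call
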