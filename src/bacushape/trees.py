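"""Array-backed rooted phylogenies and regime-painted (simmap-style) trees.

Newick/NEXUS parsing and serialization are delegated to dendropy; this module
keeps a flat array representation (parent pointers, branch lengths, postorder)
because the comparative machinery rebuilds covariance matrices inside
optimizer loops and samples per-branch regime histories, both of which need
cheap indexed access rather than object traversal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "RegimePaintedTree"]


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in time units.

    Nodes are indexed ``0..n_nodes-1`` with tips first (``0..n_tips-1``,
    matching ``tip_labels`` order) and the root last in ``postorder``.
    ``parent[root] == -1`` and ``edge_length[root] == 0``.
    """

    parent: np.ndarray          # (n_nodes,) int
    edge_length: np.ndarray     # (n_nodes,) float, length of edge above node
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        self._index()

    def _index(self) -> None:
        n = self.parent.size
        (roots,) = np.nonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.n_tips = len(self.tip_labels)
        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                children[p].append(v)
        self.children = children
        # iterative postorder
        post: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(children[v])
        post.reverse()
        self.postorder = np.array(post, dtype=int)
        # node heights (distance from root)
        h = np.zeros(n)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                h[v] = h[p] + self.edge_length[v]
        self.node_height = h

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tree_length(self) -> float:
        return float(self.edge_length.sum())

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        depths = self.node_height[: self.n_tips]
        return bool(np.ptp(depths) <= tol * max(1.0, depths.max()))

    def root_height(self) -> float:
        return float(self.node_height[: self.n_tips].max())

    def rescale(self, new_height: float = 1.0) -> "Phylogeny":
        """Return a copy with root-to-tip height scaled to ``new_height``."""
        h = self.root_height()
        if h <= 0:
            raise ValueError("tree has zero height")
        return Phylogeny(self.parent.copy(), self.edge_length * (new_height / h),
                         list(self.tip_labels))

    # -- descendant bookkeeping -------------------------------------------
    def tip_descendants(self) -> list[np.ndarray]:
        """Tip indices below each node (a tip is its own descendant)."""
        desc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in self.postorder:
            if not self.children[v]:
                desc[v] = [v]
            else:
                for c in self.children[v]:
                    desc[v].extend(desc[c])
        return [np.array(d, dtype=int) for d in desc]

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of MRCA node indices (cached)."""
        if getattr(self, "_mrca_cache", None) is not None:
            return self._mrca_cache
        n = self.n_tips
        M = np.empty((n, n), dtype=int)
        np.fill_diagonal(M, np.arange(n))
        desc = self.tip_descendants()
        for v in self.postorder:
            ch = self.children[v]
            for i in range(len(ch)):
                for j in range(i + 1, len(ch)):
                    a, b = desc[ch[i]], desc[ch[j]]
                    M[np.ix_(a, b)] = v
                    M[np.ix_(b, a)] = v
        self._mrca_cache = M
        return M

    def vcv(self) -> np.ndarray:
        """Brownian-motion tip covariance: shared root-to-MRCA path length."""
        if getattr(self, "_vcv_cache", None) is None:
            M = self.mrca_matrix()
            C = self.node_height[M]
            np.fill_diagonal(C, self.node_height[: self.n_tips])
            self._vcv_cache = C
        return self._vcv_cache.copy()

    # -- I/O ----------------------------------------------------------------
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = taxa.get_taxon(lab)
        for v in range(self.n_nodes):
            nodes[v].edge.length = float(self.edge_length[v])
            for c in self.children[v]:
                nodes[v].add_child(nodes[c])
        t = dendropy.Tree(taxon_namespace=taxa)
        t.seed_node = nodes[self.root]
        return t

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick",
                                            suppress_rooting=True).strip()

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        tips = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else f"t{i}"
                  for i, lf in enumerate(tips)]
        order: dict[dendropy.Node, int] = {}
        for i, lf in enumerate(tips):
            order[lf] = i
        nxt = len(tips)
        for nd in tree.postorder_node_iter():
            if nd not in order:
                order[nd] = nxt
                nxt += 1
        parent = np.full(nxt, -1, dtype=int)
        elen = np.zeros(nxt)
        for nd in tree.preorder_node_iter():
            v = order[nd]
            if nd.parent_node is not None:
                parent[v] = order[nd.parent_node]
                elen[v] = nd.edge.length or 0.0
        return cls(parent, elen, labels)

    @classmethod
    def from_newick(cls, s: str) -> "Phylogeny":
        t = dendropy.Tree.get(data=s, schema="newick")
        return cls.from_dendropy(t)

    @classmethod
    def read(cls, path: str, schema: str = "newick") -> "Phylogeny":
        t = dendropy.Tree.get(path=str(path), schema=schema)
        return cls.from_dendropy(t)


@dataclass
class RegimePaintedTree:
    """A phylogeny whose branches carry an ordered discrete-regime history.

    ``segments[v]`` lists ``(state, duration)`` pairs along the edge above
    node ``v``, ordered rootward-to-tipward; durations sum to
    ``tree.edge_length[v]``. ``states`` is the declared regime alphabet.
    """

    tree: Phylogeny
    segments: list[list[tuple[int, float]]]
    root_state: int
    states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.states:
            k = 1 + max([self.root_state] +
                        [s for segs in self.segments for s, _ in segs])
            self.states = [str(i) for i in range(k)]
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.states)

    def validate(self, tol: float = 1e-8) -> None:
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            tot = sum(d for _, d in self.segments[v])
            if abs(tot - self.tree.edge_length[v]) > tol * max(1.0, tot):
                raise ValueError(
                    f"segment durations on edge {v} sum to {tot}, "
                    f"branch length is {self.tree.edge_length[v]}")

    def node_states(self) -> np.ndarray:
        """Regime at each node (the last segment state on its edge)."""
        out = np.empty(self.tree.n_nodes, dtype=int)
        out[self.tree.root] = self.root_state
        for v in self.tree.postorder:
            if v == self.tree.root:
                continue
            segs = self.segments[v]
            if segs:
                out[v] = segs[-1][0]
            else:   # zero-length edge inherits the parent state (set later)
                out[v] = -1
        for v in self.tree.postorder[::-1]:
            if out[v] == -1:
                out[v] = out[self.tree.parent[v]]
        return out

    def tip_states(self) -> np.ndarray:
        return self.node_states()[: self.tree.n_tips]

    def n_transitions(self) -> int:
        count = 0
        prev_state = self.node_states()
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            s = prev_state[self.tree.parent[v]]
            for st, _ in self.segments[v]:
                if st != s:
                    count += 1
                s = st
        return count

    def regime_time_to_node(self) -> np.ndarray:
        """(n_nodes, n_states) cumulative time in each regime root→node."""
        k = self.n_states
        out = np.zeros((self.tree.n_nodes, k))
        for v in self.tree.postorder[::-1]:   # preorder
            p = self.tree.parent[v]
            if p < 0:
                continue
            out[v] = out[p]
            for st, dur in self.segments[v]:
                out[v, st] += dur

        return out

    def observed_states(self) -> np.ndarray:
        seen = {self.root_state}
        for segs in self.segments:
            seen.update(s for s, _ in segs)
        return np.array(sorted(seen), dtype=int)

    # -- simmap-style serialization ----------------------------------------
    def to_simmap_newick(self) -> str:
        """Annotated Newick with per-branch ``{state,dur:state,dur}`` maps."""
        labels = self.tree.tip_labels

        def render(v: int) -> str:
            ch = self.tree.children[v]
            core = labels[v] if not ch else \
                "(" + ",".join(render(c) for c in ch) + ")"
            if v == self.tree.root:
                return core
            segs = ":".join(f"{self.states[s]},{d:.10g}"
                            for s, d in self.segments[v])
            return f"{core}:{{{segs}}}"

        return render(self.tree.root) + ";"

    @classmethod
    def from_simmap_newick(cls, s: str, states: list[str]) -> "RegimePaintedTree":
        """Parse the ``{state,dur:state,dur}`` branch annotation format."""
        return _parse_simmap(s, states)


def _parse_simmap(s: str, states: list[str]) -> RegimePaintedTree:
    """Minimal recursive-descent parser for simmap-annotated newick."""
    s = s.strip().rstrip(";")
    idx = {lab: i for i, lab in enumerate(states)}
    pos = 0

    parent_list: list[int] = []
    elen_list: list[float] = []
    seg_list: list[list[tuple[int, float]]] = []
    label_list: list[str | None] = []

    def new_node() -> int:
        parent_list.append(-1)
        elen_list.append(0.0)
        seg_list.append([])
        label_list.append(None)
        return len(parent_list) - 1

    def parse_clade() -> int:
        nonlocal pos
        v = new_node()
        if s[pos] == "(":
            pos += 1
            while True:
                c = parse_clade()
                parent_list[c] = v
                if s[pos] == ",":
                    pos += 1
                    continue
                break
            assert s[pos] == ")", f"expected ')' at {pos}"
            pos += 1
        m = re.match(r"[^:,(){};]+", s[pos:])
        if m:
            label_list[v] = m.group(0)
            pos += m.end()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            assert s[pos] == "{", "expected simmap annotation"
            end = s.index("}", pos)
            body = s[pos + 1:end]
            pos = end + 1
            segs = []
            for part in body.split(":"):
                st, dur = part.split(",")
                segs.append((idx[st], float(dur)))
            seg_list[v] = segs
            elen_list[v] = sum(d for _, d in segs)
        return v

    root = parse_clade()
    n = len(parent_list)
    # reindex: tips first in label order of appearance
    tips = [v for v in range(n) if label_list[v] is not None and
            not any(parent_list[c] == v for c in range(n))]
    internal = [v for v in range(n) if v not in tips]
    order = {v: i for i, v in enumerate(tips)}
    for j, v in enumerate(internal):
        order[v] = len(tips) + j
    parent = np.full(n, -1, dtype=int)
    elen = np.zeros(n)
    segs_out: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for v in range(n):
        w = order[v]
        parent[w] = order[parent_list[v]] if parent_list[v] >= 0 else -1
        elen[w] = elen_list[v]
        segs_out[w] = seg_list[v]
    labels = [label_list[v] for v in tips]
    phylo = Phylogeny(parent, elen, labels)  # type: ignore[arg-type]
    # root state = state of the first segment of any root child
    root_children = phylo.children[phylo.root]
    root_state = segs_out[root_children[0]][0][0] if segs_out[root_children[0]] else 0
    return RegimePaintedTree(phylo, segs_out, root_state, list(states))
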