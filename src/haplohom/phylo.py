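"""Distance matrices and neighbor-joining trees over haplotypes.

Each phased haplotype is an independent taxon; the distance between two
haplotypes is their per-site mismatch proportion (normalized Hamming
distance), i.e. one minus their haplotype homozygosity.  Trees are built
with the Saitou–Nei neighbor-joining algorithm, which recovers the
generating tree exactly whenever the input matrix is additive, and can be
rooted on a designated outgroup clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .homozygosity import pairwise_homozygosity_matrix
from .io_formats import HaplotypeMatrix, PanelError


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PanelError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise PanelError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise PanelError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise PanelError("distances must be non-negative")


def distance_matrix(m: HaplotypeMatrix) -> DistanceMatrix:
    """Pairwise mismatch-proportion distances: d(i,j) = 1 − homozygosity."""
    if m.n_sites == 0 or m.n_haplotypes == 0:
        raise PanelError("cannot build distances from an empty panel")
    d = 1.0 - pairwise_homozygosity_matrix(m.alleles).astype(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.haplotype_ids), d)


@dataclass
class NJTree:
    """Neighbor-joining tree (dendropy-backed) with clamping bookkeeping."""

    tree: dendropy.Tree
    n_clamped: int = 0

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def patristic_distances(self, labels: list[str]) -> np.ndarray:
        """Leaf-to-leaf path-length matrix in the order of ``labels``."""
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        taxa = [tns.get_taxon(lab) for lab in labels]
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return out


def parse_newick(text: str) -> NJTree:
    tree = dendropy.Tree.get(data=text, schema="newick")
    return NJTree(tree)


def neighbor_join(dm: DistanceMatrix, clamp_negative: bool = True) -> NJTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q-criterion is joined; exact ties
    resolve to the lexicographically smallest pair of subtree labels (a
    subtree is labelled by its smallest leaf).  Negative branch lengths are
    clamped to zero by default, with the number of clamped edges recorded.
    The final three subtrees are attached to an unresolved (trifurcating)
    node, giving the conventional unrooted representation.
    """
    n = len(dm.labels)
    if n < 3:
        raise PanelError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in dm.labels]
    reps = list(dm.labels)
    n_clamped = 0

    def clamp(v: float) -> float:
        nonlocal n_clamped
        if clamp_negative and v < 0:
            n_clamped += 1
            return 0.0
        return v

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q = np.minimum(Q, Q.T)  # exact symmetry despite float rounding order
        iu = np.triu_indices(m, 1)
        vals = Q[iu]
        ties = np.flatnonzero(vals == vals.min())
        i, j = min(
            ((int(iu[0][k]), int(iu[1][k])) for k in ties),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))),
        )
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = clamp(vi)
        nodes[j].edge.length = clamp(vj)
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    # resolve the last three subtrees around an unresolved central node
    root = dendropy.Node()
    (a, b, c) = range(3)
    lengths = [
        0.5 * (D[a, b] + D[a, c] - D[b, c]),
        0.5 * (D[a, b] + D[b, c] - D[a, c]),
        0.5 * (D[a, c] + D[b, c] - D[a, b]),
    ]
    for node, v in zip(nodes, lengths):
        root.add_child(node)
        node.edge.length = clamp(v)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return NJTree(tree, n_clamped=n_clamped)


def root_on_outgroup(t: NJTree, outgroup_labels: list[str]) -> NJTree:
    """Root on the edge separating the outgroup clade from the ingroup.

    The outgroup must form a clade of the unrooted tree (i.e. some edge
    bipartitions the leaves into exactly the outgroup and the rest); the
    root splits that edge's length equally.
    """
    out = set(outgroup_labels)
    all_leaves = set(lf.taxon.label for lf in t.tree.leaf_node_iter())
    missing = out - all_leaves
    if missing:
        raise PanelError(f"outgroup labels not in tree: {sorted(missing)}")
    if not out or out == all_leaves:
        raise PanelError("outgroup must be a non-empty proper subset of leaves")

    tree = t.tree.clone(depth=1)
    target_edge = None
    nearest = None
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in nd.leaf_iter()}
        if below == out or (all_leaves - below) == out:
            target_edge = nd.edge
            break
        if below & out and below - out:
            nearest = below
    if target_edge is None:
        raise PanelError(
            "outgroup is not a clade of the unrooted tree; smallest mixed "
            f"bipartition seen: {sorted(nearest) if nearest else None}"
        )
    half = (target_edge.length or 0.0) / 2
    tree.reroot_at_edge(target_edge, length1=half, length2=half)
    tree.is_rooted = True
    return NJTree(tree, n_clamped=t.n_clamped)


def is_monophyletic(t: NJTree, labels: list[str]) -> bool:
    """True if ``labels`` form a clade of (possibly unrooted) ``t``."""
    want = set(labels)
    all_leaves = set(lf.taxon.label for lf in t.tree.leaf_node_iter())
    for nd in t.tree.preorder_node_iter():
        below = {lf.taxon.label for lf in nd.leaf_iter()}
        if below == want:
            return True
        if not t.tree.is_rooted and all_leaves - below == want:
            return True
    return False


# ---------------------------------------------------------------------------
# PHYLIP square distance-matrix interop
# ---------------------------------------------------------------------------

def write_phylip_dm(dm: DistanceMatrix, path: str | Path) -> Path:
    lines = [f"{len(dm.labels):5d}"]
    for lab, row in zip(dm.labels, dm.d):
        lines.append(lab + "  " + "  ".join(f"{v:.8f}" for v in row))
    p = Path(path)
    p.write_text("\n".join(lines) + "\n")
    return p


def read_phylip_dm(path: str | Path) -> DistanceMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))
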