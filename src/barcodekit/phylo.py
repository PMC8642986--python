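"""Neighbor-joining trees, nonparametric bootstrap, and monophyly scoring.

Trees are ``dendropy.Tree`` objects; NJ output is unrooted (the seed node
has degree 3) and the rooting is irrelevant to every consumer here because
support and monophyly both attach to leaf-set bipartitions, not nodes.

Externally built trees (e.g. ML or Bayesian) can be loaded with
``read_newick`` — internal node labels are interpreted as support
percentages — and scored with the same ``monophyly_assess``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distmat import DEFAULT_MIN_OVERLAP, DistanceMatrix, encode_alignment, matrix_from_codes
from .seq_io import MarkerAlignment, SpecimenRecord


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a complete finite distance matrix.

    Negative branch length estimates are clamped to zero with the deficit
    transferred to the sibling branch, preserving the pair's path length.
    MISSING or saturated entries are refused: filter the matrix first.
    """
    n = len(m.ids)
    if n < 3:
        raise ValueError("nj_tree needs at least 3 taxa")
    if not np.all(np.isfinite(m.d)):
        raise ValueError("nj_tree requires a complete finite matrix (no MISSING/saturated entries)")

    tns = dendropy.TaxonNamespace()
    nodes: Dict[int, dendropy.Node] = {}
    for i, sid in enumerate(m.ids):
        leaf = dendropy.Node(taxon=tns.new_taxon(sid))
        nodes[i] = leaf

    D = m.d.astype(float).copy()
    active = list(range(n))
    next_idx = n
    # Grow D lazily: index by position within `active`.
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=0)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        gi, gj = active[i_loc], active[j_loc]
        parent = dendropy.Node()
        ci, cj = nodes.pop(gi), nodes.pop(gj)
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = float(li)
        cj.edge.length = float(lj)
        # Distances from the new node to every other active node.
        grown = np.pad(D, ((0, 1), (0, 1)))
        for loc, g in enumerate(active):
            if g in (gi, gj):
                continue
            grown[next_idx, g] = grown[g, next_idx] = 0.5 * (
                sub[i_loc, loc] + sub[j_loc, loc] - dij
            )
        D = grown
        nodes[next_idx] = parent
        active = [g for g in active if g not in (gi, gj)] + [next_idx]
        next_idx += 1

    # Terminal 3-taxon star: exact branch lengths.
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    center = dendropy.Node()
    for g, ln in zip((a, b, c), (la, lb, lc)):
        child = nodes.pop(g)
        center.add_child(child)
        child.edge.length = float(ln)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths induced by the tree's branch lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(ids, d, np.zeros((n, n), dtype=int))


def bipartitions(tree: dendropy.Tree) -> Dict[FrozenSet[str], dendropy.Node]:
    """Nontrivial leaf-set bipartitions, keyed by the side excluding a fixed
    reference leaf so the key is rooting-invariant."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    out: Dict[FrozenSet[str], dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = node._leafset if ref not in node._leafset else leaves - node._leafset
        if 2 <= len(side) <= len(leaves) - 2:
            out.setdefault(side, node)
    return out


def _node_support(node: Optional[dendropy.Node]) -> Optional[float]:
    if node is None:
        return None
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def bootstrap_support(
    aln: MarkerAlignment,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dendropy.Tree:
    """NJ point-estimate tree annotated with column-bootstrap support.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    internal edge of the point tree receives the percentage of replicate NJ
    trees containing the same bipartition.  Saturated distances are replaced
    by 1.5x the largest finite distance so replicates stay computable; a
    MISSING entry (insufficient overlap) raises.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids, codes = encode_alignment(aln)
    if len(ids) < 3:
        raise ValueError("bootstrap_support needs at least 3 sequences")
    rng = np.random.default_rng(seed)

    def _matrix(cols: np.ndarray) -> DistanceMatrix:
        m = matrix_from_codes(ids, cols, min_overlap=min_overlap)
        if np.isnan(m.d).any():
            raise ValueError("MISSING distances (insufficient overlap); filter sequences first")
        if np.isinf(m.d).any():
            cap = 1.5 * np.max(m.d[np.isfinite(m.d)])
            m.d[np.isinf(m.d)] = cap
        return m

    point = nj_tree(_matrix(codes))
    point_bips = bipartitions(point)
    counts = {key: 0 for key in point_bips}

    L = codes.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_tree = nj_tree(_matrix(codes[:, cols]))
        rep_bips = bipartitions(rep_tree)
        for key in counts:
            if key in rep_bips:
                counts[key] += 1

    for key, node in point_bips.items():
        sup = 100.0 * counts[key] / n_reps
        node.support = sup
        node.label = f"{sup:g}"
    return point


@dataclass
class MonophylyReport:
    """Per-species monophyly verdicts for one tree.

    ``counted`` species (>= 2 leaves, or singletons when explicitly
    included) enter the overall percentage.
    """

    table: pd.DataFrame  # species, n_leaves, is_monophyletic, support, counted
    monophyly_pct: float


def monophyly_assess(
    tree: dendropy.Tree,
    specimens: Sequence[SpecimenRecord],
    min_support: float = 50.0,
    partition_of: Optional[Dict[str, str]] = None,
    include_singletons: bool = False,
) -> MonophylyReport:
    """Score species monophyly on a (possibly support-annotated) tree.

    A species is monophyletic iff some bipartition exactly separates its
    leaves from all others and that edge's support strictly exceeds
    ``min_support`` (edges without a support value pass).  Singleton species
    are trivially monophyletic but excluded from the overall percentage
    unless ``include_singletons``.

    ``partition_of`` (species -> partition label, e.g. taxonomic order)
    restricts each test to leaves within the species' own partition; a
    species alone in its partition counts as monophyletic.  This mirrors the
    fallback of building per-order trees when a joint tree is unavailable.
    """
    leaf_names = {l.taxon.label for l in tree.leaf_node_iter()}
    species_leaves: Dict[str, set] = {}
    for rec in specimens:
        if rec.specimen_id in leaf_names and rec.group != "hybrid":
            species_leaves.setdefault(rec.species, set()).add(rec.specimen_id)
    if not species_leaves:
        raise ValueError("no labelled species have leaves in this tree")

    all_considered = frozenset().union(*species_leaves.values())
    # Precompute both orientations of every edge's leaf set.
    edge_sides: List[tuple] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
        if node.parent_node is not None:
            edge_sides.append((node._leafset, leaf_names - node._leafset, node))

    rows = []
    n_mono = n_counted = 0
    for sp in sorted(species_leaves):
        leaves = frozenset(species_leaves[sp])
        if partition_of is not None:
            part = partition_of.get(sp)
            scope = frozenset().union(
                *(species_leaves[s] for s in species_leaves if partition_of.get(s) == part)
            )
        else:
            scope = all_considered
        support: Optional[float] = None
        if leaves == scope or len(leaves) == 1:
            mono = True
        else:
            # Several edges can realize the same bipartition (e.g. the two
            # edges at a degree-2 root); the bipartition's support is the
            # defined value among them, if any.
            matched = False
            sups: List[float] = []
            for side_a, side_b, node in edge_sides:
                if side_a & scope == leaves or side_b & scope == leaves:
                    matched = True
                    sup = _node_support(node)
                    if sup is not None:
                        sups.append(sup)
            if sups:
                support = max(sups)
            mono = matched and (support is None or support > min_support)
        counted = len(leaves) >= 2 or include_singletons
        if counted:
            n_counted += 1
            n_mono += mono
        rows.append(
            {
                "species": sp,
                "n_leaves": len(leaves),
                "is_monophyletic": mono,
                "support": support,
                "counted": counted,
            }
        )
    pct = round(100.0 * n_mono / n_counted, 1) if n_counted else float("nan")
    return MonophylyReport(table=pd.DataFrame(rows), monophyly_pct=pct)


def combined_monophyly_pct(reports: Sequence[MonophylyReport]) -> float:
    """Conservative combination across tree methods: the lowest percentage."""
    if not reports:
        raise ValueError("no reports supplied")
    return min(r.monophyly_pct for r in reports)


def reroot_at_edge(tree: dendropy.Tree, edge: dendropy.Edge) -> dendropy.Tree:
    """Reroot in place, keeping support attached to bipartitions.

    Plain Newick rerooting leaves support labels on their original nodes,
    which silently reassigns them to different edges; this helper captures
    the bipartition -> support map first and restores it afterwards.
    """
    sup = {key: _node_support(node) for key, node in bipartitions(tree).items()}
    tree.reroot_at_edge(edge, update_bipartitions=False)
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
            if hasattr(node, "support"):
                node.support = None
    for key, node in bipartitions(tree).items():
        s = sup.get(key)
        if s is not None:
            node.support = s
            node.label = f"{s:g}"
    return tree


def read_newick(path) -> dendropy.Tree:
    """Load a Newick tree; internal node labels become support values."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
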