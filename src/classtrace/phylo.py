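"""Distance-based phylogenetics: p-distances, neighbour joining, and
class annotation of query sequences by co-clustering with labelled
reference leaves.

The classification step mirrors a common genome-survey idiom: motor-domain
sequences of candidate genes are placed on a neighbour-joining tree together
with representative sequences of known subfamilies plus non-family outgroups
(kinesin, ATPase, helicase); a candidate inherits the subfamily of the
smallest clade that contains it and whose reference members are of a single
class.

Trees are :class:`dendropy.Tree` objects; distance matrices are
:class:`skbio.DistanceMatrix`.  Neighbour joining is implemented here
(Saitou–Nei agglomeration) so tie-breaking and branch-length clamping are
deterministic and documented; tests cross-check it against an independent
library implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .seqio import GAP, AlignedSequenceSet

__all__ = [
    "ClassAnnotation",
    "p_distance_matrix",
    "poisson_distance_matrix",
    "nj_build",
    "read_newick",
    "write_newick",
    "read_phylip_dm",
    "write_phylip_dm",
    "tree_distance_matrix",
    "assign_class_by_coclustering",
]


class NewickParseError(ValueError):
    """Newick text could not be parsed."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pairwise_p(a: str, b: str, pair: tuple[str, str]) -> float:
    comparable = matches = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        comparable += 1
        if x == y and x != GAP:
            matches += 1
    if comparable == 0:
        raise ValueError(
            f"pair {pair[0]!r}/{pair[1]!r} has no comparable (non-dual-gap) columns"
        )
    return 1.0 - matches / comparable


def p_distance_matrix(msa: AlignedSequenceSet) -> DistanceMatrix:
    """Pairwise p-distances: fraction of differing residues per pair.

    Columns gapped in both rows of a pair are excluded from that pair's
    denominator; a column gapped in exactly one row counts as a difference.
    """
    ids = msa.ids
    n = len(ids)
    mat = np.zeros((n, n))
    rows = [row for _, row in msa.records]
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_p(rows[i], rows[j], (ids[i], ids[j]))
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def poisson_distance_matrix(msa: AlignedSequenceSet) -> DistanceMatrix:
    """Poisson-corrected distances, d = -ln(1 - p); p must be < 1."""
    pdm = p_distance_matrix(msa)
    data = np.asarray(pdm.data)
    if np.any(data >= 1.0 - 1e-12):
        raise ValueError("Poisson correction undefined for p-distance >= 1")
    return DistanceMatrix(-np.log(1.0 - data), list(pdm.ids))


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def nj_build(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted tree by Saitou–Nei neighbour joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster keys, where a cluster's key is
    the smallest leaf label it contains.  Negative branch lengths are clamped
    to zero.  Requires n >= 3 taxa and finite distances.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError(f"neighbour joining needs at least 3 taxa, got {n}")
    d = np.array(dm.data, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains NaN or infinite values")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=lab)
        nodes.append(nd)
        keys.append(lab)

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_idx = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best: tuple | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                cand = (q, key, i, j)
                if best is None or cand[0] < best[0] - 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = cand
        _, _, i, j = best  # type: ignore[misc]
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    # final three clusters join at the (unrooted) central node
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = max(length, 0.0)
        tree.seed_node.add_child(nodes[idx])
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Newick / PHYLIP round-trips
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Serialise a tree as Newick with branch lengths to ``precision``."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}f",
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text into an (unrooted) tree.

    Unbalanced parentheses raise :class:`NewickParseError` naming the
    character position of the imbalance.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character position {pos}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of input"
        )
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_phylip_dm(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a PHYLIP square distance matrix (labels padded to 10 chars)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids):5d}\n")
        for lab in dm.ids:
            row = " ".join(f"{dm[lab, other]:.6f}" for other in dm.ids)
            fh.write(f"{lab[:10]:<10s} {row}\n")


def read_phylip_dm(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (unwrapped rows)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty distance-matrix file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: bad taxon-count header") from exc
    if len(lines) - 1 != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(np.array(rows), labels)


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------

def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dd = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = dd
    return DistanceMatrix(mat, labels)


@dataclass(frozen=True)
class ClassAnnotation:
    """Class assignment of one query leaf by co-clustering."""

    query_id: str
    assigned_class: str  # a reference class label or "unclassified"
    support_clade_size: int  # reference leaves in the assigning clade


def _root_on_outgroup(
    tree: dendropy.Tree, outgroup_ids: set[str]
) -> dendropy.Tree:
    """Return a copy rooted at the midpoint of the outgroup attachment edge."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    out_present = [leaves[o] for o in sorted(outgroup_ids) if o in leaves]
    if not out_present:
        raise ValueError(
            "no outgroup leaf present in tree; rooting is undefined"
        )

    def reroot_mid(edge: dendropy.Edge) -> None:
        length = edge.length or 0.0
        tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)

    if len(out_present) == 1:
        reroot_mid(out_present[0].edge)
        return tree
    # root provisionally at one outgroup leaf, then split at the edge above
    # the ingroup MRCA (the outgroup attachment edge when outgroups are
    # monophyletic in the unrooted sense).
    reroot_mid(out_present[0].edge)
    ingroup = [
        lf.taxon for lf in tree.leaf_node_iter()
        if lf.taxon.label not in outgroup_ids
    ]
    mrca = tree.mrca(taxa=ingroup)
    if mrca is not None and mrca.parent_node is not None:
        reroot_mid(mrca.edge)
    return tree


def assign_class_by_coclustering(
    tree: dendropy.Tree,
    reference_classes: Mapping[str, str],
    outgroup_ids: Iterable[str],
) -> list[ClassAnnotation]:
    """Annotate query leaves by the class of their smallest pure clade.

    The tree is rooted on the outgroup split; every leaf that is neither a
    reference nor an outgroup is a query.  Walking from each query toward the
    root, the first ancestral clade containing any reference leaves assigns
    its class if those references are all of one class; a mixed-class clade
    (or a query stranded among outgroups) yields ``"unclassified"``.
    Deterministic given the tree; queries are reported sorted by id.
    """
    if not reference_classes:
        raise ValueError("reference_classes must be non-empty")
    outgroup_ids = set(outgroup_ids)
    rooted = _root_on_outgroup(tree, outgroup_ids)

    leaf_labels = {lf.taxon.label for lf in rooted.leaf_node_iter()}
    missing = set(reference_classes) - leaf_labels
    if missing:
        raise ValueError(f"reference ids absent from tree: {sorted(missing)}")
    queries = sorted(leaf_labels - set(reference_classes) - outgroup_ids)

    # reference leaves under each node, by postorder accumulation
    refs_below: dict[dendropy.Node, list[str]] = {}
    for nd in rooted.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            refs_below[nd] = [lab] if lab in reference_classes else []
        else:
            acc: list[str] = []
            for ch in nd.child_nodes():
                acc.extend(refs_below[ch])
            refs_below[nd] = acc

    leaf_by_label = {lf.taxon.label: lf for lf in rooted.leaf_node_iter()}
    out: list[ClassAnnotation] = []
    for q in queries:
        node = leaf_by_label[q].parent_node
        assigned, support = "unclassified", 0
        while node is not None:
            refs = refs_below[node]
            if refs:
                classes = {reference_classes[r] for r in refs}
                if len(classes) == 1:
                    assigned, support = classes.pop(), len(refs)
                break
            node = node.parent_node
        out.append(ClassAnnotation(q, assigned, support))
    return out
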