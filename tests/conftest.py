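"""Shared fixtures and independent oracle helpers.

The oracles here re-implement the rules being tested from scratch (plain
loops, no calls into the package's own logic) so that tests compare two
independent derivations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from classtrace.seqio import AlignedSequenceSet

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# random alignment battery
# ---------------------------------------------------------------------------

def random_alignment(
    rng: np.random.Generator,
    max_rows: int = 10,
    max_cols: int = 50,
    gap_prob: float = 0.15,
) -> tuple[AlignedSequenceSet, dict[str, str]]:
    """A random alignment with a random >= 2x2 class partition."""
    n_classes = int(rng.integers(2, 4))
    rows_left = int(rng.integers(2 * n_classes, max_rows + 1))
    sizes = []
    for c in range(n_classes):
        remaining_classes = n_classes - c - 1
        hi = rows_left - 2 * remaining_classes
        size = int(rng.integers(2, hi + 1)) if c < n_classes - 1 else rows_left
        sizes.append(size)
        rows_left -= size
    n_cols = int(rng.integers(5, max_cols + 1))
    records = []
    partition = {}
    k = 0
    for c, size in enumerate(sizes):
        for _ in range(size):
            rid = f"S{k:02d}"
            chars = [
                "-" if rng.random() < gap_prob else AA[int(rng.integers(len(AA)))]
                for _ in range(n_cols)
            ]
            # guarantee the row is not pure gap (SequenceRecord-ish sanity)
            if all(ch == "-" for ch in chars):
                chars[0] = "A"
            records.append((rid, "".join(chars)))
            partition[rid] = f"class{c}"
            k += 1
    return AlignedSequenceSet(tuple(records)), partition


# ---------------------------------------------------------------------------
# independent per-column trace oracle
# ---------------------------------------------------------------------------

def oracle_column_status(
    residues_by_id: list[tuple[str, str]],
    partition: dict[str, str],
    conservation: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> str:
    """Brute-force restatement of the column rule, written independently."""
    residues = [r for _, r in residues_by_id]
    n_gaps = sum(1 for r in residues if r == "-")
    if n_gaps / len(residues) > max_gap_fraction:
        return "gapped"

    def consensus(vals: list[str]) -> str | None:
        vals = [v for v in vals if v != "-"]
        if not vals:
            return None
        best = max(set(vals), key=lambda v: (vals.count(v), v))
        return best if vals.count(best) / len(vals) >= conservation - 1e-12 else None

    if consensus(residues) is not None:
        return "conserved"
    per_class: dict[str, list[str]] = {}
    for rid, res in residues_by_id:
        per_class.setdefault(partition[rid], []).append(res)
    cons = {c: consensus(v) for c, v in per_class.items()}
    if all(v is not None for v in cons.values()) and len(set(cons.values())) >= 2:
        return "class_specific"
    return "variable"


# ---------------------------------------------------------------------------
# brute-force geometry oracles
# ---------------------------------------------------------------------------

def dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def oracle_contacts(structure, cfg) -> set[tuple[int, int, str]]:
    """All-pairs distance scan over non-adjacent residues, typed."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    acidic3 = {"ASP", "GLU"}
    basic3 = {"LYS", "ARG", "HIS"}
    hydro3 = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
    out = set()
    res = structure.residues
    for i, j in itertools.combinations(range(len(res)), 2):
        if j - i < 2:
            continue
        r1, r2 = res[i], res[j]
        pair = (r1.number, r2.number)
        for acid, base in ((r1, r2), (r2, r1)):
            if acid.name in acidic3 and base.name in basic3:
                ds = [
                    dist(a.coord, b.coord)
                    for a in acid.atoms
                    if a.name not in backbone and a.element == "O"
                    for b in base.atoms
                    if b.name not in backbone and b.element == "N"
                ]
                if ds and min(ds) <= cfg.salt_bridge_cutoff:
                    out.add((*pair, "salt_bridge"))
        ds = [
            dist(a.coord, b.coord)
            for a in r1.atoms if a.element in "NO"
            for b in r2.atoms if b.element in "NO"
        ]
        if ds and min(ds) <= cfg.hbond_cutoff:
            out.add((*pair, "hbond"))
        if r1.name in hydro3 and r2.name in hydro3:
            ds = [
                dist(a.coord, b.coord)
                for a in r1.atoms if a.name not in backbone and a.element == "C"
                for b in r2.atoms if b.name not in backbone and b.element == "C"
            ]
            if ds and min(ds) <= cfg.hydrophobic_cutoff:
                out.add((*pair, "hydrophobic"))
        ca1 = [a for a in r1.atoms if a.name == "CA"]
        ca2 = [a for a in r2.atoms if a.name == "CA"]
        if ca1 and ca2 and dist(ca1[0].coord, ca2[0].coord) <= cfg.cluster_linkage_cutoff:
            out.add((*pair, "proximity"))
    return out


def oracle_components(numbers, coords, cutoff) -> list[set[int]]:
    """Connected components of the threshold graph, by label propagation."""
    parent = {n: n for n in numbers}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(numbers, 2):
        if dist(coords[a], coords[b]) <= cutoff:
            parent[find(a)] = find(b)
    comps: dict[int, set[int]] = {}
    for n in numbers:
        comps.setdefault(find(n), set()).add(n)
    return sorted(comps.values(), key=min)


def oracle_path_lengths(tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths by explicit edge-graph BFS."""
    # build adjacency over node ids
    adj: dict[int, list[tuple[int, float]]] = {}
    label_of: dict[int, str] = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(id(nd), [])
        if nd.taxon is not None:
            label_of[id(nd)] = nd.taxon.label
        if nd.parent_node is not None:
            w = nd.edge.length or 0.0
            adj.setdefault(id(nd.parent_node), []).append((id(nd), w))
            adj[id(nd)].append((id(nd.parent_node), w))
    out: dict[frozenset, float] = {}
    for start, lab in label_of.items():
        seen = {start: 0.0}
        queue = [start]
        while queue:
            cur = queue.pop()
            for nxt, w in adj[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    queue.append(nxt)
        for node, d in seen.items():
            if node in label_of and node != start:
                out[frozenset((lab, label_of[node]))] = d
    return out


def unrooted_splits(leaf_sets_fn, all_leaves) -> set[frozenset]:
    """Canonical non-trivial bipartitions from a clade-leafset iterator."""
    splits = set()
    universe = frozenset(all_leaves)
    for ls in leaf_sets_fn():
        side = frozenset(ls)
        if 1 < len(side) < len(universe) - 1:
            splits.add(frozenset((side, universe - side)))
    return splits


def dendropy_splits(tree) -> set[frozenset]:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]

    def clades():
        for nd in tree.preorder_internal_node_iter():
            yield [lf.taxon.label for lf in nd.leaf_iter()]

    return unrooted_splits(clades, leaves)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
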