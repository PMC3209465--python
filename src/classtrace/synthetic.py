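"""Seed-deterministic generators of inputs with known ("planted") truth.

Every pipeline stage has a generator that emulates its real input at desk
scale and returns the ground truth alongside:

* :func:`gen_planted_msa` — a two-(or more-)class protein alignment with
  planted conserved / class-specific / variable / gapped columns.  Defaults
  mirror the study conditions of a V-vs-XI trace: 2 classes x 15 sequences,
  300 columns, 21 class-specific columns.
* :func:`gen_labeled_tree` — a class-monophyletic tree with reference,
  query and outgroup leaves plus its exact (additive) path-length matrix.
* :func:`gen_random_tree` — an unconstrained random binary tree with its
  additive matrix, for NJ-consistency checks.
* :func:`gen_toy_structure` — PDB text for a single chain with planted
  spatial clusters and planted contact pairs at exact distances.
* :func:`gen_candidate_table` — a candidate-gene cohort (hits, domain hits,
  pre-aligned motor domains, labelled references, outgroups) with planted
  class membership and decoy rejection modes.

Amino acids are drawn uniformly rather than at natural frequencies: the
generators exist to make truth unambiguous, not to imitate evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .genome import DomainHit, SearchHit
from .phylo import tree_distance_matrix
from .seqio import AMINO_ACIDS, GAP, AlignedSequenceSet

__all__ = [
    "PlantedMsaSpec",
    "PlantedTruth",
    "ToyStructureSpec",
    "CandidateCohort",
    "gen_planted_msa",
    "gen_labeled_tree",
    "gen_random_tree",
    "gen_toy_structure",
    "gen_candidate_table",
]

_AA = list(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# planted alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMsaSpec:
    """Recipe for a planted-truth alignment.

    The status fractions are of ``n_columns`` (rounded); the remainder is
    planted as gapped columns (gap fraction 0.6, above the default 0.5
    tracing cutoff).  ``substitution_noise`` / ``gap_noise`` are per-cell
    probabilities applied after planting.
    """

    n_classes: int = 2
    rows_per_class: int = 15
    n_columns: int = 300
    fraction_conserved: float = 0.40
    fraction_class_specific: float = 0.07  # 21 of 300 columns
    fraction_variable: float = 0.50
    substitution_noise: float = 0.0
    gap_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.fraction_conserved, self.fraction_class_specific,
              self.fraction_variable)
        if any(not 0.0 <= f <= 1.0 for f in fr) or sum(fr) > 1.0 + 1e-9:
            raise ValueError("status fractions must lie in [0,1] and sum <= 1")
        if self.rows_per_class < 2:
            raise ValueError("rows_per_class must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for p in (self.substitution_noise, self.gap_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("noise probabilities must lie in [0,1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted alignment."""

    column_status: tuple[str, ...]  # per column, 1-based order
    class_residues: tuple[Mapping[str, str] | None, ...]  # per column
    labels: Mapping[str, str]  # sequence id -> class label

    @property
    def class_specific_columns(self) -> set[int]:
        return {
            i + 1 for i, s in enumerate(self.column_status)
            if s == "class_specific"
        }


def _class_names(n: int) -> list[str]:
    base = ["V", "XI"]  # the two-subfamily contrast the defaults emulate
    return base[:n] + [f"C{i}" for i in range(3, n + 1)]


def gen_planted_msa(
    spec: PlantedMsaSpec = PlantedMsaSpec(),
) -> tuple[AlignedSequenceSet, dict[str, str], PlantedTruth]:
    """Generate an alignment with planted column statuses.

    Conserved columns share one residue in every row; class-specific columns
    draw a distinct residue per class; variable columns are i.i.d. uniform;
    gapped columns put gaps in 60% of rows.  Noise (substitution, then gap)
    is applied last, cell-wise.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    classes = _class_names(spec.n_classes)
    ids = [f"{c}_{i:02d}" for c in classes for i in range(1, spec.rows_per_class + 1)]
    labels = {f"{c}_{i:02d}": c for c in classes for i in range(1, spec.rows_per_class + 1)}
    n_rows, n_cols = len(ids), spec.n_columns

    n_cons = round(spec.fraction_conserved * n_cols)
    n_spec = round(spec.fraction_class_specific * n_cols)
    n_var = round(spec.fraction_variable * n_cols)
    if n_cons + n_spec + n_var > n_cols:
        raise ValueError("rounded status counts exceed n_columns")
    statuses = (
        ["conserved"] * n_cons + ["class_specific"] * n_spec
        + ["variable"] * n_var
        + ["gapped"] * (n_cols - n_cons - n_spec - n_var)
    )
    rng.shuffle(statuses)

    grid = np.empty((n_rows, n_cols), dtype="<U1")
    class_residues: list[Mapping[str, str] | None] = []
    row_class = np.array([labels[i] for i in ids])
    n_gap_rows = math.ceil(0.6 * n_rows)
    for j, status in enumerate(statuses):
        if status == "conserved":
            res = rng.choice(_AA)
            grid[:, j] = res
            class_residues.append({c: res for c in classes})
        elif status == "class_specific":
            picks = rng.choice(_AA, size=spec.n_classes, replace=False)
            per_class = dict(zip(classes, picks))
            for c in classes:
                grid[row_class == c, j] = per_class[c]
            class_residues.append(per_class)
        elif status == "variable":
            grid[:, j] = rng.choice(_AA, size=n_rows)
            class_residues.append(None)
        else:  # gapped
            grid[:, j] = rng.choice(_AA, size=n_rows)
            gap_rows = rng.choice(n_rows, size=n_gap_rows, replace=False)
            grid[gap_rows, j] = GAP
            class_residues.append(None)

    if spec.substitution_noise > 0:
        mask = rng.random((n_rows, n_cols)) < spec.substitution_noise
        grid[mask] = rng.choice(_AA, size=int(mask.sum()))
    if spec.gap_noise > 0:
        mask = rng.random((n_rows, n_cols)) < spec.gap_noise
        grid[mask] = GAP

    records = tuple((rid, "".join(grid[i])) for i, rid in enumerate(ids))
    msa = AlignedSequenceSet(records)
    truth = PlantedTruth(tuple(statuses), tuple(class_residues), labels)
    return msa, labels, truth


# ---------------------------------------------------------------------------
# labelled trees and additive matrices
# ---------------------------------------------------------------------------

def _random_binary_subtree(
    leaves: list[dendropy.Node], rng: np.random.Generator
) -> dendropy.Node:
    """Join nodes pairwise at random into one binary subtree root."""
    pool = list(leaves)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(int(j))
        a = pool.pop(int(i))
        parent = dendropy.Node()
        a.edge.length = float(rng.uniform(0.05, 0.5))
        b.edge.length = float(rng.uniform(0.05, 0.5))
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    return pool[0]


def _leaf(tns: dendropy.TaxonNamespace, label: str) -> dendropy.Node:
    nd = dendropy.Node()
    nd.taxon = tns.require_taxon(label=label)
    return nd


def gen_labeled_tree(
    n_classes: int = 2,
    leaves_per_class: int = 5,
    queries_per_class: int = 2,
    n_outgroups: int = 3,
    seed: int = 0,
):
    """A class-monophyletic tree with grafted queries and outgroups.

    Reference leaves are ``REF_<class>_<i>``, queries ``Q_<class>_<i>``
    (grafted inside their class clade, so their planted class is the truth
    for co-clustering), outgroups ``OUT_<i>``.  Returns
    ``(tree, reference_classes, outgroup_ids, query_truth, additive_dm)``
    where the distance matrix holds the exact leaf-to-leaf path lengths.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if leaves_per_class < 2:
        raise ValueError("leaves_per_class must be >= 2 for a class clade")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    classes = _class_names(n_classes)

    reference_classes: dict[str, str] = {}
    query_truth: dict[str, str] = {}
    class_roots = []
    for c in classes:
        members = []
        for i in range(1, leaves_per_class + 1):
            lab = f"REF_{c}_{i}"
            reference_classes[lab] = c
            members.append(_leaf(tns, lab))
        for i in range(1, queries_per_class + 1):
            lab = f"Q_{c}_{i}"
            query_truth[lab] = c
            members.append(_leaf(tns, lab))
        root = _random_binary_subtree(members, rng)
        root.edge.length = float(rng.uniform(0.3, 0.8))
        class_roots.append(root)

    ingroup = _random_binary_subtree(class_roots, rng) if len(class_roots) > 1 else class_roots[0]
    ingroup.edge.length = float(rng.uniform(0.5, 1.0))

    outgroup_ids = {f"OUT_{i}" for i in range(1, n_outgroups + 1)}
    out_nodes = [_leaf(tns, lab) for lab in sorted(outgroup_ids)]
    if len(out_nodes) > 1:
        out_root = _random_binary_subtree(out_nodes, rng)
    else:
        out_root = out_nodes[0]
    out_root.edge.length = float(rng.uniform(1.0, 2.0))

    tree.seed_node.add_child(ingroup)
    tree.seed_node.add_child(out_root)
    tree.is_rooted = False
    dm = tree_distance_matrix(tree)
    return tree, reference_classes, outgroup_ids, query_truth, dm


def gen_random_tree(n_leaves: int, seed: int = 0):
    """Random binary tree over ``T1..Tn`` with its additive path-length
    matrix (for NJ-consistency checks)."""
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves for a non-trivial topology")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = [_leaf(tns, f"T{i}") for i in range(1, n_leaves + 1)]
    root = _random_binary_subtree(leaves, rng)
    # make the seed node trifurcating (an unrooted binary tree)
    a, b = root.child_nodes()
    root.remove_child(a)
    root.remove_child(b)
    for child in (a, b):
        tree.seed_node.add_child(child)
    if not a.is_leaf():
        ga, gb = a.child_nodes()
        a.remove_child(ga)
        tree.seed_node.add_child(ga)
        ga.edge.length = (ga.edge.length or 0.1) + (a.edge.length or 0.1)
        if len(a.child_nodes()) == 1:
            only = a.child_nodes()[0]
            only.edge.length = (only.edge.length or 0.1) + (a.edge.length or 0.1)
            a.remove_child(only)
            tree.seed_node.remove_child(a)
            tree.seed_node.add_child(only)
    tree.is_rooted = False
    return tree, tree_distance_matrix(tree)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureSpec:
    """Recipe for a toy single-chain structure.

    ``clusters`` lists groups of residue numbers; members of a cluster are
    chained at ``intra_spacing`` Å Cα steps (below the linkage cutoff) and
    cluster anchors sit ``inter_separation`` Å apart (> 3x the cutoff).
    ``contact_pairs`` are ``(res_a, res_b, kind, distance)`` with kind in
    {"salt_bridge", "hbond", "hydrophobic"}; the pair's defining atoms are
    placed at exactly ``distance`` Å.
    """

    n_residues: int = 10
    clusters: tuple[tuple[int, ...], ...] = ()
    contact_pairs: tuple[tuple[int, int, str, float], ...] = ()
    intra_spacing: float = 5.0
    inter_separation: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        seen: set[int] = set()
        for cl in self.clusters:
            for r in cl:
                if not 1 <= r <= self.n_residues:
                    raise ValueError(f"cluster residue {r} out of range")
                if r in seen:
                    raise ValueError(f"residue {r} in more than one cluster")
                seen.add(r)
        for a, b, kind, dist in self.contact_pairs:
            if kind not in ("salt_bridge", "hbond", "hydrophobic"):
                raise ValueError(f"unknown planted contact kind {kind!r}")
            if dist <= 0:
                raise ValueError("planted contact distance must be positive")


#: residue types and the side-chain atoms that realise each planted contact
_CONTACT_RECIPES = {
    "salt_bridge": (("ASP", "OD1", "O"), ("LYS", "NZ", "N")),
    "hbond": (("SER", "OG", "O"), ("SER", "OG", "O")),
    "hydrophobic": (("LEU", "CD1", "C"), ("VAL", "CG1", "C")),
}


def _pdb_atom_line(
    serial: int, name: str, resname: str, resnum: int, xyz: tuple[float, float, float],
    element: str,
) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} A{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def gen_toy_structure(
    spec: ToyStructureSpec = ToyStructureSpec(),
) -> tuple[str, dict]:
    """Emit PDB text for a toy chain and the planted truth.

    Truth dict keys: ``clusters`` (list of frozensets of residue numbers,
    including singletons for unclustered residues) and ``contacts`` (the
    planted ``(a, b, kind, distance)`` tuples).  Atom distances are verified
    post-hoc to 0.01 Å; infeasibility raises ``ValueError``.
    """
    in_cluster = {r for cl in spec.clusters for r in cl}
    singles = [r for r in range(1, spec.n_residues + 1) if r not in in_cluster]

    # at most one planted contact per residue keeps the geometry solvable
    partner: dict[int, tuple[int, str, float]] = {}
    for a, b, kind, dist in spec.contact_pairs:
        for r in (a, b):
            if r in partner:
                raise ValueError(
                    f"residue {r} participates in more than one planted contact"
                )
        same_cluster = any(a in cl and b in cl for cl in spec.clusters)
        both_single = a not in in_cluster and b not in in_cluster
        if not (same_cluster or both_single):
            raise ValueError(
                f"contact pair {a}-{b} spans different planted groups; "
                "a planted contact must stay within one spatial group"
            )
        partner[a] = (b, kind, dist)
        partner[b] = (a, kind, dist)

    resnames = {r: "GLY" for r in range(1, spec.n_residues + 1)}
    extra_atoms: dict[int, list[tuple[str, str, np.ndarray]]] = {
        r: [] for r in range(1, spec.n_residues + 1)
    }
    anchors: dict[int, np.ndarray] = {}  # residue -> C-alpha position

    def _place_contact(first: int, second: int) -> None:
        """Realise a planted atom pair once ``first`` has an anchor."""
        a, b, kind, dist = next(
            pr for pr in spec.contact_pairs if {pr[0], pr[1]} == {first, second}
        )
        (rn_a, atom_a, el_a), (rn_b, atom_b, el_b) = _CONTACT_RECIPES[kind]
        resnames[a], resnames[b] = rn_a, rn_b
        at_first, el_first = (atom_a, el_a) if first == a else (atom_b, el_b)
        at_second, el_second = (atom_b, el_b) if first == a else (atom_a, el_a)
        pa = anchors[first] + np.array([1.5, 0.0, 0.0])
        pb = pa + np.array([0.0, 0.0, dist])
        anchors[second] = pb + np.array([1.5, 0.0, 0.0])
        extra_atoms[first].append((at_first, el_first, pa))
        extra_atoms[second].append((at_second, el_second, pb))

    # lay out clusters as C-alpha chains, realising planted contacts during
    # the walk (partners end up sqrt(9 + d^2) apart, inside the linkage
    # cutoff for any planted distance below it); singletons go on
    # well-separated sites afterwards
    site = 0
    for cl in spec.clusters:
        origin = np.array([site * spec.inter_separation, 0.0, 0.0])
        prev: int | None = None
        for r in sorted(cl):
            if r in anchors:
                prev = r
                continue  # already placed as a contact partner
            if r in partner and partner[r][0] in anchors:
                _place_contact(partner[r][0], r)
            elif prev is None:
                anchors[r] = origin
            else:
                anchors[r] = anchors[prev] + np.array(
                    [0.0, spec.intra_spacing, 0.0]
                )
            prev = r
        site += 1
    for r in singles:
        if r in anchors:
            continue
        if r in partner and partner[r][0] in anchors:
            _place_contact(partner[r][0], r)
        else:
            anchors[r] = np.array([site * spec.inter_separation, 0.0, 0.0])
            site += 1

    lines = ["HEADER    TOY STRUCTURE (SYNTHETIC)"]
    serial = 1
    for r in range(1, spec.n_residues + 1):
        lines.append(
            _pdb_atom_line(serial, "CA", resnames[r], r, tuple(anchors[r]), "C")
        )
        serial += 1
        for name, el, xyz in extra_atoms[r]:
            lines.append(_pdb_atom_line(serial, name, resnames[r], r, tuple(xyz), el))
            serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"

    # post-hoc verification of every planted distance
    atom_pos = {}
    for r in range(1, spec.n_residues + 1):
        atom_pos[(r, "CA")] = anchors[r]
        for name, _, xyz in extra_atoms[r]:
            atom_pos[(r, name)] = xyz
    for a, b, kind, dist in spec.contact_pairs:
        (_, atom_a, _), (_, atom_b, _) = _CONTACT_RECIPES[kind]
        got = float(np.linalg.norm(atom_pos[(a, atom_a)] - atom_pos[(b, atom_b)]))
        if abs(got - dist) > 0.01:
            raise ValueError(
                f"planted {kind} {a}-{b}: realised {got:.3f} Å != {dist} Å"
            )

    # truth clusters: planted clusters plus singletons, with singleton pairs
    # that a planted contact pulled together merged into one group
    groups: list[set[int]] = [set(cl) for cl in spec.clusters] + [
        {r} for r in singles
    ]
    for a, b, _, _ in spec.contact_pairs:
        ga = next(g for g in groups if a in g)
        gb = next(g for g in groups if b in g)
        if ga is not gb:
            ga |= gb
            groups.remove(gb)
    truth_clusters = [frozenset(g) for g in groups]
    truth = {"clusters": truth_clusters, "contacts": list(spec.contact_pairs)}
    return text, truth


# ---------------------------------------------------------------------------
# candidate cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateCohort:
    """A synthetic genome-scan cohort with planted truth.

    ``truth`` maps candidate id to "XI" / "VIII" / a decoy rejection reason.
    """

    candidates: Mapping[str, str]  # id -> annotation string
    hits: tuple[SearchHit, ...]
    domains: tuple[DomainHit, ...]
    msa: AlignedSequenceSet
    reference_classes: Mapping[str, str]
    outgroup_ids: frozenset[str]
    truth: Mapping[str, str]

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": h.query_id, "subject_id": h.subject_id,
                    "identity": h.identity, "evalue": h.evalue,
                    "coverage": h.coverage, "annotation": h.subject_annotation,
                }
                for h in self.hits
            ]
        )

    def domains_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seq_id": d.seq_id, "source": d.source, "name": d.name,
                    "start": d.start, "end": d.end, "score": d.score,
                }
                for d in self.domains
            ]
        )

    def write(self, directory) -> tuple[str, str]:
        """Emit hits.tsv and domains.tsv; returns their paths."""
        from pathlib import Path

        d = Path(directory)
        hp, dp = d / "hits.tsv", d / "domains.tsv"
        self.hits_frame().to_csv(hp, sep="\t", index=False)
        self.domains_frame().to_csv(dp, sep="\t", index=False)
        return str(hp), str(dp)


def _xi_domains(cid: str, rng: np.random.Generator) -> list[DomainHit]:
    j = lambda: int(rng.integers(-10, 11))
    out = [
        DomainHit(cid, "pfam", "motor_head", 60 + j(), 730 + j(), 250.0),
        DomainHit(cid, "cdd", "motor_head", 63 + j(), 739 + j(), 230.0),
    ]
    pos = 740
    for _ in range(6):
        out.append(DomainHit(cid, "smart", "IQ", pos, pos + 22, 15.0))
        pos += 25
    out.append(DomainHit(cid, "coils", "CC", 900 + j(), 1100 + j(), 0.0))
    out.append(DomainHit(cid, "pfam", "DIL", 1300 + j(), 1450 + j(), 90.0))
    out.append(DomainHit(cid, "cdd", "DIL", 1302 + j(), 1452 + j(), 85.0))
    return out


def _viii_domains(cid: str, rng: np.random.Generator) -> list[DomainHit]:
    j = lambda: int(rng.integers(-10, 11))
    return [
        DomainHit(cid, "pfam", "motor_head", 190 + j(), 860 + j(), 240.0),
        DomainHit(cid, "cdd", "motor_head", 192 + j(), 868 + j(), 220.0),
        DomainHit(cid, "coils", "CC", 900 + j(), 1050 + j(), 0.0),
    ]


def gen_candidate_table(
    n_true_XI: int = 9,
    n_true_VIII: int = 1,
    n_decoys: int = 5,
    seed: int = 0,
) -> CandidateCohort:
    """Generate a cohort of candidate genes with planted classes.

    True XI/VIII candidates carry strong hits, family-consistent domain
    architectures across >= 2 sources (with jittered boundaries), and
    motor-domain rows pre-aligned with class-labelled references plus three
    non-family outgroups.  Decoys cycle three rejection modes:
    ``low_identity_unannotated`` (no family keyword, identity < 35%),
    ``no_significant_hit`` (fails E-value/coverage), and ``architecture``
    (keyword-free but similar, with a kinase architecture).  The defaults
    mirror a plant-genome survey yielding nine XI and one VIII gene.
    """
    if min(n_true_XI, n_true_VIII, n_decoys) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)

    candidates: dict[str, str] = {}
    hits: list[SearchHit] = []
    domains: list[DomainHit] = []
    truth: dict[str, str] = {}

    def add_hit(cid: str, identity: float, evalue: float, coverage: float,
                annotation: str) -> None:
        hits.append(
            SearchHit(f"REF_MYO_{int(rng.integers(1, 20))}", cid,
                      round(identity, 1), evalue, round(coverage, 2), annotation)
        )

    xi_ids, viii_ids = [], []
    for i in range(1, n_true_XI + 1):
        cid = f"CAND_XI_{i:02d}"
        xi_ids.append(cid)
        # half annotated (category 1), half hypothetical (category 2)
        annotation = (
            "myosin XI heavy chain" if i % 2 == 1 else "hypothetical protein"
        )
        candidates[cid] = annotation
        add_hit(cid, rng.uniform(45, 80), 10 ** rng.uniform(-120, -40),
                rng.uniform(0.7, 1.0), annotation)
        domains.extend(_xi_domains(cid, rng))
        truth[cid] = "XI"
    for i in range(1, n_true_VIII + 1):
        cid = f"CAND_VIII_{i:02d}"
        viii_ids.append(cid)
        annotation = "myosin VIII"
        candidates[cid] = annotation
        add_hit(cid, rng.uniform(30, 45), 10 ** rng.uniform(-90, -30),
                rng.uniform(0.6, 0.9), annotation)
        domains.extend(_viii_domains(cid, rng))
        truth[cid] = "VIII"

    decoy_modes = ["low_identity_unannotated", "no_significant_hit", "architecture"]
    for i in range(1, n_decoys + 1):
        cid = f"DECOY_{i:02d}"
        mode = decoy_modes[(i - 1) % len(decoy_modes)]
        if mode == "low_identity_unannotated":
            candidates[cid] = "hypothetical protein"
            add_hit(cid, rng.uniform(15, 30), 1e-8, rng.uniform(0.3, 0.6),
                    candidates[cid])
            domains.append(DomainHit(cid, "pfam", "kinase", 10, 300, 120.0))
        elif mode == "no_significant_hit":
            candidates[cid] = "unknown protein"
            add_hit(cid, rng.uniform(20, 40), 1e-3, rng.uniform(0.05, 0.15),
                    candidates[cid])
        else:  # architecture
            candidates[cid] = "hypothetical protein"
            add_hit(cid, rng.uniform(36, 45), 1e-10, rng.uniform(0.4, 0.7),
                    candidates[cid])
            domains.append(DomainHit(cid, "pfam", "kinase", 10, 300, 150.0))
            domains.append(DomainHit(cid, "cdd", "kinase", 12, 305, 140.0))
        truth[cid] = mode

    # pre-aligned motor-domain rows: class profiles with shared conserved
    # columns, class-distinct columns, and per-member substitution noise
    n_cols = 120
    n_shared = 70
    shared = rng.choice(_AA, size=n_cols)
    profiles: dict[str, np.ndarray] = {}
    distinct_cols = np.arange(n_shared, n_cols)
    for c in ("XI", "VIII"):
        prof = shared.copy()
        prof[distinct_cols] = rng.choice(_AA, size=len(distinct_cols))
        profiles[c] = prof

    def member_row(profile: np.ndarray, p_mut: float = 0.05) -> str:
        row = profile.copy()
        mask = rng.random(n_cols) < p_mut
        row[mask] = rng.choice(_AA, size=int(mask.sum()))
        return "".join(row)

    rows: list[tuple[str, str]] = []
    reference_classes: dict[str, str] = {}
    for k in range(1, 5):
        rid = f"REF_XI_{k}"
        reference_classes[rid] = "XI"
        rows.append((rid, member_row(profiles["XI"])))
    for k in range(1, 4):
        rid = f"REF_VIII_{k}"
        reference_classes[rid] = "VIII"
        rows.append((rid, member_row(profiles["VIII"])))
    for cid in xi_ids:
        rows.append((cid, member_row(profiles["XI"])))
    for cid in viii_ids:
        rows.append((cid, member_row(profiles["VIII"])))
    outgroup_ids = frozenset({"OUT_kinesin", "OUT_atpase", "OUT_helicase"})
    for og in sorted(outgroup_ids):
        rows.append((og, "".join(rng.choice(_AA, size=n_cols))))
    msa = AlignedSequenceSet(tuple(rows))

    return CandidateCohort(
        candidates, tuple(hits), tuple(domains), msa,
        reference_classes, outgroup_ids, truth,
    )
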