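"""Mapping traced columns onto a 3-D structure and typing residue contacts.

The trace names class-specific positions in reference numbering; here they
are placed on a template structure (a PDB chain), grouped into spatial
clusters, and the residue–residue interactions they participate in are
typed geometrically:

* salt bridge — side-chain O of Asp/Glu within ``salt_bridge_cutoff`` of a
  side-chain N of Lys/Arg/His;
* hydrogen bond — any N/O pair within ``hbond_cutoff`` (distance only: the
  template structures carry no hydrogens, so no donor–acceptor angle term);
* hydrophobic — side-chain carbons of two apolar residues within
  ``hydrophobic_cutoff``;
* proximity — Cα–Cα within the cluster linkage cutoff.

A substitution report then asks, with the geometry frozen, whether each
interaction would survive the class-consensus substitutions — the
qualitative inference style of comparative mechanistic analysis (e.g. a
D→N / K→L pair abolishing a switch-I salt bridge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .seqio import GAP, AlignedSequenceSet

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ContactConfig",
    "ResidueContact",
    "ColumnResidueMap",
    "SubstitutionEvent",
    "DiffEntry",
    "InteractionDiffReport",
    "read_structure",
    "map_columns_to_structure",
    "find_contacts",
    "spatial_clusters",
    "interaction_diff_report",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
ACIDIC = {"D", "E"}
BASIC = {"K", "R", "H"}
HYDROPHOBIC = {"A", "V", "L", "I", "M", "F", "W", "P", "Y"}
#: residues with side-chain N or O capable of hydrogen bonding
POLAR_SIDECHAIN = {"S", "T", "Y", "N", "Q", "D", "E", "K", "R", "H", "W"}

AA3TO1 = dict(protein_letters_3to1)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    """One residue: author number (+ insertion code), type, atoms."""

    number: int
    icode: str  # "" when absent
    name: str  # 3-letter code
    atoms: tuple[Atom, ...]

    @property
    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def ca(self) -> Atom | None:
        return self.atom("CA")

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]


@dataclass(frozen=True)
class StructureModel:
    """A single protein chain: ordered residues with atom coordinates (Å)."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"duplicate residue numbers in chain {self.chain_id!r}"
            )
        for r in self.residues:
            for a in r.atoms:
                if not np.all(np.isfinite(a.xyz)):
                    raise ValueError(
                        f"non-finite coordinates at {r.label} atom {a.name}"
                    )

    def residue(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(
            f"residue {number}{icode} not in chain {self.chain_id!r}"
        )

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass(frozen=True)
class ContactConfig:
    """Distance cutoffs (Å) for interaction typing and clustering."""

    salt_bridge_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 4.5
    cluster_linkage_cutoff: float = 8.0  # Cα–Cα, single linkage

    def __post_init__(self) -> None:
        for f in (
            self.salt_bridge_cutoff,
            self.hbond_cutoff,
            self.hydrophobic_cutoff,
            self.cluster_linkage_cutoff,
        ):
            if f <= 0:
                raise ValueError("all cutoffs must be positive")


@dataclass(frozen=True)
class ResidueContact:
    """A typed residue pair; stored with the lower-numbered residue first."""

    res1: tuple[str, int, str]  # (chain, number, icode)
    res2: tuple[str, int, str]
    res1_name: str  # 3-letter
    res2_name: str
    interaction_type: str  # salt_bridge | hbond | hydrophobic | proximity
    distance: float  # Å, minimum over qualifying atom pairs
    atom_pair: tuple[str, str]  # atom names achieving the minimum


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path, chain: str, model: int = 0
) -> StructureModel:
    """Read one chain of one model from a PDB file.

    HETATM records and waters are dropped; for disordered atoms the
    highest-occupancy altloc is kept.  A missing chain raises ``KeyError``
    listing the chains that are present.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if model >= len(models):
        raise IndexError(f"model {model} absent; file has {len(models)} model(s)")
    mdl = models[model]
    chains = {c.id: c for c in mdl}
    if chain not in chains:
        raise KeyError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}"
        )
    residues: list[Residue] = []
    for res in chains[chain]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():  # HETATM / water
            continue
        atoms: list[Atom] = []
        for atom in res:
            if atom.is_disordered():
                atom = max(atom.child_dict.values(), key=lambda a: a.get_occupancy() or 0.0)
            x, y, z = (float(v) for v in atom.get_coord())
            atoms.append(Atom(atom.get_name(), (atom.element or "").strip(), (x, y, z)))
        residues.append(
            Residue(int(resseq), icode.strip(), res.get_resname().strip(), tuple(atoms))
        )
    return StructureModel(chain, tuple(residues))


# ---------------------------------------------------------------------------
# alignment-column -> structure-residue mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnResidueMap:
    """Alignment column (1-based) → structure residue, plus mismatch list.

    ``mismatches`` lists ``(column, alignment_residue, structure_residue)``
    for mapped positions where the residue types disagree (sequence drift
    between the traced reference and the deposited structure).
    """

    mapping: Mapping[int, tuple[str, int, str]]
    mismatches: tuple[tuple[int, str, str], ...]
    identity_percent: float


def map_columns_to_structure(
    msa: AlignedSequenceSet,
    ref_id: str,
    structure: StructureModel,
    min_identity_percent: float = 30.0,
) -> ColumnResidueMap:
    """Pair alignment columns with structure residues via global alignment.

    The ungapped reference row is globally aligned (BLOSUM62) to the
    structure's observed sequence; reference positions matched to a
    structure residue are carried back to their alignment columns.
    Residues unobserved in the structure stay unmapped.  An identity below
    ``min_identity_percent`` aborts: it almost always means the wrong
    reference row or the wrong chain.
    """
    ref_row = msa.row(ref_id)
    ref_seq = ref_row.replace(GAP, "")
    struct_seq = structure.sequence
    if not struct_seq:
        raise ValueError("structure has no residues")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(ref_seq, struct_seq)[0]

    # paired (ref position, structure index), both 0-based
    pairs: list[tuple[int, int]] = []
    for (r0, r1), (s0, s1) in zip(*aln.aligned):
        pairs.extend(zip(range(r0, r1), range(s0, s1)))
    matches = sum(1 for ri, si in pairs if ref_seq[ri] == struct_seq[si])
    identity = 100.0 * matches / max(len(pairs), 1)
    if identity < min_identity_percent:
        raise ValueError(
            f"reference/structure identity {identity:.1f}% below guard "
            f"{min_identity_percent}%: check that ref_id {ref_id!r} matches "
            f"chain {structure.chain_id!r}"
        )

    # reference residue index (0-based) -> alignment column (1-based)
    res2col: dict[int, int] = {}
    resno = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch != GAP:
            res2col[resno] = col
            resno += 1

    mapping: dict[int, tuple[str, int, str]] = {}
    mismatches: list[tuple[int, str, str]] = []
    for ri, si in pairs:
        col = res2col[ri]
        res = structure.residues[si]
        mapping[col] = (structure.chain_id, res.number, res.icode)
        if ref_seq[ri] != struct_seq[si]:
            mismatches.append((col, ref_seq[ri], struct_seq[si]))
    return ColumnResidueMap(mapping, tuple(mismatches), identity)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _min_atom_distance(
    atoms1: Sequence[Atom], atoms2: Sequence[Atom]
) -> tuple[float, tuple[str, str]] | None:
    if not atoms1 or not atoms2:
        return None
    c1 = np.array([a.xyz for a in atoms1])
    c2 = np.array([a.xyz for a in atoms2])
    dmat = cdist(c1, c2)
    i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
    return float(dmat[i, j]), (atoms1[i].name, atoms2[j].name)


def _typed_contacts(
    r1: Residue, r2: Residue, cfg: ContactConfig
) -> list[tuple[str, float, tuple[str, str]]]:
    out: list[tuple[str, float, tuple[str, str]]] = []
    t1, t2 = r1.one_letter, r2.one_letter

    # salt bridge: acidic side-chain O vs basic side-chain N, either order
    for acid, base, flip in ((r1, r2, False), (r2, r1, True)):
        if acid.one_letter in ACIDIC and base.one_letter in BASIC:
            a_o = [a for a in acid.sidechain_atoms() if a.element == "O"]
            b_n = [a for a in base.sidechain_atoms() if a.element == "N"]
            hit = _min_atom_distance(a_o, b_n)
            if hit and hit[0] <= cfg.salt_bridge_cutoff:
                d, (n1, n2) = hit
                out.append(("salt_bridge", d, (n2, n1) if flip else (n1, n2)))
                break

    # hydrogen bond: any N/O vs N/O (backbone included), distance only
    no1 = [a for a in r1.atoms if a.element in ("N", "O")]
    no2 = [a for a in r2.atoms if a.element in ("N", "O")]
    hit = _min_atom_distance(no1, no2)
    if hit and hit[0] <= cfg.hbond_cutoff:
        out.append(("hbond", hit[0], hit[1]))

    # hydrophobic: side-chain carbons of two apolar residues
    if t1 in HYDROPHOBIC and t2 in HYDROPHOBIC:
        c1 = [a for a in r1.sidechain_atoms() if a.element == "C"]
        c2 = [a for a in r2.sidechain_atoms() if a.element == "C"]
        hit = _min_atom_distance(c1, c2)
        if hit and hit[0] <= cfg.hydrophobic_cutoff:
            out.append(("hydrophobic", hit[0], hit[1]))

    # proximity: Cα–Cα within the cluster linkage cutoff
    ca1, ca2 = r1.ca(), r2.ca()
    if ca1 is not None and ca2 is not None:
        d = float(np.linalg.norm(ca1.xyz - ca2.xyz))
        if d <= cfg.cluster_linkage_cutoff:
            out.append(("proximity", d, ("CA", "CA")))
    return out


def find_contacts(
    structure: StructureModel,
    pairs: Literal["all"] | Iterable[tuple[tuple[int, str], tuple[int, str]]] = "all",
    cfg: ContactConfig = ContactConfig(),
) -> list[ResidueContact]:
    """Type residue–residue contacts, one record per (pair, type).

    ``pairs="all"`` scans every residue pair except sequence-adjacent ones
    (peptide-bond geometry is not an interaction); explicit pairs, given as
    ``((number, icode), (number, icode))`` tuples, are always evaluated.
    Results are deterministic, ordered by residue pair then type, with the
    lower-numbered residue stored first.
    """
    if not structure.residues:
        raise ValueError("empty structure")
    index = {r.key: i for i, r in enumerate(structure.residues)}

    if pairs == "all":
        todo = [
            (i, j)
            for i, j in itertools.combinations(range(len(structure.residues)), 2)
            if j - i >= 2
        ]
    else:
        todo = []
        for k1, k2 in pairs:
            k1 = (k1, "") if isinstance(k1, int) else tuple(k1)
            k2 = (k2, "") if isinstance(k2, int) else tuple(k2)
            for k in (k1, k2):
                if k not in index:
                    raise KeyError(
                        f"residue {k[0]}{k[1]} not in chain {structure.chain_id!r}"
                    )
            i, j = sorted((index[k1], index[k2]))
            todo.append((i, j))

    contacts: list[ResidueContact] = []
    for i, j in todo:
        r1, r2 = structure.residues[i], structure.residues[j]
        for itype, dist, apair in _typed_contacts(r1, r2, cfg):
            contacts.append(
                ResidueContact(
                    (structure.chain_id, r1.number, r1.icode),
                    (structure.chain_id, r2.number, r2.icode),
                    r1.name,
                    r2.name,
                    itype,
                    dist,
                    apair,
                )
            )
    contacts.sort(key=lambda c: (c.res1[1], c.res1[2], c.res2[1], c.res2[2], c.interaction_type))
    return contacts


# ---------------------------------------------------------------------------
# spatial clusters
# ---------------------------------------------------------------------------

def spatial_clusters(
    positions: Iterable[int | tuple[int, str]],
    structure: StructureModel,
    cfg: ContactConfig = ContactConfig(),
) -> list[list[tuple[int, str]]]:
    """Single-linkage clusters of residues under the Cα–Cα cutoff.

    Clusters are connected components of the threshold graph; the result is
    ordered by each cluster's lowest residue number and is invariant to the
    input ordering of ``positions``.
    """
    keys = sorted(
        {(p, "") if isinstance(p, int) else (int(p[0]), p[1]) for p in positions}
    )
    if not keys:
        return []
    res = [structure.residue(n, ic) for n, ic in keys]
    cas = []
    for r in res:
        ca = r.ca()
        if ca is None:
            raise ValueError(f"residue {r.label} has no Cα atom")
        cas.append(ca.xyz)
    coords = np.array(cas)
    adj = cdist(coords, coords) <= cfg.cluster_linkage_cutoff
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [
        sorted(k for k, lab in zip(keys, labels) if lab == c)
        for c in range(n_comp)
    ]
    clusters.sort(key=lambda cl: cl[0])
    return clusters


# ---------------------------------------------------------------------------
# substitution / interaction diff report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionEvent:
    """A class-consensus substitution at a mapped structure residue.

    ``from_type`` / ``to_type`` are one-letter amino acids; e.g. the
    reference class carries D at residue 215 while the contrasted class's
    consensus is N — written D215→N.
    """

    number: int
    from_type: str
    to_type: str
    icode: str = ""

    def __post_init__(self) -> None:
        for t in (self.from_type, self.to_type):
            if t not in set("ACDEFGHIKLMNPQRSTVWY"):
                raise ValueError(f"invalid amino-acid type {t!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.from_type}{self.number}{self.icode}{self.to_type}"


@dataclass(frozen=True)
class DiffEntry:
    contact: ResidueContact
    status: str  # retained | type_changed | abolished
    before_type: str
    after_types: tuple[str, ...]


@dataclass(frozen=True)
class InteractionDiffReport:
    entries: tuple[DiffEntry, ...]
    #: entries touching each substitution, keyed by its label (may be empty)
    by_substitution: Mapping[str, tuple[DiffEntry, ...]]


def _eligible_types(
    contact: ResidueContact,
    t1: str,
    t2: str,
    cfg: ContactConfig,
) -> set[str]:
    """Interaction types a contact could carry under residue types t1/t2.

    Geometry is frozen: the observed minimum distance stands in for the
    would-be contact distance, checked against each type's own cutoff.
    Backbone N/O survive any substitution; side-chain polarity follows the
    new residue type.
    """
    d = contact.distance
    out: set[str] = set()
    if d <= cfg.salt_bridge_cutoff and (
        (t1 in ACIDIC and t2 in BASIC) or (t2 in ACIDIC and t1 in BASIC)
    ):
        out.add("salt_bridge")
    if d <= cfg.hbond_cutoff:
        a1, a2 = contact.atom_pair

        def donor_ok(atom: str, t: str) -> bool:
            return atom in BACKBONE_ATOMS or t in POLAR_SIDECHAIN

        if donor_ok(a1, t1) and donor_ok(a2, t2):
            out.add("hbond")
    if d <= cfg.hydrophobic_cutoff and t1 in HYDROPHOBIC and t2 in HYDROPHOBIC:
        if t1 != "G" and t2 != "G":
            out.add("hydrophobic")
    if contact.interaction_type == "proximity":
        out.add("proximity")  # Cα geometry is type-independent
    return out


def interaction_diff_report(
    contacts: Sequence[ResidueContact],
    substitutions: Sequence[SubstitutionEvent],
    cfg: ContactConfig = ContactConfig(),
) -> InteractionDiffReport:
    """Re-evaluate contacts under class-consensus substitutions.

    Each contact touching a substituted residue is re-typed with the new
    residue types and the geometry frozen: ``retained`` when the original
    type is still eligible, ``type_changed`` when only other types are,
    ``abolished`` when none is.  Contacts not touching any substitution are
    reported ``retained``.  A substitution with no contacts yields an empty
    entry list under its label.
    """
    subs = {s.key: s for s in substitutions}
    entries: list[DiffEntry] = []
    touched: dict[str, list[DiffEntry]] = {s.label: [] for s in substitutions}

    for c in contacts:
        k1 = (c.res1[1], c.res1[2])
        k2 = (c.res2[1], c.res2[2])
        s1, s2 = subs.get(k1), subs.get(k2)
        if s1 is None and s2 is None:
            entries.append(
                DiffEntry(c, "retained", c.interaction_type, (c.interaction_type,))
            )
            continue
        t1 = s1.to_type if s1 else AA3TO1.get(c.res1_name, "X")
        t2 = s2.to_type if s2 else AA3TO1.get(c.res2_name, "X")
        after = _eligible_types(c, t1, t2, cfg)
        if c.interaction_type in after:
            status = "retained"
        elif after:
            status = "type_changed"
        else:
            status = "abolished"
        entry = DiffEntry(c, status, c.interaction_type, tuple(sorted(after)))
        entries.append(entry)
        for s in (s1, s2):
            if s is not None:
                touched[s.label].append(entry)

    return InteractionDiffReport(
        tuple(entries),
        {lab: tuple(v) for lab, v in touched.items()},
    )
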