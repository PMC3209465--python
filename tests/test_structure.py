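"""PDB reading, column→residue mapping, contacts, clusters, diff reports."""

import pytest

from classtrace.seqio import AlignedSequenceSet
from classtrace.structure import (
    ContactConfig,
    SubstitutionEvent,
    find_contacts,
    interaction_diff_report,
    map_columns_to_structure,
    read_structure,
    spatial_clusters,
)
from classtrace.synthetic import ToyStructureSpec, gen_toy_structure

from conftest import oracle_components, oracle_contacts

# a hand-written 3-residue fixture: ALA-GLY-SER with an altloc on the SER OG
# (A at occupancy 0.6 wins) and an insertion-code residue 2A
PDB_FIXTURE = """\
HEADER    HAND-WRITTEN FIXTURE (SYNTHETIC)
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  CA  GLY A   2       5.458   0.000   0.000  1.00  0.00           C
ATOM      7  CA  GLY A   2A      7.458   0.000   0.000  1.00  0.00           C
ATOM      8  CA  SER A   3       9.458   0.000   0.000  1.00  0.00           C
ATOM      9  OG ASER A   3      10.000   1.000   0.000  0.60  0.00           O
ATOM     10  OG BSER A   3      10.000  -1.000   0.000  0.40  0.00           O
HETATM   11  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""


@pytest.fixture
def fixture_structure(tmp_path):
    p = tmp_path / "fixture.pdb"
    p.write_text(PDB_FIXTURE)
    return read_structure(p, chain="A")


def test_read_structure_residues_and_atoms(fixture_structure):
    s = fixture_structure
    assert [r.name for r in s.residues] == ["ALA", "GLY", "GLY", "SER"]
    assert len(s.residues[0].atoms) == 5  # waters dropped
    assert s.sequence == "AGGS"


def test_altloc_highest_occupancy_kept(fixture_structure):
    ser = fixture_structure.residue(3)
    og = ser.atom("OG")
    assert og is not None
    assert og.coord[1] == pytest.approx(1.0)  # the A conformer (occ 0.6)


def test_insertion_code_addressable(fixture_structure):
    res = fixture_structure.residue(2, "A")
    assert res.name == "GLY"
    with pytest.raises(KeyError):
        fixture_structure.residue(99)


def test_missing_chain_lists_available(tmp_path):
    p = tmp_path / "fixture.pdb"
    p.write_text(PDB_FIXTURE)
    with pytest.raises(KeyError, match="available chains.*A"):
        read_structure(p, chain="Z")


# ---------------------------------------------------------------------------
# column -> residue mapping
# ---------------------------------------------------------------------------

def _structure_from_sequence(tmp_path, seq, missing=()):
    """Cα-only PDB for a 1-letter sequence, optionally dropping residues."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1
    for i, aa in enumerate(seq, start=1):
        if i in missing:
            continue
        lines.append(
            f"ATOM  {serial:5d}  CA {three[aa]:>4s} A{i:4d}    "
            f"{i * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {'C':>2s}"
        )
        serial += 1
    p = tmp_path / "seq.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    return read_structure(p, chain="A")


REFSEQ = "MAKLVDEFGHIKWNPQRSTY"


def test_identity_mapping_when_sequences_match(tmp_path):
    structure = _structure_from_sequence(tmp_path, REFSEQ)
    msa = AlignedSequenceSet((("ref", REFSEQ), ("other", REFSEQ[:-1] + "W")))
    cmap = map_columns_to_structure(msa, "ref", structure)
    assert cmap.identity_percent == pytest.approx(100.0)
    assert len(cmap.mapping) == len(REFSEQ)
    for col in range(1, len(REFSEQ) + 1):
        assert cmap.mapping[col] == ("A", col, "")
    assert cmap.mismatches == ()


def test_disordered_residues_stay_unmapped(tmp_path):
    missing = {7, 8, 9, 10, 11}
    structure = _structure_from_sequence(tmp_path, REFSEQ, missing=missing)
    msa = AlignedSequenceSet((("ref", REFSEQ), ("other", REFSEQ)))
    cmap = map_columns_to_structure(msa, "ref", structure)
    unmapped = set(range(1, len(REFSEQ) + 1)) - set(cmap.mapping)
    assert unmapped == missing


def test_mismatches_reported_but_mapping_returned(tmp_path):
    mutated = "MAKLVNEFGHIKWNPQRSTY"  # D6N relative to REFSEQ
    structure = _structure_from_sequence(tmp_path, mutated)
    msa = AlignedSequenceSet((("ref", REFSEQ), ("other", REFSEQ)))
    cmap = map_columns_to_structure(msa, "ref", structure)
    assert len(cmap.mapping) == len(REFSEQ)
    assert cmap.mismatches == ((6, "D", "N"),)


def test_identity_guard_rejects_wrong_pairing(tmp_path):
    structure = _structure_from_sequence(tmp_path, "WWWWWWWWWWCCCCCCCCCC")
    msa = AlignedSequenceSet((("ref", REFSEQ), ("other", REFSEQ)))
    with pytest.raises(ValueError, match="below guard"):
        map_columns_to_structure(msa, "ref", structure)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def test_far_apart_residues_have_no_contact(tmp_path):
    text, _ = gen_toy_structure(ToyStructureSpec(n_residues=2, seed=0))
    p = tmp_path / "far.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    assert find_contacts(s, pairs=[((1, ""), (2, ""))]) == []


def test_planted_salt_bridge_is_salt_bridge_and_hbond(tmp_path):
    spec = ToyStructureSpec(
        n_residues=5, clusters=((1, 2, 3),),
        contact_pairs=((1, 3, "salt_bridge", 3.0),), seed=0,
    )
    text, _ = gen_toy_structure(spec)
    p = tmp_path / "sb.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    types = {
        c.interaction_type
        for c in find_contacts(s)
        if (c.res1[1], c.res2[1]) == (1, 3)
    }
    assert "salt_bridge" in types and "hbond" in types
    sb = next(
        c for c in find_contacts(s)
        if c.interaction_type == "salt_bridge"
    )
    assert sb.distance == pytest.approx(3.0, abs=1e-3)
    assert set(sb.atom_pair) == {"OD1", "NZ"}


def test_contacts_match_bruteforce_scan_on_toy_battery(tmp_path):
    cfg = ContactConfig()
    specs = [
        ToyStructureSpec(n_residues=6, clusters=((1, 2, 3), (4, 5, 6)),
                         contact_pairs=((1, 3, "salt_bridge", 3.0),
                                        (4, 6, "hydrophobic", 4.0)), seed=1),
        ToyStructureSpec(n_residues=7, clusters=((2, 3, 4, 5),),
                         contact_pairs=((2, 4, "hbond", 3.2),), seed=2),
        ToyStructureSpec(n_residues=4, seed=3),
    ]
    for k, spec in enumerate(specs):
        text, _ = gen_toy_structure(spec)
        p = tmp_path / f"batt{k}.pdb"
        p.write_text(text)
        s = read_structure(p, "A")
        ours = {
            (c.res1[1], c.res2[1], c.interaction_type)
            for c in find_contacts(s, cfg=cfg)
        }
        assert ours == oracle_contacts(s, cfg)


def test_explicit_pair_not_in_structure_raises(tmp_path):
    text, _ = gen_toy_structure(ToyStructureSpec(n_residues=3, seed=0))
    p = tmp_path / "t.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    with pytest.raises(KeyError, match="99"):
        find_contacts(s, pairs=[((1, ""), (99, ""))])


def test_contact_list_symmetric_and_deterministic(tmp_path):
    spec = ToyStructureSpec(n_residues=5, clusters=((1, 2, 3, 4, 5),),
                            contact_pairs=((1, 3, "salt_bridge", 3.5),), seed=4)
    text, _ = gen_toy_structure(spec)
    p = tmp_path / "t.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    fwd = find_contacts(s, pairs=[((1, ""), (3, ""))])
    rev = find_contacts(s, pairs=[((3, ""), (1, ""))])
    assert fwd == rev
    assert find_contacts(s) == find_contacts(s)


# ---------------------------------------------------------------------------
# spatial clusters
# ---------------------------------------------------------------------------

def test_single_residue_is_a_singleton_cluster(tmp_path):
    text, _ = gen_toy_structure(ToyStructureSpec(n_residues=1, seed=0))
    p = tmp_path / "one.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    assert spatial_clusters([1], s) == [[(1, "")]]


def test_planted_clusters_recovered_exactly(tmp_path):
    spec = ToyStructureSpec(
        n_residues=9, clusters=((1, 2, 3), (7, 8, 9)), seed=5
    )
    text, truth = gen_toy_structure(spec)
    p = tmp_path / "cl.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    got = [
        frozenset(n for n, _ in cl)
        for cl in spatial_clusters(range(1, 10), s)
    ]
    assert sorted(got, key=min) == sorted(truth["clusters"], key=min)


def test_clusters_equal_bruteforce_components_and_order_invariant(tmp_path):
    cfg = ContactConfig()
    spec = ToyStructureSpec(
        n_residues=10, clusters=((1, 2, 3, 4), (6, 7)), seed=6
    )
    text, _ = gen_toy_structure(spec)
    p = tmp_path / "cc.pdb"
    p.write_text(text)
    s = read_structure(p, "A")
    numbers = list(range(1, 11))
    coords = {r.number: r.ca().coord for r in s.residues}
    expected = oracle_components(numbers, coords, cfg.cluster_linkage_cutoff)
    got = [
        {n for n, _ in cl} for cl in spatial_clusters(numbers, s, cfg)
    ]
    assert got == expected
    shuffled = [numbers[i] for i in (3, 0, 9, 5, 1, 7, 2, 8, 4, 6)]
    assert spatial_clusters(shuffled, s, cfg) == spatial_clusters(numbers, s, cfg)


# ---------------------------------------------------------------------------
# interaction diff report
# ---------------------------------------------------------------------------

@pytest.fixture
def salt_bridge_structure(tmp_path):
    spec = ToyStructureSpec(
        n_residues=5, clusters=((1, 2, 3),),
        contact_pairs=((1, 3, "salt_bridge", 3.0),), seed=0,
    )
    text, _ = gen_toy_structure(spec)
    p = tmp_path / "sb.pdb"
    p.write_text(text)
    return read_structure(p, "A")


def test_charge_losing_substitutions_abolish_salt_bridge(salt_bridge_structure):
    # the switch-I scenario: D->N and K->L leave neither side charged
    contacts = find_contacts(salt_bridge_structure)
    report = interaction_diff_report(
        contacts,
        [SubstitutionEvent(1, "D", "N"), SubstitutionEvent(3, "K", "L")],
    )
    sb = [e for e in report.entries if e.before_type == "salt_bridge"]
    assert sb and all(e.status == "abolished" for e in sb)
    # the accompanying side-chain O...N hbond dies too: N is polar, L is not
    hb = [
        e for e in report.entries
        if e.before_type == "hbond"
        and (e.contact.res1[1], e.contact.res2[1]) == (1, 3)
    ]
    assert hb and all(e.status == "abolished" for e in hb)


def test_lysine_to_valine_swaps_hbond_for_hydrophobic(tmp_path):
    # a lysine side-chain NZ hydrogen-bonded to a backbone O; K->V kills the
    # hbond but the V/V pair gains hydrophobic eligibility
    pdb = (
        "ATOM      1  CA  LYS A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  NZ  LYS A   1       3.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      3  CA  GLY A   2       4.000   8.000   0.000  1.00  0.00           C\n"
        "ATOM      4  CA  VAL A   3       7.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      5  O   VAL A   3       6.000   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )
    p = tmp_path / "kv.pdb"
    p.write_text(pdb)
    s = read_structure(p, "A")
    contacts = find_contacts(s)
    hb = [c for c in contacts if c.interaction_type == "hbond"]
    assert len(hb) == 1 and hb[0].atom_pair == ("NZ", "O")
    report = interaction_diff_report(contacts, [SubstitutionEvent(1, "K", "V")])
    (entry,) = [e for e in report.entries if e.before_type == "hbond"]
    assert entry.status == "type_changed"
    assert entry.after_types == ("hydrophobic",)


def test_empty_substitution_list_retains_everything(salt_bridge_structure):
    contacts = find_contacts(salt_bridge_structure)
    report = interaction_diff_report(contacts, [])
    assert len(report.entries) == len(contacts)
    assert all(e.status == "retained" for e in report.entries)


def test_substitution_with_no_contacts_yields_empty_entry(salt_bridge_structure):
    contacts = find_contacts(salt_bridge_structure)
    sub = SubstitutionEvent(5, "G", "A")  # residue 5 is isolated
    report = interaction_diff_report(contacts, [sub])
    assert report.by_substitution[sub.label] == ()
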