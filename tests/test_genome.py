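"""Hit filtering, annotation triage, architecture consensus, full pipeline."""

import itertools
import warnings

import pytest

from classtrace.genome import (
    CandidateRecord,
    DomainHit,
    SearchHit,
    categorize_annotation,
    classify_architecture,
    consensus_architecture,
    filter_hits,
    read_domains_tsv,
    read_hits_tsv,
    run_validation,
    write_candidate_tsv,
)
from classtrace.synthetic import gen_candidate_table


def hit(evalue=1e-6, coverage=0.30, identity=50.0, subject="s1", ann="x"):
    return SearchHit("q1", subject, identity, evalue, coverage, ann)


# ---------------------------------------------------------------------------
# filter_hits
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "evalue, coverage, kept",
    [
        (1e-6, 0.30, True),   # both pass
        (1e-4, 0.30, False),  # E-value above the 1e-5 cutoff
        (1e-6, 0.10, False),  # coverage below 25%
        (1e-5, 0.25, True),   # boundary values are inclusive
    ],
)
def test_filter_hits_rules(evalue, coverage, kept):
    out = filter_hits([hit(evalue=evalue, coverage=coverage)])
    assert (len(out) == 1) is kept


def test_filter_hits_preserves_order_and_handles_empty():
    hits = [hit(subject=f"s{i}") for i in range(5)]
    assert [h.subject_id for h in filter_hits(hits)] == [f"s{i}" for i in range(5)]
    assert filter_hits([]) == []


def test_negative_evalue_rejected_at_construction():
    with pytest.raises(ValueError, match="negative E-value"):
        hit(evalue=-1.0)


# ---------------------------------------------------------------------------
# annotation triage
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "annotation, identity, expected",
    [
        ("myosin heavy chain XI", 20.0, "cat1_annotated"),
        ("Unconventional MYOSIN", 20.0, "cat1_annotated"),  # case-insensitive
        ("hypothetical protein", 51.0, "cat2_unannotated"),
        ("hypothetical protein", 30.0, "rejected"),
        ("", 40.0, "cat2_unannotated"),
    ],
)
def test_categorize_annotation(annotation, identity, expected):
    rec = CandidateRecord("c1", annotation, best_identity=identity)
    assert categorize_annotation(rec) == expected


# ---------------------------------------------------------------------------
# consensus architecture
# ---------------------------------------------------------------------------

def test_consensus_full_length_myosin_xi():
    hits = [
        DomainHit("g", "pfam", "motor_head", 60, 730, 250.0),
        DomainHit("g", "cdd", "Myosin_head", 63, 739, 230.0),
    ]
    pos = 740
    for _ in range(6):
        hits.append(DomainHit("g", "smart", "IQ", pos, pos + 22, 15.0))
        pos += 25
    hits.append(DomainHit("g", "coils", "CC", 900, 1100, 0.0))
    hits.append(DomainHit("g", "pfam", "DIL", 1300, 1450, 90.0))
    hits.append(DomainHit("g", "cdd", "DIL", 1302, 1452, 85.0))
    arch = consensus_architecture(hits)
    assert arch == ["head"] + ["IQ"] * 6 + ["CC", "DIL"]


def test_single_source_uncontradicted_hit_kept():
    assert consensus_architecture(
        [DomainHit("g", "pfam", "kinase", 10, 300, 120.0)]
    ) == ["kinase"]


def test_conflicting_names_resolved_by_score_with_warning():
    hits = [
        DomainHit("g", "pfam", "kinase", 10, 300, 150.0),
        DomainHit("g", "smart", "phosphatase", 12, 305, 80.0),
    ]
    with pytest.warns(UserWarning, match="conflicting domain calls"):
        arch = consensus_architecture(hits)
    assert arch == ["kinase"]


def test_same_source_duplicates_merged_with_warning():
    hits = [
        DomainHit("g", "pfam", "IQ", 10, 32, 12.0),
        DomainHit("g", "pfam", "IQ", 11, 33, 11.0),
    ]
    with pytest.warns(UserWarning, match="duplicate"):
        arch = consensus_architecture(hits)
    assert arch == ["IQ"]


def test_multi_sequence_hits_rejected():
    with pytest.raises(ValueError, match="multiple sequences"):
        consensus_architecture(
            [DomainHit("a", "pfam", "IQ", 1, 20), DomainHit("b", "pfam", "IQ", 1, 20)]
        )


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "arch, expected",
    [
        (["head"] + ["IQ"] * 6 + ["CC", "DIL"], "XI"),
        (["head", "CC"], "VIII"),
        (["kinase"], "not_myosin"),
        (["head"] + ["IQ"] * 6 + ["CC"], "XI_DIL_minus"),
        ([], "not_myosin"),
    ],
)
def test_classify_architecture_reference_cases(arch, expected):
    assert classify_architecture(arch) == expected


def test_classify_architecture_truth_table():
    """Exhaustive enumeration over presence/absence of the domain vocabulary.

    The package rule: no head -> not_myosin; DIL -> XI; IQ count >= 5 or an
    SH3-like N-terminal domain -> the DIL-less XI variant; a coiled coil
    alone -> VIII; a bare head -> not_myosin.
    """
    for has_head, has_dil, iq_count, has_sh3, has_cc, has_other in (
        itertools.product([False, True], [False, True], [0, 1, 5, 6],
                          [False, True], [False, True], [False, True])
    ):
        arch = []
        if has_sh3:
            arch.append("SH3")
        if has_head:
            arch.append("head")
        arch.extend(["IQ"] * iq_count)
        if has_cc:
            arch.append("CC")
        if has_dil:
            arch.append("DIL")
        if has_other:
            arch.append("kinase")

        if not has_head:
            expected = "not_myosin"
        elif has_dil:
            expected = "XI"
        elif iq_count >= 5 or has_sh3:
            expected = "XI_DIL_minus"
        elif has_cc:
            expected = "VIII"
        else:
            expected = "not_myosin"
        assert classify_architecture(arch) == expected, arch


# ---------------------------------------------------------------------------
# TSV round trips
# ---------------------------------------------------------------------------

def test_cohort_tsv_roundtrip(tmp_path):
    cohort = gen_candidate_table(2, 1, 1, seed=0)
    hits_path, domains_path = cohort.write(tmp_path)
    hits = read_hits_tsv(hits_path)
    domains = read_domains_tsv(domains_path)
    assert {h.subject_id for h in hits} == set(cohort.candidates)
    assert set(d.seq_id for d in domains) <= set(cohort.candidates)
    for got, orig in zip(hits, cohort.hits):
        assert (got.query_id, got.subject_id, got.subject_annotation) == (
            orig.query_id, orig.subject_id, orig.subject_annotation
        )
        assert got.identity == orig.identity
        assert got.coverage == orig.coverage
        assert got.evalue == pytest.approx(orig.evalue, rel=1e-12)
    assert domains == list(cohort.domains)


def test_candidate_report_tsv(tmp_path):
    cohort = gen_candidate_table(3, 1, 2, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = run_validation(
            cohort.candidates, cohort.hits, cohort.domains, cohort.msa,
            cohort.reference_classes, cohort.outgroup_ids,
        )
    out = tmp_path / "report.tsv"
    write_candidate_tsv(records, out)
    lines = out.read_text().splitlines()
    assert len(lines) == len(records) + 1


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_planted_cohort_counts_and_reasons():
    cohort = gen_candidate_table(12, 2, 6, seed=3)
    records, summary = run_validation(
        cohort.candidates, cohort.hits, cohort.domains, cohort.msa,
        cohort.reference_classes, cohort.outgroup_ids,
    )
    assert summary["XI"] == 12
    assert summary["VIII"] == 2
    assert sum(v for k, v in summary.items() if k.startswith("rejected")) == 6
    for rec in records:
        expected = cohort.truth[rec.seq_id]
        if expected in ("XI", "VIII"):
            assert rec.assigned_class == expected
            assert rec.rejection_reason is None
        else:
            assert rec.category == "rejected"
            assert rec.rejection_reason == expected


def test_every_rejection_carries_exactly_one_reason():
    cohort = gen_candidate_table(4, 1, 6, seed=9)
    records, summary = run_validation(
        cohort.candidates, cohort.hits, cohort.domains, cohort.msa,
        cohort.reference_classes, cohort.outgroup_ids,
    )
    assert len(records) == len(cohort.candidates)
    for rec in records:
        if rec.category == "rejected":
            assert rec.rejection_reason
        else:
            assert rec.rejection_reason is None


def test_all_decoy_cohort_validates_nothing():
    cohort = gen_candidate_table(0, 0, 6, seed=4)
    records, summary = run_validation(
        cohort.candidates, cohort.hits, cohort.domains, cohort.msa,
        cohort.reference_classes, cohort.outgroup_ids,
    )
    assert all(r.category == "rejected" for r in records)
    assert not any(k in ("XI", "VIII") for k in summary)


def test_validation_order_invariant():
    cohort = gen_candidate_table(5, 1, 3, seed=6)
    rec1, sum1 = run_validation(
        cohort.candidates, cohort.hits, cohort.domains, cohort.msa,
        cohort.reference_classes, cohort.outgroup_ids,
    )
    reordered = dict(reversed(list(cohort.candidates.items())))
    rec2, sum2 = run_validation(
        reordered, tuple(reversed(cohort.hits)), tuple(reversed(cohort.domains)),
        cohort.msa, cohort.reference_classes, cohort.outgroup_ids,
    )
    assert sum1 == sum2
    assert {r.seq_id: r.assigned_class for r in rec1} == {
        r.seq_id: r.assigned_class for r in rec2
    }


def test_missing_alignment_row_names_id_and_table():
    cohort = gen_candidate_table(3, 1, 0, seed=2)
    msa = cohort.msa.subset(
        [i for i in cohort.msa.ids if i != "CAND_XI_01"]
    )
    with pytest.raises(KeyError, match="CAND_XI_01.*reference_msa"):
        run_validation(
            cohort.candidates, cohort.hits, cohort.domains, msa,
            cohort.reference_classes, cohort.outgroup_ids,
        )
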