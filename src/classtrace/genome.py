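"""Validation of genome-scan candidate genes: hit filtering, annotation
triage, domain-architecture consensus, and final class annotation.

The workflow mirrors a genome survey for a gene family: reference family
members are searched against a proteome (the search itself is external; its
tabular output is consumed here), hits are filtered on E-value and query
coverage, triaged into annotated ("category 1", annotation string names the
family) and unannotated-but-similar ("category 2", best identity above a
cutoff) candidates, checked for the family's expected domain architecture
across several domain databases, and finally classed by co-clustering on a
neighbour-joining tree with labelled references and non-family outgroups.

External tools (PSI-BLAST, gene predictors, domain servers) are never
executed; their outputs arrive as plain TSV tables.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import phylo
from .seqio import AlignedSequenceSet

__all__ = [
    "SearchHit",
    "FilterConfig",
    "DomainHit",
    "CandidateRecord",
    "read_hits_tsv",
    "read_domains_tsv",
    "filter_hits",
    "categorize_annotation",
    "consensus_architecture",
    "classify_architecture",
    "run_validation",
    "write_candidate_tsv",
]

DOMAIN_SOURCES = ("pfam", "cdd", "smart", "coils")

#: canonical domain vocabulary used by the architecture classifier
_NAME_MAP = {
    "head": "head",
    "motor_head": "head",
    "myosin_head": "head",
    "mysc": "head",
    "motor": "head",
    "iq": "IQ",
    "cc": "CC",
    "coil": "CC",
    "coils": "CC",
    "coiled_coil": "CC",
    "coiled-coil": "CC",
    "dil": "DIL",
    "sh3": "SH3",
    "sh3_like": "SH3",
    "myosin_n": "SH3",
}


def canonical_domain_name(name: str) -> str:
    return _NAME_MAP.get(name.strip().lower(), name.strip().lower())


@dataclass(frozen=True)
class SearchHit:
    """One row of a sequence-search table.

    The candidate gene is the *subject* (references are queried against the
    proteome), so candidate tables are keyed by ``subject_id``.  ``coverage``
    is the query-length coverage as a fraction.
    """

    query_id: str
    subject_id: str
    identity: float  # percent, 0-100
    evalue: float
    coverage: float  # fraction, 0-1
    subject_annotation: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside 0-100")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage {self.coverage} outside 0-1")


@dataclass(frozen=True)
class FilterConfig:
    """Hit-quality and triage cutoffs.

    Defaults are the deliberately permissive genome-scan settings: E-value
    1e-5 with 25% query coverage (to retain distant family members), and a
    35% identity cutoff for rescuing unannotated hits.
    """

    evalue_cutoff: float = 1e-5
    coverage_cutoff: float = 0.25
    identity_cutoff_percent: float = 35.0
    annotation_keywords: tuple[str, ...] = ("myosin",)

    def __post_init__(self) -> None:
        if min(self.evalue_cutoff, self.coverage_cutoff,
               self.identity_cutoff_percent) <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class DomainHit:
    """One domain prediction for one sequence from one source database."""

    seq_id: str
    source: str  # pfam | cdd | smart | coils
    name: str
    start: int  # 1-based inclusive
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"domain {self.name!r} on {self.seq_id!r}: start > end"
            )
        if self.source not in DOMAIN_SOURCES:
            raise ValueError(f"unknown domain source {self.source!r}")


@dataclass(frozen=True)
class CandidateRecord:
    """A candidate gene with its filter verdicts.

    ``category`` is ``cat1_annotated`` / ``cat2_unannotated`` / ``rejected``;
    rejected records carry exactly one ``rejection_reason`` code.
    ``provenance`` is free-form pass-through metadata (chromosome region,
    re-predicted gene boundaries, ...).
    """

    seq_id: str
    annotation: str = ""
    best_identity: float | None = None
    category: str = "cat2_unannotated"
    architecture: tuple[str, ...] = ()
    architecture_class: str | None = None
    assigned_class: str = "unclassified"
    rejection_reason: str | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category == "rejected" and not self.rejection_reason:
            raise ValueError("rejected records must carry a reason code")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_HIT_COLS = ["query_id", "subject_id", "identity", "evalue", "coverage", "annotation"]
_DOM_COLS = ["seq_id", "source", "name", "start", "end", "score"]


def read_hits_tsv(path: str | Path) -> list[SearchHit]:
    """Read a search-hit table (BLAST outfmt-6-like TSV with header).

    Columns: query_id, subject_id, identity (percent), evalue, coverage
    (fraction), annotation.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_HIT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit columns {sorted(missing)}")
    return [
        SearchHit(
            str(r.query_id), str(r.subject_id), float(r.identity),
            float(r.evalue), float(r.coverage),
            "" if pd.isna(r.annotation) else str(r.annotation),
        )
        for r in df.itertuples()
    ]


def read_domains_tsv(path: str | Path) -> list[DomainHit]:
    """Read a domain-hit table (seq_id, source, name, start, end, score)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_DOM_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing domain columns {sorted(missing)}")
    return [
        DomainHit(str(r.seq_id), str(r.source), str(r.name),
                  int(r.start), int(r.end), float(r.score))
        for r in df.itertuples()
    ]


def write_candidate_tsv(records: Sequence[CandidateRecord], path: str | Path) -> None:
    """Validated-gene report: id, identity, annotation, architecture, class."""
    rows = [
        {
            "seq_id": r.seq_id,
            "annotation": r.annotation,
            "best_identity": r.best_identity,
            "category": r.category,
            "architecture": "-".join(r.architecture),
            "architecture_class": r.architecture_class or "",
            "assigned_class": r.assigned_class,
            "rejection_reason": r.rejection_reason or "",
            **{k: v for k, v in r.provenance.items()},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and triage
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Sequence[SearchHit], cfg: FilterConfig = FilterConfig()
) -> list[SearchHit]:
    """Keep hits with E-value <= cutoff AND coverage >= cutoff, in order."""
    return [
        h for h in hits
        if h.evalue <= cfg.evalue_cutoff and h.coverage >= cfg.coverage_cutoff
    ]


def categorize_annotation(
    record: CandidateRecord, cfg: FilterConfig = FilterConfig()
) -> str:
    """Triage a candidate by annotation string, then by identity.

    A case-insensitive keyword match (default: "myosin") makes category 1;
    otherwise best identity >= the cutoff rescues the record as category 2
    (mis-annotated or unannotated genes); otherwise it is rejected with
    reason ``low_identity_unannotated``.
    """
    ann = (record.annotation or "").lower()
    if any(kw.lower() in ann for kw in cfg.annotation_keywords):
        return "cat1_annotated"
    if record.best_identity is not None and (
        record.best_identity >= cfg.identity_cutoff_percent
    ):
        return "cat2_unannotated"
    return "rejected"


# ---------------------------------------------------------------------------
# domain-architecture consensus
# ---------------------------------------------------------------------------

def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the shorter span length."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if hi < lo:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return (hi - lo + 1) / shorter


@dataclass
class _Group:
    name: str
    start: int
    end: int
    sources: set[str]
    score: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def consensus_architecture(hits: Sequence[DomainHit]) -> list[str]:
    """Merge per-source domain calls into one ordered architecture.

    Same-name hits overlapping >= 50% (of the shorter span) are unified into
    one domain whose span is the union of the members.  A domain is kept when
    reported by >= 2 sources, or by a single source when no other source
    covers that span (COILS is accepted as sole authority for coiled-coil).
    When two single-source calls of *different* names overlap, the
    higher-scoring name is kept and the conflict logged as a warning.
    Same-source duplicates are merged with a warning.  The result is ordered
    by start position, canonical names (head, IQ, CC, DIL, SH3, ...).
    """
    if not hits:
        return []
    ids = {h.seq_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple sequences: {sorted(ids)}")

    # 1. merge same-name overlapping hits across (and within) sources
    groups: list[_Group] = []
    for h in sorted(hits, key=lambda h: (h.start, h.end, h.source)):
        name = canonical_domain_name(h.name)
        merged = False
        for g in groups:
            if g.name == name and _overlap_frac(g.span, (h.start, h.end)) >= 0.5:
                if h.source in g.sources:
                    warnings.warn(
                        f"{h.seq_id}: duplicate {h.source} hit for {name} "
                        f"at {h.start}-{h.end} merged"
                    )
                g.start = min(g.start, h.start)
                g.end = max(g.end, h.end)
                g.sources.add(h.source)
                g.score = max(g.score, h.score)
                merged = True
                break
        if not merged:
            groups.append(_Group(name, h.start, h.end, {h.source}, h.score))

    # 2. resolve cross-name conflicts between single-source groups
    dropped: set[int] = set()
    for i, gi in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gj = groups[j]
            if i in dropped or j in dropped:
                continue
            if gi.name != gj.name and _overlap_frac(gi.span, gj.span) >= 0.5:
                if len(gi.sources) >= 2 and len(gj.sources) < 2:
                    loser = j
                elif len(gj.sources) >= 2 and len(gi.sources) < 2:
                    loser = i
                else:
                    loser = j if gi.score >= gj.score else i
                winner = i + j - loser
                warnings.warn(
                    f"conflicting domain calls {gi.name!r} vs {gj.name!r} over "
                    f"the same span; keeping {groups[winner].name!r} "
                    f"(higher support/score)"
                )
                dropped.add(loser)

    # 3. keep rule: >=2 sources, sole authority, or COILS for coiled-coil
    kept: list[_Group] = []
    for i, g in enumerate(groups):
        if i in dropped:
            continue
        if len(g.sources) >= 2:
            kept.append(g)
        elif g.name == "CC" and "coils" in g.sources:
            kept.append(g)
        else:
            covered = any(
                j != i and j not in dropped
                and not (groups[j].sources <= g.sources)
                and _overlap_frac(g.span, groups[j].span) >= 0.5
                for j in range(len(groups))
            )
            if not covered:
                kept.append(g)
    kept.sort(key=lambda g: (g.start, g.end))
    return [g.name for g in kept]


def classify_architecture(arch: Sequence[str]) -> str:
    """Bin an ordered architecture into XI / XI_DIL_minus / VIII / not_myosin.

    Myosin XI: motor head ... coiled-coil ... DIL cargo-binding domain.
    A DIL-less architecture with a long IQ neck (>= 5 IQ motifs) or an
    N-terminal SH3-like domain is the XI variant lacking DIL; a bare
    head + coiled-coil is myosin VIII; anything without a motor head (or a
    head with neither neck nor coil) is not a myosin.
    """
    if not arch:
        return "not_myosin"
    names = [canonical_domain_name(a) for a in arch]
    if "head" not in names:
        return "not_myosin"
    iq_count = names.count("IQ")
    if "DIL" in names:
        return "XI"
    if iq_count >= 5 or "SH3" in names:
        return "XI_DIL_minus"
    if "CC" in names:
        return "VIII"
    return "not_myosin"


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_validation(
    candidates: Mapping[str, str],
    search_hits: Sequence[SearchHit],
    domain_hits: Sequence[DomainHit],
    reference_msa: AlignedSequenceSet,
    reference_classes: Mapping[str, str],
    outgroup_ids: Iterable[str],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[CandidateRecord], dict[str, int]]:
    """Run the full multi-fold validation over a candidate cohort.

    ``candidates`` maps candidate id -> annotation string.  The stages are:
    hit filtering (E-value/coverage), annotation triage (category 1/2 or
    reject), domain-architecture consensus + classification (reject
    non-family architectures), and NJ co-clustering of the survivors'
    motor-domain rows in ``reference_msa`` with class-labelled references
    and outgroups.  Returns the per-candidate records (input order) and a
    summary of per-class counts plus rejection reasons.

    Raises ``KeyError`` naming the id and table when a surviving candidate
    has no row in the reference alignment.
    """
    outgroup_ids = set(outgroup_ids)
    surviving = filter_hits(search_hits, cfg)
    best_identity: dict[str, float] = {}
    for h in surviving:
        if h.subject_id in candidates:
            cur = best_identity.get(h.subject_id)
            if cur is None or h.identity > cur:
                best_identity[h.subject_id] = h.identity

    domains_by_id: dict[str, list[DomainHit]] = defaultdict(list)
    for d in domain_hits:
        domains_by_id[d.seq_id].append(d)

    records: dict[str, CandidateRecord] = {}
    passed: list[str] = []
    for cid, annotation in candidates.items():
        rec = CandidateRecord(
            seq_id=cid, annotation=annotation,
            best_identity=best_identity.get(cid),
        )
        if cid not in best_identity:
            records[cid] = replace(
                rec, category="rejected", rejection_reason="no_significant_hit"
            )
            continue
        category = categorize_annotation(rec, cfg)
        if category == "rejected":
            records[cid] = replace(
                rec, category="rejected",
                rejection_reason="low_identity_unannotated",
            )
            continue
        arch = tuple(consensus_architecture(domains_by_id.get(cid, [])))
        arch_class = classify_architecture(arch)
        rec = replace(rec, category=category, architecture=arch,
                      architecture_class=arch_class)
        if arch_class == "not_myosin":
            records[cid] = replace(
                rec, category="rejected", rejection_reason="architecture",
                assigned_class="unclassified",
            )
            continue
        records[cid] = rec
        passed.append(cid)

    if passed:
        needed = set(passed) | set(reference_classes) | outgroup_ids
        missing = needed - set(reference_msa.ids)
        missing_candidates = missing & set(passed)
        if missing_candidates:
            raise KeyError(
                f"candidate {sorted(missing_candidates)[0]!r} missing from "
                f"table 'reference_msa'"
            )
        if missing:
            raise KeyError(
                f"id {sorted(missing)[0]!r} missing from table 'reference_msa'"
            )
        sub = reference_msa.subset(needed)
        tree = phylo.nj_build(phylo.p_distance_matrix(sub))
        annotations = phylo.assign_class_by_coclustering(
            tree, reference_classes, outgroup_ids
        )
        by_query = {a.query_id: a for a in annotations}
        for cid in passed:
            assigned = by_query[cid].assigned_class
            rec = records[cid]
            if assigned == "unclassified":
                records[cid] = replace(
                    rec, category="rejected", rejection_reason="phylogeny",
                    assigned_class="unclassified",
                )
            else:
                records[cid] = replace(rec, assigned_class=assigned)

    ordered = [records[cid] for cid in candidates]
    summary: dict[str, int] = defaultdict(int)
    for r in ordered:
        if r.category == "rejected":
            summary[f"rejected_{r.rejection_reason}"] += 1
        else:
            summary[r.assigned_class] += 1
    return ordered, dict(summary)
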