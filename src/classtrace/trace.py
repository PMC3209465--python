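"""Evolutionary Trace of an alignment against a class partition.

Given a multiple sequence alignment whose rows are partitioned into protein
subfamilies ("classes", e.g. myosin V vs myosin XI), every column is
classified as one of:

``conserved``
    one residue type reaches the conservation threshold over all non-gap
    residues of the column — an invariant position of the whole family;
``class_specific``
    every class individually reaches the threshold on some residue type and
    at least two classes settle on *different* types — within-class
    invariant, between-class divergent; these are the positions of interest;
``variable``
    neither of the above;
``gapped``
    the column's gap fraction exceeds ``max_gap_fraction`` and it is
    excluded from tracing (loop insertions between subfamilies would
    otherwise flood the trace).

Class-specific columns are reported in reference numbering: the 1-based
position in the ungapped reference row, plus a user offset so results can be
quoted in a published structure's author numbering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .seqio import GAP, AlignedSequenceSet

__all__ = [
    "TraceConfig",
    "TraceColumn",
    "TraceSummary",
    "validate_partition",
    "column_status",
    "trace_alignment",
    "summarize_trace",
    "partition_from_tree",
    "write_trace_tsv",
]

#: placeholder consensus for a class with no conserved residue at a column
NO_CONSENSUS = "·"  # "·"

STATUSES = ("conserved", "class_specific", "variable", "gapped")


@dataclass(frozen=True)
class TraceConfig:
    """Thresholds of the trace.

    within_class_conservation
        fraction of (non-gap) members of a group that must share a residue
        type for the group to have a consensus; 1.0 is the strict trace in
        which a single deviant vetoes the column.
    max_gap_fraction
        columns with a larger fraction of gaps are set aside as "gapped".
    min_class_size
        smallest class allowed in a partition; tracing against singleton
        classes is trivially class-specific everywhere and is refused.
    """

    within_class_conservation: float = 1.0
    max_gap_fraction: float = 0.5
    min_class_size: int = 2

    def __post_init__(self) -> None:
        for name in ("within_class_conservation", "max_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")


@dataclass(frozen=True)
class TraceColumn:
    """Verdict for one alignment column."""

    column_index: int  # 1-based alignment column
    status: str
    class_consensus: Mapping[str, str] = field(default_factory=dict)
    ref_residue_number: int | None = None  # None when reference is gapped
    ref_residue_type: str | None = None


@dataclass(frozen=True)
class TraceSummary:
    """Per-status counts plus the list of class-specific columns."""

    counts: Mapping[str, int]
    class_specific: tuple[TraceColumn, ...]
    region_class_specific: int | None = None  # count inside a region filter


def validate_partition(
    partition: Mapping[str, str],
    msa: AlignedSequenceSet | None = None,
    min_class_size: int = 2,
) -> None:
    """Check a class partition: coverage, non-empty labels, class sizes."""
    if not partition:
        raise ValueError("class partition is empty")
    if any(not lab for lab in partition.values()):
        raise ValueError("class labels must be non-empty")
    sizes = Counter(partition.values())
    if len(sizes) < 2:
        raise ValueError("a trace needs at least 2 classes")
    small = [c for c, n in sizes.items() if n < min_class_size]
    if small:
        raise ValueError(
            f"classes below minimum size {min_class_size}: {sorted(small)}"
        )
    if msa is not None:
        missing = set(msa.ids) - set(partition)
        if missing:
            raise ValueError(
                f"partition does not cover alignment ids: {sorted(missing)}"
            )


def _group_consensus(residues: Sequence[str], threshold: float) -> str:
    """Consensus residue of a group, or NO_CONSENSUS.

    Gaps are excluded from the count; an all-gap group has no consensus.
    """
    nongap = [r for r in residues if r != GAP]
    if not nongap:
        return NO_CONSENSUS
    (res, count), = Counter(nongap).most_common(1)
    return res if count / len(nongap) >= threshold - 1e-12 else NO_CONSENSUS


def column_status(
    column: Sequence[tuple[str, str]],
    partition: Mapping[str, str],
    cfg: TraceConfig = TraceConfig(),
    column_index: int = 1,
) -> TraceColumn:
    """Classify a single column (list of ``(id, residue)`` pairs).

    The rules, applied in order: gapped when the gap fraction exceeds
    ``max_gap_fraction``; conserved when one residue type reaches the
    conservation fraction over the column's non-gap residues; class-specific
    when every class has a consensus (gaps excluded within a class, an
    all-gap class blocks) and at least two consensuses differ; else variable.
    """
    missing = [rid for rid, _ in column if rid not in partition]
    if missing:
        raise KeyError(f"ids missing from partition: {sorted(missing)}")
    residues = [res.upper() for _, res in column]
    n = len(residues)
    if n == 0:
        raise ValueError("empty column")
    gap_fraction = residues.count(GAP) / n
    if gap_fraction > cfg.max_gap_fraction:
        return TraceColumn(column_index, "gapped", {})

    thr = cfg.within_class_conservation
    overall = _group_consensus(residues, thr)
    classes = sorted({partition[rid] for rid, _ in column})
    if overall != NO_CONSENSUS:
        return TraceColumn(
            column_index, "conserved", {c: overall for c in classes}
        )

    consensus = {
        c: _group_consensus(
            [res.upper() for rid, res in column if partition[rid] == c], thr
        )
        for c in classes
    }
    if all(v != NO_CONSENSUS for v in consensus.values()) and len(
        set(consensus.values())
    ) >= 2:
        return TraceColumn(column_index, "class_specific", consensus)
    return TraceColumn(column_index, "variable", consensus)


def trace_alignment(
    msa: AlignedSequenceSet,
    partition: Mapping[str, str],
    cfg: TraceConfig = TraceConfig(),
    ref_id: str | None = None,
    ref_offset: int = 0,
) -> list[TraceColumn]:
    """Trace every column of an alignment.

    ``ref_id`` names the row whose ungapped residue count provides reference
    numbering (plus ``ref_offset``, e.g. to match a published structure's
    numbering); columns where the reference is gapped carry no number.
    """
    validate_partition(partition, msa, cfg.min_class_size)
    if ref_id is None:
        ref_id = msa.ids[0]
    ref_row = msa.row(ref_id)

    out: list[TraceColumn] = []
    resno = 0
    for idx in range(1, msa.n_columns + 1):
        col = msa.column(idx)
        verdict = column_status(col, partition, cfg, column_index=idx)
        ref_char = ref_row[idx - 1]
        if ref_char != GAP:
            resno += 1
            verdict = TraceColumn(
                verdict.column_index,
                verdict.status,
                verdict.class_consensus,
                ref_residue_number=resno + ref_offset,
                ref_residue_type=ref_char.upper(),
            )
        out.append(verdict)
    return out


def summarize_trace(
    trace: Sequence[TraceColumn],
    regions: Iterable[tuple[int, int]] | None = None,
) -> TraceSummary:
    """Count statuses and collect class-specific columns.

    ``regions`` is an optional list of 1-based inclusive reference-number
    intervals (e.g. actin-binding sites); when given, the summary also counts
    class-specific columns whose reference number falls in any interval.
    """
    if not trace:
        raise ValueError("empty trace")
    counts = {s: 0 for s in STATUSES}
    specific: list[TraceColumn] = []
    for tc in trace:
        if tc.status not in counts:
            raise ValueError(f"unknown column status {tc.status!r}")
        counts[tc.status] += 1
        if tc.status == "class_specific":
            specific.append(tc)
    region_count = None
    if regions is not None:
        intervals = list(regions)
        region_count = sum(
            1
            for tc in specific
            if tc.ref_residue_number is not None
            and any(a <= tc.ref_residue_number <= b for a, b in intervals)
        )
    return TraceSummary(counts, tuple(specific), region_count)


def partition_from_tree(
    tree: dendropy.Tree, n_groups: int
) -> dict[str, str]:
    """Cut a rooted tree into at least ``n_groups`` monophyletic groups.

    The cut depth is measured in edges from the root: the smallest depth k
    at which the clades hanging at depth k (leaves shallower than k stand as
    singletons) number at least ``n_groups``.  Leaves are labelled
    ``"G1"``.. in order of first leaf appearance.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if n_groups < 2:
        raise ValueError(f"n_groups must be >= 2, got {n_groups}")
    if n_groups > len(leaves):
        raise ValueError(
            f"n_groups {n_groups} exceeds leaf count {len(leaves)}"
        )

    depth: dict[dendropy.Node, int] = {tree.seed_node: 0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + 1

    def groups_at(k: int) -> dict[str, int]:
        anchor_of: dict[str, dendropy.Node] = {}
        for lf in leaves:
            node = lf
            while depth[node] > k:
                node = node.parent_node
            anchor_of[lf.taxon.label] = node
        order: dict[dendropy.Node, int] = {}
        labels: dict[str, int] = {}
        for lf in leaves:
            anchor = anchor_of[lf.taxon.label]
            if anchor not in order:
                order[anchor] = len(order) + 1
            labels[lf.taxon.label] = order[anchor]
        return labels

    max_depth = max(depth[lf] for lf in leaves)
    for k in range(1, max_depth + 1):
        labels = groups_at(k)
        if len(set(labels.values())) >= n_groups:
            return {lab: f"G{g}" for lab, g in labels.items()}
    # every leaf a singleton; guaranteed >= n_groups by the precondition
    return {lab: f"G{g}" for lab, g in groups_at(max_depth).items()}


def write_trace_tsv(trace: Sequence[TraceColumn], path: str | Path) -> None:
    """Trace report: column, status, ref number/type, per-class consensus."""
    classes = sorted(
        {c for tc in trace for c in tc.class_consensus}
    )
    with open(path, "w") as fh:
        header = ["column", "status", "ref_number", "ref_residue"] + [
            f"consensus_{c}" for c in classes
        ]
        fh.write("\t".join(header) + "\n")
        for tc in trace:
            row = [
                str(tc.column_index),
                tc.status,
                "" if tc.ref_residue_number is None else str(tc.ref_residue_number),
                tc.ref_residue_type or "",
            ] + [tc.class_consensus.get(c, "") for c in classes]
            fh.write("\t".join(row) + "\n")
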