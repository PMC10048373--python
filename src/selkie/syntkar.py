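"""Synteny-block filtering, chromosome correspondence, and inversion calling.

Chromosome-length scaffolds of related species are reconciled through
oriented synteny blocks (reference chromosome vs. query scaffold segments,
each with a strand sense). After dropping blocks below a minimum reference
span, each query scaffold is assigned to the reference chromosome that
receives most of its aligned bases; scaffolds are then named either from a
cytogenetic (Zoo-FISH style) map ("chr" + number) or, absent one, the X
homolog is named "chrX" and the remaining scaffolds "aut1..autN" from longest
to shortest. Inversions appear as maximal runs of blocks whose orientation
opposes the dominant orientation of their scaffold pair; runs spanning at
least a megabase are classed separately from the short ones, and calls from
different query genomes are grouped as shared when they reciprocally overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SyntenyBlock",
    "SyntenyBlockSet",
    "ChromosomeCorrespondence",
    "InversionCall",
    "filter_blocks",
    "assign_chromosomes",
    "scaffold_orientation",
    "call_inversions",
    "group_shared_calls",
]


@dataclass(frozen=True)
class SyntenyBlock:
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    orientation: str  # '+' or '-'; query coordinates always ascending

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError("invalid reference interval")
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("invalid query interval")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class SyntenyBlockSet:
    blocks: list[SyntenyBlock]
    ref_lengths: dict[str, int] = field(default_factory=dict)
    query_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: (b.ref_chrom, b.ref_start))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (b.ref_chrom, b.ref_start, b.ref_end,
                 b.query_chrom, b.query_start, b.query_end, b.orientation)
                for b in self.blocks
            ],
            columns=["ref_chrom", "ref_start", "ref_end",
                     "query_chrom", "query_start", "query_end", "orientation"],
        )


@dataclass
class ChromosomeCorrespondence:
    """Query scaffold -> reference chromosome assignment with naming.

    ``mapping``: query scaffold -> (ref chromosome, aligned bp on it,
    fraction of the scaffold covered by blocks to that chromosome).
    ``assigned_name``: unique display name per query scaffold.
    ``dominant_orientation``: per (query, assigned ref) pair, the strand
    carrying the majority of aligned bp, with that majority fraction.
    ``unassigned``: scaffolds with zero aligned bp.
    """

    mapping: dict[str, tuple[str, int, float]]
    assigned_name: dict[str, str]
    dominant_orientation: dict[tuple[str, str], tuple[str, float]]
    unassigned: list[str] = field(default_factory=list)


def filter_blocks(block_set: SyntenyBlockSet, min_len: int = 50_000) -> tuple[SyntenyBlockSet, int]:
    """Keep blocks whose reference span is at least ``min_len`` (inclusive).

    Returns the filtered set and the number of blocks removed.
    """
    kept = [b for b in block_set.blocks if b.ref_span >= min_len]
    removed = len(block_set.blocks) - len(kept)
    return (
        SyntenyBlockSet(kept, dict(block_set.ref_lengths), dict(block_set.query_lengths)),
        removed,
    )


def _is_x_name(name: str) -> bool:
    return name.lower() in ("x", "chrx")


def assign_chromosomes(
    block_set: SyntenyBlockSet,
    fish_map: Mapping[str, int | str] | None = None,
) -> ChromosomeCorrespondence:
    """Assign every query scaffold to the reference chromosome receiving the
    most aligned bp, and name the scaffolds.

    With a cytogenetic map (query scaffold -> chromosome number) names are
    "chr" + number. Without one, the scaffold whose best reference is the X
    is named "chrX" and the rest get "aut1..autN" by descending scaffold
    length (block-footprint length when scaffold lengths are unknown).
    Scaffolds present in ``query_lengths`` but receiving no aligned bp are
    reported unassigned.
    """
    aligned: dict[str, dict[str, int]] = {}
    orient_bp: dict[tuple[str, str], dict[str, int]] = {}
    for b in block_set.blocks:
        aligned.setdefault(b.query_chrom, {}).setdefault(b.ref_chrom, 0)
        aligned[b.query_chrom][b.ref_chrom] += b.ref_span
        key = (b.query_chrom, b.ref_chrom)
        orient_bp.setdefault(key, {"+": 0, "-": 0})
        orient_bp[key][b.orientation] += b.ref_span

    mapping: dict[str, tuple[str, int, float]] = {}
    for q, per_ref in aligned.items():
        best_ref = max(per_ref, key=lambda r: (per_ref[r], r))
        bp = per_ref[best_ref]
        q_len = block_set.query_lengths.get(q, sum(per_ref.values()))
        mapping[q] = (best_ref, bp, bp / q_len if q_len else 0.0)

    unassigned = [q for q in block_set.query_lengths if q not in aligned]

    dominant: dict[tuple[str, str], tuple[str, float]] = {}
    for (q, r), counts in orient_bp.items():
        total = counts["+"] + counts["-"]
        strand = "+" if counts["+"] >= counts["-"] else "-"
        dominant[(q, r)] = (strand, counts[strand] / total if total else 0.0)

    assigned_name: dict[str, str] = {}
    if fish_map is not None:
        for q in mapping:
            if q in fish_map:
                num = fish_map[q]
                assigned_name[q] = num if str(num).startswith("chr") else f"chr{num}"
            else:
                assigned_name[q] = q
    else:
        def q_len(q: str) -> int:
            return block_set.query_lengths.get(q, mapping[q][1])

        rest = []
        for q in mapping:
            if _is_x_name(mapping[q][0]):
                assigned_name[q] = "chrX"
            else:
                rest.append(q)
        rest.sort(key=lambda q: (-q_len(q), q))
        for i, q in enumerate(rest, start=1):
            assigned_name[q] = f"aut{i}"

    if len(set(assigned_name.values())) != len(assigned_name):
        raise ValueError("assigned scaffold names are not unique")
    return ChromosomeCorrespondence(mapping, assigned_name, dominant, unassigned)


def scaffold_orientation(
    corr: ChromosomeCorrespondence,
    flag_fraction: float = 0.8,
) -> dict[str, str]:
    """Classify each query scaffold's global orientation against its
    assigned reference chromosome.

    Returns per scaffold: "inverted" when the '-' strand carries at least
    ``flag_fraction`` of the aligned bp, "forward" when '+' does, and
    "ambiguous" otherwise (e.g. 50/50 mixtures).
    """
    out: dict[str, str] = {}
    for q, (ref, _, _) in corr.mapping.items():
        strand, frac = corr.dominant_orientation[(q, ref)]
        if frac >= flag_fraction:
            out[q] = "inverted" if strand == "-" else "forward"
        else:
            out[q] = "ambiguous"
    return out


@dataclass(frozen=True)
class InversionCall:
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    n_blocks: int
    scale_class: str  # 'short' or 'megabase'
    sharing: frozenset[str] = frozenset()

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def call_inversions(
    block_set: SyntenyBlockSet,
    corr: ChromosomeCorrespondence,
    megabase_threshold: int = 1_000_000,
    max_intervening: int = 0,
) -> list[InversionCall]:
    """Call inversions as maximal runs of anti-dominant blocks.

    Within each (query scaffold, assigned reference chromosome) pair, blocks
    sorted by reference position are scanned for maximal runs whose
    orientation opposes the pair's dominant orientation, tolerating up to
    ``max_intervening`` dominant-orientation blocks inside a run. Each run
    becomes a call spanning the first block's reference start to the last
    block's reference end, classed 'megabase' when the span reaches
    ``megabase_threshold``. Calls from different query scaffolds overlapping
    reciprocally >= 50% on the same reference chromosome are annotated as
    shared.
    """
    calls: list[InversionCall] = []
    pairs: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in block_set.blocks:
        ref = corr.mapping.get(b.query_chrom, (None,))[0]
        if b.ref_chrom == ref:
            pairs.setdefault((b.query_chrom, b.ref_chrom), []).append(b)

    for (q, ref), blocks in pairs.items():
        dom = corr.dominant_orientation[(q, ref)][0]
        blocks = sorted(blocks, key=lambda b: b.ref_start)
        run: list[SyntenyBlock] = []
        slack = 0

        def flush() -> None:
            nonlocal run, slack
            # trim trailing tolerated dominant blocks
            while run and run[-1].orientation == dom:
                run.pop()
            if run:
                start, end = run[0].ref_start, run[-1].ref_end
                n_anti = sum(1 for b in run if b.orientation != dom)
                calls.append(
                    InversionCall(
                        ref_chrom=ref,
                        ref_start=start,
                        ref_end=end,
                        query_chrom=q,
                        n_blocks=n_anti,
                        scale_class=(
                            "megabase" if end - start >= megabase_threshold else "short"
                        ),
                    )
                )
            run, slack = [], 0

        for b in blocks:
            if b.orientation != dom:
                run.append(b)
            elif run and slack < max_intervening:
                run.append(b)
                slack += 1
            else:
                flush()
        flush()

    # shared-call annotation across query scaffolds on the same reference
    annotated: list[InversionCall] = []
    for c in calls:
        sharers = {
            o.query_chrom
            for o in calls
            if o.query_chrom != c.query_chrom
            and o.ref_chrom == c.ref_chrom
            and _reciprocal_overlap(
                (c.ref_start, c.ref_end), (o.ref_start, o.ref_end)
            ) >= 0.5
        }
        annotated.append(replace(c, sharing=frozenset(sharers)))
    annotated.sort(key=lambda c: (c.ref_chrom, c.ref_start, c.query_chrom))
    return annotated


def group_shared_calls(
    call_sets: Sequence[Sequence[InversionCall]],
    labels: Sequence[str],
) -> list[InversionCall]:
    """Merge inversion calls from several query genomes, annotating each call
    with the labels of the other genomes carrying a reciprocally (>= 50%)
    overlapping call on the same reference chromosome."""
    if len(call_sets) != len(labels):
        raise ValueError("one label per call set required")
    flat = [(lab, c) for lab, cs in zip(labels, call_sets) for c in cs]
    out: list[InversionCall] = []
    for lab, c in flat:
        sharers = {
            olab
            for olab, o in flat
            if olab != lab
            and o.ref_chrom == c.ref_chrom
            and _reciprocal_overlap(
                (c.ref_start, c.ref_end), (o.ref_start, o.ref_end)
            ) >= 0.5
        }
        out.append(replace(c, sharing=frozenset(sharers)))
    out.sort(key=lambda c: (c.ref_chrom, c.ref_start, c.query_chrom))
    return out
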