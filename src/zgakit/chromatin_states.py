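"""Cross-stage peak unification and mark-state classification.

H3K27me3 (Polycomb repression) and H3K27ac (activation) sit on the same
histone residue and are mutually exclusive on a single tail.  In bulk
data from a whole embryo, however, a region can carry peaks of both
marks at the same stage — an "ambivalent" call.  These operations build
a unified peak universe across stages, classify each unified peak per
stage as me3 / ac / ambivalent / unassigned, tabulate state transitions
between consecutive stages, and assign peaks to genes by TSS proximity.
The central property these definitions support: pooling cell types with
mutually exclusive marks manufactures ambivalent calls that vanish when
each cell type is classified on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic import GeneRecord, GenomicInterval, PeakSet

__all__ = [
    "STATES",
    "StageClassification",
    "unify_peaks",
    "classify_stage",
    "transitions",
    "peaks_to_genes",
]

STATES = ("me3", "ac", "ambivalent", "unassigned")


@dataclass
class StageClassification:
    """State of every unified peak at one stage; states partition the peak list."""

    stage: str
    states: dict[str, str]

    def __post_init__(self):
        bad = {s for s in self.states.values() if s not in STATES}
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATES}
        for s in self.states.values():
            out[s] += 1
        return out


def unify_peaks(per_stage_peaksets: Iterable[PeakSet | tuple]) -> PeakSet:
    """Merge all overlapping peaks across stages into a unified list.

    Accepts bare peak sets or ``(stage, mark, PeakSet)`` tuples.  The
    result is the set of connected components of the overlap graph
    (transitive merge): disjoint, sorted intervals covering exactly the
    input bases.  Book-ended half-open intervals (``[a,b)``, ``[b,c)``)
    share no base and are NOT merged.
    """
    intervals: list[GenomicInterval] = []
    for item in per_stage_peaksets:
        ps = item[-1] if isinstance(item, tuple) else item
        intervals.extend(ps)
    if not intervals:
        return PeakSet()
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = intervals[0].chrom, intervals[0].start, intervals[0].end
    k = 0
    for iv in intervals[1:]:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end, id=f"u{k}"))
            k += 1
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end, id=f"u{k}"))
    return PeakSet(merged)


def _overlaps_any(iv: GenomicInterval, per_chrom: Mapping[str, list[GenomicInterval]]) -> bool:
    return any(
        iv.start < o.end and o.start < iv.end
        for o in per_chrom.get(iv.chrom, ())
    )


def classify_stage(
    unified: PeakSet, me3_peaks: PeakSet, ac_peaks: PeakSet, stage: str = ""
) -> StageClassification:
    """Classify each unified peak by its overlaps at one stage.

    A peak overlapping (>= 1 shared base) both an me3 and an ac peak is
    ambivalent; only one of them gives that mark's state; neither gives
    ``unassigned``.
    """
    me3_by = me3_peaks.by_chrom()
    ac_by = ac_peaks.by_chrom()
    states = {}
    for iv in unified:
        has_me3 = _overlaps_any(iv, me3_by)
        has_ac = _overlaps_any(iv, ac_by)
        if has_me3 and has_ac:
            states[iv.id] = "ambivalent"
        elif has_me3:
            states[iv.id] = "me3"
        elif has_ac:
            states[iv.id] = "ac"
        else:
            states[iv.id] = "unassigned"
    return StageClassification(stage, states)


def transitions(c1: StageClassification, c2: StageClassification) -> pd.DataFrame:
    """Peak counts for every (state at stage 1, state at stage 2) pair.

    Row/column marginals reproduce the per-stage state counts and the
    grand total equals the size of the shared peak universe.
    """
    if set(c1.states) != set(c2.states):
        raise ValueError("classifications cover different peak universes")
    table = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    for peak, s1 in c1.states.items():
        table.loc[s1, c2.states[peak]] += 1
    table.index.name = c1.stage or "from"
    table.columns.name = c2.stage or "to"
    return table


def peaks_to_genes(
    peaks: PeakSet,
    genes: Sequence[GeneRecord],
    max_tss_dist: int = 10_000,
) -> dict[str, set[str]]:
    """Assign each peak the genes whose TSS lies within ``max_tss_dist``.

    Distance is from the peak interval to the TSS point (0 when the TSS
    falls inside the peak); the comparison is strict, so a TSS exactly
    ``max_tss_dist`` away is not assigned.  All qualifying genes are
    returned per peak.
    """
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, set[str]] = {}
    for iv in peaks:
        hits = set()
        for g in genes_by_chrom.get(iv.chrom, ()):
            d = iv.distance_to_point(g.chrom, g.tss)
            if d is not None and d < max_tss_dist:
                hits.add(g.gene_id)
        out[iv.id] = hits
    return out
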