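"""Multicopy-gene discovery and analysis-window construction.

A "multicopy" gene is one annotated at two or more mutually non-overlapping
positions on the same chromosome (records on the chromosome's ``_random``
unplaced scaffold count towards the same chromosome).  Windows extend each
qualifying probe alignment by a symmetric flank and are merged per
chromosome; all window logic is strandless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    gene_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"{self.gene_name}: start must be < end, got [{self.start}, {self.end})"
            )


@dataclass
class WindowSet:
    """Merged, disjoint analysis intervals for one probe, keyed by chromosome."""

    probe_id: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"windows for {self.probe_id} overlap on {chrom}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def _base_chrom(chrom: str) -> str:
    """chrN_random pairs with chrN for the multicopy discovery rule."""
    return chrom[: -len("_random")] if chrom.endswith("_random") else chrom


def _overlaps(a: GeneInterval, b: GeneInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def discover_multicopy_genes(
    annotation: list[GeneInterval],
) -> list[tuple[str, int]]:
    """Self-join discovery of genes with >1 non-overlapping annotated copy.

    A gene is reported iff it has >=2 records (same name) whose intervals do
    not overlap, on one chromosome or on that chromosome's ``_random``
    scaffold; ``copy_count`` is the size of a maximum set of mutually
    non-overlapping records (earliest-end greedy; records on different
    scaffolds never overlap).  Order-independent in the input.
    """
    groups: dict[tuple[str, str], list[GeneInterval]] = {}
    for rec in annotation:
        groups.setdefault((rec.gene_name, _base_chrom(rec.chrom)), []).append(rec)

    best: dict[str, int] = {}
    for (gene, _), recs in groups.items():
        count = _max_disjoint(recs)
        if count >= 2:
            best[gene] = max(best.get(gene, 0), count)
    return sorted(best.items())


def _max_disjoint(recs: list[GeneInterval]) -> int:
    count = 0
    # earliest-end greedy per scaffold gives a maximum disjoint set
    by_scaffold: dict[str, list[GeneInterval]] = {}
    for r in recs:
        by_scaffold.setdefault(r.chrom, []).append(r)
    for scaffold_recs in by_scaffold.values():
        scaffold_recs.sort(key=lambda r: (r.end, r.start, r.gene_name))
        cursor = -1
        for r in scaffold_recs:
            if r.start >= cursor:
                count += 1
                cursor = r.end
    return count


def read_gene_annotation(path) -> list[GeneInterval]:
    """Gene annotation as BED-like TSV: name, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "chrom": str})
    return [
        GeneInterval(r.gene_name, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; touching intervals merge."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_windows(
    probe: ProbeAnnotation,
    flank_bp: int,
    min_identity: float = 95.0,
    exclude_unplaced: bool = False,
) -> WindowSet:
    """Symmetric flanks around each qualifying alignment, merged per chrom.

    Alignments below ``min_identity`` are excluded.  With
    ``exclude_unplaced`` alignments on chrY and ``_random`` scaffolds are
    dropped as well (the methylation analysis uses this).  Window starts are
    clipped at 0.
    """
    if flank_bp <= 0:
        raise ValidationError(f"flank_bp must be positive, got {flank_bp}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for aln in probe.alignments:
        if aln.percent_identity < min_identity:
            continue
        if exclude_unplaced and (aln.chrom == "chrY" or aln.chrom.endswith("_random")):
            continue
        by_chrom.setdefault(aln.chrom, []).append(
            (max(0, aln.start - flank_bp), aln.end + flank_bp)
        )
    intervals = [
        (chrom, s, e)
        for chrom in sorted(by_chrom)
        for s, e in merge_intervals(by_chrom[chrom])
    ]
    if not intervals:
        logger.warning("probe %s: no alignments qualify for windows", probe.probe_id)
    return WindowSet(probe_id=probe.probe_id, intervals=intervals)


def features_in_windows(windows: WindowSet, features: FeatureMatrix) -> list[str]:
    """Feature ids whose anchor coordinate falls in any window (half-open).

    Each feature is returned at most once, in matrix order.  Features without
    coordinates are skipped (count logged).
    """
    if features.coords is None:
        raise ValidationError("features carry no coordinates")
    coords = features.coords
    has_coords = coords["pos"].notna() & coords["chrom"].notna()
    n_skipped = int((~has_coords).sum())
    if n_skipped:
        logger.info("features_in_windows: skipped %d features without coordinates", n_skipped)
    coords = coords[has_coords]

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in windows.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))

    hits: set[str] = set()
    for chrom, ivs in by_chrom.items():
        sub = coords[coords["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        # disjoint merged intervals: position is inside iff the preceding
        # start's interval has not yet ended
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hits.update(sub.index[inside])
    return [fid for fid in features.feature_ids if fid in hits]
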