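"""Genomic-interval algebra: consensus peaks, overlap summaries,
peak categorization, relative-distance statistics, signal matrices,
and feature distributions.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of genomic intervals.

    Intervals are kept sorted by (chrom, start, end). Construction accepts
    `Interval` objects or (chrom, start, end[, name]) tuples.
    """

    def __init__(self, intervals: Iterable[Interval | tuple] = ()) -> None:
        records = []
        for iv in intervals:
            if not isinstance(iv, Interval):
                iv = Interval(*iv)
            records.append(iv)
        self.records: list[Interval] = sorted(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(r.chrom, r.start, r.end) for r in self.records] == [
            (r.chrom, r.start, r.end) for r in other.records
        ]

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.records})

    def on(self, chrom: str) -> list[Interval]:
        return [r for r in self.records if r.chrom == chrom]

    def midpoints(self, chrom: str) -> np.ndarray:
        return np.array([r.midpoint for r in self.on(chrom)], dtype=float)

    # ---- BED I/O -------------------------------------------------------

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                name = parts[3] if len(parts) > 3 else None
                records.append(Interval(parts[0], int(parts[1]), int(parts[2]), name))
        return cls(records)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                if r.name is None:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
                else:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_intervals(
    replicate_sets: Sequence[IntervalSet], min_support: int = 2
) -> IntervalSet:
    """Maximal intervals covered by >= `min_support` replicate sets.

    Bases covered by at least `min_support` of the input sets are merged
    into maximal runs; bookended runs coalesce.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(replicate_sets) < min_support:
        return IntervalSet()

    chroms = sorted({c for s in replicate_sets for c in s.chroms})
    out: list[Interval] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for s in replicate_sets:
            # merge within one replicate first so double-counted self-overlaps
            # do not inflate support
            for iv in _merge_intervals(s.on(chrom)):
                events.append((iv.start, +1))
                events.append((iv.end, -1))
        events.sort()
        depth = 0
        run_start = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                if pos > run_start:
                    out.append(Interval(chrom, run_start, pos))
                run_start = None
    return IntervalSet(out)


def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping (not bookended) intervals on one chromosome."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start < last.end:
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# overlap / Venn
# ---------------------------------------------------------------------------

def overlap_venn(set_a: IntervalSet, set_b: IntervalSet) -> dict[str, int]:
    """Two-set overlap summary.

    Returns counts of A-only and B-only intervals (no cross-set overlap)
    and `shared`, the number of connected components of the cross-set
    overlap graph (many-to-many overlaps collapse to one shared event).
    Raw per-set overlapping-interval counts are also emitted
    (`A_overlapping`, `B_overlapping`) since plotting-tool conventions vary.
    """
    n_a, n_b = len(set_a), len(set_b)
    parent = list(range(n_a + n_b))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    a_hit = [False] * n_a
    b_hit = [False] * n_b
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for j, iv in enumerate(set_b.records):
        by_chrom_b.setdefault(iv.chrom, []).append((j, 0))
    for i, a in enumerate(set_a.records):
        for j, _ in by_chrom_b.get(a.chrom, ()):
            b = set_b.records[j]
            if a.start < b.end and b.start < a.end:
                a_hit[i] = True
                b_hit[j] = True
                union(i, n_a + j)

    comps = set()
    for i in range(n_a):
        if a_hit[i]:
            comps.add(find(i))
    for j in range(n_b):
        if b_hit[j]:
            comps.add(find(n_a + j))

    return {
        "A_only": sum(not h for h in a_hit),
        "B_only": sum(not h for h in b_hit),
        "shared": len(comps),
        "A_overlapping": sum(a_hit),
        "B_overlapping": sum(b_hit),
    }


def _overlaps_any(iv: Interval, other: IntervalSet) -> bool:
    return any(iv.overlaps(o) for o in other.on(iv.chrom))


@dataclass
class CategoryResult:
    """Three peak categories from comparing a subunit's parental consensus
    peaks with catalytic-subunit peaks in parental and knockout cells."""

    specific: IntervalSet
    non_specific: IntervalSet
    ko_specific: IntervalSet


def categorize_peaks(
    pbrm1: IntervalSet,
    smarca4_parental: IntervalSet,
    smarca4_ko: IntervalSet,
    ko_vs_both_parental: bool = True,
) -> CategoryResult:
    """Partition peaks into specific / non-specific / KO-specific.

    specific: `pbrm1` peaks with no overlap in `smarca4_ko`.
    non_specific: `pbrm1` peaks overlapping `smarca4_ko`.
    ko_specific: `smarca4_ko` peaks overlapping neither parental set
    (with `ko_vs_both_parental=False`, only `smarca4_parental` is excluded).
    """
    specific, non_specific = [], []
    for iv in pbrm1:
        (non_specific if _overlaps_any(iv, smarca4_ko) else specific).append(iv)
    ko_specific = []
    for iv in smarca4_ko:
        hit_parental = _overlaps_any(iv, smarca4_parental)
        if ko_vs_both_parental:
            hit_parental = hit_parental or _overlaps_any(iv, pbrm1)
        if not hit_parental:
            ko_specific.append(iv)
    return CategoryResult(
        IntervalSet(specific), IntervalSet(non_specific), IntervalSet(ko_specific)
    )


# ---------------------------------------------------------------------------
# relative distance
# ---------------------------------------------------------------------------

@dataclass
class RelDistResult:
    d1: np.ndarray
    d2: np.ndarray
    reldist: np.ndarray
    n_skipped: int

    @property
    def r(self) -> np.ndarray:
        return self.d1 + self.d2

    def cumulative(self, step: float = 0.01) -> pd.DataFrame:
        """Cumulative fraction of query locations at each relative
        distance on a grid up to the maximum possible of 0.5."""
        grid = np.round(np.arange(step, 0.5 + step / 2, step), 10)
        n = len(self.reldist)
        frac = (
            np.array([(self.reldist <= g).sum() for g in grid]) / n
            if n
            else np.zeros_like(grid)
        )
        return pd.DataFrame({"reldist": grid, "cumulative_fraction": frac})


def relative_distance(
    query: IntervalSet, reference: IntervalSet, use: str = "midpoint"
) -> RelDistResult:
    """Relative distance min(d1, d2) / (d1 + d2) of each query location
    between its two flanking reference locations.

    Locations are interval midpoints (`use="start"` switches to start
    coordinates). Query locations outside the outermost reference locations
    on their chromosome are skipped; a query coincident with a reference
    location scores 0.
    """
    if use not in ("midpoint", "start"):
        raise ValueError("use must be 'midpoint' or 'start'")

    def locs(s: IntervalSet, chrom: str) -> np.ndarray:
        vals = [
            (r.midpoint if use == "midpoint" else r.start) for r in s.on(chrom)
        ]
        return np.unique(np.asarray(vals, dtype=float))

    d1s, d2s, rels = [], [], []
    n_skipped = 0
    usable = False
    for chrom in query.chroms:
        ref = locs(reference, chrom)
        q = locs(query, chrom)
        if len(ref) < 2:
            n_skipped += len(q)
            continue
        usable = True
        idx = np.searchsorted(ref, q)
        for qi, i in zip(q, idx):
            if i < len(ref) and ref[i] == qi:
                d1 = 0.0
                d2 = ref[i + 1] - qi if i + 1 < len(ref) else qi - ref[i - 1]
                if d2 == 0.0:  # single-point degenerate; treat r as next gap
                    d2 = 1.0
            elif 0 < i < len(ref):
                d1 = qi - ref[i - 1]
                d2 = ref[i] - qi
            else:
                n_skipped += 1
                continue
            d1s.append(d1)
            d2s.append(d2)
            rels.append(min(d1, d2) / (d1 + d2))
    if not usable:
        warnings.warn(
            "reference has < 2 locations on every query chromosome; "
            "empty relative-distance result"
        )
    return RelDistResult(
        np.asarray(d1s), np.asarray(d2s), np.asarray(rels), n_skipped
    )


# ---------------------------------------------------------------------------
# signal matrix
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    values: np.ndarray          # rows x bins, ordered
    intervals: list[Interval]   # same order as rows
    flank: int
    binsize: int

    @property
    def profile(self) -> np.ndarray:
        """Column-mean average signal profile."""
        return self.values.mean(axis=0) if len(self.values) else np.array([])


def coverage_from_fragments(
    fragments: IntervalSet, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base fragment-depth coverage from fragment intervals."""
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    for iv in fragments:
        if iv.chrom not in cov:
            continue
        arr = cov[iv.chrom]
        arr[max(iv.start, 0): min(iv.end, len(arr))] += 1
    return cov


def signal_matrix(
    intervals: IntervalSet,
    coverage: Mapping[str, np.ndarray],
    flank: int = 5000,
    bins: int = 100,
    order_by: "SignalMatrix | None" = None,
) -> SignalMatrix:
    """Mean coverage in `bins` bins across interval centers +/- `flank`.

    Rows are ordered by descending row sum of `order_by` (default: this
    matrix itself). Positions outside the chromosome contribute 0.
    """
    if (2 * flank) % bins != 0:
        raise ValueError("bins must divide 2*flank")
    binsize = 2 * flank // bins
    rows = []
    for iv in intervals:
        cov = coverage.get(iv.chrom)
        window = np.zeros(2 * flank, dtype=float)
        if cov is not None:
            c = iv.midpoint
            lo, hi = c - flank, c + flank
            src_lo, src_hi = max(lo, 0), min(hi, len(cov))
            if src_hi > src_lo:
                window[src_lo - lo: src_hi - lo] = cov[src_lo:src_hi]
        rows.append(window.reshape(bins, binsize).mean(axis=1))
    values = np.array(rows) if rows else np.zeros((0, bins))

    key = order_by.values if order_by is not None else values
    if len(key) != len(values):
        raise ValueError("ordering matrix has a different number of rows")
    order = np.argsort(-key.sum(axis=1), kind="stable")
    return SignalMatrix(
        values[order], [intervals[i] for i in order], flank, binsize
    )


# ---------------------------------------------------------------------------
# feature distribution
# ---------------------------------------------------------------------------

DEFAULT_PRIORITY = ("promoter", "exon", "intron", "downstream")


def feature_distribution(
    peaks: IntervalSet,
    features: IntervalSet,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[str, float]:
    """Fraction of peaks per feature label, assigned by peak center.

    Each peak takes the single highest-priority feature label overlapping
    its center; peaks overlapping nothing are `intergenic`. Fractions sum
    to 1.
    """
    if len(set(priority)) != len(priority):
        raise ValueError("duplicate priority labels")
    rank = {label: i for i, label in enumerate(priority)}
    counts = {label: 0 for label in priority}
    counts["intergenic"] = 0
    if not len(peaks):
        return {k: 0.0 for k in counts}
    for peak in peaks:
        c = peak.midpoint
        best = None
        for f in features.on(peak.chrom):
            if f.start <= c < f.end and f.name in rank:
                if best is None or rank[f.name] < rank[best]:
                    best = f.name
        counts[best if best is not None else "intergenic"] += 1
    n = len(peaks)
    return {k: v / n for k, v in counts.items()}


def promoter_windows(
    genes: IntervalSet, upstream: int = 3000, downstream: int = 3000
) -> IntervalSet:
    """Toy promoter builder: windows around each gene start."""
    out = []
    for g in genes:
        start = max(0, g.start - upstream)
        out.append(Interval(g.chrom, start, g.start + downstream, "promoter"))
    return IntervalSet(out)
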