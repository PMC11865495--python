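"""Exact re-mapping of k-mers to a genome and attribution of mapping
sites to annotation classes.

Coordinates are 0-based half-open. A k-mer's mapping sites are all exact
occurrences of the k-mer (+) or its reverse complement (-), enumerated
left-to-right with + before - at equal coordinates and truncated at
`max_hits` per k-mer. For reverse-complement palindromes the coincident
+/- hits collapse to a single + hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._seq import reverse_complement
from .interval_ops import IntervalSet
from .simulate.genome import ToyGenome


@dataclass(frozen=True)
class KmerHit:
    kmer_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _as_sequences(genome) -> dict[str, str]:
    if isinstance(genome, ToyGenome):
        return {genome.name: genome.sequence}
    if isinstance(genome, Mapping):
        return dict(genome)
    raise TypeError("genome must be a ToyGenome or a mapping chrom -> sequence")


def map_exact(
    kmers: Mapping[str, str] | Iterable[tuple[str, str]],
    genome,
    max_hits: int = 5000,
) -> tuple[list[KmerHit], set[str]]:
    """All exact occurrences of each k-mer on both strands.

    `kmers` maps k-mer id -> sequence. Returns the hit list and the set of
    k-mer ids whose hits were truncated at `max_hits` (so saturated k-mers
    are identifiable). K-mers with non-ACGT characters are skipped with a
    warning.
    """
    seqs = _as_sequences(genome)
    if isinstance(kmers, Mapping):
        items = list(kmers.items())
    else:
        items = list(kmers)

    hits: list[KmerHit] = []
    truncated: set[str] = set()
    for kmer_id, kmer in items:
        kmer = kmer.upper()
        if any(c not in "ACGT" for c in kmer):
            warnings.warn(f"skipping k-mer {kmer_id!r} with non-ACGT characters")
            continue
        rc = reverse_complement(kmer)
        palindrome = kmer == rc
        k = len(kmer)
        kmer_hits: list[KmerHit] = []
        for chrom in sorted(seqs):
            seq = seqs[chrom].upper()
            fwd = _find_all(seq, kmer)
            rev = [] if palindrome else _find_all(seq, rc)
            fi = ri = 0
            # coordinate order, + before - at equal start
            while fi < len(fwd) or ri < len(rev):
                if ri >= len(rev) or (fi < len(fwd) and fwd[fi] <= rev[ri]):
                    pos, strand = fwd[fi], "+"
                    fi += 1
                else:
                    pos, strand = rev[ri], "-"
                    ri += 1
                kmer_hits.append(KmerHit(kmer_id, chrom, pos, pos + k, strand))
        if len(kmer_hits) > max_hits:
            truncated.add(kmer_id)
            kmer_hits = kmer_hits[:max_hits]
        hits.extend(kmer_hits)
    return hits, truncated


def split_class(annotation_name: str) -> str:
    """Annotation class: the substring before the first underscore.

    e.g. ``ct_1_1(p_arm)`` -> ``ct``; names without an underscore are
    returned whole.
    """
    return annotation_name.split("_", 1)[0]


def pivot_regions(hits: Iterable[KmerHit], annotation: IntervalSet) -> pd.DataFrame:
    """k-mer x annotation-class matrix of mapping-site counts.

    A hit overlapping an annotation interval by >= 1 bp increments the
    (kmer, class) cell; a hit straddling a boundary counts once per
    overlapped interval. Hits outside the annotation are dropped.
    """
    cells: dict[tuple[str, str], int] = {}
    by_chrom: dict[str, list] = {}
    for iv in annotation:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for hit in hits:
        for iv in by_chrom.get(hit.chrom, ()):
            if hit.start < iv.end and iv.start < hit.end and iv.name:
                key = (hit.kmer_id, split_class(iv.name))
                cells[key] = cells.get(key, 0) + 1
    if not cells:
        return pd.DataFrame()
    df = pd.Series(cells).unstack(fill_value=0)
    df.index.name = "kmer"
    df.columns.name = "class"
    return df


def region_percentages(
    pivot: pd.DataFrame,
    enriched_set: Iterable[str],
    denominator: str = "all_enriched",
) -> dict[str, float]:
    """Percentage of enriched k-mers with >= 1 mapping site in each class.

    A k-mer hitting several classes contributes to each, so percentages may
    sum above 100. `denominator="mapped"` restricts the denominator to
    enriched k-mers with at least one in-annotation hit.
    """
    enriched = set(enriched_set)
    if not enriched:
        raise ValueError("enriched set is empty")
    if denominator not in ("all_enriched", "mapped"):
        raise ValueError("denominator must be 'all_enriched' or 'mapped'")
    if pivot.empty:
        return {}
    rows = pivot.loc[pivot.index.intersection(enriched)]
    denom = len(enriched)
    if denominator == "mapped":
        denom = int((rows.sum(axis=1) > 0).sum())
        if denom == 0:
            return {str(c): 0.0 for c in pivot.columns}
    return {
        str(c): 100.0 * int((rows[c] > 0).sum()) / denom for c in pivot.columns
    }


def hits_to_bed(hits: Iterable[KmerHit], path) -> None:
    """Write hits as BED6 (name = k-mer id, score = 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.kmer_id}\t0\t{h.strand}\n"
            )


def hit_coverage_bedgraph(
    hits: Iterable[KmerHit], chrom_lengths: Mapping[str, int], path
) -> None:
    """Per-base hit-coverage bedGraph for genome-browser-style inspection."""
    import numpy as np

    cov = {c: np.zeros(n, dtype=int) for c, n in chrom_lengths.items()}
    for h in hits:
        if h.chrom in cov:
            cov[h.chrom][h.start: h.end] += 1
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            arr = cov[chrom]
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")
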