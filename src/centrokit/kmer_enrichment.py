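"""Canonical k-mer counting and enrichment calling against an averaged
nonspecific control.

The pipeline counts canonical 51-mers per replicate (dropping k-mers seen
fewer than `min_count` times), normalizes by each replicate's total base
count (missing k-mers floored to a raw count of 1 before dividing), pools
low/high salt fractions by adding their normalized counts, averages the
control replicates, and calls a k-mer enriched when its fold change over
the averaged control exceeds `fc_threshold` in at least
`min_enriched_replicates` replicates that individually pass the
`norm_threshold` abundance filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import canonical


@dataclass(frozen=True)
class KmerConfig:
    k: int = 51
    min_count: int = 2
    missing_floor: int = 1
    norm_threshold: float = 5e-09
    fc_threshold: float = 2.0
    min_enriched_replicates: int = 2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.norm_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class KmerTable:
    """Raw canonical k-mer counts for one replicate."""

    replicate_id: str
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class NormalizedKmerTable:
    """Normalized (count / total bases) k-mer rates for one replicate.

    `floor_value` is the rate assigned to a k-mer absent from this table
    (raw-count floor divided by the total base count); it is carried so
    unions with other tables can apply the floor lazily.
    """

    replicate_id: str
    total_base_count: int
    values: dict[str, float]
    floor_value: float

    def get(self, kmer: str) -> float:
        return self.values.get(kmer, self.floor_value)

    def kmers(self) -> set[str]:
        return set(self.values)


def count_kmers(
    reads: Iterable[str], cfg: KmerConfig, replicate_id: str = "rep"
) -> KmerTable:
    """Count canonical k-mers across all length-k read windows.

    Windows containing non-ACGT characters are skipped; k-mers with total
    count below `cfg.min_count` are dropped.
    """
    k = cfg.k
    counts: dict[str, int] = {}
    for read in reads:
        read = read.upper()
        n = len(read)
        if n < k:
            continue
        clean = all(c in "ACGT" for c in read)
        for i in range(n - k + 1):
            kmer = read[i: i + k]
            if not clean and any(c not in "ACGT" for c in kmer):
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    if cfg.min_count > 1:
        counts = {s: c for s, c in counts.items() if c >= cfg.min_count}
    return KmerTable(replicate_id, counts)


def total_base_count(reads: Iterable[str]) -> int:
    """Sum of read lengths over the replicate's full read set (both mates)."""
    return sum(len(r) for r in reads)


def normalize_counts(
    tables: Mapping[str, KmerTable],
    base_counts: Mapping[str, int],
    cfg: KmerConfig,
) -> dict[str, NormalizedKmerTable]:
    """Join raw tables over the union of k-mers and divide by base counts.

    A k-mer absent from a replicate gets the raw-count floor
    (`cfg.missing_floor`, applied before division), so floored values
    differ between replicates with different base counts.
    """
    for rep in tables:
        if rep not in base_counts:
            raise ValueError(f"no base count for replicate {rep!r}")
        if base_counts[rep] <= 0:
            raise ValueError(
                f"replicate {rep!r} has non-positive total base count; "
                "cannot normalize"
            )
    union: set[str] = set()
    for t in tables.values():
        union |= set(t.counts)
    out = {}
    for rep, table in tables.items():
        bases = base_counts[rep]
        floor = cfg.missing_floor / bases
        values = {
            kmer: max(table.counts.get(kmer, 0), cfg.missing_floor) / bases
            for kmer in union
        }
        out[rep] = NormalizedKmerTable(rep, bases, values, floor)
    return out


def pool_salt_fractions(
    low: NormalizedKmerTable, high: NormalizedKmerTable
) -> NormalizedKmerTable:
    """Add the normalized counts of a replicate's salt fractions.

    Each fraction is normalized by its own base count before the sum; the
    floor applies per fraction, so a k-mer missing from one fraction still
    contributes that fraction's floor.
    """
    if low.replicate_id != high.replicate_id:
        raise ValueError(
            f"salt fractions belong to different replicates: "
            f"{low.replicate_id!r} vs {high.replicate_id!r}"
        )
    union = low.kmers() | high.kmers()
    values = {kmer: low.get(kmer) + high.get(kmer) for kmer in union}
    return NormalizedKmerTable(
        low.replicate_id,
        low.total_base_count + high.total_base_count,
        values,
        low.floor_value + high.floor_value,
    )


def average_control(
    control_tables: Sequence[NormalizedKmerTable],
) -> NormalizedKmerTable:
    """Arithmetic mean per k-mer over the control replicates.

    Replicates missing a k-mer contribute their floored value; the result
    covers any k-mer via its own (averaged) floor.
    """
    if not control_tables:
        raise ValueError("need at least one control replicate")
    n = len(control_tables)
    union: set[str] = set()
    for t in control_tables:
        union |= t.kmers()
    values = {
        kmer: sum(t.get(kmer) for t in control_tables) / n for kmer in union
    }
    return NormalizedKmerTable(
        "control_avg",
        sum(t.total_base_count for t in control_tables),
        values,
        sum(t.floor_value for t in control_tables) / n,
    )


@dataclass
class EnrichmentResult:
    """Per-k-mer fold changes vs the averaged control and enrichment calls.

    `table` columns: norm_<rep> per replicate, control_avg, fc_<rep> per
    replicate (NaN where the replicate failed the abundance filter),
    n_passing, enriched.
    """

    table: pd.DataFrame
    replicates: list[str]
    config: KmerConfig

    @property
    def enriched_kmers(self) -> list[str]:
        return list(self.table.index[self.table["enriched"]])

    def to_fasta(self, path) -> None:
        """Enriched k-mers as FASTA with serial headers >1, >2, ..."""
        with open(path, "w") as fh:
            for i, kmer in enumerate(self.enriched_kmers, start=1):
                fh.write(f">{i}\n{kmer}\n")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="kmer")


def call_enrichment(
    targets: Mapping[str, NormalizedKmerTable],
    control_avg: NormalizedKmerTable,
    cfg: KmerConfig,
) -> EnrichmentResult:
    """Call enriched k-mers from target replicates vs the averaged control.

    Per replicate, a k-mer is eligible iff its normalized count exceeds
    `cfg.norm_threshold`; its fold change is the replicate value divided by
    the control average. A replicate passes when it is eligible AND its
    fold change exceeds `cfg.fc_threshold`. A k-mer is enriched iff at
    least `cfg.min_enriched_replicates` replicates pass.
    """
    if not targets:
        raise ValueError("no target replicates")
    reps = list(targets)
    union: set[str] = set()
    for t in targets.values():
        union |= t.kmers()
    union |= control_avg.kmers()
    kmers = sorted(union)

    rows: dict[str, list] = {}
    for rep in reps:
        rows[f"norm_{rep}"] = [targets[rep].get(k) for k in kmers]
    ctrl = [control_avg.get(k) for k in kmers]
    if any(c <= 0 for c in ctrl):
        raise ValueError("control average contains non-positive values")
    rows["control_avg"] = ctrl

    df = pd.DataFrame(rows, index=pd.Index(kmers, name="kmer"))
    n_passing = pd.Series(0, index=df.index)
    for rep in reps:
        eligible = df[f"norm_{rep}"] > cfg.norm_threshold
        fc = df[f"norm_{rep}"] / df["control_avg"]
        df[f"fc_{rep}"] = fc.where(eligible)
        n_passing += (eligible & (fc > cfg.fc_threshold)).astype(int)
    df["n_passing"] = n_passing
    df["enriched"] = n_passing >= cfg.min_enriched_replicates
    return EnrichmentResult(df, reps, cfg)
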