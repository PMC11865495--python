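"""Paired-end read simulation with planted per-interval enrichment.

Fragment start positions are drawn with per-base sampling weight 1
outside enrichment intervals and the interval's weight inside; fragment
lengths come from a truncated normal. Mate 1 is the forward left end of
the fragment, mate 2 the reverse complement of the right end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .._seq import reverse_complement
from .genome import ToyGenome

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadSimConfig:
    n_pairs: int
    read_length: int = 75
    fragment_mean: float = 180.0
    fragment_sd: float = 30.0
    #: (start, end, weight) triples; weight >= 0, coordinates half-open
    enrichment: Sequence[tuple[int, int, float]] = field(default_factory=tuple)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for start, end, w in self.enrichment:
            if w < 0:
                raise ValueError("enrichment weights must be >= 0")
            if start >= end:
                raise ValueError(f"invalid enrichment interval [{start}, {end})")


@dataclass
class SimulatedReads:
    """Read pairs plus the fragment coordinates they came from."""

    names: list[str]
    mate1: list[str]
    mate2: list[str]
    fragments: np.ndarray  # n_pairs x 2 (start, end)

    def __len__(self) -> int:
        return len(self.names)

    def reads(self) -> list[str]:
        """All read sequences, both mates interleaved."""
        out = []
        for r1, r2 in zip(self.mate1, self.mate2):
            out.append(r1)
            out.append(r2)
        return out

    def write_fastq(self, path1, path2) -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for name, r1, r2 in zip(self.names, self.mate1, self.mate2):
                q1, q2 = "I" * len(r1), "I" * len(r2)
                f1.write(f"@{name}/1\n{r1}\n+\n{q1}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{q2}\n")


def simulate_reads(
    genome: ToyGenome | str, cfg: ReadSimConfig, prefix: str = "frag"
) -> SimulatedReads:
    """Simulate paired-end reads from a genome. Deterministic under seed."""
    seq = genome.sequence if isinstance(genome, ToyGenome) else genome
    L = len(seq)
    if L < cfg.read_length:
        raise ValueError("genome shorter than read length")
    for start, end, _ in cfg.enrichment:
        if start < 0 or end > L:
            raise ValueError(f"enrichment interval [{start}, {end}) out of bounds")

    rng = np.random.default_rng(cfg.seed)

    weights = np.ones(L, dtype=float)
    for start, end, w in cfg.enrichment:
        weights[start:end] = w
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    p = weights / total

    starts = rng.choice(L, size=cfg.n_pairs, p=p)
    lengths = rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=cfg.n_pairs)
    lengths = np.maximum(np.rint(lengths).astype(int), cfg.read_length)

    ends = np.minimum(starts + lengths, L)
    # keep the fragment on the genome without shortening below read length
    starts = np.minimum(starts, ends - cfg.read_length)
    starts = np.maximum(starts, 0)

    names, m1, m2 = [], [], []
    fragments = np.column_stack([starts, ends])
    rl = cfg.read_length
    for i, (s, e) in enumerate(fragments):
        frag = seq[s:e]
        r1 = frag[:rl]
        r2 = reverse_complement(frag[-rl:])
        if cfg.error_rate > 0:
            r1 = _add_errors(r1, cfg.error_rate, rng)
            r2 = _add_errors(r2, cfg.error_rate, rng)
        names.append(f"{prefix}_{i}_{s}_{e}")
        m1.append(r1)
        m2.append(r2)
    return SimulatedReads(names, m1, m2, fragments)


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    hit = rng.random(len(read)) < rate
    if not hit.any():
        return read
    chars = np.array(list(read))
    chars[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(chars)
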