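"""Toy repeat genomes with censat-style annotation.

A genome is assembled segment-by-segment from a plan of
(class-label, size) pairs. Higher-order-repeat-like classes (`hor`,
`dhor`, `mon`) are sized in monomer copies; all other classes in bp.
Everything except `arm` segments is annotated with censat-style names
such as ``ct_1_1(p_arm)`` whose class prefix precedes the first
underscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .._seq import IUPAC
from ..interval_ops import Interval, IntervalSet

SEGMENT_CLASSES = frozenset({"arm", "ct", "mon", "hor", "dhor", "hsat1", "hsat2"})
MONOMER_CLASSES = frozenset({"hor", "dhor", "mon"})

#: 17-bp degenerate CENP-B-box-like consensus; N positions are resolved
#: per genome under the seed.
DEFAULT_CENPB_MOTIF = "NTTCGNNNNANNCGGGN"

_BASES = np.array(list("ACGT"))

# detail suffix used in annotation names per class (ct handled separately)
_CLASS_DETAIL = {
    "hor": "S1C1H1L",
    "dhor": "S1C1dH1",
    "mon": "mon",
    "hsat1": "HSat1",
    "hsat2": "HSat2",
}

_HSAT_UNIT_LENGTH = {"hsat1": 42, "hsat2": 5}


@dataclass(frozen=True)
class GenomeSpec:
    """Plan for a single-chromosome toy genome.

    segments: ordered (class-label, size) pairs; size is a monomer count
    for classes in MONOMER_CLASSES and bp otherwise.
    """

    segments: Sequence[tuple[str, int]]
    monomer_length: int = 171
    cenpb_motif: str = DEFAULT_CENPB_MOTIF
    seed: int = 0
    chrom_name: str = "chrTOY"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segment plan is empty")
        for label, size in self.segments:
            if label not in SEGMENT_CLASSES:
                raise ValueError(f"unknown segment class {label!r}")
            if size <= 0:
                raise ValueError(f"segment size must be > 0, got {size}")
        if self.monomer_length < len(self.cenpb_motif):
            raise ValueError("motif longer than monomer")
        for b in self.cenpb_motif.upper():
            if b not in IUPAC:
                raise ValueError(f"invalid IUPAC code {b!r} in motif")

    def segment_length_bp(self, label: str, size: int) -> int:
        return size * self.monomer_length if label in MONOMER_CLASSES else size

    @property
    def total_length(self) -> int:
        return sum(self.segment_length_bp(lb, sz) for lb, sz in self.segments)


@dataclass
class ToyGenome:
    name: str
    sequence: str
    annotation: IntervalSet
    motif: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i: i + 80] + "\n")

    def to_bed(self, path) -> None:
        self.annotation.to_bed(path)

    def annotation_interval(self, class_prefix: str) -> list[Interval]:
        """Annotated intervals whose name starts with `class_prefix`."""
        return [
            r
            for r in self.annotation
            if r.name is not None and r.name.split("_", 1)[0] == class_prefix
        ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _resolve_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        b if len(IUPAC[b]) == 1 else IUPAC[b][rng.integers(0, len(IUPAC[b]))]
        for b in motif.upper()
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    if hit.any():
        chars[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(chars)


def build_toy_genome(spec: GenomeSpec) -> ToyGenome:
    """Assemble the genome and its annotation from a GenomeSpec.

    HOR segments are tandem copies of one seeded random monomer carrying
    the resolved motif once per monomer; `dhor` copies are mildly diverged,
    `mon` copies more diverged and motif-free. `hsat1`/`hsat2` tile a
    seeded random unit. `ct` and `arm` are unique random sequence; only
    non-arm segments are annotated. Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    motif = _resolve_motif(spec.cenpb_motif, rng)

    # shared monomer for alpha-satellite-like classes, motif at a fixed
    # seeded offset
    monomer = list(_random_seq(rng, spec.monomer_length))
    offset = int(rng.integers(0, spec.monomer_length - len(motif) + 1))
    monomer[offset: offset + len(motif)] = motif
    monomer = "".join(monomer)

    hsat_units = {
        cls: _random_seq(rng, n) for cls, n in _HSAT_UNIT_LENGTH.items()
    }

    parts: list[str] = []
    annotation: list[Interval] = []
    class_counter: dict[str, int] = {}
    pos = 0
    seen_satellite = False

    for label, size in spec.segments:
        length = spec.segment_length_bp(label, size)
        if label == "arm":
            seg = _random_seq(rng, length)
        elif label == "ct":
            seg = _random_seq(rng, length)
        elif label in MONOMER_CLASSES:
            copies = []
            for _ in range(size):
                if label == "hor":
                    copies.append(monomer)
                elif label == "dhor":
                    copies.append(_mutate(monomer, 0.05, rng))
                else:  # mon: diverged, motif-free
                    copy = _mutate(monomer, 0.15, rng)
                    copy = (
                        copy[:offset]
                        + _random_seq(rng, len(motif))
                        + copy[offset + len(motif):]
                    )
                    copies.append(copy)
            seg = "".join(copies)
        else:  # hsat1 / hsat2
            unit = hsat_units[label]
            reps = length // len(unit) + 1
            seg = (unit * reps)[:length]

        if label != "arm":
            count = class_counter.get(label, 0) + 1
            class_counter[label] = count
            if label == "ct":
                detail = "p_arm" if not seen_satellite else "q_arm"
            else:
                detail = _CLASS_DETAIL[label]
            name = f"{label}_1_{count}({detail})"
            annotation.append(Interval(spec.chrom_name, pos, pos + length, name))
        if label in MONOMER_CLASSES or label.startswith("hsat"):
            seen_satellite = True

        parts.append(seg)
        pos += length

    genome = ToyGenome(
        spec.chrom_name, "".join(parts), IntervalSet(annotation), motif
    )
    assert len(genome.sequence) == spec.total_length
    return genome
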