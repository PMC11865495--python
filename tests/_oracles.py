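"""Independent brute-force oracles used to verify the package.

These deliberately avoid the implementations under test: reverse
complements come from Biopython, counting from collections.Counter, and
interval logic from per-base boolean arrays.
"""

from collections import Counter

import numpy as np
from Bio.Seq import Seq


def rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def kmer_count_oracle(reads, k, min_count):
    """Enumerate every length-k window, canonicalize, filter by count."""
    counter = Counter()
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            w = read[i: i + k]
            if any(c not in "ACGT" for c in w):
                continue
            counter[min(w, rc(w))] += 1
    return {s: c for s, c in counter.items() if c >= min_count}


def exact_map_oracle(kmer, genome_seqs):
    """All exact two-strand occurrences as (chrom, start, strand);
    palindromes report only the + hit."""
    out = []
    kmer = kmer.upper()
    k = len(kmer)
    kmer_rc = rc(kmer)
    palindrome = kmer == kmer_rc
    for chrom, seq in genome_seqs.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i: i + k]
            if window == kmer:
                out.append((chrom, i, "+"))
            if not palindrome and window == kmer_rc:
                out.append((chrom, i, "-"))
    return sorted(out)


def consensus_oracle(replicate_sets, min_support, chrom_length):
    """Per-base coverage sweep on a single chromosome of known length.

    replicate_sets: list of lists of (start, end). Returns sorted
    (start, end) runs where >= min_support sets cover the base.
    """
    depth = np.zeros(chrom_length, dtype=int)
    for intervals in replicate_sets:
        covered = np.zeros(chrom_length, dtype=bool)
        for start, end in intervals:
            covered[start:end] = True
        depth += covered
    keep = depth >= min_support
    runs = []
    start = None
    for i, v in enumerate(keep):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, chrom_length))
    return runs


def ring_ground_truth(spec, center, nucleus_mask, cfg):
    """Per-pixel evaluation of the ground-truth ring averages around one
    focus of a synthetic image (single-focus images only)."""
    from centrokit.simulate.images import evaluate_radial

    h, w = nucleus_mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d_um = np.hypot(yy - center[0], xx - center[1]) * spec.pixel_size
    truth = spec.background + evaluate_radial(spec.radial_profile, d_um)
    width = cfg.max_radius / cfg.n_rings
    means = []
    for r in range(1, cfg.n_rings + 1):
        lo, hi = (r - 1) * width, r * width
        sel = nucleus_mask & (d_um > lo) & (d_um <= hi)
        if r == 1:
            sel |= nucleus_mask & (d_um == 0)
        means.append(truth[sel].mean() if sel.any() else np.nan)
    return np.array(means)
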