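"""Protein-abundance panel statistics.

From a matrix of positive (sum-normalized) abundances with a design
mapping samples to the parental line or a knockout clone: per-clone log2
fold changes against the parental mean, column-median centering,
per-protein one-sample t-tests, and panel medians.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

PARENTAL = "parental"


def log2fc_vs_parental(
    abundances: pd.DataFrame,
    design: Mapping[str, str],
    min_detection: float = 0.5,
) -> pd.DataFrame:
    """log2(clone / parental mean) per protein per clone.

    `abundances` is proteins x samples with positive values (NaN allowed
    for missing). `design` maps sample -> "parental" or a clone id; samples
    sharing a clone id are averaged. Proteins detected in fewer than
    `min_detection` of the samples are dropped; remaining missing values
    propagate as NaN per protein-clone pair (no imputation).
    """
    missing = [s for s in abundances.columns if s not in design]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    groups = pd.Series({s: design[s] for s in abundances.columns})
    parental_cols = groups.index[groups == PARENTAL]
    clone_ids = [g for g in pd.unique(groups) if g != PARENTAL]
    if len(parental_cols) == 0:
        raise ValueError("no parental samples in design")
    if not clone_ids:
        raise ValueError("no knockout clones in design")
    values = abundances.to_numpy(dtype=float)
    if np.nanmin(values) <= 0:
        raise ValueError("abundances must be positive")

    detected = abundances.notna().mean(axis=1) >= min_detection
    mat = abundances.loc[detected]

    parental_mean = mat[parental_cols].mean(axis=1)
    out = {}
    for clone in clone_ids:
        cols = groups.index[groups == clone]
        out[clone] = np.log2(mat[cols].mean(axis=1) / parental_mean)
    return pd.DataFrame(out)


def median_center(log2fc: pd.DataFrame) -> pd.DataFrame:
    """Subtract each clone column's median over proteins (NaN-aware)."""
    return log2fc - log2fc.median(axis=0)


def protein_tests(centered: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mean log2FC and two-sided one-sample t-test vs 0.

    t = mean / (sd / sqrt(n)) with df = n - 1 across clones; p is NaN when
    n < 2 or the sample standard deviation is 0.
    """
    means, ps, ts, ns = [], [], [], []
    for _, row in centered.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        n = len(vals)
        ns.append(n)
        if n == 0:
            means.append(np.nan)
            ts.append(np.nan)
            ps.append(np.nan)
            continue
        mean = vals.mean()
        means.append(mean)
        sd = vals.std(ddof=1) if n >= 2 else np.nan
        if n < 2 or not np.isfinite(sd) or sd == 0:
            ts.append(np.nan)
            ps.append(np.nan)
            continue
        t = mean / (sd / np.sqrt(n))
        ts.append(t)
        ps.append(2 * stats.t.sf(abs(t), df=n - 1))
    return pd.DataFrame(
        {"mean_log2fc": means, "t": ts, "n": ns, "p_value": ps},
        index=centered.index,
    )


def panel_median(
    centered: pd.DataFrame, panel: Iterable[str]
) -> tuple[pd.Series, list[str]]:
    """Median centered log2FC over panel proteins, per clone.

    Returns the per-clone medians and the panel ids absent from the matrix.
    """
    panel = list(dict.fromkeys(panel))
    present = [p for p in panel if p in centered.index]
    dropped = [p for p in panel if p not in centered.index]
    if not present:
        raise ValueError("no panel proteins present in the matrix")
    medians = centered.loc[present].median(axis=0)
    medians.name = "panel_median_log2fc"
    return medians, dropped
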