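"""Radial ring intensity profiles, focus shape metrics, and per-nucleus
intensities from multi-channel images.

Analysis is 2-D (maximum-intensity projections). The measured channel is
quantified in concentric rings around each focus center out to
`max_radius` um; each in-nucleus pixel is assigned to its nearest focus
(ties to the lower focus id) so overlapping ring disks of neighbouring
foci do not double count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.segmentation import watershed


@dataclass(frozen=True)
class RingConfig:
    max_radius: float = 4.0  # um
    n_rings: int = 8
    pixel_size: float = 0.1  # um / px
    statistic: str = "mean"  # or "integrated"

    def __post_init__(self) -> None:
        if self.max_radius <= 0:
            raise ValueError("max_radius must be > 0")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.statistic not in ("mean", "integrated"):
            raise ValueError("statistic must be 'mean' or 'integrated'")

    @property
    def ring_width(self) -> float:
        return self.max_radius / self.n_rings


@dataclass
class FocusMeasurement:
    nucleus_id: int
    focus_id: int
    center: tuple[float, float]  # (y, x) px
    ring_values: np.ndarray      # length n_rings, NaN where a ring is empty
    ring_pixel_counts: np.ndarray
    area_um2: float = float("nan")
    eccentricity: float = float("nan")


def segment_nuclei(
    dna_channel: np.ndarray | None = None,
    masks: np.ndarray | None = None,
    min_area: int = 100,
) -> np.ndarray:
    """Label nuclei by Otsu threshold, hole filling, and size filtering.

    Supplied label `masks` are passed through unchanged.
    """
    if masks is not None:
        return masks
    if dna_channel is None:
        raise ValueError("provide dna_channel or masks")
    img = np.asarray(dna_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if img.max() == img.min():
        warnings.warn("image has no contrast; zero nuclei found")
        return np.zeros(img.shape, dtype=np.int32)
    binary = img > threshold_otsu(img)
    binary = ndimage.binary_fill_holes(binary)
    labeled = sk_label(binary)
    sizes = np.bincount(labeled.ravel())
    keep = np.flatnonzero(sizes >= min_area)
    keep = keep[keep != 0]
    relabel = np.zeros(len(sizes), dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    return relabel[labeled]


@dataclass
class FociResult:
    table: pd.DataFrame        # nucleus, focus, y, x
    labels: np.ndarray         # focus label mask (focus id + 1)

    def centers(self) -> np.ndarray:
        return self.table[["y", "x"]].to_numpy(dtype=float)


def detect_foci(
    focus_channel: np.ndarray,
    nuclei: np.ndarray,
    k_sd: float = 5.0,
    min_distance: int = 3,
) -> FociResult:
    """Detect foci within labeled nuclei.

    Seeds are local maxima above background + k_sd * sd (background
    statistics are median/MAD over in-nucleus pixels); masks grow from the
    seeds by watershed over the above-threshold region. Centers are
    intensity-weighted centroids. Foci outside nuclei are discarded by
    construction.
    """
    from skimage.feature import peak_local_max

    img = np.asarray(focus_channel, dtype=float)
    inside = nuclei > 0
    if not inside.any():
        return _empty_foci(img.shape)
    vals = img[inside]
    bg = float(np.median(vals))
    sd = float(1.4826 * np.median(np.abs(vals - bg)))
    if sd == 0:
        sd = float(vals.std())
    threshold = bg + k_sd * sd

    peaks = peak_local_max(
        img,
        min_distance=min_distance,
        threshold_abs=threshold,
        labels=nuclei,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return _empty_foci(img.shape)

    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    mask = (img > threshold) & inside
    labels = watershed(-img, markers=markers, mask=mask)

    rows = []
    for i in range(1, len(peaks) + 1):
        sel = labels == i
        if not sel.any():
            continue
        ys, xs = np.nonzero(sel)
        wts = img[ys, xs]
        cy = float(np.average(ys, weights=wts))
        cx = float(np.average(xs, weights=wts))
        nucleus = int(nuclei[int(round(cy)), int(round(cx))])
        if nucleus == 0:
            continue
        rows.append({"nucleus": nucleus, "y": cy, "x": cx, "label": i})
    if not rows:
        return _empty_foci(img.shape)
    table = pd.DataFrame(rows).sort_values(["nucleus", "y", "x"])
    table["focus"] = range(len(table))
    relabel = np.zeros(len(peaks) + 1, dtype=np.int32)
    for fid, lab in zip(table["focus"], table["label"]):
        relabel[lab] = fid + 1
    return FociResult(
        table[["nucleus", "focus", "y", "x"]].reset_index(drop=True),
        relabel[labels],
    )


def _empty_foci(shape) -> FociResult:
    return FociResult(
        pd.DataFrame(columns=["nucleus", "focus", "y", "x"]),
        np.zeros(shape, dtype=np.int32),
    )


def ring_profile(
    measure_channel: np.ndarray,
    foci: pd.DataFrame,
    nuclei: np.ndarray,
    cfg: RingConfig,
    foci_masks: np.ndarray | None = None,
) -> list[FocusMeasurement]:
    """Ring statistics of the measured channel around each focus.

    Every in-nucleus pixel is assigned to the nearest focus center of its
    nucleus (ties to the lower focus id); the pixel joins ring
    ceil(d / ring_width) where d is its center's Euclidean distance (um)
    from the focus, ring 1 covering (0, width] with the center pixel in
    ring 1. Rings past `max_radius` are discarded; empty rings are NaN.
    `foci` needs columns nucleus, focus, y, x (as from `detect_foci`).
    """
    img = np.asarray(measure_channel, dtype=float)
    width = cfg.ring_width
    out: list[FocusMeasurement] = []
    for nucleus_id in sorted(pd.unique(foci["nucleus"])):
        sub = foci[foci["nucleus"] == nucleus_id].sort_values("focus")
        centers = sub[["y", "x"]].to_numpy(dtype=float)
        focus_ids = sub["focus"].to_numpy()
        ys, xs = np.nonzero(nuclei == nucleus_id)
        if len(ys) == 0 or len(centers) == 0:
            continue
        # distance of each in-nucleus pixel to each focus, um
        d = np.sqrt(
            (ys[:, None] - centers[None, :, 0]) ** 2
            + (xs[:, None] - centers[None, :, 1]) ** 2
        ) * cfg.pixel_size
        nearest = np.argmin(d, axis=1)  # argmin ties -> lowest focus id
        dmin = d[np.arange(len(ys)), nearest]
        ring = np.ceil(dmin / width).astype(int)
        ring[dmin == 0] = 1

        vals = img[ys, xs]
        for fi, fid in enumerate(focus_ids):
            ring_values = np.full(cfg.n_rings, np.nan)
            ring_counts = np.zeros(cfg.n_rings, dtype=int)
            mine = nearest == fi
            for r in range(1, cfg.n_rings + 1):
                sel = mine & (ring == r)
                n = int(sel.sum())
                ring_counts[r - 1] = n
                if n:
                    ring_values[r - 1] = (
                        vals[sel].mean()
                        if cfg.statistic == "mean"
                        else vals[sel].sum()
                    )
            area = ecc = float("nan")
            if foci_masks is not None:
                mask = foci_masks == fid + 1
                if mask.any():
                    area, ecc = shape_metrics(mask, cfg.pixel_size)
            out.append(
                FocusMeasurement(
                    int(nucleus_id),
                    int(fid),
                    (float(centers[fi, 0]), float(centers[fi, 1])),
                    ring_values,
                    ring_counts,
                    area,
                    ecc,
                )
            )
    return out


def ring_profile_table(measurements: list[FocusMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        row = {"nucleus": m.nucleus_id, "focus": m.focus_id,
               "y": m.center[0], "x": m.center[1],
               "area_um2": m.area_um2, "eccentricity": m.eccentricity}
        for i, v in enumerate(m.ring_values, start=1):
            row[f"ring_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def shape_metrics(mask: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Area (um^2) and moment eccentricity of a binary mask.

    Eccentricity is sqrt(1 - l2/l1) for eigenvalues l1 >= l2 of the mask's
    second central moment matrix: 0 for a disk, -> 1 for elongated shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask")
    area = len(ys) * pixel_size * pixel_size
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    mu20 = (dy * dy).mean()
    mu02 = (dx * dx).mean()
    mu11 = (dy * dx).mean()
    tr = mu20 + mu02
    det = mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4 - det, 0.0)
    l1 = tr / 2 + math.sqrt(disc)
    l2 = tr / 2 - math.sqrt(disc)
    ecc = 0.0 if l1 <= 0 else math.sqrt(max(1.0 - l2 / l1, 0.0))
    return float(area), float(ecc)


def paired_focus_distance(
    centers: np.ndarray, pixel_size: float
) -> tuple[list[float], list[int]]:
    """Mutual-nearest-neighbour pairing of focus centers.

    Returns Euclidean pair distances in um and the indices of unpaired
    foci. Requires >= 2 foci (otherwise both lists are empty).
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    if n < 2:
        return [], list(range(n))
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    dist, idx = tree.query(centers, k=2)
    # with coincident points the self index may come second; pick the
    # neighbour that is not i
    nn = np.where(idx[:, 0] == np.arange(n), idx[:, 1], idx[:, 0])
    nn_dist = np.where(idx[:, 0] == np.arange(n), dist[:, 1], dist[:, 0])
    distances = []
    paired = set()
    for i in range(n):
        j = int(nn[i])
        if j > i and int(nn[j]) == i:
            distances.append(float(nn_dist[i]) * pixel_size)
            paired.update((i, j))
    unpaired = [i for i in range(n) if i not in paired]
    return distances, unpaired


def nuclear_intensity(
    channel: np.ndarray,
    nuclei: np.ndarray,
    reference: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Per-nucleus total and mean intensity, normalized to a cohort median.

    `reference` is the cohort of per-nucleus mean intensities to normalize
    against (e.g. the parental cohort); by default the measured cohort
    itself. Normalized columns divide by the reference median.
    """
    img = np.asarray(channel, dtype=float)
    labels = [int(v) for v in np.unique(nuclei) if v != 0]
    rows = []
    for lab in labels:
        vals = img[nuclei == lab]
        rows.append(
            {"nucleus": lab, "total": float(vals.sum()), "mean": float(vals.mean())}
        )
    df = pd.DataFrame(rows, columns=["nucleus", "total", "mean"])
    ref = df["mean"].to_numpy() if reference is None else np.asarray(reference, float)
    if ref.size == 0:
        raise ValueError("empty reference cohort")
    ref_median = float(np.median(ref))
    if ref_median == 0:
        raise ValueError("reference cohort has zero median intensity")
    df["normalized_mean"] = df["mean"] / ref_median
    df["normalized_total"] = df["total"] / ref_median
    return df
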