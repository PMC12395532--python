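"""Segmentation and quantification of CUG-repeat nuclear foci in FISH images.

Expanded-repeat DMPK transcripts aggregate into nuclear foci visible by RNA
FISH (red channel) inside Hoechst-stained nuclei (blue channel), optionally
co-stained for the sequestered splicing factor MBNL1 (green channel).  The
pipeline is deliberately classical and parameter-transparent:

1. local mean thresholding of each channel (box mean over a (2w+1) x (2h+1)
   window plus an additive offset) — presets ``NUCLEI_THRESHOLD`` (w = h =
   250, offset = 0.06), ``FOCI_THRESHOLD`` (w = h = 4, offset = 0.02) and the
   two-operation MBNL1 union (w = 4, offset = 0.05 | w = 2, offset = 0.1);
2. morphological refinement (hole filling, opening, border-nucleus removal,
   minimum focus area);
3. watershed splitting of touching objects on the negated distance
   transform;
4. focus-to-nucleus assignment by majority pixel overlap;
5. per-focus area / mean intensity and per-nucleus focus count / percent
   nuclear area occupied by foci.

All images are 2-D arrays normalized to [0, 1]; pixel coordinates are
row-major and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening, remove_small_objects
from skimage.segmentation import relabel_sequential, watershed
from sklearn.base import BaseEstimator

__all__ = [
    "ThresholdParams",
    "NUCLEI_THRESHOLD",
    "FOCI_THRESHOLD",
    "MBNL1_THRESHOLD_1",
    "MBNL1_THRESHOLD_2",
    "local_mean_threshold",
    "refine_mask",
    "watershed_label",
    "associate_by_overlap",
    "measure",
    "foci_histogram",
    "mbnl1_union_mask",
    "mbnl1_positive_foci",
    "FociSegmenter",
    "ImageQuantification",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Half-window sizes (pixels) and additive offset of the local mean test."""

    w: int
    h: int
    offset: float

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("half-windows w, h must be >= 1")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


NUCLEI_THRESHOLD = ThresholdParams(w=250, h=250, offset=0.06)
FOCI_THRESHOLD = ThresholdParams(w=4, h=4, offset=0.02)
MBNL1_THRESHOLD_1 = ThresholdParams(w=4, h=4, offset=0.05)
MBNL1_THRESHOLD_2 = ThresholdParams(w=2, h=2, offset=0.1)


def _check_channel(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("channel must be a 2-D array")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    if channel.min() < 0 or channel.max() > 1:
        raise ValueError("channel must be normalized to [0, 1]")
    return channel


def local_mean_threshold(channel: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Foreground where value exceeds its local box mean plus the offset.

    The box is (2w+1) columns by (2h+1) rows centred on the pixel; borders
    are handled by edge replication.  A constant image therefore yields an
    empty mask for any positive offset.
    """
    channel = _check_channel(channel)
    size = (2 * params.h + 1, 2 * params.w + 1)
    if size[0] > 2 * channel.shape[0] or size[1] > 2 * channel.shape[1]:
        raise ValueError(
            f"window {size} larger than twice the image {channel.shape} in some dimension"
        )
    local_mean = ndi.uniform_filter(channel, size=size, mode="nearest")
    return channel > local_mean + params.offset


def refine_mask(
    mask: np.ndarray,
    object_class: str,
    opening_radius: int | None = None,
    min_area: int = 4,
) -> np.ndarray:
    """Morphological cleanup of a binary mask.

    Nuclei: fill holes, opening (default disc radius 5), and removal of
    connected components touching any image border (partially imaged nuclei
    cannot be scored).  Foci: opening (default disc radius 1) and a minimum
    area filter (default 4 px); foci at borders are kept — the border rule
    applies to nuclei only.
    """
    mask = np.asarray(mask, dtype=bool)
    if object_class == "nucleus":
        radius = 5 if opening_radius is None else opening_radius
        out = ndi.binary_fill_holes(mask)
        if radius > 0:
            out = opening(out, disk(radius))
        labels = cc_label(out)
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        out &= ~np.isin(labels, border[border > 0])
        return out
    if object_class == "focus":
        radius = 1 if opening_radius is None else opening_radius
        out = mask
        if radius > 0:
            out = opening(out, disk(radius))
        if min_area > 1:
            out = remove_small_objects(out, max_size=min_area - 1)
        return out
    raise ValueError(f"object_class must be 'nucleus' or 'focus', got {object_class!r}")


def watershed_label(mask: np.ndarray, min_seed_distance: int = 5) -> np.ndarray:
    """Split touching objects with a distance-transform watershed.

    Seeds are regional maxima of the Euclidean distance transform separated
    by at least ``min_seed_distance`` pixels (set it near the expected
    object radius); the watershed runs on the negated distance transform
    restricted to the mask.  Separate components that contain a single seed
    come out identical to connected-component labelling.  Labels are
    contiguous from 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_seed_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: fall back to plain components
        labels = cc_label(mask).astype(np.int32)
        return relabel_sequential(labels)[0].astype(np.int32)
    labels = watershed(-distance, markers, mask=mask)
    # components that received no seed (smaller than min_seed_distance)
    # would vanish; keep them as their own objects
    orphan = mask & (labels == 0)
    if orphan.any():
        extra = cc_label(orphan)
        extra[extra > 0] += labels.max()
        labels = labels + extra
    return relabel_sequential(labels)[0].astype(np.int32)


def associate_by_overlap(nuclei: np.ndarray, foci: np.ndarray) -> dict[int, int]:
    """Assign each focus to the nucleus covering most of its pixels.

    Returns ``{focus_label: nucleus_label}`` with 0 for foci that overlap
    no nucleus (these are excluded from per-nucleus statistics).  Ties are
    broken toward the lower nucleus label, deterministically.
    """
    nuclei = np.asarray(nuclei)
    foci = np.asarray(foci)
    if nuclei.shape != foci.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs foci {foci.shape}")
    assignments: dict[int, int] = {}
    focus_labels = np.unique(foci)
    for f in focus_labels[focus_labels > 0]:
        under = nuclei[foci == f]
        under = under[under > 0]
        if under.size == 0:
            assignments[int(f)] = 0
            continue
        labels, counts = np.unique(under, return_counts=True)
        assignments[int(f)] = int(labels[np.argmax(counts)])  # unique() sorts: tie -> lower
    return assignments


def measure(
    nuclei: np.ndarray,
    foci: np.ndarray,
    foci_channel: np.ndarray,
    assignments: dict[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nucleus and per-focus measurements.

    Returns ``(nucleus_records, focus_records)``.  Per focus: area (pixel
    count), mean foci-channel intensity over its pixels, assigned nucleus
    (0 = unassigned).  Per nucleus: area, number of assigned foci, and the
    percentage of nuclear area occupied by those foci.
    """
    foci_channel = _check_channel(foci_channel)
    if assignments is None:
        assignments = associate_by_overlap(nuclei, foci)

    focus_rows = []
    focus_labels = np.unique(foci)
    for f in focus_labels[focus_labels > 0]:
        pix = foci == f
        focus_rows.append(
            {
                "focus": int(f),
                "nucleus": assignments.get(int(f), 0),
                "area": int(pix.sum()),
                "mean_intensity": float(foci_channel[pix].mean()),
            }
        )
    focus_df = pd.DataFrame(
        focus_rows, columns=["focus", "nucleus", "area", "mean_intensity"]
    )

    nucleus_rows = []
    nucleus_labels = np.unique(nuclei)
    for nlab in nucleus_labels[nucleus_labels > 0]:
        area = int((nuclei == nlab).sum())
        assigned = focus_df[focus_df["nucleus"] == nlab] if len(focus_df) else focus_df
        foci_area = int(assigned["area"].sum()) if len(assigned) else 0
        nucleus_rows.append(
            {
                "nucleus": int(nlab),
                "area": area,
                "foci_count": int(len(assigned)),
                "foci_area": foci_area,
                "pct_area_foci": 100.0 * foci_area / area,
            }
        )
    nucleus_df = pd.DataFrame(
        nucleus_rows, columns=["nucleus", "area", "foci_count", "foci_area", "pct_area_foci"]
    )
    return nucleus_df, focus_df


def foci_histogram(counts, k_max: int = 5) -> pd.DataFrame:
    """Percentage of nuclei with 0, 1, ..., >=k_max foci; sums to 100."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no nuclei to histogram")
    bins = []
    for k in range(k_max):
        bins.append({"bin": str(k), "percent": 100.0 * np.mean(counts == k)})
    bins.append({"bin": f">={k_max}", "percent": 100.0 * np.mean(counts >= k_max)})
    return pd.DataFrame(bins)


def mbnl1_union_mask(
    channel: np.ndarray,
    params1: ThresholdParams = MBNL1_THRESHOLD_1,
    params2: ThresholdParams = MBNL1_THRESHOLD_2,
) -> np.ndarray:
    """Pixel-wise OR of two local-mean threshold operations.

    The wide/low and narrow/high parameter pairs pick up diffuse MBNL1
    accumulations and sharp puncta respectively; their union is the MBNL1
    mask used to call MBNL1-containing foci.
    """
    return local_mean_threshold(channel, params1) | local_mean_threshold(channel, params2)


def mbnl1_positive_foci(
    nuclei: np.ndarray,
    foci: np.ndarray,
    mbnl1_mask: np.ndarray,
    assignments: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-nucleus counts and areas of MBNL1-containing nuclear foci.

    A nuclear (assigned) focus is MBNL1-containing iff at least one of its
    pixels lies in the MBNL1 mask.  Statistics mirror :func:`measure` but
    run over MBNL1-positive foci only.
    """
    nuclei = np.asarray(nuclei)
    foci = np.asarray(foci)
    mbnl1_mask = np.asarray(mbnl1_mask, dtype=bool)
    if not (nuclei.shape == foci.shape == mbnl1_mask.shape):
        raise ValueError("nuclei, foci and MBNL1 mask must share one shape")
    if assignments is None:
        assignments = associate_by_overlap(nuclei, foci)

    positive: dict[int, list[int]] = {}
    focus_labels = np.unique(foci)
    for f in focus_labels[focus_labels > 0]:
        nuc = assignments.get(int(f), 0)
        if nuc == 0:
            continue
        pix = foci == f
        if mbnl1_mask[pix].any():
            positive.setdefault(nuc, []).append(int(pix.sum()))

    rows = []
    nucleus_labels = np.unique(nuclei)
    for nlab in nucleus_labels[nucleus_labels > 0]:
        areas = positive.get(int(nlab), [])
        nucleus_area = int((nuclei == nlab).sum())
        rows.append(
            {
                "nucleus": int(nlab),
                "mbnl1_foci_count": len(areas),
                "mbnl1_foci_area": int(sum(areas)),
                "pct_area_mbnl1_foci": 100.0 * sum(areas) / nucleus_area,
            }
        )
    return pd.DataFrame(
        rows, columns=["nucleus", "mbnl1_foci_count", "mbnl1_foci_area", "pct_area_mbnl1_foci"]
    )


@dataclass
class ImageQuantification:
    """Everything the pipeline extracts from one field of view."""

    nuclei_labels: np.ndarray
    foci_labels: np.ndarray
    assignments: dict[int, int]
    nucleus_records: pd.DataFrame
    focus_records: pd.DataFrame
    mbnl1_records: pd.DataFrame | None = None


class FociSegmenter(BaseEstimator):
    """Parameterised nuclei/foci segmentation pipeline for one image.

    sklearn-style: all tuning knobs are constructor parameters exposed via
    ``get_params`` / ``set_params``; :meth:`quantify` runs threshold ->
    refine -> watershed -> associate -> measure on a (nuclei, foci[, mbnl1])
    channel triple and returns an :class:`ImageQuantification`.

    Parameters mirror the documented presets: the nuclei threshold uses a
    wide window (w = h = 250, offset = 0.06) because nuclei are large
    against a dark field, the foci threshold a tight one (w = h = 4,
    offset = 0.02) to catch small bright puncta.
    """

    def __init__(
        self,
        nuc_w: int = 250,
        nuc_h: int = 250,
        nuc_offset: float = 0.06,
        foci_w: int = 4,
        foci_h: int = 4,
        foci_offset: float = 0.02,
        nuc_opening_radius: int = 5,
        foci_opening_radius: int = 1,
        foci_min_area: int = 4,
        nuc_seed_distance: int = 10,
        foci_seed_distance: int = 2,
        mbnl1_w1: int = 4,
        mbnl1_h1: int = 4,
        mbnl1_offset1: float = 0.05,
        mbnl1_w2: int = 2,
        mbnl1_h2: int = 2,
        mbnl1_offset2: float = 0.1,
    ):
        self.nuc_w = nuc_w
        self.nuc_h = nuc_h
        self.nuc_offset = nuc_offset
        self.foci_w = foci_w
        self.foci_h = foci_h
        self.foci_offset = foci_offset
        self.nuc_opening_radius = nuc_opening_radius
        self.foci_opening_radius = foci_opening_radius
        self.foci_min_area = foci_min_area
        self.nuc_seed_distance = nuc_seed_distance
        self.foci_seed_distance = foci_seed_distance
        self.mbnl1_w1 = mbnl1_w1
        self.mbnl1_h1 = mbnl1_h1
        self.mbnl1_offset1 = mbnl1_offset1
        self.mbnl1_w2 = mbnl1_w2
        self.mbnl1_h2 = mbnl1_h2
        self.mbnl1_offset2 = mbnl1_offset2

    def quantify(
        self,
        nuclei_channel: np.ndarray,
        foci_channel: np.ndarray,
        mbnl1_channel: np.ndarray | None = None,
    ) -> ImageQuantification:
        nuc_mask = local_mean_threshold(
            nuclei_channel, ThresholdParams(self.nuc_w, self.nuc_h, self.nuc_offset)
        )
        nuc_mask = refine_mask(nuc_mask, "nucleus", opening_radius=self.nuc_opening_radius)
        nuclei = watershed_label(nuc_mask, min_seed_distance=self.nuc_seed_distance)

        foci_mask = local_mean_threshold(
            foci_channel, ThresholdParams(self.foci_w, self.foci_h, self.foci_offset)
        )
        foci_mask = refine_mask(
            foci_mask,
            "focus",
            opening_radius=self.foci_opening_radius,
            min_area=self.foci_min_area,
        )
        foci = watershed_label(foci_mask, min_seed_distance=self.foci_seed_distance)

        assignments = associate_by_overlap(nuclei, foci)
        nucleus_records, focus_records = measure(nuclei, foci, foci_channel, assignments)

        mbnl1_records = None
        if mbnl1_channel is not None:
            union = mbnl1_union_mask(
                mbnl1_channel,
                ThresholdParams(self.mbnl1_w1, self.mbnl1_h1, self.mbnl1_offset1),
                ThresholdParams(self.mbnl1_w2, self.mbnl1_h2, self.mbnl1_offset2),
            )
            mbnl1_records = mbnl1_positive_foci(nuclei, foci, union, assignments)

        return ImageQuantification(
            nuclei_labels=nuclei,
            foci_labels=foci,
            assignments=assignments,
            nucleus_records=nucleus_records,
            focus_records=focus_records,
            mbnl1_records=mbnl1_records,
        )
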