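"""Object-based colocalization scoring of fluorescence puncta.

Reproduces the classic cell-scoring workflow: threshold each channel,
segment the marker channel into puncta (8-connected components), partition
the puncta into reference-positive and reference-negative groups with the
reference-channel mask, and score each group for overlap with a third
channel.  Images (not puncta) are the statistical unit: per-image fractions
are compared with a paired two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


@dataclass(frozen=True)
class Punctum:
    label: int
    pixels: frozenset[tuple[int, int]]
    centroid: tuple[float, float]

    @property
    def area(self) -> int:
        return len(self.pixels)


@dataclass
class PunctumSet:
    """Connected components of one channel of one image."""

    shape: tuple[int, int]
    puncta: list[Punctum]

    def __len__(self) -> int:
        return len(self.puncta)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (pages, y, x) stack."""
    arr = np.asarray(stack)
    return arr.max(axis=0) if arr.ndim == 3 else arr


def threshold_channel(
    image: np.ndarray, method: str = "percentile", value: float | None = None
) -> np.ndarray:
    """Binary mask from a single-channel image.

    methods: ``fixed`` (mask = image >= value), ``percentile`` (value is the
    percentile, default 99), ``otsu`` (histogram-based; rejects constant
    images).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("threshold_channel expects a single 2-D channel")
    if (img < 0).any():
        raise ValueError("negative intensities")
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        return img >= value
    if method == "percentile":
        q = 99.0 if value is None else value
        return img > np.percentile(img, q)
    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("degenerate histogram: constant image")
        return img > threshold_otsu(img)
    raise ValueError(f"unknown threshold method {method!r}")


def detect_puncta(
    mask: np.ndarray, min_area: int = 4, connectivity: int = 2
) -> PunctumSet:
    """8-connected components of a binary mask, dropping specks below
    ``min_area`` pixels."""
    lab = label(mask, connectivity=connectivity)
    puncta = []
    for region in regionprops(lab):
        if region.area < min_area:
            continue
        pixels = frozenset((int(y), int(x)) for y, x in region.coords)
        puncta.append(
            Punctum(label=region.label, pixels=pixels, centroid=tuple(region.centroid))
        )
    return PunctumSet(shape=mask.shape, puncta=puncta)


def _overlap(punctum: Punctum, mask: np.ndarray) -> int:
    return sum(1 for (y, x) in punctum.pixels if mask[y, x])


def apply_reference_mask(
    marker_puncta: PunctumSet,
    reference_mask: np.ndarray,
    min_overlap_pixels: int = 1,
    min_overlap_fraction: float | None = None,
) -> tuple[list[Punctum], list[Punctum]]:
    """Partition marker puncta into reference-positive / -negative groups.

    Default overlap rule: at least one shared pixel; optionally a fractional
    rule (overlap / punctum area >= min_overlap_fraction).
    """
    if tuple(reference_mask.shape) != tuple(marker_puncta.shape):
        raise ValueError(
            f"mask shape {reference_mask.shape} != image shape {marker_puncta.shape}"
        )
    pos, neg = [], []
    for p in marker_puncta.puncta:
        ov = _overlap(p, reference_mask)
        if min_overlap_fraction is not None:
            hit = ov / p.area >= min_overlap_fraction
        else:
            hit = ov >= min_overlap_pixels
        (pos if hit else neg).append(p)
    return pos, neg


@dataclass
class ColocalizationResult:
    """Pooled colocalization summary across images."""

    per_image: pd.DataFrame
    n_refpos_marker: int
    n_refneg_marker: int
    frac_third_pos_refpos: float  # pooled over puncta; NaN if no puncta
    frac_third_pos_refneg: float
    p_value: float  # paired two-sided t-test across images; NaN if < 2 pairs


def _group_fraction(puncta: Sequence[Punctum], third_mask: np.ndarray) -> float:
    if not puncta:
        return float("nan")
    hits = sum(1 for p in puncta if _overlap(p, third_mask) >= 1)
    return hits / len(puncta)


def score_third_channel(
    partitions: Sequence[tuple[Sequence[Punctum], Sequence[Punctum]]],
    third_masks: Sequence[np.ndarray],
) -> ColocalizationResult:
    """Score each image's reference-positive/-negative marker puncta for
    third-channel overlap and compare the two groups across images.

    ``partitions`` holds one (ref_positive, ref_negative) pair per image.
    Images in which a group is empty report a missing fraction and are
    excluded from the paired test.
    """
    rows = []
    n_pos = n_neg = hits_pos = hits_neg = 0
    for i, ((pos, neg), mask) in enumerate(zip(partitions, third_masks)):
        f_pos = _group_fraction(pos, mask)
        f_neg = _group_fraction(neg, mask)
        rows.append(
            {
                "image": i,
                "n_refpos": len(pos),
                "n_refneg": len(neg),
                "frac_refpos": f_pos,
                "frac_refneg": f_neg,
            }
        )
        n_pos += len(pos)
        n_neg += len(neg)
        hits_pos += sum(1 for p in pos if _overlap(p, mask) >= 1)
        hits_neg += sum(1 for p in neg if _overlap(p, mask) >= 1)
    per_image = pd.DataFrame(rows)
    paired = per_image.dropna(subset=["frac_refpos", "frac_refneg"])
    if len(paired) >= 2 and not np.allclose(
        paired["frac_refpos"], paired["frac_refneg"]
    ):
        p_value = float(
            stats.ttest_rel(paired["frac_refpos"], paired["frac_refneg"]).pvalue
        )
    else:
        p_value = float("nan")
    return ColocalizationResult(
        per_image=per_image,
        n_refpos_marker=n_pos,
        n_refneg_marker=n_neg,
        frac_third_pos_refpos=hits_pos / n_pos if n_pos else float("nan"),
        frac_third_pos_refneg=hits_neg / n_neg if n_neg else float("nan"),
        p_value=p_value,
    )


def score_image_set(
    images: Sequence[Mapping[str, np.ndarray]],
    threshold_method: str = "percentile",
    threshold_value: float | None = 97.0,
    min_area: int = 4,
    min_overlap_pixels: int = 1,
) -> ColocalizationResult:
    """Full scoring of a set of three-channel images.

    Each image is a mapping with ``marker``, ``reference``, ``third``
    channels (2-D, or stacks that are max-projected first).
    """
    partitions = []
    third_masks = []
    for im in images:
        marker = max_project(im["marker"])
        ref_mask = threshold_channel(
            max_project(im["reference"]), threshold_method, threshold_value
        )
        third_mask = threshold_channel(
            max_project(im["third"]), threshold_method, threshold_value
        )
        marker_mask = threshold_channel(marker, threshold_method, threshold_value)
        puncta = detect_puncta(marker_mask, min_area=min_area)
        partitions.append(
            apply_reference_mask(puncta, ref_mask, min_overlap_pixels=min_overlap_pixels)
        )
        third_masks.append(third_mask)
    return score_third_channel(partitions, third_masks)


def read_tiff_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


def write_colocalization_report(result: ColocalizationResult, path: str | Path) -> None:
    result.per_image.to_csv(path, sep="\t", index=False)
    pooled = Path(path).with_suffix(".pooled.tsv")
    pd.DataFrame(
        [
            {
                "n_refpos_marker": result.n_refpos_marker,
                "n_refneg_marker": result.n_refneg_marker,
                "frac_third_pos_refpos": result.frac_third_pos_refpos,
                "frac_third_pos_refneg": result.frac_third_pos_refneg,
                "p_value": result.p_value,
            }
        ]
    ).to_csv(pooled, sep="\t", index=False)
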