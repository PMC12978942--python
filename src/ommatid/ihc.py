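"""Automated ommatidial classification from opsin antibody stains.

Pipeline: per-channel binary masks -> connected-component segmentation of
the merged mask with area filtering -> per-channel fill fractions with an
inclusive >= 4% positivity rule -> UV-UV / B-B / UV-B class calls -> the
cross-section consistency QC (an individual is excluded when the blue-
photoreceptor proportion differs by more than 5 percentage points across
its consecutive sections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .proportions import ClassProportions, blue_photoreceptor_fraction

FILL_THRESHOLD = 0.04  # inclusive: "at least 4% of the ommatidium filled"
CONSISTENCY_TOL = 0.05  # strict: "differed by more than 5%"


@dataclass
class ChannelMasks:
    """Binary masks for the UV1, UV2, and B channels plus their union."""

    uv1_mask: np.ndarray
    uv2_mask: np.ndarray
    b_mask: np.ndarray
    merged_mask: np.ndarray
    binarization_method: str = "otsu"
    threshold_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.uv1_mask, self.uv2_mask, self.b_mask, self.merged_mask)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")

    @property
    def channel_masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.uv1_mask, self.uv2_mask, self.b_mask)


MIN_CONTRAST = 30.0  # 8-bit units; below this a channel is called stain-free


def _binarize_one(img: np.ndarray, method: str, fixed,
                  min_contrast: float = MIN_CONTRAST) -> tuple[np.ndarray, float | None]:
    img = np.asarray(img)
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed-threshold binarization needs a per-channel threshold")
        return img > fixed, float(fixed)
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    if img.max() == img.min():
        # constant channel: no stain present
        return np.zeros(img.shape, dtype=bool), None
    thr = threshold_otsu(img)
    mask = img > thr
    # Otsu always splits, even a channel holding nothing but camera noise.
    # Demand real contrast between the two classes before accepting stain.
    if mask.any() and not mask.all():
        contrast = float(img[mask].mean()) - float(img[~mask].mean())
        if contrast < min_contrast:
            return np.zeros(img.shape, dtype=bool), None
    return mask, float(thr)


def binarize_channels(section, method: str = "otsu", params: dict | None = None) -> ChannelMasks:
    """Binarize the three stain channels; the merged mask is their pixelwise OR.

    ``section`` may be an IHCSection or a (3, H, W) array.  ``params`` holds
    fixed thresholds keyed 'uv1'/'uv2'/'b' when ``method='fixed'``.
    """
    channels = getattr(section, "channels", section)
    channels = np.asarray(channels)
    if channels.ndim != 3 or channels.shape[0] != 3:
        raise ValueError(f"expected 3 channels (3, H, W), got shape {channels.shape}")
    params = params or {}
    masks, thresholds = [], {}
    for name, img in zip(("uv1", "uv2", "b"), channels):
        m, thr = _binarize_one(img, method, params.get(name))
        masks.append(m)
        thresholds[name] = thr
    return ChannelMasks(
        uv1_mask=masks[0],
        uv2_mask=masks[1],
        b_mask=masks[2],
        merged_mask=masks[0] | masks[1] | masks[2],
        binarization_method=method,
        threshold_params=thresholds,
    )


@dataclass
class SegmentedOmmatidium:
    """One connected component of the merged mask, later scored per channel."""

    label: int
    pixels: np.ndarray  # (area, 2) array of (row, col)
    area_px: int
    fill_fraction_per_channel: tuple[float, float, float] | None = None
    positive_per_channel: tuple[bool, bool, bool] | None = None
    call: str | None = None


def segment_ommatidia(
    masks, area_range: tuple[float, float] | None = None
) -> list[SegmentedOmmatidium]:
    """Connected components (8-connectivity) of the merged mask, area-filtered.

    Components with area outside ``[A_min, A_max]`` are dropped.  When
    ``area_range`` is omitted it defaults to [0.3, 3.0] times the median
    component area, a scale-free choice robust to magnification.  Surviving
    components are relabeled 1..k in raster-scan order of their
    topmost-leftmost pixel, so labels are deterministic.
    """
    merged = masks.merged_mask if isinstance(masks, ChannelMasks) else np.asarray(masks, bool)
    lab = cc_label(merged, connectivity=2)
    n = lab.max()
    if n == 0:
        return []
    areas = np.bincount(lab.ravel())[1:]
    if area_range is None:
        med = float(np.median(areas))
        area_range = (max(1.0, 0.3 * med), 3.0 * med)
    a_min, a_max = area_range
    if a_min < 1 or a_max < a_min:
        raise ValueError("area_range must satisfy 1 <= A_min <= A_max")

    segments = []
    for lbl in range(1, n + 1):
        if not a_min <= areas[lbl - 1] <= a_max:
            continue
        pixels = np.argwhere(lab == lbl)  # row-major: first entry is topmost-leftmost
        segments.append(
            SegmentedOmmatidium(label=0, pixels=pixels, area_px=int(areas[lbl - 1]))
        )
    segments.sort(key=lambda s: (int(s.pixels[0, 0]), int(s.pixels[0, 1])))
    for i, seg in enumerate(segments, start=1):
        seg.label = i
    return segments


def score_and_classify(
    segments: list[SegmentedOmmatidium],
    masks: ChannelMasks,
    fill_threshold: float = FILL_THRESHOLD,
) -> ClassProportions:
    """Score channel fill fractions, call classes, and tally proportions.

    A segment is positive for a channel when at least ``fill_threshold`` of
    its area overlaps that channel's mask (inclusive).  UV-positive means
    positive in UV1 or UV2.  Calls: UV only -> UV-UV, B only -> B-B, both ->
    UV-B, neither -> unclassified (annotated on the segment, excluded from
    the returned proportions).
    """
    counts = {"UV-UV": 0, "B-B": 0, "UV-B": 0, "unclassified": 0}
    shape = masks.merged_mask.shape
    for seg in segments:
        if seg.pixels[:, 0].max() >= shape[0] or seg.pixels[:, 1].max() >= shape[1]:
            raise ValueError(f"segment {seg.label} lies outside the mask shape {shape}")
        idx = (seg.pixels[:, 0], seg.pixels[:, 1])
        fills = tuple(float(m[idx].sum()) / seg.area_px for m in masks.channel_masks)
        pos = tuple(f >= fill_threshold for f in fills)
        uv_pos = pos[0] or pos[1]
        b_pos = pos[2]
        if uv_pos and b_pos:
            call = "UV-B"
        elif uv_pos:
            call = "UV-UV"
        elif b_pos:
            call = "B-B"
        else:
            call = "unclassified"
        seg.fill_fraction_per_channel = fills
        seg.positive_per_channel = pos
        seg.call = call
        counts[call] += 1
    return ClassProportions(n_uvuv=counts["UV-UV"], n_bb=counts["B-B"], n_uvb=counts["UV-B"])


def quantify_section(section, fill_threshold: float = FILL_THRESHOLD,
                     area_range=None, method: str = "otsu", params=None):
    """Convenience wrapper: binarize, segment, and classify one section."""
    masks = binarize_channels(section, method=method, params=params)
    segments = segment_ommatidia(masks, area_range=area_range)
    props = score_and_classify(segments, masks, fill_threshold=fill_threshold)
    return props, segments, masks


@dataclass
class SectionSeries:
    """Consistency QC over 2-4 consecutive sections of one individual.

    The blue-photoreceptor proportion (2*BB + UVB) / (2*total) is computed
    per section; the individual is excluded when the maximum pairwise
    difference exceeds the tolerance (strictly), otherwise class
    proportions are averaged unweighted across sections.
    """

    sections: list[ClassProportions]
    blue_fractions: tuple[float, ...]
    consistency_delta: float
    status: str  # "kept" | "excluded"
    mean_proportions: tuple[float, float, float]
    individual: str | None = None


def section_consistency(
    series: list[ClassProportions],
    tol: float = CONSISTENCY_TOL,
    individual: str | None = None,
) -> SectionSeries:
    """Apply the more-than-5-percentage-point blue-proportion exclusion rule."""
    if len(series) < 2:
        who = individual if individual is not None else "<unnamed>"
        raise ValueError(f"individual {who}: need at least 2 sections, got {len(series)}")
    blue = tuple(blue_photoreceptor_fraction(p) for p in series)
    delta = float(max(blue) - min(blue))
    # strict inequality with an epsilon so a delta exactly at the tolerance
    # is kept despite floating-point representation of the fractions
    status = "excluded" if delta > tol + 1e-12 else "kept"
    mean_props = tuple(
        float(np.mean([getattr(p, attr) for p in series]))
        for attr in ("p_uvuv", "p_bb", "p_uvb")
    )
    return SectionSeries(
        sections=list(series),
        blue_fractions=blue,
        consistency_delta=delta,
        status=status,
        mean_proportions=mean_props,
        individual=individual,
    )


def compare_manual(auto: ClassProportions, manual: ClassProportions) -> float:
    """Absolute difference in blue-photoreceptor proportion, automated vs manual.

    Used to validate the automated program against blind manual counts of
    the same eye; returned as a fraction (0.041 means 4.1 points).
    """
    return abs(blue_photoreceptor_fraction(auto) - blue_photoreceptor_fraction(manual))
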