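"""Red/yellow eyeshine surveys along the dorsoventral axis.

An eyeshine survey is an ordered series of photographs tiling the eye from
dorsal to ventral.  Each bright spot is one ommatidium whose color (red =
screening pigment present, yellow = absent) is called from the red/green
balance of its pixels.  Regional summaries follow the survey convention:
the dorsal value pools the two most dorsal images, the ventral value pools
the ventral half (last ceil(n/2) images).  Spot detection is automated for
synthetic imagery and convenience; manual counts can be imported from CSV
so the regional summaries and repeatability checks work either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

COLOR_TAU = 0.60  # red iff R / (R + G) >= tau

COUNT_COLUMNS = ["image_index", "n_red", "n_yellow", "is_duplicate_of"]


@dataclass
class Spot:
    centroid: tuple[float, float]
    area: int
    mean_rgb: tuple[float, float, float]
    color_call: str | None = None


def detect_spots(image: np.ndarray, min_distance: int = 5, min_area: int = 4,
                 threshold: float | None = None) -> list[Spot]:
    """Detect bright eyeshine spots in an RGB image.

    Foreground is thresholded (Otsu by default) on the per-pixel channel
    maximum; touching spots are split by watershed on the distance
    transform seeded at local maxima.  Dark/constant images yield [].
    """
    rgb = np.asarray(image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    gray = rgb.max(axis=2)
    if gray.max() == gray.min():
        return []
    thr = threshold if threshold is not None else threshold_otsu(gray)
    fg = gray > thr
    if not fg.any():
        return []
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=fg, exclude_border=False)
    if len(peaks) == 0:
        labels, _ = ndi.label(fg)
    else:
        markers = np.zeros(fg.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=fg)
    spots = []
    for lbl in range(1, labels.max() + 1):
        mask = labels == lbl
        area = int(mask.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(mask)
        spots.append(
            Spot(
                centroid=(float(ys.mean()), float(xs.mean())),
                area=area,
                mean_rgb=tuple(float(rgb[..., c][mask].mean()) for c in range(3)),
            )
        )
    return spots


def classify_spot_color(spot, tau: float = COLOR_TAU) -> str:
    """Call a spot red or yellow from its mean RGB.

    Red iff R / (R + G) >= tau.  A spot with R + G == 0 carries no pigment
    signal and is reported as 'unclassifiable'.
    """
    rgb = spot.mean_rgb if isinstance(spot, Spot) else spot
    r, g = float(rgb[0]), float(rgb[1])
    if r + g == 0:
        return "unclassifiable"
    return "red" if r / (r + g) >= tau else "yellow"


def count_image(image, tau: float = COLOR_TAU, **detect_kwargs) -> tuple[int, int]:
    """(n_red, n_yellow) for one image; unclassifiable spots are dropped."""
    calls = [classify_spot_color(s, tau=tau) for s in detect_spots(image, **detect_kwargs)]
    return calls.count("red"), calls.count("yellow")


@dataclass
class EyeshineSurvey:
    """Ordered per-image red/yellow counts for one individual.

    ``counts`` columns: image_index (0 = most dorsal), n_red, n_yellow,
    is_duplicate_of (NaN for primary images; otherwise the index of the
    image this row re-counts, used only by the repeatability check).
    """

    counts: pd.DataFrame
    individual: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"counts table missing columns {missing}")
        primary = self.counts[self.counts["is_duplicate_of"].isna()]
        if primary["image_index"].duplicated().any():
            raise ValueError("image_index must be unique among primary images")

    @classmethod
    def from_images(cls, images, individual: str = "", tau: float = COLOR_TAU,
                    **detect_kwargs) -> "EyeshineSurvey":
        """Build a survey by detecting and classifying spots in each image.

        ``images`` are RGB arrays (or objects with an ``rgb`` attribute) in
        dorsal-to-ventral order.
        """
        rows = []
        for i, img in enumerate(images):
            rgb = getattr(img, "rgb", img)
            n_red, n_yellow = count_image(rgb, tau=tau, **detect_kwargs)
            rows.append({"image_index": i, "n_red": n_red, "n_yellow": n_yellow,
                         "is_duplicate_of": np.nan})
        return cls(counts=pd.DataFrame(rows), individual=individual)

    @classmethod
    def from_counts(cls, table: pd.DataFrame, individual: str = "") -> "EyeshineSurvey":
        df = table.copy()
        if "is_duplicate_of" not in df.columns:
            df["is_duplicate_of"] = np.nan
        return cls(counts=df[COUNT_COLUMNS].copy(), individual=individual)

    @classmethod
    def from_csv(cls, path, individual: str = "") -> "EyeshineSurvey":
        return cls.from_counts(pd.read_csv(path), individual=individual)

    @property
    def primary(self) -> pd.DataFrame:
        return (
            self.counts[self.counts["is_duplicate_of"].isna()]
            .sort_values("image_index")
            .reset_index(drop=True)
        )

    @property
    def n_images(self) -> int:
        return len(self.primary)

    def yellow_fraction(self, rows: pd.DataFrame) -> float:
        y, r = int(rows["n_yellow"].sum()), int(rows["n_red"].sum())
        if y + r == 0:
            raise ValueError("no ommatidia counted in the requested region")
        return y / (y + r)

    def regional_proportions(self) -> tuple[float, float]:
        """(dorsal yellow fraction, ventral yellow fraction).

        Dorsal pools the two most dorsal images; ventral pools the last
        ceil(n/2) images of the ordered primary series.
        """
        primary = self.primary
        n = len(primary)
        if n < 4:
            raise ValueError(f"need at least 4 images for regional summaries, got {n}")
        dorsal = primary.iloc[:2]
        ventral = primary.iloc[n - math.ceil(n / 2):]
        return self.yellow_fraction(dorsal), self.yellow_fraction(ventral)

    def repeatability_check(self) -> pd.DataFrame:
        """Per-duplicate percentage differences against the primary count.

        Columns: image_index, duplicate_of, prop_diff_pct (absolute
        difference in yellow proportion, percentage points), count_diff_pct
        (absolute total-count difference as % of the primary total).
        Empty when no duplicates are flagged.
        """
        dups = self.counts[self.counts["is_duplicate_of"].notna()]
        primary = self.counts[self.counts["is_duplicate_of"].isna()].set_index("image_index")
        rows = []
        for _, d in dups.iterrows():
            ref = primary.loc[int(d["is_duplicate_of"])]
            tot_d = d["n_red"] + d["n_yellow"]
            tot_r = ref["n_red"] + ref["n_yellow"]
            prop_d = d["n_yellow"] / tot_d if tot_d else np.nan
            prop_r = ref["n_yellow"] / tot_r if tot_r else np.nan
            rows.append(
                {
                    "image_index": int(d["image_index"]),
                    "duplicate_of": int(d["is_duplicate_of"]),
                    "prop_diff_pct": abs(prop_d - prop_r) * 100.0,
                    "count_diff_pct": abs(tot_d - tot_r) / tot_r * 100.0 if tot_r else np.nan,
                }
            )
        return pd.DataFrame(rows, columns=["image_index", "duplicate_of",
                                           "prop_diff_pct", "count_diff_pct"])
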