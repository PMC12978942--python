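"""Synthetic retinal mosaics and renders of the three imaging modalities.

The generator builds a hexagonally packed lattice of ommatidia whose class
(UV-UV, B-B, UV-B) is drawn from proportions interpolated along the
dorsoventral (dv) axis.  Each blue (B) R1/R2 cell independently co-expresses
the long-wavelength (LW) opsin with probability ``p_coexpress``; an
ommatidium carries red screening pigment iff at least one of its R1/R2 cells
is LW-positive, otherwise its eyeshine is yellow.  This is exactly the
generative process under which the expected yellow-eyeshine fraction is

    Yellow = UVUV + (1 - p)^2 * BB + (1 - p) * UVB

which the co-expression model inverts.

Three renders share the lattice geometry:

* ``render_ihc_section`` — a 3-channel (UV1, UV2, B) 8-bit raster emulating
  an antibody-stained thin cross section, with exact ground truth.
* ``render_eyeshine`` — RGB photographs tiling the dv axis, red/yellow spots.
* ``render_reflectance_stack`` — a 31-plane monochromatic stack
  (500–800 nm, 10 nm steps) with a tapetal long-wavelength cutoff and
  red-pigment attenuation between 550 and 660 nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .proportions import ClassProportions

CLASS_NAMES = ("UV-UV", "B-B", "UV-B")
UV_MODES = ("UV1_only", "UV2_only", "coexpress")
WAVELENGTHS = np.arange(500.0, 801.0, 10.0)  # 31 planes

# Eyeshine spot palette (RGB).  Chosen so the red/(red+green) ratio cleanly
# separates the two pigments: red spots -> 200/240 = 0.83, yellow -> 0.52.
RED_RGB = (200, 40, 10)
YELLOW_RGB = (220, 200, 60)

MOSAIC_CSV_COLUMNS = [
    "id", "row", "col", "dv_position", "omm_class",
    "r1_opsin", "r2_opsin", "r1_lw", "r2_lw", "pigment",
]


def _validate_triple(name: str, triple: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in triple)
    if len(t) != 3:
        raise ValueError(f"{name} must be a (UVUV, BB, UVB) triple, got {triple!r}")
    if any(v < 0 or v > 1 for v in t):
        raise ValueError(f"{name} fractions must lie in [0, 1], got {t!r}")
    if abs(sum(t) - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions {t!r} must sum to 1")
    return t


@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of the generative retinal mosaic.

    ``class_proportions_dorsal`` defaults to the ventral triple (no
    gradient).  ``p_coexpress`` applies at the ventral pole; an optional
    ``p_coexpress_dorsal`` lets the dorsal eye follow its own Bernoulli
    rate, linearly interpolated along dv like the class proportions.
    ``uv_mix`` is the UV1 weight used when ``uv_mode='coexpress'``.
    """

    n_rows: int
    n_cols: int
    class_proportions_ventral: tuple[float, float, float] = (0.10, 0.50, 0.40)
    class_proportions_dorsal: tuple[float, float, float] | None = None
    p_coexpress: float = 0.5
    p_coexpress_dorsal: float | None = None
    uv_mode: str = "UV1_only"
    uv_mix: float = 1.0
    gradient: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")
        v = _validate_triple("class_proportions_ventral", self.class_proportions_ventral)
        object.__setattr__(self, "class_proportions_ventral", v)
        d = self.class_proportions_dorsal
        d = v if d is None else _validate_triple("class_proportions_dorsal", d)
        object.__setattr__(self, "class_proportions_dorsal", d)
        for name in ("p_coexpress", "uv_mix"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.p_coexpress_dorsal is not None and not 0.0 <= self.p_coexpress_dorsal <= 1.0:
            raise ValueError("p_coexpress_dorsal must lie in [0, 1]")
        if self.uv_mode not in UV_MODES:
            raise ValueError(f"uv_mode must be one of {UV_MODES}, got {self.uv_mode!r}")
        if self.gradient != "linear":
            raise ValueError("only the 'linear' dorsoventral gradient is implemented")

    @property
    def n_ommatidia(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class ImagingConfig:
    """Geometry and noise of the synthetic camera/microscope.

    ``fill_fraction_mean``/``sd`` set the stained area of each photoreceptor
    cell as a fraction of its footprint.  Noise is additive Gaussian,
    clipped to the 8-bit range; images are always 8-bit.
    """

    omm_radius_px: int = 6
    fill_fraction_mean: float = 0.6
    fill_fraction_sd: float = 0.05
    noise_sd: float = 0.0
    bit_depth: int = 8
    background_level: float = 0.0
    foreground_level: float = 200.0

    def __post_init__(self) -> None:
        if self.omm_radius_px < 2:
            raise ValueError("omm_radius_px must be >= 2")
        if not 0.0 < self.fill_fraction_mean <= 1.0:
            raise ValueError("fill_fraction_mean must lie in (0, 1]")
        if self.fill_fraction_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.bit_depth != 8:
            raise ValueError("images are 8-bit; bit_depth must be 8")

    @property
    def pitch(self) -> int:
        """Center-to-center lattice spacing; leaves >= 4 px between footprints."""
        return 2 * self.omm_radius_px + 4

    @property
    def margin(self) -> int:
        return self.omm_radius_px + 2


@dataclass
class RetinaMosaic:
    """Ground-truth lattice: one row per ommatidium.

    ``table`` columns: id, row, col, dv_position, omm_class, r1_opsin,
    r2_opsin, r1_lw, r2_lw, pigment.
    """

    spec: MosaicSpec
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def yellow_fraction(self) -> float:
        return float((self.table["pigment"] == "yellow").mean())

    def class_counts(self, rows: pd.DataFrame | None = None) -> ClassProportions:
        t = self.table if rows is None else rows
        vc = t["omm_class"].value_counts()
        return ClassProportions(
            n_uvuv=int(vc.get("UV-UV", 0)),
            n_bb=int(vc.get("B-B", 0)),
            n_uvb=int(vc.get("UV-B", 0)),
        )

    def to_csv(self, path) -> None:
        self.table[MOSAIC_CSV_COLUMNS].to_csv(path, index=False)


def generate_mosaic(spec: MosaicSpec) -> RetinaMosaic:
    """Draw a retinal mosaic from the generative model.

    Deterministic under a fixed ``spec.seed``: identical specs give
    bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ommatidia
    rows = np.repeat(np.arange(spec.n_rows), spec.n_cols)
    cols = np.tile(np.arange(spec.n_cols), spec.n_rows)
    dv = rows / (spec.n_rows - 1) if spec.n_rows > 1 else np.zeros(n)

    dorsal = np.asarray(spec.class_proportions_dorsal)
    ventral = np.asarray(spec.class_proportions_ventral)
    props = (1.0 - dv)[:, None] * dorsal + dv[:, None] * ventral

    u = rng.random(n)
    cls = (u >= props[:, 0]).astype(np.int8) + (u >= props[:, 0] + props[:, 1])
    omm_class = np.array(CLASS_NAMES, dtype=object)[cls]

    uv_label = {"UV1_only": "UV1", "UV2_only": "UV2", "coexpress": "UV1+UV2"}[spec.uv_mode]
    # R1/R2 order convention: the UV cell of a UV-B ommatidium is R1.
    r1 = np.where(cls == 1, "B", uv_label)
    r2 = np.where(cls == 0, uv_label, "B")

    p_ventral = spec.p_coexpress
    p_dorsal = spec.p_coexpress_dorsal if spec.p_coexpress_dorsal is not None else p_ventral
    p = (1.0 - dv) * p_dorsal + dv * p_ventral
    r1_lw = (r1 == "B") & (rng.random(n) < p)
    r2_lw = (r2 == "B") & (rng.random(n) < p)
    pigment = np.where(r1_lw | r2_lw, "red", "yellow")

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "row": rows,
            "col": cols,
            "dv_position": dv,
            "omm_class": omm_class,
            "r1_opsin": r1,
            "r2_opsin": r2,
            "r1_lw": r1_lw,
            "r2_lw": r2_lw,
            "pigment": pigment,
        }
    )
    return RetinaMosaic(spec=spec, table=table)


def expected_yellow_fraction(proportions, p: float) -> float:
    """Closed-form yellow fraction UVUV + (1-p)^2 BB + (1-p) UVB."""
    from .coexpr import predict_yellow

    return predict_yellow(proportions, p)


# --------------------------------------------------------------------------
# lattice geometry shared by the renders


def _lattice_layout(rows: np.ndarray, cols: np.ndarray, n_cols: int, cfg: ImagingConfig):
    """Pixel centers of a staggered (hex-like) lattice, plus canvas shape."""
    pitch, margin = cfg.pitch, cfg.margin
    row0 = rows.min()
    cy = margin + (rows - row0) * pitch
    cx = margin + (cols * pitch + (rows % 2) * (pitch // 2))
    height = int(cy.max()) + margin + 1
    width = margin + (n_cols - 1) * pitch + pitch // 2 + margin + 1
    return cy.astype(int), cx.astype(int), (height, width)


def _disk_indices(cy: int, cx: int, radius: float, shape) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[cy - r : cy + r + 1, cx - r : cx + r + 1]
    keep = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    keep &= (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    return yy[keep], xx[keep]


def _finalize(canvas: np.ndarray, cfg: ImagingConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, cfg.noise_sd, canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# IHC render

IHC_CHANNELS = ("UV1", "UV2", "B")


@dataclass
class IHCSection:
    """3-channel 8-bit raster of a stained cross section plus ground truth.

    ``channels`` has shape (3, H, W) ordered UV1, UV2, B.  ``truth`` has one
    row per rendered ommatidium with its painted pixel count per channel.
    """

    channels: np.ndarray
    truth: pd.DataFrame
    cfg: ImagingConfig
    channel_names: tuple[str, ...] = IHC_CHANNELS

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path, self.channels, photometric="minisblack",
            description=json.dumps({"channels": list(self.channel_names)}),
        )


def _cell_channel_weights(opsin: str, uv_mix: float) -> dict[str, float]:
    if opsin == "B":
        return {"B": 1.0}
    if opsin == "UV1":
        return {"UV1": 1.0}
    if opsin == "UV2":
        return {"UV2": 1.0}
    if opsin == "UV1+UV2":
        return {"UV1": uv_mix, "UV2": 1.0 - uv_mix}
    raise ValueError(f"unknown opsin {opsin!r}")


def render_ihc_section(
    mosaic: RetinaMosaic,
    cfg: ImagingConfig | None = None,
    row_band: range | None = None,
    seed: int | None = None,
) -> IHCSection:
    """Render an antibody-stain image of the ommatidia in ``row_band``.

    Each ommatidium contributes two half-disk cell footprints (R1 on the
    +x side, R2 on the -x side) shrunk radially so that the painted area is
    ``fill_fraction`` times the cell area.  Both footprints touch at the
    ommatidium center, so the merged stain of one ommatidium is a single
    connected component while neighboring ommatidia stay disjoint.
    """
    cfg = cfg or ImagingConfig()
    spec = mosaic.spec
    band = row_band if row_band is not None else range(spec.n_rows)
    sub = mosaic.table[mosaic.table["row"].isin(list(band))]
    if len(sub) == 0:
        raise ValueError("row_band selects no ommatidia")

    rng = np.random.default_rng([101, seed if seed is not None else spec.seed])
    rows = sub["row"].to_numpy()
    cols = sub["col"].to_numpy()
    cy, cx, shape = _lattice_layout(rows, cols, spec.n_cols, cfg)
    canvas = np.full((3, *shape), float(cfg.background_level))
    chan_idx = {name: i for i, name in enumerate(IHC_CHANNELS)}

    records = []
    R = cfg.omm_radius_px
    for k, (_, omm) in enumerate(sub.iterrows()):
        areas = {name: 0 for name in IHC_CHANNELS}
        fills = []
        for side, opsin in ((1, omm["r1_opsin"]), (-1, omm["r2_opsin"])):
            f = float(np.clip(rng.normal(cfg.fill_fraction_mean, cfg.fill_fraction_sd), 0.05, 1.0))
            fills.append(f)
            yy, xx = _disk_indices(cy[k], cx[k], R * np.sqrt(f), shape)
            half = (xx - cx[k]) >= 0 if side == 1 else (xx - cx[k]) < 0
            yy, xx = yy[half], xx[half]
            for chan, w in _cell_channel_weights(opsin, spec.uv_mix).items():
                if w <= 0:
                    continue
                canvas[chan_idx[chan], yy, xx] = cfg.background_level + w * (
                    cfg.foreground_level - cfg.background_level
                )
                areas[chan] += len(yy)
        records.append(
            {
                "id": omm["id"], "omm_class": omm["omm_class"],
                "center_y": cy[k], "center_x": cx[k],
                "fill_r1": fills[0], "fill_r2": fills[1],
                "area_uv1": areas["UV1"], "area_uv2": areas["UV2"], "area_b": areas["B"],
            }
        )

    return IHCSection(
        channels=_finalize(canvas, cfg, rng),
        truth=pd.DataFrame(records),
        cfg=cfg,
    )


# --------------------------------------------------------------------------
# Eyeshine render


@dataclass
class EyeshineImage:
    """One RGB eyeshine photograph covering a band of the dv axis."""

    rgb: np.ndarray  # (H, W, 3) uint8
    dv_index: int
    truth: pd.DataFrame  # id, center_y, center_x, pigment

    @property
    def n_red(self) -> int:
        return int((self.truth["pigment"] == "red").sum())

    @property
    def n_yellow(self) -> int:
        return int((self.truth["pigment"] == "yellow").sum())


def render_eyeshine(
    mosaic: RetinaMosaic,
    cfg: ImagingConfig | None = None,
    n_images: int = 10,
    resolution_gradient: float = 2.0,
    seed: int | None = None,
) -> list[EyeshineImage]:
    """Render an ordered, non-overlapping series of eyeshine photographs.

    The series tiles the dv axis dorsal to ventral.  ``resolution_gradient``
    emulates the higher spatial resolution (lower curvature) of the ventral
    eye: the number of lattice rows per image grows linearly so the most
    ventral image holds about ``resolution_gradient`` times as many
    ommatidia as the most dorsal.  Defaults to the roughly two-fold ratio
    seen in real eyeshine surveys.
    """
    cfg = cfg or ImagingConfig()
    spec = mosaic.spec
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if resolution_gradient <= 0:
        raise ValueError("resolution_gradient must be positive")
    if spec.n_rows < n_images:
        raise ValueError("need at least one lattice row per image")

    rng = np.random.default_rng([202, seed if seed is not None else spec.seed])
    weights = np.linspace(1.0, resolution_gradient, n_images)
    edges = np.round(np.cumsum(weights) / weights.sum() * spec.n_rows).astype(int)
    edges = np.concatenate([[0], edges])
    edges[-1] = spec.n_rows

    palette = {"red": RED_RGB, "yellow": YELLOW_RGB}
    images = []
    for i in range(n_images):
        band = range(edges[i], max(edges[i + 1], edges[i] + 1))
        sub = mosaic.table[mosaic.table["row"].isin(list(band))]
        cy, cx, shape = _lattice_layout(
            sub["row"].to_numpy(), sub["col"].to_numpy(), spec.n_cols, cfg
        )
        canvas = np.full((*shape, 3), float(cfg.background_level))
        records = []
        for k, (_, omm) in enumerate(sub.iterrows()):
            yy, xx = _disk_indices(cy[k], cx[k], cfg.omm_radius_px, shape)
            canvas[yy, xx, :] = palette[omm["pigment"]]
            records.append(
                {"id": omm["id"], "center_y": cy[k], "center_x": cx[k], "pigment": omm["pigment"]}
            )
        rgb = _finalize(np.moveaxis(canvas, 2, 0), cfg, rng)
        images.append(
            EyeshineImage(rgb=np.moveaxis(rgb, 0, 2), dv_index=i, truth=pd.DataFrame(records))
        )
    return images


# --------------------------------------------------------------------------
# Reflectance model and stack render


@dataclass(frozen=True)
class ReflectanceModel:
    """Noiseless eyeshine reflectance spectra in [0, 1].

    The yellow (unpigmented) spectrum is a plateau shaped by a rising edge
    near ``rise_center`` and the tapetal long-wavelength cutoff: reflectance
    falls to half maximum near ``fall_center`` and is nearly absent above
    ``tapetum_cutoff``.  Red ommatidia are the same spectrum attenuated by
    the red screening pigment, a smooth dip spanning
    ``red_attenuation_band`` (550–660 nm), so red <= yellow there and the
    yellow peak exceeds the red peak.  Moving ventrally the whole spectrum
    shifts to longer wavelengths by ``dv_redshift_per_unit * dv`` nm,
    emulating the longer optical path of ventral ommatidia.
    """

    wavelengths: tuple[float, ...] = tuple(WAVELENGTHS)
    peak_reflectance: float = 0.80
    rise_center: float = 545.0
    rise_width: float = 15.0
    fall_center: float = 700.0
    fall_width: float = 8.0
    tapetum_cutoff: float = 730.0
    red_attenuation_band: tuple[float, float] = (550.0, 660.0)
    red_attenuation: float = 0.5
    dv_redshift_per_unit: float = 10.0

    def __post_init__(self) -> None:
        if not np.array_equal(np.asarray(self.wavelengths), WAVELENGTHS):
            raise ValueError("wavelength grid must be 500..800 nm in 10 nm steps (31 planes)")
        if not 0.0 < self.peak_reflectance <= 1.0:
            raise ValueError("peak_reflectance must lie in (0, 1]")
        if not 0.0 <= self.red_attenuation <= 1.0:
            raise ValueError("red_attenuation must lie in [0, 1]")

    def spectrum(self, pigment: str, dv: float = 0.0, wavelengths=None) -> np.ndarray:
        lam = np.asarray(wavelengths if wavelengths is not None else self.wavelengths, dtype=float)
        lam = lam - self.dv_redshift_per_unit * dv
        refl = (
            self.peak_reflectance
            * expit((lam - self.rise_center) / self.rise_width)
            * expit((self.fall_center - lam) / self.fall_width)
        )
        if pigment == "red":
            lo, hi = self.red_attenuation_band
            mid, sigma = (lo + hi) / 2.0, (hi - lo) / 2.4
            refl = refl * (1.0 - self.red_attenuation * np.exp(-(((lam - mid) / sigma) ** 2)))
        elif pigment != "yellow":
            raise ValueError(f"pigment must be 'red' or 'yellow', got {pigment!r}")
        return refl


@dataclass
class ReflectanceStack:
    """31-plane monochromatic image stack with per-ommatidium ROIs.

    ``rois`` maps ommatidium id to its (rows, cols) pixel index arrays;
    ``truth`` carries pigment, dv position, eye region (dorsal/middle/
    ventral terciles), and ``truth_spectra`` the noiseless spectra.
    """

    wavelengths: np.ndarray
    planes: np.ndarray  # (31, H, W) uint8
    rois: dict
    truth: pd.DataFrame
    truth_spectra: np.ndarray

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path, self.planes, photometric="minisblack",
            description=json.dumps({"wavelengths_nm": list(map(float, self.wavelengths))}),
        )


def dv_region(dv: float) -> str:
    if dv < 1.0 / 3.0:
        return "dorsal"
    if dv < 2.0 / 3.0:
        return "middle"
    return "ventral"


def render_reflectance_stack(
    mosaic: RetinaMosaic,
    model: ReflectanceModel | None = None,
    cfg: ImagingConfig | None = None,
    seed: int | None = None,
) -> ReflectanceStack:
    """Render the monochromatic eyeshine stack for every ommatidium.

    Pixel intensity at each wavelength is background + reflectance *
    (255 - background), clipped to the 8-bit range after adding noise, so a
    reflectance of 1 saturates the camera.
    """
    model = model or ReflectanceModel()
    cfg = cfg or ImagingConfig()
    spec = mosaic.spec
    rng = np.random.default_rng([303, seed if seed is not None else spec.seed])

    cy, cx, shape = _lattice_layout(
        mosaic.table["row"].to_numpy(), mosaic.table["col"].to_numpy(), spec.n_cols, cfg
    )
    n_planes = len(WAVELENGTHS)
    canvas = np.full((n_planes, *shape), float(cfg.background_level))
    rois: dict = {}
    records = []
    spectra = np.zeros((len(mosaic.table), n_planes))
    scale = 255.0 - cfg.background_level
    for k, (_, omm) in enumerate(mosaic.table.iterrows()):
        refl = model.spectrum(omm["pigment"], dv=float(omm["dv_position"]))
        spectra[k] = refl
        yy, xx = _disk_indices(cy[k], cx[k], cfg.omm_radius_px, shape)
        canvas[:, yy, xx] = cfg.background_level + refl[:, None] * scale
        rois[int(omm["id"])] = (yy, xx)
        records.append(
            {
                "id": omm["id"], "pigment": omm["pigment"],
                "dv_position": omm["dv_position"], "region": dv_region(omm["dv_position"]),
            }
        )

    return ReflectanceStack(
        wavelengths=WAVELENGTHS.copy(),
        planes=_finalize(canvas, cfg, rng),
        rois=rois,
        truth=pd.DataFrame(records),
        truth_spectra=spectra,
    )
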