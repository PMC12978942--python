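"""Calibrated monochromatic eyeshine reflectance.

Monochromatic eyeshine images (500–800 nm, 10 nm steps) are captured with
per-wavelength shutter times chosen so every exposure delivers the same
photon flux (1.0e15 photons by default).  Per-ommatidium spectra are mean
ROI intensities per plane of the z-stack; spectra whose maximum falls below
50% or above 95% of the 8-bit dynamic range are excluded.  Group
comparisons run one test per wavelength (Welch t for red vs yellow, one-way
ANOVA for dorsal/middle/ventral) with Holm–Bonferroni control over the 31
wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mosaic import WAVELENGTHS

TARGET_FLUX = 1.0e15  # photons per exposure
FULL_SCALE = 255.0
QC_LOW = 0.50
QC_HIGH = 0.95


def shutter_time_for_flux(flux_rate, target: float = TARGET_FLUX):
    """Seconds of exposure delivering ``target`` photons at ``flux_rate`` photons/s."""
    rate = np.asarray(flux_rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("photon flux rate must be positive")
    out = target / rate
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FluxCalibration:
    """Per-wavelength photon flux rates and the matched shutter times."""

    wavelengths: np.ndarray
    flux_rates: np.ndarray  # photons / s
    target_flux: float = TARGET_FLUX

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "flux_rates", np.asarray(self.flux_rates, float))
        if self.wavelengths.shape != self.flux_rates.shape:
            raise ValueError("wavelengths and flux_rates must align")
        if np.any(self.flux_rates <= 0):
            raise ValueError("flux rates must be positive")

    @property
    def shutter_times(self) -> np.ndarray:
        return shutter_time_for_flux(self.flux_rates, self.target_flux)

    def delivered_flux(self, shutter_times=None) -> np.ndarray:
        t = self.shutter_times if shutter_times is None else np.asarray(shutter_times)
        return t * self.flux_rates

    @classmethod
    def from_csv(cls, path, target_flux: float = TARGET_FLUX) -> "FluxCalibration":
        df = pd.read_csv(path)
        return cls(df["wavelength"].to_numpy(), df["flux_rate"].to_numpy(), target_flux)


@dataclass
class OmmatidiumSpectrum:
    """Mean-ROI reflectance of one ommatidium across the 31 wavelengths."""

    ommatidium_id: int
    reflectance: np.ndarray  # 31 values, 8-bit intensity units
    color_call: str | None = None  # from the white-light reference photo
    region: str | None = None  # dorsal | middle | ventral
    qc_status: str = field(init=False)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != WAVELENGTHS.shape:
            raise ValueError("spectrum must have 31 values (500-800 nm, 10 nm steps)")
        self.qc_status = qc_status(self.reflectance)


def qc_status(reflectance, low: float = QC_LOW, high: float = QC_HIGH,
              full_scale: float = FULL_SCALE) -> str:
    """Dynamic-range QC: every spectrum gets exactly one status.

    'excluded_low' when the maximum intensity is below ``low`` of full
    scale, 'excluded_saturated' when above ``high`` of full scale,
    otherwise 'kept'.
    """
    peak = float(np.max(reflectance))
    if peak < low * full_scale:
        return "excluded_low"
    if peak > high * full_scale:
        return "excluded_saturated"
    return "kept"


def extract_spectra(stack, rois=None, color_calls=None, regions=None) -> list[OmmatidiumSpectrum]:
    """Mean ROI intensity per wavelength for each ommatidium in the stack.

    ``stack`` is a ReflectanceStack (whose rois/truth provide defaults) or
    a (31, H, W) array with ``rois`` mapping id -> (rows, cols) pixel index
    arrays.  Excluded spectra are retained but flagged by ``qc_status``.
    """
    planes = getattr(stack, "planes", stack)
    planes = np.asarray(planes)
    if planes.ndim != 3 or planes.shape[0] != len(WAVELENGTHS):
        raise ValueError(f"expected a 31-plane stack, got shape {planes.shape}")
    if rois is None:
        rois = getattr(stack, "rois", None)
        if rois is None:
            raise ValueError("no ROIs supplied")
    truth = getattr(stack, "truth", None)
    if truth is not None:
        t = truth.set_index("id")
        color_calls = color_calls or t["pigment"].to_dict()
        regions = regions or t["region"].to_dict()
    color_calls = color_calls or {}
    regions = regions or {}

    spectra = []
    for omm_id, (yy, xx) in rois.items():
        yy, xx = np.asarray(yy), np.asarray(xx)
        if yy.size == 0:
            raise ValueError(f"ommatidium {omm_id}: empty ROI")
        if yy.max() >= planes.shape[1] or xx.max() >= planes.shape[2]:
            raise ValueError(f"ommatidium {omm_id}: ROI outside stack bounds")
        spectra.append(
            OmmatidiumSpectrum(
                ommatidium_id=int(omm_id),
                reflectance=planes[:, yy, xx].mean(axis=1),
                color_call=color_calls.get(omm_id),
                region=regions.get(omm_id),
            )
        )
    return spectra


def holm_decisions(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """(reject, adjusted p) under Holm–Bonferroni at familywise level alpha."""
    reject, p_adj, _, _ = multipletests(np.asarray(pvalues, float), alpha=alpha, method="holm")
    return reject, p_adj


@dataclass
class SpectralComparison:
    """Per-wavelength group comparison with Holm–Bonferroni control."""

    wavelengths: np.ndarray
    group_names: tuple[str, ...]
    means: dict
    sems: dict
    pvalues: np.ndarray
    p_adjusted: np.ndarray
    reject_raw: np.ndarray
    reject: np.ndarray
    alpha: float
    design: str

    @property
    def significant_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.reject]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for name in self.group_names:
            df[f"mean_{name}"] = self.means[name]
            df[f"sem_{name}"] = self.sems[name]
        df["p_raw"] = self.pvalues
        df["p_holm"] = self.p_adjusted
        df["significant"] = self.reject
        return df

    def plot(self, ax=None):
        """Mean +/- SEM per group with significant wavelengths starred."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in self.group_names:
            ax.errorbar(self.wavelengths, self.means[name], yerr=self.sems[name], label=name)
        top = max(np.max(self.means[n]) for n in self.group_names)
        for wl in self.significant_wavelengths:
            ax.annotate("*", (wl, top * 1.05), ha="center")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("reflectance (8-bit intensity)")
        ax.legend()
        return ax


def _group_arrays(groups) -> dict[str, np.ndarray]:
    out = {}
    for name, g in groups.items():
        if len(g) and isinstance(g[0] if isinstance(g, list) else None, OmmatidiumSpectrum):
            g = [s.reflectance for s in g if s.qc_status == "kept"]
        arr = np.asarray(g, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(WAVELENGTHS):
            raise ValueError(f"group {name!r}: expected (n, 31) spectra")
        if arr.shape[0] < 2:
            raise ValueError(f"group {name!r}: need at least 2 kept spectra")
        out[str(name)] = arr
    return out


def compare_spectra(groups, design: str = "two_group", alpha: float = 0.05,
                    equal_var: bool = False) -> SpectralComparison:
    """Per-wavelength tests between spectral groups, Holm-corrected.

    ``design='two_group'`` runs a two-sample t-test (Welch by default) at
    each of the 31 wavelengths; ``design='three_region'`` runs a one-way
    ANOVA across the three eye regions.  ``groups`` maps group name to a
    list of kept OmmatidiumSpectrum or an (n, 31) array.
    """
    arrays = _group_arrays(groups)
    names = tuple(arrays)
    if design == "two_group":
        if len(names) != 2:
            raise ValueError("two_group design needs exactly 2 groups")
        _, pvals = stats.ttest_ind(arrays[names[0]], arrays[names[1]],
                                   axis=0, equal_var=equal_var)
    elif design == "three_region":
        if len(names) != 3:
            raise ValueError("three_region design needs exactly 3 groups")
        _, pvals = stats.f_oneway(*arrays.values(), axis=0)
    else:
        raise ValueError(f"unknown design {design!r}")
    pvals = np.asarray(pvals, dtype=float)
    reject, p_adj = holm_decisions(pvals, alpha=alpha)
    return SpectralComparison(
        wavelengths=WAVELENGTHS.copy(),
        group_names=names,
        means={n: arrays[n].mean(axis=0) for n in names},
        sems={n: arrays[n].std(axis=0, ddof=1) / np.sqrt(arrays[n].shape[0]) for n in names},
        pvalues=pvals,
        p_adjusted=p_adj,
        reject_raw=pvals < alpha,
        reject=reject,
        alpha=alpha,
        design=design,
    )


def peak_ratio(yellow_spectra: np.ndarray, red_spectra: np.ndarray) -> float:
    """(yellow peak - red peak) / red peak of the group-mean spectra.

    The red peak is the denominator; positive values mean yellow eyeshine
    peaks brighter than red.
    """
    y = np.asarray(yellow_spectra, float).mean(axis=0).max()
    r = np.asarray(red_spectra, float).mean(axis=0).max()
    return float((y - r) / r)
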