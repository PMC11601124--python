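"""Density-weighted flexural-rigidity profiles from CT cross sections.

Flexural rigidity EI is the product of Young's modulus E and the second
moment of area I about a bending axis.  For bone, mineral density is the
main determinant of E, so a calibrated CT stack lets EI be computed
pixel-by-pixel per serial cross section:

    EI(slice) = sum_i E(rho(gray_i)) * (y_i - y_axis)^2 * dA

with dA the pixel area and y_i the pixel-center height.  This module
fits the gray-value -> mineral-density calibration from hydroxyapatite
phantom tables, evaluates per-slice EI for named regions of interest,
segments the profile into the three characteristic regions of the
hummingbird upper jaw (nasal / intermediate bending zone / symphysial),
and maps the CT axial coordinate onto the kinematic landmark axis so
rigidity and landmark-variance profiles can be juxtaposed.

Units: lengths mm, density mg/cm^3, E MPa (= N/mm^2), EI N*mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .morphometry import LandmarkVarianceProfile, N_PER_LINE

logger = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """Raised when an ROI mask selects no pixels."""


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class DensityCalibration:
    """Gray-value -> mineral-density -> Young's-modulus mapping.

    The gray -> density map is an ordinary least-squares line fitted to
    phantom measurements; density -> E is a monotone power law
    E = e_coeff * rho ** e_exponent with coefficients taken from the
    experimental bone literature (configurable; identity-like defaults are
    used for synthetic phantoms where truth is known).  Negative fitted
    densities (air or soft tissue) are clamped to zero so that non-bone
    pixels contribute no stiffness.
    """

    gray_slope: float
    gray_intercept: float
    r_squared: float = 1.0
    e_coeff: float = 1.0
    e_exponent: float = 1.0
    n_points: int = 0

    def density(self, gray: np.ndarray) -> tuple[np.ndarray, int]:
        """Mineral density per pixel; returns (density, n_clamped)."""
        rho = self.gray_slope * np.asarray(gray, dtype=float) + self.gray_intercept
        neg = rho < 0.0
        n_clamped = int(neg.sum())
        if n_clamped:
            rho = np.where(neg, 0.0, rho)
        return rho, n_clamped

    def modulus(self, gray: np.ndarray) -> tuple[np.ndarray, int]:
        rho, n_clamped = self.density(gray)
        return self.e_coeff * rho ** self.e_exponent, n_clamped


def fit_gray_density(table: pd.DataFrame, e_coeff: float = 1.0,
                     e_exponent: float = 1.0) -> DensityCalibration:
    """OLS fit of mineral density on mean phantom gray value.

    ``table`` needs columns ``mean_gray`` and ``density`` (one row per
    hydroxyapatite phantom).  Requires >= 2 distinct densities and
    non-degenerate gray values.
    """
    gray = np.asarray(table["mean_gray"], dtype=float)
    dens = np.asarray(table["density"], dtype=float)
    if np.unique(dens).size < 2:
        raise ValueError("need >= 2 distinct phantom densities")
    if np.ptp(gray) == 0.0:
        raise ValueError("phantom gray values have zero variance")
    slope, intercept = np.polyfit(gray, dens, 1)
    pred = slope * gray + intercept
    ss_res = float(((dens - pred) ** 2).sum())
    ss_tot = float(((dens - dens.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DensityCalibration(
        gray_slope=float(slope), gray_intercept=float(intercept),
        r_squared=r2, e_coeff=e_coeff, e_exponent=e_exponent,
        n_points=gray.size,
    )


# ---------------------------------------------------------------------------
# per-section rigidity
# ---------------------------------------------------------------------------

def _pixel_heights(n_rows: int, pixel_size: float) -> np.ndarray:
    """Pixel-center heights (mm), row 0 at the bottom, y increasing up."""
    return (np.arange(n_rows) + 0.5) * pixel_size


def e_weighted_centroid(gray: np.ndarray, mask: np.ndarray,
                        pixel_size: float, cal: DensityCalibration) -> float:
    """Height of the E-weighted centroid of the masked section (mm)."""
    e_mod, _ = cal.modulus(gray)
    w = e_mod * (mask > 0)
    total = w.sum()
    if total <= 0.0:
        raise EmptyMaskError("no stiffness-bearing pixels in mask")
    y = _pixel_heights(gray.shape[0], pixel_size)[:, None]
    return float((w * y).sum() / total)


def section_rigidity(gray: np.ndarray, mask: np.ndarray, pixel_size: float,
                     cal: DensityCalibration,
                     y_axis: float | None = None) -> float | None:
    """Pixel-wise flexural rigidity of one cross section (N*mm^2).

    EI = sum over masked pixels of E_i * (y_i - y_axis)^2 * dA with
    dA = pixel_size^2.  The bending axis defaults to the E-weighted
    centroid height of the masked section (the mechanically consistent
    neutral axis for a heterogeneous section); a fixed height may be
    supplied instead.  An empty mask yields ``None`` (flagged), not zero.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        logger.warning("section_rigidity: empty ROI mask")
        return None
    e_mod, n_clamped = cal.modulus(np.asarray(gray, dtype=float))
    if n_clamped:
        logger.info("section_rigidity: clamped %d negative-density pixels",
                    n_clamped)
    if y_axis is None:
        y_axis = e_weighted_centroid(gray, mask, pixel_size, cal)
    y = _pixel_heights(gray.shape[0], pixel_size)[:, None]
    da = pixel_size ** 2
    return float((e_mod * (y - y_axis) ** 2 * mask).sum() * da)


def section_area_stiffness(gray: np.ndarray, mask: np.ndarray,
                           pixel_size: float, cal: DensityCalibration) -> float:
    """Axial stiffness sum(E dA) of the masked section (N)."""
    e_mod, _ = cal.modulus(np.asarray(gray, dtype=float))
    return float((e_mod * (np.asarray(mask) > 0)).sum() * pixel_size ** 2)


# ---------------------------------------------------------------------------
# stack profiles
# ---------------------------------------------------------------------------

@dataclass
class RigidityProfile:
    """Per-slice EI for named ROIs plus the combined dorsoventral profile.

    ``z_mm`` runs from the rostral bony tip toward the cranial base.
    Empty-mask slices are reported as NaN so profile length is preserved.
    """

    z_mm: np.ndarray
    ei: dict[str, np.ndarray]
    combined: np.ndarray
    combined_rois: tuple[str, ...]
    slice_spacing: float
    regions: np.ndarray | None = None    # labels 1/2/3 per slice, if segmented

    @property
    def n_slices(self) -> int:
        return self.z_mm.size

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for roi, vals in {**self.ei, "combined": self.combined}.items():
            for k in range(self.n_slices):
                rows.append(
                    {
                        "slice": k,
                        "z_mm": self.z_mm[k],
                        "roi": roi,
                        "EI_Nmm2": vals[k],
                        "region": int(self.regions[k])
                        if self.regions is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def stack_profile(stack: np.ndarray, masks: Mapping[str, np.ndarray],
                  pixel_size: float, cal: DensityCalibration,
                  slice_spacing: float | None = None,
                  axis_rule: str = "e_centroid",
                  fixed_axis: float | None = None,
                  combine: Sequence[str] | None = None,
                  smooth_window_mm: float = 0.0) -> RigidityProfile:
    """Per-slice, per-ROI flexural rigidity along an image stack.

    The combined profile sums the named ROIs (default: all) about a shared
    bending axis per slice -- the E-weighted centroid of the ROI union for
    ``axis_rule="e_centroid"``, or a fixed user height.  An optional
    moving-average smoothing window (mm) may be applied to all profiles.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_slices, H, W)")
    if axis_rule not in ("e_centroid", "fixed"):
        raise ValueError(f"unknown axis rule {axis_rule!r}")
    if axis_rule == "fixed" and fixed_axis is None:
        raise ValueError("fixed axis rule requires fixed_axis")
    n = stack.shape[0]
    roi_names = list(masks)
    for name in roi_names:
        if np.asarray(masks[name]).shape != stack.shape:
            raise ValueError(f"mask {name!r} does not match stack shape")
    combine = tuple(combine) if combine is not None else tuple(roi_names)

    spacing = slice_spacing if slice_spacing is not None else pixel_size
    ei = {name: np.full(n, np.nan) for name in roi_names}
    combined = np.full(n, np.nan)
    for k in range(n):
        union = np.zeros(stack.shape[1:], dtype=bool)
        for name in combine:
            union |= np.asarray(masks[name][k]) > 0
        if union.any():
            axis = (fixed_axis if axis_rule == "fixed"
                    else e_weighted_centroid(stack[k], union, pixel_size, cal))
            combined[k] = section_rigidity(stack[k], union, pixel_size, cal,
                                           y_axis=axis)
        for name in roi_names:
            m = np.asarray(masks[name][k]) > 0
            if not m.any():
                continue
            axis = (fixed_axis if axis_rule == "fixed"
                    else e_weighted_centroid(stack[k], union if union.any() else m,
                                             pixel_size, cal))
            val = section_rigidity(stack[k], m, pixel_size, cal, y_axis=axis)
            ei[name][k] = np.nan if val is None else val

    profile = RigidityProfile(
        z_mm=np.arange(n) * spacing,
        ei=ei,
        combined=combined,
        combined_rois=combine,
        slice_spacing=spacing,
    )
    if smooth_window_mm > 0:
        w = max(1, int(round(smooth_window_mm / spacing)))
        for name in roi_names:
            profile.ei[name] = _moving_average(profile.ei[name], w)
        profile.combined = _moving_average(profile.combined, w)
    return profile


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(w) / w
    out = np.convolve(xp, kernel, mode="valid")
    return out[: x.size]


# ---------------------------------------------------------------------------
# region segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Region labels per slice (1 nasal, 2 bending, 3 symphysial)."""

    labels: np.ndarray | None
    peak_indices: tuple[int, int] | None
    defined: bool


def segment_regions(profile: RigidityProfile,
                    smooth_frac: float = 0.02,
                    prominence_frac: float = 0.05) -> SegmentationResult:
    """Split a rigidity profile into the three characteristic regions.

    The two dominant peaks of the (smoothed) combined EI profile mark the
    rostral fusion of the premaxillae and the craniofacial hinge; the span
    between them is labeled region 2 (the low-rigidity bending zone),
    slices distal of the distal peak region 3 (symphysial) and slices
    proximal of the proximal peak region 1 (nasal).  Profiles without two
    detectable peaks are flagged undefined.
    """
    if profile.n_slices < 10:
        raise ValueError("need >= 10 slices to segment regions")
    y = profile.combined.copy()
    finite = np.isfinite(y)
    if finite.sum() < 10:
        return SegmentationResult(None, None, False)
    y[~finite] = np.nanmin(y)
    w = max(1, int(round(smooth_frac * profile.n_slices)))
    ys = _moving_average(y, w)
    span = float(ys.max() - ys.min())
    if span <= 0:
        return SegmentationResult(None, None, False)
    padded = np.concatenate([[-np.inf], ys, [-np.inf]])
    peaks, props = find_peaks(padded, prominence=prominence_frac * span)
    peaks = peaks - 1
    if peaks.size < 2:
        return SegmentationResult(None, None, False)
    order = np.argsort(props["prominences"])[::-1]
    top2 = np.sort(peaks[order[:2]])
    i_distal, i_proximal = int(top2[0]), int(top2[1])
    labels = np.empty(profile.n_slices, dtype=int)
    labels[: i_distal + 1] = 3
    labels[i_distal + 1: i_proximal] = 2
    labels[i_proximal:] = 1
    profile.regions = labels
    return SegmentationResult(labels, (i_distal, i_proximal), True)


def region_means(profile: RigidityProfile,
                 seg: SegmentationResult) -> dict[int, float]:
    """Mean combined EI per region label."""
    if not seg.defined:
        raise ValueError("regions undefined")
    return {
        r: float(np.nanmean(profile.combined[seg.labels == r]))
        for r in (1, 2, 3)
    }


# ---------------------------------------------------------------------------
# axis alignment with the kinematic landmark axis
# ---------------------------------------------------------------------------

@dataclass
class AxisAlignment:
    """Affine map from CT axial position to the landmark axis.

    The landmark axis measures position (mm) from the keratinous rostral
    culmen tip; the CT axis starts at the rostral *bony* tip, offset by
    ``keratin_tip_offset`` (the rhamphotheca-only tip).  The CT specimen
    is scaled so its bony span matches
    ``total_culmen_length - keratin_tip_offset``.
    """

    keratin_tip_offset: float
    exposed_culmen_length: float
    total_culmen_length: float
    ct_bony_length: float | None = None

    def __post_init__(self) -> None:
        if not (self.total_culmen_length > self.exposed_culmen_length > 0):
            raise ValueError("require total > exposed culmen length > 0")
        if self.keratin_tip_offset < 0:
            raise ValueError("keratin tip offset must be >= 0")
        if self.keratin_tip_offset >= self.total_culmen_length:
            raise ValueError("keratin offset must be < total culmen length")

    @property
    def scale(self) -> float:
        target = self.total_culmen_length - self.keratin_tip_offset
        src = self.ct_bony_length if self.ct_bony_length else target
        return target / src

    def position_from_tip(self, z_ct: np.ndarray) -> np.ndarray:
        """Landmark-axis position (mm from keratinous tip) of CT z (mm)."""
        return self.keratin_tip_offset + self.scale * np.asarray(z_ct, float)

    def landmark_index(self, z_ct: np.ndarray) -> np.ndarray:
        """Fractional landmark index (1..21 spans the exposed culmen)."""
        pos = self.position_from_tip(z_ct)
        return 1.0 + (N_PER_LINE - 1) * pos / self.exposed_culmen_length

    def fraction_of_total(self, z_ct: np.ndarray) -> np.ndarray:
        return self.position_from_tip(z_ct) / self.total_culmen_length


def align_axes(profile: RigidityProfile, alignment: AxisAlignment,
               variance: LandmarkVarianceProfile | None = None,
               line: str = "culmen") -> pd.DataFrame:
    """Merged table juxtaposing EI(z) with the landmark-variance profile.

    Columns: ``z_mm`` (CT), ``position_mm`` (from keratinous tip),
    ``landmark_index`` (fractional, 1..21 over the exposed culmen),
    ``EI_Nmm2`` (combined profile) and ``S2`` (variance interpolated at
    the fractional landmark index; NaN beyond the traced culmen).
    """
    pos = alignment.position_from_tip(profile.z_mm)
    idx = alignment.landmark_index(profile.z_mm)
    out = pd.DataFrame(
        {
            "z_mm": profile.z_mm,
            "position_mm": pos,
            "landmark_index": idx,
            "EI_Nmm2": profile.combined,
        }
    )
    if variance is not None:
        grid = np.arange(1, N_PER_LINE + 1, dtype=float)
        s2_line = variance.mean_s2[
            {"culmen": slice(0, 21), "tomium": slice(21, 42),
             "ventrum": slice(42, 63)}[line]
        ]
        s2 = np.interp(idx, grid, s2_line, left=np.nan, right=np.nan)
        out["S2"] = s2
    return out
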