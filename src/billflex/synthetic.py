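"""Synthetic lick-cycle landmark sequences and CT-like beam phantoms.

These generators stand in for the study's high-speed videos and micro-CT
scans: they produce (a) semi-landmark frame sequences with *known* bending
zones (hinge locations, deflection amplitudes, tracking noise) and (b)
voxelized beam phantoms (annulus, rectangle, arched shell) with known
density maps and therefore known flexural-rigidity profiles.  Every
downstream stage of the package can thus be tested against ground truth.

Coordinates follow the lateral-view convention of :mod:`.morphometry`:
x runs rostral tip -> base, y ventral -> dorsal, all lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .morphometry import (
    FrameConfiguration,
    N_PER_LINE,
    resample_equidistant,
)

N_FRAMES_PER_CYCLE = 11


class InvalidScenarioError(ValueError):
    """Raised for physically inadmissible bending scenarios."""


# ---------------------------------------------------------------------------
# bill template
# ---------------------------------------------------------------------------

@dataclass
class BillTemplate:
    """Three dense profile polylines of a resting bill, traced tip -> base.

    The culmen (dorsal ridge) lies dorsal to the tomium (cutting edge of
    the upper bill) at every arc-length fraction; the ventrum is the lower
    margin of the mandible.  ``total_culmen_length`` runs from the
    keratinous rostral tip to the nasofrontal hinge; ``keratin_tip_length``
    is the rhamphotheca-only portion beyond the bony tip.
    """

    culmen_curve: np.ndarray
    tomium_curve: np.ndarray
    ventrum_curve: np.ndarray
    total_culmen_length: float
    keratin_tip_length: float

    def __post_init__(self) -> None:
        for name in ("culmen_curve", "tomium_curve", "ventrum_curve"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.total_culmen_length > self.keratin_tip_length > 0):
            raise ValueError("require total_culmen_length > keratin_tip_length > 0")

    @property
    def exposed_culmen_length(self) -> float:
        """Arc length of the traced culmen (tip to feather margin)."""
        return float(
            np.linalg.norm(np.diff(self.culmen_curve, axis=0), axis=1).sum()
        )

    def resampled_frame(self, frame_index: int = 0, cycle_id: int = 0,
                        subject_id: str = "template") -> FrameConfiguration:
        """Resting 63-landmark configuration from the template curves."""
        lm = np.concatenate(
            [
                resample_equidistant(self.culmen_curve, N_PER_LINE),
                resample_equidistant(self.tomium_curve, N_PER_LINE),
                resample_equidistant(self.ventrum_curve, N_PER_LINE),
            ]
        )
        return FrameConfiguration(lm, frame_index, cycle_id, subject_id)


def default_template(exposed_culmen_length: float = 18.0,
                     total_culmen_length: float = 20.0,
                     keratin_tip_length: float = 1.2,
                     n_dense: int = 361) -> BillTemplate:
    """A realistic straight-billed hummingbird template (~mm scale).

    The upper bill tapers from ~1.5 mm depth at the base to ~0.12 mm near
    the tip, with a gentle dorsal rise of the culmen toward the base; the
    mandible adds a comparable ventral depth.  Proportions are typical of
    a straight-billed hummingbird.
    """
    L = float(exposed_culmen_length)
    x = np.linspace(0.0, L, n_dense)
    t = x / L
    y_mid = 0.5 * t ** 2                       # slight decurvature (tip low)
    d_upper = 0.12 + 1.4 * t ** 0.8            # upper-bill depth
    d_lower = 0.10 + 1.2 * t                   # mandible depth
    culmen = np.column_stack([x, y_mid])
    tomium = np.column_stack([x, y_mid - d_upper])
    ventrum = np.column_stack([x, y_mid - d_upper - d_lower])
    return BillTemplate(
        culmen_curve=culmen,
        tomium_curve=tomium,
        ventrum_curve=ventrum,
        total_culmen_length=total_culmen_length,
        keratin_tip_length=keratin_tip_length,
    )


# ---------------------------------------------------------------------------
# bending scenarios
# ---------------------------------------------------------------------------

@dataclass
class BendingScenario:
    """Commanded bill deformation over one lick cycle.

    ``hinge_positions`` are arc-length fractions in (0, 1) measured from
    the bill *base* toward the tip along the culmen (0.65 places the hinge
    65% of the way out, leaving the rostral 35% to bend -- distal
    rhynchokinesis); ``tip_deflections_mm`` gives the commanded tip
    displacement per hinge at full amplitude.  The
    ``phase_profile`` scales the deflection per frame (default: smooth
    open-close sin^2 bump over the 11 frames, zero at frames 0 and 10).
    ``mode`` selects how the bend is realized:

    * ``"distal_rotation"`` -- rigid rotation of the curve segment distal
      to each hinge about the hinge point (unambiguous hinge ground truth);
    * ``"local_flex"`` -- a localized dorsoventral displacement bump of
      Gaussian width ``flex_width_frac`` centered on the hinge, emulating
      arch-flattening within a bending zone (variance peaks at the zone).

    Tracking noise is isotropic Gaussian per landmark (sd in mm).  The
    mandible may optionally translate ventrally by ``mandible_motion`` mm
    at full amplitude (expected ~0 in hummingbirds while drinking).
    """

    hinge_positions: tuple[float, ...] = (0.65,)
    tip_deflections_mm: tuple[float, ...] = (0.5,)
    phase_profile: np.ndarray | None = None
    mode: str = "distal_rotation"
    bend_lines: tuple[str, ...] = ("culmen", "tomium")
    flex_width_frac: float = 0.08
    mandible_motion: float = 0.0
    tracking_noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        hp = tuple(self.hinge_positions)
        if any(not (0.0 < h < 1.0) for h in hp):
            raise InvalidScenarioError("hinge positions must lie in (0, 1)")
        if any(hp[i] >= hp[i + 1] for i in range(len(hp) - 1)):
            raise InvalidScenarioError("hinge positions must be strictly increasing")
        if len(self.tip_deflections_mm) != len(hp):
            raise InvalidScenarioError("one tip deflection per hinge required")
        vals = list(self.tip_deflections_mm) + [self.mandible_motion,
                                                self.tracking_noise_sd]
        if not np.all(np.isfinite(vals)):
            raise InvalidScenarioError("amplitudes must be finite")
        if self.mode not in ("distal_rotation", "local_flex"):
            raise InvalidScenarioError(f"unknown bending mode {self.mode!r}")
        if not self.bend_lines or not set(self.bend_lines) <= {"culmen", "tomium"}:
            raise InvalidScenarioError("bend_lines must be a nonempty subset "
                                       "of {'culmen', 'tomium'}")

    def phases(self) -> np.ndarray:
        if self.phase_profile is not None:
            p = np.asarray(self.phase_profile, dtype=float)
            if p.shape != (N_FRAMES_PER_CYCLE,):
                raise InvalidScenarioError("phase profile must have 11 entries")
            return p
        f = np.arange(N_FRAMES_PER_CYCLE)
        return np.sin(np.pi * f / (N_FRAMES_PER_CYCLE - 1)) ** 2


def _arc_fractions(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum / cum[-1]


def _point_at_fraction(pts: np.ndarray, frac: np.ndarray, s: float) -> np.ndarray:
    return np.array(
        [np.interp(s, frac, pts[:, 0]), np.interp(s, frac, pts[:, 1])]
    )


def rotate_distal(pts: np.ndarray, tip_fraction: float,
                  angle: float) -> np.ndarray:
    """Rigidly rotate the portion of a tip->base curve distal to a hinge.

    ``tip_fraction`` is the hinge's arc-length fraction measured from the
    tip end of the polyline; points with smaller fractions (closer to the
    tip) rotate about the hinge point, ``angle`` > 0 deflecting the tip
    dorsally (+y).  The hinge point is inserted as an exact vertex before
    rotating so that arc length -- and therefore the position of every
    proximal semi-landmark after equidistant resampling -- is preserved
    exactly.
    """
    frac = _arc_fractions(pts)
    hinge = _point_at_fraction(pts, frac, tip_fraction)
    insert_at = int(np.searchsorted(frac, tip_fraction))
    out = np.insert(pts, insert_at, hinge, axis=0)
    frac = np.insert(frac, insert_at, tip_fraction)
    mask = frac < tip_fraction
    # tip lies at negative x relative to the hinge, so a clockwise matrix
    # rotation (angle -> -angle) lifts the tip dorsally for angle > 0
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, s], [-s, c]])
    out[mask] = (out[mask] - hinge) @ rot.T + hinge
    return out


def _deform_curves(template: BillTemplate, scenario: BendingScenario,
                   amplitude: float) -> dict[str, np.ndarray]:
    curves = {
        "culmen": template.culmen_curve.copy(),
        "tomium": template.tomium_curve.copy(),
        "ventrum": template.ventrum_curve.copy(),
    }
    cul_frac = _arc_fractions(template.culmen_curve)
    tip = template.culmen_curve[0]
    for s_h, defl in zip(scenario.hinge_positions, scenario.tip_deflections_mm):
        s_tip = 1.0 - s_h        # hinge fraction measured from the tip
        if scenario.mode == "distal_rotation":
            hinge_pt = _point_at_fraction(template.culmen_curve, cul_frac, s_tip)
            lever = float(np.linalg.norm(tip - hinge_pt))
            angle = amplitude * defl / lever if lever > 0 else 0.0
            for name in scenario.bend_lines:
                curves[name] = rotate_distal(curves[name], s_tip, angle)
        else:  # local_flex: dorsoventral bump centered on the hinge
            w = scenario.flex_width_frac
            for name in scenario.bend_lines:
                frac = _arc_fractions(curves[name])
                bump = np.exp(-0.5 * ((frac - s_tip) / w) ** 2)
                curves[name][:, 1] += amplitude * defl * bump
    if scenario.mandible_motion != 0.0:
        curves["ventrum"][:, 1] -= amplitude * scenario.mandible_motion
    return curves


def generate_lick_dataset(template: BillTemplate, scenario: BendingScenario,
                          n_cycles: int, subject_id: str = "synthetic",
                          ) -> list[FrameConfiguration]:
    """Generate ``n_cycles`` lick cycles of 11 frames each.

    Per frame, the template curves are deformed according to the scenario's
    phase profile, resampled to 21 equidistant semi-landmarks per line and
    perturbed with i.i.d. Gaussian tracking noise.  Deterministic given
    ``scenario.seed``.
    """
    scenario.validate()
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    phases = scenario.phases()
    frames: list[FrameConfiguration] = []
    for cycle in range(n_cycles):
        for f in range(N_FRAMES_PER_CYCLE):
            curves = _deform_curves(template, scenario, phases[f])
            lm = np.concatenate(
                [
                    resample_equidistant(curves["culmen"], N_PER_LINE),
                    resample_equidistant(curves["tomium"], N_PER_LINE),
                    resample_equidistant(curves["ventrum"], N_PER_LINE),
                ]
            )
            if scenario.tracking_noise_sd > 0:
                lm = lm + rng.normal(0.0, scenario.tracking_noise_sd,
                                     size=lm.shape)
            frames.append(FrameConfiguration(lm, f, cycle, subject_id))
    return frames


# ---------------------------------------------------------------------------
# beam phantoms
# ---------------------------------------------------------------------------

@dataclass
class BeamPhantomSpec:
    """Voxelized beam phantom with known density, hence known EI.

    ``section_params`` holds shape dimensions in mm; each value may be a
    scalar, an array of length ``n_slices`` or a callable of the axial
    fraction z/L in [0, 1]:

    * ``annulus``: outer_radius, inner_radius
    * ``rectangle``: width, height
    * ``arched_shell``: outer_radius, inner_radius (upper half-annulus)

    ``density`` is the mineral density in mg/cm^3 (uniform scalar or a
    callable rho(x, y, z_frac)).  Gray values encode density through the
    invertible linear map density = gray_slope * gray + gray_intercept.
    """

    section_shape: str
    section_params: dict
    density: float | Callable = 1000.0
    n_slices: int = 40
    pixel_size: float = 0.02
    slice_spacing: float | None = None
    image_shape: tuple[int, int] | None = None
    gray_slope: float = 0.05
    gray_intercept: float = 0.0
    supersample: int = 4   # subpixel sampling for partial-volume rendering
    seed: int = 0

    def validate(self) -> None:
        if self.section_shape not in ("annulus", "rectangle", "arched_shell"):
            raise ValueError(f"unknown section shape {self.section_shape!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.gray_slope == 0:
            raise ValueError("gray map must be invertible (nonzero slope)")


@dataclass
class BeamStack:
    """Generated phantom: gray stack, ROI masks and analytic EI profile."""

    gray: np.ndarray                     # (n, H, W) uint16
    masks: dict[str, np.ndarray]         # name -> (n, H, W) uint8 in {0, 1}
    density: np.ndarray                  # (n, H, W) float, mg/cm^3
    analytic_ei: np.ndarray              # (n,) N*mm^2 about centroid axis
    z_mm: np.ndarray                     # (n,)
    pixel_size: float
    slice_spacing: float
    gray_slope: float
    gray_intercept: float


def _param_at(value, z_frac: float):
    if callable(value):
        return float(value(z_frac))
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    return float(arr[int(round(z_frac * (arr.size - 1)))])


def _section_mask(shape: str, params: dict, z_frac: float,
                  xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    if shape == "annulus":
        ro = _param_at(params["outer_radius"], z_frac)
        ri = _param_at(params["inner_radius"], z_frac)
        r = np.hypot(xx, yy)
        return (r <= ro) & (r >= ri)
    if shape == "rectangle":
        b = _param_at(params["width"], z_frac)
        h = _param_at(params["height"], z_frac)
        return (np.abs(xx) <= b / 2) & (np.abs(yy) <= h / 2)
    # arched shell: upper half-annulus
    ro = _param_at(params["outer_radius"], z_frac)
    ri = _param_at(params["inner_radius"], z_frac)
    r = np.hypot(xx, yy)
    return (r <= ro) & (r >= ri) & (yy >= 0)


def _analytic_i(shape: str, params: dict, z_frac: float) -> float:
    """Second moment of area about the section's own centroid axis."""
    if shape == "annulus":
        ro = _param_at(params["outer_radius"], z_frac)
        ri = _param_at(params["inner_radius"], z_frac)
        return math.pi / 4.0 * (ro ** 4 - ri ** 4)
    if shape == "rectangle":
        b = _param_at(params["width"], z_frac)
        h = _param_at(params["height"], z_frac)
        return b * h ** 3 / 12.0
    ro = _param_at(params["outer_radius"], z_frac)
    ri = _param_at(params["inner_radius"], z_frac)
    area = math.pi / 2.0 * (ro ** 2 - ri ** 2)
    ybar = (4.0 / (3.0 * math.pi)) * (ro ** 3 - ri ** 3) / (ro ** 2 - ri ** 2)
    i_base = math.pi / 8.0 * (ro ** 4 - ri ** 4)
    return i_base - area * ybar ** 2


def arch_i_quadrature(ro: float, ri: float, n: int = 2000) -> float:
    """Second moment of an upper half-annulus by dense grid quadrature.

    Independent numerical oracle for the arched-shell closed form:
    integrates y^2 dA over the analytic region on an n x n grid and refers
    the result to the area centroid.
    """
    x = np.linspace(-ro, ro, n)
    y = np.linspace(0.0, ro, n)
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx, yy)
    inside = (r <= ro) & (r >= ri)
    area = inside.sum() * dx * dy
    ybar = (yy * inside).sum() * dx * dy / area
    return float(((yy - ybar) ** 2 * inside).sum() * dx * dy)


def generate_beam_stack(spec: BeamPhantomSpec,
                        elastic_map: Callable[[np.ndarray], np.ndarray] | None = None,
                        ) -> BeamStack:
    """Render a phantom image stack with masks and its analytic EI profile.

    ``elastic_map`` converts mineral density (mg/cm^3) to Young's modulus
    (MPa); identity by default so that E == rho numerically, which keeps
    ground truth trivial for uniform-density phantoms.  The analytic EI is
    E * I(z) about each section's centroid axis (uniform density assumed;
    for heterogeneous density rules the analytic profile is not emitted).
    """
    spec.validate()
    if elastic_map is None:
        elastic_map = lambda rho: rho
    # field of view: generous margin around the largest section
    extents = []
    for zf in np.linspace(0.0, 1.0, spec.n_slices):
        p = spec.section_params
        if spec.section_shape == "rectangle":
            extents.append(max(_param_at(p["width"], zf),
                               _param_at(p["height"], zf)) / 2)
        else:
            extents.append(_param_at(p["outer_radius"], zf))
    half = max(extents) * 1.15
    if spec.image_shape is None:
        npix = int(np.ceil(2 * half / spec.pixel_size))
        npix += npix % 2   # even count: pixel centers straddle the midline,
        shape = (npix, npix)  # so section edges never coincide with centers
    else:
        shape = spec.image_shape
    h_pix, w_pix = shape
    yv = (np.arange(h_pix) + 0.5) * spec.pixel_size - h_pix * spec.pixel_size / 2
    xv = (np.arange(w_pix) + 0.5) * spec.pixel_size - w_pix * spec.pixel_size / 2
    xx, yy = np.meshgrid(xv, yv)

    spacing = spec.slice_spacing if spec.slice_spacing is not None else spec.pixel_size
    n = spec.n_slices
    gray = np.zeros((n, h_pix, w_pix), dtype=np.uint16)
    density = np.zeros((n, h_pix, w_pix), dtype=float)
    mask = np.zeros((n, h_pix, w_pix), dtype=np.uint8)
    ei = np.zeros(n)
    z_fracs = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    uniform = not callable(spec.density)
    # partial-volume rendering: each pixel's density is the area-weighted
    # mean over subpixel samples, as in a real CT reconstruction; this
    # also gives the pixel-sum EI smooth second-order convergence
    nss = max(1, int(spec.supersample))
    offsets = (np.arange(nss) + 0.5) / nss - 0.5
    for k, zf in enumerate(z_fracs):
        rho = np.zeros_like(xx)
        cover = np.zeros_like(xx)
        for ox in offsets:
            for oy in offsets:
                xs = xx + ox * spec.pixel_size
                ys = yy + oy * spec.pixel_size
                ms = _section_mask(spec.section_shape, spec.section_params,
                                   zf, xs, ys)
                cover += ms
                if callable(spec.density):
                    rho += np.where(ms, spec.density(xs, ys, zf), 0.0)
                else:
                    rho += np.where(ms, float(spec.density), 0.0)
        rho /= nss * nss
        cover /= nss * nss
        m = cover > 0.0
        g = (rho - spec.gray_intercept) / spec.gray_slope
        gray[k] = np.clip(np.round(g), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        density[k] = rho
        mask[k] = m.astype(np.uint8)
        if uniform:
            e_mod = float(elastic_map(np.asarray(float(spec.density))))
            ei[k] = e_mod * _analytic_i(spec.section_shape,
                                        spec.section_params, zf)
        else:
            ei[k] = np.nan
    return BeamStack(
        gray=gray,
        masks={"section": mask},
        density=density,
        analytic_ei=ei,
        z_mm=np.arange(n) * spacing,
        pixel_size=spec.pixel_size,
        slice_spacing=spacing,
        gray_slope=spec.gray_slope,
        gray_intercept=spec.gray_intercept,
    )


def waisted_annulus_spec(length_mm: float = 18.8, waist_fraction: float = 0.5,
                         outer_radius: float = 0.8, waist_depth: float = 0.45,
                         waist_width_frac: float = 0.12,
                         wall_fraction: float = 0.55,
                         n_slices: int = 60, pixel_size: float = 0.02,
                         ) -> BeamPhantomSpec:
    """Annular beam with a smooth waist (reduced EI) at ``waist_fraction``.

    Emulates a bill whose bending zone has depressed flexural rigidity:
    the outer radius dips by ``waist_depth`` (relative) in a Gaussian
    trough centered at the waist, with the wall thickness scaled along.
    """
    def ro(zf: float) -> float:
        dip = waist_depth * math.exp(
            -0.5 * ((zf - waist_fraction) / waist_width_frac) ** 2
        )
        return outer_radius * (1.0 - dip)

    def ri(zf: float) -> float:
        return ro(zf) * wall_fraction

    return BeamPhantomSpec(
        section_shape="annulus",
        section_params={"outer_radius": ro, "inner_radius": ri},
        n_slices=n_slices,
        pixel_size=pixel_size,
        slice_spacing=length_mm / max(n_slices - 1, 1),
    )


# ---------------------------------------------------------------------------
# phantom calibration tables
# ---------------------------------------------------------------------------

def generate_phantom_calibration(densities, gray_slope: float = 0.05,
                                 gray_intercept: float = 0.0,
                                 noise_sd: float = 0.0,
                                 seed: int = 0) -> pd.DataFrame:
    """Table of (mean gray value, known mineral density) phantom pairs.

    Gray values follow the invertible linear map
    density = gray_slope * gray + gray_intercept, with Gaussian noise of
    ``noise_sd`` (gray units) added to the measured means.  Deterministic
    given ``seed``.
    """
    dens = np.asarray(densities, dtype=float)
    if np.unique(dens).size < 2:
        raise ValueError("need at least 2 distinct phantom densities")
    rng = np.random.default_rng(seed)
    gray = (dens - gray_intercept) / gray_slope
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    return pd.DataFrame({"mean_gray": gray, "density": dens})
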