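"""Semi-landmark morphometrics for lick-cycle bill kinematics.

Each video frame of a feeding hummingbird is digitized as three profile
lines (dorsal culmen, maxillary tomium, mandibular ventrum), resampled to
21 equidistant semi-landmarks per line and concatenated into a single
63-landmark configuration.  This module provides:

* arc-length resampling of traced profile lines,
* selection of equally spaced frames from a lick cycle,
* generalized Procrustes alignment (GPA) of all frames of a subject,
* tangent sliding of semi-landmarks (Procrustes-distance criterion),
* per-landmark variance profiles (S^2) with confidence intervals,
* a Procrustes "leakage" experiment quantifying how much variance the
  superimposition spreads from perturbed onto unperturbed landmarks,
* PCA of aligned shapes (shape-space trajectories of lick cycles).

Coordinate convention: 2D lateral view, x increases from rostral bill tip
toward the base, y increases ventral -> dorsal; lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

N_LINES = 3
N_PER_LINE = 21
N_LANDMARKS = N_LINES * N_PER_LINE
LINE_NAMES = ("culmen", "tomium", "ventrum")
LINE_SLICES = {
    "culmen": slice(0, 21),
    "tomium": slice(21, 42),
    "ventrum": slice(42, 63),
}


class DegenerateTraceError(ValueError):
    """Raised when a profile trace has zero arc length."""


class DegenerateShapeError(ValueError):
    """Raised when a configuration has zero centroid size."""


@dataclass
class FrameConfiguration:
    """One frame's 63 semi-landmarks with lick-cycle metadata.

    ``landmarks`` is a (63, 2) float array: three 21-point lines
    concatenated in the order culmen, tomium, ventrum.
    """

    landmarks: np.ndarray
    frame_index: int
    cycle_id: int | str
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected ({N_LANDMARKS}, 2) landmarks, got {self.landmarks.shape}"
            )
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError("landmarks must be finite")

    def line(self, name: str) -> np.ndarray:
        return self.landmarks[LINE_SLICES[name]]


@dataclass
class ProcrustesResult:
    """GPA output: consensus, aligned coordinates, centroid sizes."""

    consensus: np.ndarray          # (k, 2), unit centroid size
    aligned: np.ndarray            # (m, k, 2)
    centroid_sizes: np.ndarray     # (m,)
    iterations: int
    converged: bool

    @property
    def n_configs(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates as (m, 2k) row vectors."""
        return self.aligned.reshape(self.n_configs, -1)


@dataclass
class LandmarkVarianceProfile:
    """Per-landmark total GPA variance S^2, averaged over groups.

    S^2 at a landmark is var(x) + var(y) of its aligned position over the
    frames of one group (a lick cycle, or one frame across replicate
    trackings), with denominator n-1.  ``mean_s2`` and the t-based 95% CI
    summarize S^2 across groups; CIs are ``None`` for a single group.
    """

    per_group_s2: np.ndarray           # (n_groups, k)
    mean_s2: np.ndarray                # (k,)
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    group_ids: tuple
    confidence: float = 0.95

    @property
    def n_groups(self) -> int:
        return self.per_group_s2.shape[0]

    def line_mean(self, name: str) -> np.ndarray:
        return self.mean_s2[LINE_SLICES[name]]


@dataclass
class ShapeTrajectory:
    """PCA of aligned shapes: per-frame scores along shape axes."""

    scores: np.ndarray            # (m, n_axes)
    eigenvalues: np.ndarray       # (n_axes,)
    percent_variance: np.ndarray  # (n_axes,) sums to 100
    loadings: np.ndarray          # (n_axes, 2k) orthonormal rows
    center: np.ndarray            # (2k,) mean aligned shape


# ---------------------------------------------------------------------------
# resampling and frame selection
# ---------------------------------------------------------------------------

def resample_equidistant(points: np.ndarray, n_points: int = N_PER_LINE) -> np.ndarray:
    """Resample a traced polyline to ``n_points`` arc-length-equidistant points.

    Points are placed at arc-length fractions k/(n_points-1) along the
    piecewise-linear trace; the trace endpoints are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("trace must be an (m >= 2, 2) array")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise DegenerateTraceError("trace has zero arc length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, total, n_points)
    out = np.column_stack(
        [np.interp(target, cum, pts[:, 0]), np.interp(target, cum, pts[:, 1])]
    )
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def extract_frames(n_frames: int, n_out: int = 11) -> np.ndarray:
    """Indices of ``n_out`` equally spaced frames including both endpoints.

    Index k maps to round(k * (n_frames-1) / (n_out-1)) with round-half-up,
    so the first and last frames of the cycle are always selected.
    """
    if n_frames < n_out:
        raise ValueError(f"cycle has {n_frames} frames, need at least {n_out}")
    k = np.arange(n_out, dtype=float)
    idx = np.floor(k * (n_frames - 1) / (n_out - 1) + 0.5).astype(int)
    return idx


# ---------------------------------------------------------------------------
# generalized Procrustes alignment
# ---------------------------------------------------------------------------

def _center(shapes: np.ndarray) -> np.ndarray:
    return shapes - shapes.mean(axis=-2, keepdims=True)


def centroid_size(shape: np.ndarray) -> float:
    c = shape - shape.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _optimal_rotations(shapes: np.ndarray, target: np.ndarray,
                       allow_reflection: bool) -> np.ndarray:
    """Batch of 2x2 rotations R_i minimizing ||X_i R_i - target||."""
    h = np.einsum("mki,kj->mij", shapes, target)
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection:
        neg = np.linalg.det(r) < 0
        if np.any(neg):
            u = u.copy()
            u[neg, :, 1] *= -1.0
            r = u @ vt
    return r


def gpa_align(configs, scale: bool = True, allow_reflection: bool = False,
              tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes alignment of a set of configurations.

    Each configuration is centered, scaled to unit centroid size (if
    ``scale``) and iteratively rotated to the running consensus (orthogonal
    Procrustes with determinant +1 unless reflections are allowed); the
    consensus is the renormalized coordinate-wise mean.  Iteration stops
    when the consensus moves by less than ``tol``.

    ``configs`` may be an (m, k, 2) array or a sequence of
    :class:`FrameConfiguration` / (k, 2) arrays.
    """
    x = _as_config_array(configs)
    m = x.shape[0]
    if m < 2:
        raise ValueError("GPA needs at least 2 configurations")
    x = _center(x.astype(float))
    cs = np.sqrt((x ** 2).sum(axis=(1, 2)))
    if np.any(cs <= 0.0):
        raise DegenerateShapeError("configuration with zero centroid size")
    if scale:
        x = x / cs[:, None, None]

    consensus = x[0] / np.linalg.norm(x[0])
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        r = _optimal_rotations(x, consensus, allow_reflection)
        x = np.einsum("mki,mij->mkj", x, r)
        new_c = x.mean(axis=0)
        new_c = new_c - new_c.mean(axis=0)
        norm = np.linalg.norm(new_c)
        if norm <= 0.0:
            raise DegenerateShapeError("degenerate consensus")
        new_c = new_c / norm
        # fix the rotational gauge: a collective rotation of all aligned
        # shapes leaves residuals unchanged, so pin the consensus
        # orientation to the previous iterate before measuring progress
        g = _optimal_rotations(new_c[None], consensus, allow_reflection)[0]
        new_c = new_c @ g
        x = x @ g
        delta = np.linalg.norm(new_c - consensus)
        consensus = new_c
        if delta < tol:
            converged = True
            break
    return ProcrustesResult(
        consensus=consensus,
        aligned=x,
        centroid_sizes=cs,
        iterations=iterations,
        converged=converged,
    )


def _as_config_array(configs) -> np.ndarray:
    if isinstance(configs, np.ndarray) and configs.ndim == 3:
        return np.array(configs, dtype=float)
    arrs = []
    for c in configs:
        if isinstance(c, FrameConfiguration):
            arrs.append(c.landmarks)
        else:
            arrs.append(np.asarray(c, dtype=float))
    return np.stack(arrs)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared distance between two pre-aligned shapes."""
    return float(np.linalg.norm(a - b))


def total_procrustes_ss(result: ProcrustesResult) -> float:
    """Sum of squared aligned-shape distances to the mean shape."""
    mean = result.aligned.mean(axis=0)
    return float(((result.aligned - mean) ** 2).sum())


# ---------------------------------------------------------------------------
# semi-landmark sliding
# ---------------------------------------------------------------------------

def default_slide_sets() -> dict[str, np.ndarray]:
    """Interior semi-landmark indices per line (endpoints stay fixed)."""
    return {
        name: np.arange(sl.start + 1, sl.stop - 1)
        for name, sl in LINE_SLICES.items()
    }


def slide_semilandmarks(result: ProcrustesResult,
                        slide_sets: Mapping[str, Sequence[int]] | None = None,
                        tol: float = 1e-8, max_iter: int = 20,
                        ) -> ProcrustesResult:
    """Slide interior semi-landmarks to minimize Procrustes distance.

    Tangent directions are estimated at the consensus by central
    differences of neighboring semi-landmarks; each specimen's slidable
    landmark is displaced along its tangent by the projection of its
    residual to the consensus, and the set is re-aligned by GPA.  The outer
    loop repeats until the total Procrustes sum of squares changes by less
    than ``tol``.  Intended only for shape-trajectory (PCA) analysis, not
    for variance profiles.
    """
    if slide_sets is None:
        slide_sets = default_slide_sets()
    k = result.n_landmarks
    idx = np.concatenate([np.asarray(v, dtype=int) for v in slide_sets.values()])
    if idx.size and (idx.min() < 0 or idx.max() >= k):
        raise IndexError("slide index out of range")
    for name, sl in LINE_SLICES.items():
        if name in slide_sets:
            s = np.asarray(slide_sets[name], dtype=int)
            if np.any((s <= sl.start) | (s >= sl.stop - 1)):
                raise IndexError(f"slide set for {name} includes an endpoint")

    current = result
    prev_ss = total_procrustes_ss(current)
    for _ in range(max_iter):
        cons = current.consensus
        tangents = np.zeros((k, 2))
        tangents[idx] = cons[idx + 1] - cons[idx - 1]
        norms = np.linalg.norm(tangents[idx], axis=1)
        norms[norms == 0.0] = 1.0
        tangents[idx] /= norms[:, None]

        shapes = current.aligned.copy()
        resid = cons[None, idx, :] - shapes[:, idx, :]
        lam = np.einsum("mkd,kd->mk", resid, tangents[idx])
        shapes[:, idx, :] += lam[..., None] * tangents[idx]

        current = gpa_align(shapes)
        ss = total_procrustes_ss(current)
        if abs(prev_ss - ss) < tol:
            break
        prev_ss = ss
    return current


# ---------------------------------------------------------------------------
# variance profiles and the leakage experiment
# ---------------------------------------------------------------------------

def landmark_variance_profile(result: ProcrustesResult, group_labels,
                              confidence: float = 0.95,
                              ) -> LandmarkVarianceProfile:
    """Per-landmark S^2 within each group, summarized across groups.

    ``group_labels`` assigns each aligned configuration to a group (one
    lick cycle).  Within each group S^2(landmark) = var(x) + var(y) over
    that group's frames (ddof=1); the profile reports the mean across
    groups with a Student-t confidence interval (df = n_groups - 1).
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != result.n_configs:
        raise ValueError("one group label per configuration required")
    groups = list(dict.fromkeys(labels.tolist()))
    per = []
    for g in groups:
        sub = result.aligned[labels == g]
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 frames")
        per.append(sub.var(axis=0, ddof=1).sum(axis=1))
    per = np.stack(per)
    mean = per.mean(axis=0)
    n = per.shape[0]
    if n >= 2:
        sem = per.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo = hi = None
    return LandmarkVarianceProfile(
        per_group_s2=per, mean_s2=mean, ci_low=lo, ci_high=hi,
        group_ids=tuple(groups), confidence=confidence,
    )


def leakage_fraction(base_frame, varied_indices,
                     displacement_ranges: tuple[float, float],
                     n_replicates: int = 100, seed: int = 0) -> float:
    """Fraction of GPA variance leaked onto unperturbed landmarks.

    Replicates one frame ``n_replicates`` times, perturbs only
    ``varied_indices`` with uniform displacements in
    ``+/- displacement_ranges`` along the bill's own long and transverse
    axes (so the experiment is invariant to the global orientation of the
    frame), GPA-aligns the replicates, and returns (summed S^2 at
    unvaried landmarks) / (summed S^2 at varied landmarks).  Quantifies
    how much the superimposition spreads localized landmark motion across
    the configuration.
    """
    if isinstance(base_frame, FrameConfiguration):
        base = base_frame.landmarks
    else:
        base = np.asarray(base_frame, dtype=float)
    k = base.shape[0]
    varied = np.unique(np.asarray(varied_indices, dtype=int))
    if varied.size == 0 or varied.size >= k:
        raise ValueError("varied indices must be a nonempty proper subset")
    if varied.min() < 0 or varied.max() >= k:
        raise IndexError("varied index out of range")
    dx, dy = float(displacement_ranges[0]), float(displacement_ranges[1])
    if dx == 0.0 and dy == 0.0:
        return 0.0
    # bill-intrinsic axes: long axis from tip toward base of the first line
    axis = base[min(N_PER_LINE, k) - 1] - base[0]
    axis = axis / np.linalg.norm(axis)
    ortho = np.array([-axis[1], axis[0]])
    rng = np.random.default_rng(seed)
    reps = np.repeat(base[None], n_replicates, axis=0)
    pert = rng.uniform(-1.0, 1.0, size=(n_replicates, varied.size, 2))
    pert *= np.array([dx, dy])
    reps[:, varied, :] += (pert[..., 0:1] * axis[None, None, :]
                           + pert[..., 1:2] * ortho[None, None, :])
    res = gpa_align(reps)
    s2 = res.aligned.var(axis=0, ddof=1).sum(axis=1)
    unvaried = np.setdiff1d(np.arange(k), varied)
    denom = s2[varied].sum()
    if denom == 0.0:
        return 0.0
    return float(s2[unvaried].sum() / denom)


# ---------------------------------------------------------------------------
# shape-space trajectories
# ---------------------------------------------------------------------------

def shape_pca(result: ProcrustesResult, eig_tol: float = 1e-12) -> ShapeTrajectory:
    """PCA of aligned coordinates (covariance of 2k-vectors, no rescaling).

    Scores are centered on the mean aligned shape, so each aligned shape is
    exactly ``center + scores @ loadings``.  Percent variances are computed
    over all retained axes and sum to 100 (empty for identical shapes).
    """
    y = result.flat()
    m = y.shape[0]
    if m < 3:
        raise ValueError("PCA needs at least 3 aligned configurations")
    center = y.mean(axis=0)
    yc = y - center
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    eig = s ** 2 / (m - 1)
    keep = eig > eig_tol * max(eig[0], 1.0) if eig.size else np.zeros(0, bool)
    eig = eig[keep]
    vt = vt[keep]
    scores = u[:, keep] * s[keep]
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return ShapeTrajectory(
        scores=scores, eigenvalues=eig, percent_variance=pct,
        loadings=vt, center=center,
    )


def deformation_wireframe(traj: ShapeTrajectory, axis: int, score: float,
                          magnification: float = 1.5) -> np.ndarray:
    """Shape at ``magnification * score`` along one PC axis, as (k, 2).

    Magnification factors of roughly 1.5-7x make subtle bill-shape changes
    visible in wireframe plots.
    """
    flat = traj.center + magnification * score * traj.loadings[axis]
    return flat.reshape(-1, 2)


# ---------------------------------------------------------------------------
# bending-zone localization from variance profiles
# ---------------------------------------------------------------------------

def estimate_hinge_index(s2: np.ndarray) -> float:
    """Locate the bending hinge from a per-landmark variance profile.

    Under rigid rotation of the segment distal to a hinge, the aligned
    displacement field is piecewise linear in arc position with a kink at
    the hinge (the Procrustes superimposition superposes a compensating
    rigid motion, so each branch crosses zero at a cancellation node
    flanking the hinge).  sqrt(S^2) along the line therefore exhibits an
    interior local maximum exactly at the hinge, between two local minima;
    the same detector localizes a localized-flex bending zone, whose
    variance peaks at the zone itself.  The most prominent interior peak
    of sqrt(S^2) is refined by parabolic interpolation and returned as a
    fractional landmark index in [1, n] (index 1 = bill tip).
    """
    from scipy.signal import find_peaks

    y = np.sqrt(np.maximum(np.asarray(s2, dtype=float), 0.0))
    n = y.size
    peaks, props = find_peaks(y, prominence=0.0)
    if peaks.size == 0:
        # monotone profile: fall back to the point of steepest descent
        return float(np.argmax(-np.diff(y)) + 1.5)
    j = int(peaks[np.argmax(props["prominences"])])
    refined = float(j)
    if 0 < j < n - 1:
        denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
        if denom < 0:
            refined = j + 0.5 * (y[j - 1] - y[j + 1]) / denom
    return refined + 1.0


def profile_peak_index(s2: np.ndarray, smooth: int = 3) -> float:
    """Sub-landmark location of the variance maximum along a line.

    Smooths with a short moving average and refines the argmax by
    parabolic interpolation of its two neighbors; returns a fractional
    landmark index in [1, n].  Suited to localized bending-zone (flexing)
    variance patterns that peak at the zone itself.
    """
    y = np.asarray(s2, dtype=float)
    n = y.size
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        ypad = np.pad(y, smooth // 2, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[:n]
    j = int(np.argmax(y))
    if 0 < j < n - 1:
        denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
        if denom < 0:
            j = j + 0.5 * (y[j - 1] - y[j + 1]) / denom
    return float(j + 1)
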