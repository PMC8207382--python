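"""Fit a helicospiral shell model to 2D landmarks from a photograph.

Photographs follow the aperture-up mounting convention: the shell lies on
a flat surface with the aperture facing the camera and the columella (the
coiling axis) parallel to the surface.  The camera is modelled as
orthographic, viewing along the normal of the generating plane at the lip,
so the model frame is rotated about the coiling axis until the lip azimuth
lies in the image plane and the out-of-plane coordinate is dropped.  The
in-plane model coordinates are then mapped to pixels by a similarity
transform (rotation, translation, isotropic scale).

Landmarks are user-defined, role-tagged points: the apex, an ordered run
of points along the suture spiral, points on the aperture outline (the lip
circle), the umbilicus, and one pair of points per band marking its edges
along the lip arc.  Fitting minimizes summed squared pixel distances from
the landmarks to the corresponding projected model curves over the six
size/growth parameters, the total coiling angle and the pose, using
trust-region nonlinear least squares from a grid of heuristic starts.

Note that under orthographic projection the pixel scale and the absolute
model size are confounded; supply the photograph's mm-per-pixel scale to
recover parameters in millimetres (otherwise they are in pixel units with
the pose scale locked to 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .helicospiral import ShellParams, visible_arc, visible_arc_many
from .banding import Band, BandConfig

__all__ = [
    "LandmarkSet",
    "Pose",
    "FitResult",
    "project",
    "fit_shell",
    "bands_from_landmarks",
    "read_landmarks",
    "write_landmarks",
]

TWO_PI = 2.0 * math.pi

#: coiling-angle sampling step (radians) for polyline curve projection
CURVE_DTHETA = 0.01

ROLE_MIN = {"apex": 1, "suture_spiral": 5, "aperture_outline": 6, "umbilicus": 1}


@dataclass(frozen=True)
class Pose:
    """Similarity transform from model plane (mm) to image plane (px)."""

    rotation: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    scale: float = 1.0  # px per mm

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"pose scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + np.array([self.tx, self.ty])

    def invert(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points) - np.array([self.tx, self.ty])
        return d @ np.linalg.inv(self.matrix).T


@dataclass
class LandmarkSet:
    """Role-tagged 2D landmarks (px) from one aperture-up photograph."""

    image_id: str
    apex: np.ndarray  # (2,)
    suture_spiral: np.ndarray  # (>=5, 2), ordered from early whorl to lip
    aperture_outline: np.ndarray  # (>=6, 2)
    umbilicus: np.ndarray  # (2,)
    band_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    n_bands: int = 0
    mm_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float).reshape(2)
        self.umbilicus = np.asarray(self.umbilicus, dtype=float).reshape(2)
        self.suture_spiral = np.asarray(self.suture_spiral, dtype=float).reshape(-1, 2)
        self.aperture_outline = np.asarray(self.aperture_outline, dtype=float).reshape(-1, 2)
        self.band_edges = np.asarray(self.band_edges, dtype=float).reshape(-1, 2)
        if len(self.suture_spiral) < ROLE_MIN["suture_spiral"]:
            raise ValueError("need at least 5 suture-spiral landmarks")
        if len(self.aperture_outline) < ROLE_MIN["aperture_outline"]:
            raise ValueError("need at least 6 aperture-outline landmarks")
        if len(self.band_edges) % 2 != 0:
            raise ValueError("band_edges count must be even (start/end per band)")
        for name in ("apex", "umbilicus", "suture_spiral", "aperture_outline", "band_edges"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite coordinates in {name}")


@dataclass
class FitResult:
    """Outcome of a landmark fit: shell parameters, pose and diagnostics."""

    params: ShellParams
    pose: Pose
    rms_residual: float  # px
    converged: bool
    iterations: int
    n_starts: int = 1

    def to_json(self, path: Optional[str | Path] = None) -> str:
        data = {
            "params": asdict(self.params),
            "pose": asdict(self.pose),
            "rms_residual": self.rms_residual,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_starts": self.n_starts,
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _model_plane_point(params: ShellParams, theta, phi) -> np.ndarray:
    """In-plane model coordinates (rho', z) of circle points, with the
    azimuth measured relative to the lip so the lip circle projects true."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    rho = params.r(theta) + params.a(theta) * np.sin(phi)
    x = rho * np.cos(theta - params.theta_max)
    z = -params.z(theta) + params.a(theta) * np.cos(phi)
    return np.stack([x, z], axis=-1)


def _model_curve(params: ShellParams, curve: str, dtheta: float = CURVE_DTHETA) -> np.ndarray:
    """Sampled model curve in the 2D model plane (mm)."""
    if curve == "center":
        theta = np.arange(0.0, params.theta_max + dtheta, dtheta)
        theta = np.clip(theta, 0.0, params.theta_max)
        rho = params.r(theta)
        return np.stack([rho * np.cos(theta - params.theta_max), -params.z(theta)], axis=-1)
    if curve == "suture":
        theta = np.arange(TWO_PI, params.theta_max + dtheta, dtheta)
        theta = np.clip(theta, TWO_PI, params.theta_max)
        phi_s, _, _, _ = visible_arc_many(params, theta)
        return _model_plane_point(params, theta, phi_s)
    if curve == "aperture":
        phi = np.linspace(0.0, TWO_PI, 128, endpoint=False)
        theta = np.full_like(phi, params.theta_max)
        return _model_plane_point(params, theta, phi)
    raise ValueError(f"unknown curve {curve!r}; expected suture|aperture|center")


def _apex_point(params: ShellParams) -> np.ndarray:
    """Topmost point of the first modelled aperture circle."""
    return _model_plane_point(params, 0.0, 0.0)


def _umbilicus_point(params: ShellParams) -> np.ndarray:
    """Umbilicus endpoint of the visible arc at the lip."""
    arc = visible_arc(params, params.theta_max)
    return _model_plane_point(params, params.theta_max, arc.phi_umbilicus)


def project(params: ShellParams, pose: Pose, curve: str) -> np.ndarray:
    """Project the named model curve into image pixels as a 2D polyline."""
    return pose.apply(_model_curve(params, curve))


def _point_polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest segment of a polyline.

    For a densely sampled smooth curve the nearest segment adjoins the
    nearest vertex, so only the two segments around each point's nearest
    vertex are projected onto exactly.
    """
    d2 = (
        (points[:, 0:1] - poly[None, :, 0]) ** 2
        + (points[:, 1:2] - poly[None, :, 1]) ** 2
    )
    nearest = d2.argmin(axis=1)  # (P,)
    n_seg = len(poly) - 1
    best = np.full(len(points), np.inf)
    for offset in (-1, 0):
        s = np.clip(nearest + offset, 0, n_seg - 1)
        a = poly[s]
        ab = poly[s + 1] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom = np.where(denom == 0, 1.0, denom)
        t = np.clip(np.einsum("ij,ij->i", points - a, ab) / denom, 0.0, 1.0)
        d = points - (a + t[:, None] * ab)
        best = np.minimum(best, np.einsum("ij,ij->i", d, d))
    return np.sqrt(best)


# -- parameter packing ------------------------------------------------------

_THETA_BOUNDS = (TWO_PI * 1.001, 12.0 * math.pi)
_G_MAX = 0.5


def _pack(params: ShellParams, pose: Pose, fit_scale: bool) -> np.ndarray:
    q = [
        math.log(params.r0),
        math.log(max(params.z0, 1e-6)),
        math.log(params.a0),
        params.g_r,
        params.g_z,
        params.g_a,
        params.theta_max,
        pose.rotation,
        pose.tx,
        pose.ty,
    ]
    if fit_scale:
        q.append(math.log(pose.scale))
    return np.array(q)


def _unpack(q: np.ndarray, fit_scale: bool, scale: float) -> tuple[ShellParams, Pose]:
    params = ShellParams(
        r0=math.exp(q[0]),
        z0=math.exp(q[1]),
        a0=math.exp(q[2]),
        g_r=q[3],
        g_z=q[4],
        g_a=q[5],
        theta_max=q[6],
    )
    s = math.exp(q[10]) if fit_scale else scale
    pose = Pose(rotation=q[7], tx=q[8], ty=q[9], scale=s)
    return params, pose


def _residuals(
    q: np.ndarray, lm: LandmarkSet, fit_scale: bool, scale: float,
    dtheta: float = CURVE_DTHETA,
) -> np.ndarray:
    try:
        params, pose = _unpack(q, fit_scale, scale)
    except (ValueError, OverflowError):
        return np.full(_n_residuals(lm), 1e6)
    try:
        suture = pose.apply(_model_curve(params, "suture", dtheta))
        d_sut = _point_polyline_distance(lm.suture_spiral, suture)
        # the lip circle projects to a true circle: use the exact distance
        lip_center = np.array([params.r(params.theta_max), -params.z(params.theta_max)])
        c_img = pose.apply(lip_center)
        r_img = float(params.a(params.theta_max)) * pose.scale
        d_ap = np.linalg.norm(lm.aperture_outline - c_img, axis=1) - r_img
        apex = pose.apply(_apex_point(params))
        umb = pose.apply(_umbilicus_point(params))
        return np.concatenate(
            [d_sut, d_ap, lm.apex - apex, lm.umbilicus - umb]
        )
    except Exception:
        return np.full(_n_residuals(lm), 1e6)


def _n_residuals(lm: LandmarkSet) -> int:
    return len(lm.suture_spiral) + len(lm.aperture_outline) + 4


def _fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit: returns (center, radius)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx**2 + cy**2, 1e-12))
    return np.array([cx, cy]), r


_START_GRID = [
    (8 * math.pi, 0.08),
    (6 * math.pi, 0.08),
    (8 * math.pi, 0.05),
    (8 * math.pi, 0.12),
    (6 * math.pi, 0.12),
    (10 * math.pi, 0.06),
    (7 * math.pi, 0.10),
    (9 * math.pi, 0.07),
]


def _initial_guesses(
    lm: LandmarkSet, n_starts: int, seed: int
) -> list[tuple[ShellParams, Pose]]:
    """Heuristic starts: lip circle from the aperture outline, overall size
    from the apex-to-aperture distance, growth rates and whorl count from a
    coarse grid (jittered beyond the grid length)."""
    rng = np.random.default_rng(seed)
    c_px, r_px = _fit_circle(lm.aperture_outline)
    u = c_px - lm.apex
    L_px = float(np.linalg.norm(u))
    scale0 = 1.0 / lm.mm_per_px if lm.mm_per_px else 1.0

    guesses = []
    for i in range(n_starts):
        if i < len(_START_GRID):
            theta_m, g = _START_GRID[i]
        else:
            theta_m = rng.uniform(5 * math.pi, 10 * math.pi)
            g = rng.uniform(0.04, 0.15)
        a_lip = r_px / scale0
        a0 = a_lip * math.exp(-g * theta_m)
        rz_lip = max(L_px / scale0 / math.sqrt(2.0), 1e-3)
        r0 = z0 = rz_lip * math.exp(-g * theta_m)
        try:
            params = ShellParams(
                r0=r0, z0=z0, a0=a0, g_r=g, g_z=g, g_a=g, theta_max=theta_m
            )
        except ValueError:
            continue
        apex_m = _apex_point(params)
        lip_m = np.array([params.r(theta_m), -params.z(theta_m)])
        v_m = lip_m - apex_m
        rot = math.atan2(u[1], u[0]) - math.atan2(v_m[1], v_m[0])
        c, s = math.cos(rot), math.sin(rot)
        t = lm.apex - scale0 * (np.array([[c, -s], [s, c]]) @ apex_m)
        guesses.append(
            (params, Pose(rotation=rot, tx=float(t[0]), ty=float(t[1]), scale=scale0))
        )
    return guesses


def fit_shell(
    landmarks: LandmarkSet,
    init: Optional[FitResult] = None,
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 500,
) -> FitResult:
    """Fit shell parameters and pose to a landmark set.

    Minimizes summed squared pixel distances from the suture-spiral
    landmarks to the projected suture curve, the aperture-outline landmarks
    to the projected lip circle, and the apex/umbilicus landmarks to their
    projected model points, by trust-region-reflective least squares from
    multiple heuristic starts.  Deterministic for a given seed.  If the
    landmark set carries ``mm_per_px``, the pose scale is locked to its
    reciprocal and parameters come out in millimetres.
    """
    # Orthographic projection confounds pose scale with absolute size, so
    # the scale is always locked: to 1/mm_per_px when known, else to 1 px/mm
    # (parameters then come out in pixel units).
    fit_scale = False
    scale = 1.0 / landmarks.mm_per_px if landmarks.mm_per_px else 1.0

    starts: list[tuple[ShellParams, Pose]]
    if init is not None:
        starts = [(init.params, init.pose)]
        scale = init.pose.scale
    else:
        starts = _initial_guesses(landmarks, n_starts, seed)
    if not starts:
        raise ValueError("no valid initialization found")

    lo = np.array(
        [-10, -10, -10, 0.0, 0.0, 0.0, _THETA_BOUNDS[0], -np.inf, -np.inf, -np.inf]
    )
    hi = np.array(
        [10, 10, 10, _G_MAX, _G_MAX, _G_MAX, _THETA_BOUNDS[1], np.inf, np.inf, np.inf]
    )
    if fit_scale:
        lo = np.append(lo, -10)
        hi = np.append(hi, 10)

    n_res = _n_residuals(landmarks)
    total_nfev = 0

    # stage A: isometric-constrained coarse search from every start.  The
    # shared-growth-rate subspace has broad, well-separated basins; the
    # full parameterization is released only once the right basin is found.
    iso_idx = [0, 1, 2, 3, 6, 7, 8, 9]  # log sizes, g, theta_max, pose

    def _iso_residuals(qi):
        q = np.empty(10)
        q[iso_idx] = qi
        q[4] = q[5] = q[3]  # g_z = g_a = g_r
        return _residuals(q, landmarks, fit_scale, scale, 0.06)

    candidates = []
    for params0, pose0 in starts:
        q0 = np.clip(_pack(params0, pose0, fit_scale), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                _iso_residuals,
                q0[iso_idx],
                bounds=(lo[iso_idx], hi[iso_idx]),
                method="trf",
                xtol=1e-8,
                ftol=1e-8,
                max_nfev=80,
            )
        except Exception:
            continue
        total_nfev += res.nfev
        q = np.empty(10)
        q[iso_idx] = res.x
        q[4] = q[5] = q[3]
        candidates.append((res.cost, q))
        if math.sqrt(2.0 * res.cost / n_res) < 0.5:  # already sub-pixel
            break
    if not candidates:
        raise RuntimeError("no optimizer start converged")
    candidates.sort(key=lambda c: c[0])

    # stage B: release all parameters for the best coarse candidates
    refined = []
    for _, q in candidates[:2]:
        try:
            res = least_squares(
                _residuals,
                q,
                args=(landmarks, fit_scale, scale, 0.02),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-9,
                ftol=1e-10,
                max_nfev=120,
            )
        except Exception:
            continue
        total_nfev += res.nfev
        refined.append(res)
    if not refined:
        raise RuntimeError("refinement failed from every candidate")
    best = min(refined, key=lambda r: r.cost)
    cost_before_polish = best.cost

    # stage C: polish at full curve resolution
    res = least_squares(
        _residuals,
        best.x,
        args=(landmarks, fit_scale, scale, CURVE_DTHETA),
        bounds=(lo, hi),
        method="trf",
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=min(200, max_iter),
    )
    total_nfev += res.nfev
    if res.cost <= best.cost:
        best = res

    params, pose = _unpack(best.x, fit_scale, scale)
    rms = float(np.sqrt(2.0 * best.cost / _n_residuals(landmarks)))
    # an iteration-capped polish counts as converged when it sits on a cost
    # plateau (noisy fits exhaust the budget long after progress stops)
    plateau = best.cost >= 0.99 * cost_before_polish
    return FitResult(
        params=params,
        pose=pose,
        rms_residual=rms,
        converged=bool(best.status > 0 or rms < 0.05 or plateau),
        iterations=int(total_nfev),
        n_starts=len(starts),
    )


def bands_from_landmarks(fit: FitResult, landmarks: LandmarkSet) -> BandConfig:
    """Band positions/widths from band-edge landmarks and a fitted shell.

    Each edge point is snapped to the projected lip circle (the nearest
    circle point shares its polar angle), converted to an aperture angle
    and then to an arc fraction through the visible arc at the lip.
    Consecutive pairs give each band's start/end fractions.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to extract bands")
    edges = landmarks.band_edges
    if len(edges) == 0:
        raise ValueError("landmark set has no band_edges")
    params, pose = fit.params, fit.pose
    c_m = np.array([params.r(params.theta_max), -params.z(params.theta_max)])
    pts_m = pose.invert(edges)
    v = pts_m - c_m
    phi = np.arctan2(v[:, 0], v[:, 1])  # x-component ~ outward, z-component ~ up
    arc = visible_arc(params, params.theta_max)
    frac = np.asarray(arc.fraction_at_phi(phi))
    bands = []
    for i in range(0, len(frac), 2):
        f0, f1 = float(frac[i]), float(frac[i + 1])
        if not f0 < f1:
            raise ValueError(
                f"band {i // 2 + 1}: edge pair out of order along the arc "
                f"({f0:.4f} >= {f1:.4f})"
            )
        bands.append(
            Band(index=i // 2 + 1, position_frac=0.5 * (f0 + f1), width_frac=f1 - f0)
        )
    return BandConfig(bands)


# -- landmark CSV I/O -------------------------------------------------------

def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    """Write a landmark CSV: image_id, role, order, x_px, y_px."""
    rows = []

    def add(role, pts):
        for k, p in enumerate(np.atleast_2d(pts)):
            rows.append((lm.image_id, role, k, p[0], p[1]))

    add("apex", lm.apex)
    add("suture_spiral", lm.suture_spiral)
    add("aperture_outline", lm.aperture_outline)
    add("umbilicus", lm.umbilicus)
    add("band_edges", lm.band_edges)
    frame = pd.DataFrame(rows, columns=["image_id", "role", "order", "x_px", "y_px"])
    with open(path, "w") as fh:
        if lm.mm_per_px is not None:
            fh.write(f"# mm_per_px: {lm.mm_per_px!r}\n")
        frame.to_csv(fh, index=False)


def read_landmarks(path: str | Path, mm_per_px: Optional[float] = None) -> LandmarkSet:
    """Read a landmark CSV (see :func:`write_landmarks` for the dialect)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "mm_per_px" in first and mm_per_px is None:
                mm_per_px = float(first.split(":", 1)[1])
        else:
            fh.seek(0)
        frame = pd.read_csv(fh)
    required = {"image_id", "role", "order", "x_px", "y_px"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"landmark file missing columns: {sorted(missing)}")

    def pts(role):
        sub = frame[frame["role"] == role].sort_values("order")
        return sub[["x_px", "y_px"]].to_numpy(dtype=float)

    be = pts("band_edges")
    return LandmarkSet(
        image_id=str(frame["image_id"].iloc[0]),
        apex=pts("apex")[0],
        suture_spiral=pts("suture_spiral"),
        aperture_outline=pts("aperture_outline"),
        umbilicus=pts("umbilicus")[0],
        band_edges=be,
        n_bands=len(be) // 2,
        mm_per_px=mm_per_px,
    )
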