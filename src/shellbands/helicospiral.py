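"""Logarithmic-helicospiral shell geometry with circular apertures.

The shell is modelled as a circle (the aperture, or generating curve) swept
along a logarithmic helicospiral.  At coiling angle ``theta`` (radians) the
aperture centre sits at radial distance ``r(theta) = r0 * exp(g_r * theta)``
from the coiling axis and axial depth ``z(theta) = z0 * exp(g_z * theta)``
below the apex; the aperture radius is ``a(theta) = a0 * exp(g_a * theta)``.
The coiling axis is the z-axis, the apex points up and growth proceeds
downward.  The aperture circle lies in the *generating plane*: the plane
spanned by the z-axis and the radial direction at azimuth ``theta``.

Points on the aperture circle are parameterized by the aperture angle
``phi``: ``phi = 0`` at the topmost point of the circle (maximum z),
increasing toward the side away from the coiling axis.  When all three
exponential rates are equal the shell is *isometric* (self-similar from one
whorl to the next); unequal rates give allometric growth, e.g. the convex
spire of Cepaea requires the axial rate to exceed the radial one.

Units are millimetres throughout; angles are radians.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ShellParams",
    "Mesh",
    "VisibleArc",
    "DegenerateGeometryError",
    "aperture_center",
    "aperture_circle",
    "visible_arc",
    "visible_arc_many",
    "surface_mesh",
    "whorl_increments",
]

TWO_PI = 2.0 * math.pi

#: Aperture angle used for the umbilicus endpoint when the aperture does not
#: intersect the previous whorl: the point of the circle nearest the coiling
#: axis, reached from the top (phi=0) by travelling over the outer side.
FALLBACK_PHI_UMBILICUS = 1.5 * math.pi


class DegenerateGeometryError(ValueError):
    """Raised when the aperture and previous-whorl circles coincide."""


@dataclass(frozen=True)
class ShellParams:
    """Parameters of a logarithmic-helicospiral shell.

    Attributes
    ----------
    r0, z0 : float
        Initial radial distance and axial depth (mm) of the aperture centre.
    g_r, g_z : float
        Radial and axial exponential growth rates (per radian).
    a0 : float
        Initial aperture radius (mm).
    g_a : float
        Aperture-radius exponential growth rate (per radian).
    theta_max : float
        Total modelled coiling angle (radians); must exceed one whorl so
        that a previous whorl exists for suture computation.
    chirality : str
        ``"dextral"`` (default) or ``"sinistral"``.
    """

    r0: float
    z0: float
    g_r: float
    g_z: float
    a0: float
    g_a: float
    theta_max: float
    chirality: str = "dextral"

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if self.z0 < 0:
            raise ValueError(f"z0 must be non-negative, got {self.z0}")
        if self.a0 <= 0:
            raise ValueError(f"a0 must be positive, got {self.a0}")
        if self.g_r < 0 or self.g_z < 0 or self.g_a < 0:
            raise ValueError("growth rates must be non-negative")
        if self.theta_max <= TWO_PI:
            raise ValueError(
                f"theta_max must exceed 2*pi (one full whorl), got {self.theta_max}"
            )
        if self.chirality not in ("dextral", "sinistral"):
            raise ValueError(f"chirality must be dextral or sinistral, got {self.chirality!r}")

    @property
    def is_isometric(self) -> bool:
        return self.g_r == self.g_z == self.g_a

    @property
    def sign(self) -> float:
        """Sign of the y-coordinate: +1 for dextral, -1 for sinistral."""
        return 1.0 if self.chirality == "dextral" else -1.0

    def r(self, theta):
        return self.r0 * np.exp(self.g_r * np.asarray(theta, dtype=float))

    def z(self, theta):
        return self.z0 * np.exp(self.g_z * np.asarray(theta, dtype=float))

    def a(self, theta):
        return self.a0 * np.exp(self.g_a * np.asarray(theta, dtype=float))

    def to_json(self, path: Optional[str | Path] = None) -> str:
        """Serialize to flat JSON; write to *path* if given."""
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ShellParams":
        """Read parameters from a JSON string or file path."""
        p = Path(str(source))
        if p.suffix == ".json" and p.exists():
            data = json.loads(p.read_text())
        else:
            data = json.loads(str(source))
        return cls(**data)


@dataclass(frozen=True)
class VisibleArc:
    """Endpoints of the suture-to-umbilicus arc on one aperture circle.

    ``phi_suture`` is the aperture angle of the suture endpoint (arc
    fraction 0), ``phi_umbilicus`` that of the umbilicus endpoint (arc
    fraction 1), unwrapped so that ``phi_umbilicus > phi_suture`` and the
    traversal passes over the outer side of the whorl.  ``arc_length`` is
    the length (mm) of this arc, and ``intersects`` records whether the
    aperture actually met the previous whorl (else the documented fallback
    endpoints were used).
    """

    phi_suture: float
    phi_umbilicus: float
    arc_length: float
    intersects: bool

    @property
    def span(self) -> float:
        return self.phi_umbilicus - self.phi_suture

    def phi_at_fraction(self, f):
        """Aperture angle at arc fraction *f* (0 = suture, 1 = umbilicus)."""
        return self.phi_suture + np.asarray(f, dtype=float) * self.span

    def fraction_at_phi(self, phi):
        """Arc fraction of aperture angle *phi* (unwrapped near the arc)."""
        phi = np.asarray(phi, dtype=float)
        # bring phi into the branch closest to the arc midpoint
        mid = 0.5 * (self.phi_suture + self.phi_umbilicus)
        phi = phi + TWO_PI * np.round((mid - phi) / TWO_PI)
        return (phi - self.phi_suture) / self.span


@dataclass
class Mesh:
    """Triangle mesh of the swept shell surface.

    ``face_labels`` assigns each face a region label: 0 for gap/unlabelled,
    or the 1-based band index for faces inside a band's angular sector.
    """

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    face_labels: np.ndarray  # (F,) int

    def export_obj(self, path: str | Path) -> None:
        """Write Wavefront OBJ with band labels as material groups."""
        lines = ["# shellbands swept helicospiral surface"]
        for v in self.vertices:
            lines.append(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}")
        order = np.argsort(self.face_labels, kind="stable")
        current = None
        for fi in order:
            lab = int(self.face_labels[fi])
            if lab != current:
                name = "gap" if lab == 0 else f"band_{lab}"
                lines.append(f"usemtl {name}")
                lines.append(f"g {name}")
                current = lab
            a, b, c = (int(i) + 1 for i in self.faces[fi])
            lines.append(f"f {a} {b} {c}")
        Path(path).write_text("\n".join(lines) + "\n")

    def export_ply(self, path: str | Path) -> None:
        """Write ASCII PLY (via trimesh)."""
        import trimesh

        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        Path(path).write_bytes(tm.export(file_type="ply", encoding="ascii"))


def _radial_unit(params: ShellParams, theta):
    theta = np.asarray(theta, dtype=float)
    return np.stack(
        [np.cos(theta), params.sign * np.sin(theta), np.zeros_like(theta)], axis=-1
    )


def aperture_center(params: ShellParams, theta) -> np.ndarray:
    """3D position of the aperture centre at coiling angle *theta*.

    Returns ``(r cos(theta), +/- r sin(theta), -z)`` with the sign set by
    chirality; accepts scalars or arrays.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > params.theta_max):
        raise ValueError(f"theta outside [0, theta_max={params.theta_max}]")
    r = params.r(th)
    z = params.z(th)
    out = np.stack([r * np.cos(th), params.sign * r * np.sin(th), -z], axis=-1)
    return out


def aperture_circle(params: ShellParams, theta: float, n: int = 64) -> np.ndarray:
    """*n* points on the aperture circle at *theta*, in the generating plane.

    The circle is parameterized by aperture angle ``phi`` in ``[0, 2*pi)``;
    the first point (``phi = 0``) is the topmost point of the circle.
    """
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    center = aperture_center(params, theta)
    a = float(params.a(theta))
    u = _radial_unit(params, theta)
    zhat = np.array([0.0, 0.0, 1.0])
    phi = np.linspace(0.0, TWO_PI, n, endpoint=False)
    return center + a * (np.cos(phi)[:, None] * zhat + np.sin(phi)[:, None] * u)


def circle_point(params: ShellParams, theta: float, phi) -> np.ndarray:
    """3D point(s) at aperture angle(s) *phi* on the circle at *theta*."""
    center = aperture_center(params, theta)
    a = float(params.a(theta))
    u = _radial_unit(params, theta)
    zhat = np.array([0.0, 0.0, 1.0])
    phi = np.asarray(phi, dtype=float)
    return center + a * (np.cos(phi)[..., None] * zhat + np.sin(phi)[..., None] * u)


def visible_arc_many(params: ShellParams, thetas) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`visible_arc` over an array of coiling angles.

    Works in the generating plane with coordinates (rho, z): the current
    aperture circle at ``theta`` and the previous-whorl circle at
    ``theta - 2*pi`` share that plane.  The measured arc is the portion of
    the current circle exterior to the previous one, from the upper
    intersection (suture) over the outer side to the lower intersection
    (umbilicus).  Where the circles do not intersect, the fallback endpoints
    are ``phi = 0`` (top) and ``phi = 3*pi/2`` (point nearest the axis).

    Returns ``(phi_suture, phi_umbilicus, arc_length, intersects)`` arrays.
    """
    th = np.atleast_1d(np.asarray(thetas, dtype=float))
    if np.any(th < TWO_PI - 1e-12) or np.any(th > params.theta_max + 1e-12):
        raise ValueError("visible arc requires 2*pi <= theta <= theta_max")

    # current and previous-whorl circles in (rho, z) generating-plane coords
    r1, z1, a1 = params.r(th), params.z(th), params.a(th)
    r0, z0, a0 = params.r(th - TWO_PI), params.z(th - TWO_PI), params.a(th - TWO_PI)
    c1 = np.stack([r1, -z1], axis=-1)
    c0 = np.stack([r0, -z0], axis=-1)
    e = c0 - c1
    d = np.hypot(e[..., 0], e[..., 1])

    coincident = (d < 1e-12) & (np.abs(a1 - a0) < 1e-12)
    if np.any(coincident):
        raise DegenerateGeometryError(
            "aperture circle coincides with the previous whorl"
        )
    inter = (d > np.abs(a1 - a0)) & (d < a1 + a0)

    phi_s = np.zeros_like(th)
    phi_u = np.full_like(th, FALLBACK_PHI_UMBILICUS)

    if np.any(inter):
        dd = np.where(inter, d, 1.0)  # avoid division by zero on fallback rows
        m = (a1**2 - a0**2 + dd**2) / (2.0 * dd)
        h2 = np.maximum(a1**2 - m**2, 0.0)
        h = np.sqrt(h2)
        ehat = e / dd[..., None]
        nhat = np.stack([-ehat[..., 1], ehat[..., 0]], axis=-1)
        pa = c1 + m[..., None] * ehat + h[..., None] * nhat
        pb = c1 + m[..., None] * ehat - h[..., None] * nhat
        # aperture angle: phi = atan2(rho-component, z-component) of p - c1
        va, vb = pa - c1, pb - c1
        phi_a = np.arctan2(va[..., 0], va[..., 1])
        phi_b = np.arctan2(vb[..., 0], vb[..., 1])

        # choose the ordering whose arc (traversed in +phi) is exterior to
        # the previous-whorl circle, tested at the arc midpoint
        def _exterior(start, end):
            span = np.mod(end - start, TWO_PI)
            mid = start + 0.5 * span
            p_mid = c1 + a1[..., None] * np.stack(
                [np.sin(mid), np.cos(mid)], axis=-1
            )
            dist = np.hypot(p_mid[..., 0] - c0[..., 0], p_mid[..., 1] - c0[..., 1])
            return dist > a0, span

        ext_ab, span_ab = _exterior(phi_a, phi_b)
        _, span_ba = _exterior(phi_b, phi_a)
        start = np.where(ext_ab, phi_a, phi_b)
        span = np.where(ext_ab, span_ab, span_ba)
        # keep the suture angle on the continuous branch around phi = 0
        start = np.mod(start + math.pi, TWO_PI) - math.pi
        phi_s = np.where(inter, start, phi_s)
        phi_u = np.where(inter, start + span, phi_u)

    arc_len = a1 * (phi_u - phi_s)
    return phi_s, phi_u, arc_len, inter


def visible_arc(params: ShellParams, theta: float) -> VisibleArc:
    """Suture-to-umbilicus arc of the aperture circle at *theta*.

    See :func:`visible_arc_many` for the geometry.  Raises
    :class:`DegenerateGeometryError` when the circles coincide.
    """
    phi_s, phi_u, arc_len, inter = visible_arc_many(params, [theta])
    return VisibleArc(float(phi_s[0]), float(phi_u[0]), float(arc_len[0]), bool(inter[0]))


def whorl_increments(params: ShellParams, theta: float) -> tuple[float, float]:
    """Height and width increase of the whorl ending at *theta*.

    ``delta_height`` is the change of ``z + a`` (axial extent below apex)
    and ``delta_width`` the change of ``r + a`` (radial extent) over one
    full turn.  For the convex spire of Cepaea-like shells the height
    increment exceeds the width increment (axial allometry).
    """
    if theta < TWO_PI:
        raise ValueError("whorl increments require theta >= 2*pi")
    d_height = (params.z(theta) + params.a(theta)) - (
        params.z(theta - TWO_PI) + params.a(theta - TWO_PI)
    )
    d_width = (params.r(theta) + params.a(theta)) - (
        params.r(theta - TWO_PI) + params.a(theta - TWO_PI)
    )
    return float(d_height), float(d_width)


def surface_mesh(
    params: ShellParams,
    bands=None,
    n_theta: int = 120,
    n_phi: int = 36,
) -> Mesh:
    """Triangulated swept surface over ``theta in [0, theta_max]``.

    If *bands* (a :class:`~shellbands.banding.BandConfig`) is given, faces
    whose aperture-angle midpoint lies inside a band's angular sector (the
    sectors anchored at the lip) are labelled with that band's index;
    all other faces carry label 0.
    """
    if n_theta < 4 or n_phi < 4:
        raise ValueError("n_theta and n_phi must be at least 4")
    thetas = np.linspace(0.0, params.theta_max, n_theta)
    phis = np.linspace(0.0, TWO_PI, n_phi, endpoint=False)

    centers = aperture_center(params, thetas)  # (n_theta, 3)
    radii = params.a(thetas)
    u = _radial_unit(params, thetas)  # (n_theta, 3)
    zhat = np.array([0.0, 0.0, 1.0])
    ring = (
        np.cos(phis)[None, :, None] * zhat[None, None, :]
        + np.sin(phis)[None, :, None] * u[:, None, :]
    )
    verts = centers[:, None, :] + radii[:, None, None] * ring
    vertices = verts.reshape(-1, 3)

    ii, jj = np.meshgrid(np.arange(n_theta - 1), np.arange(n_phi), indexing="ij")
    j2 = (jj + 1) % n_phi
    v00 = ii * n_phi + jj
    v01 = ii * n_phi + j2
    v10 = (ii + 1) * n_phi + jj
    v11 = (ii + 1) * n_phi + j2
    quads = np.stack(
        [np.stack([v00, v10, v11], axis=-1), np.stack([v00, v11, v01], axis=-1)],
        axis=2,
    )
    faces = quads.reshape(-1, 3).astype(np.int64)
    pm = phis[jj] + (np.pi / n_phi)  # midpoint of the phi interval
    face_phi = np.repeat(pm.reshape(-1), 2)

    labels = np.zeros(len(faces), dtype=np.int64)
    if bands is not None:
        from .banding import band_sectors  # local import: banding depends on us

        sectors = band_sectors(params, bands)
        for band, (p_start, p_end) in zip(bands.bands, sectors):
            lo = np.mod(p_start, TWO_PI)
            hi = np.mod(p_end, TWO_PI)
            if lo <= hi:
                inside = (face_phi >= lo) & (face_phi < hi)
            else:  # sector wraps through 0
                inside = (face_phi >= lo) | (face_phi < hi)
            labels[inside] = band.index
    return Mesh(vertices=vertices, faces=faces, face_labels=labels)
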