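"""Acetabular cup models and orientation conventions.

Two hemispherical cup models are used: a *standard* shell (4-mm wall) for
implantation and an *eggshell* (0.01-mm wall) whose outer surface is the
measurement surface for uncoverage ratios.  The default outer diameter is
44 mm — the smallest shell that accepts a 28-mm head, and the size of
interest for small dysplastic sockets.

Orientation follows the radiographic convention: *abduction* (inclination)
is the angle between the longitudinal axis and the coronal-plane projection
of the cup axis; *anteversion* is the angle between the cup axis and the
coronal plane.  With RI = abduction and RA = anteversion, the polar axis
(pointing out of the cup opening) in (lateral, anterior, superior) frame
coordinates is

    u = (cos RA * sin RI,  sin RA,  -cos RA * cos RI)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .frames import PelvicFrame
from .geometry import unit


@dataclass(frozen=True)
class CupSpec:
    """Cup geometry: outer diameter, shell thickness, mesh subdivision."""

    outer_diameter_mm: float = 44.0
    shell_thickness_mm: float = 0.01
    subdivision: int = 3

    def __post_init__(self):
        if self.outer_diameter_mm <= 0:
            raise ValueError("outer diameter must be positive")
        if not (0 < self.shell_thickness_mm < self.outer_diameter_mm / 2):
            raise ValueError(
                "shell thickness must be in (0, outer radius)"
            )
        if not (0 <= int(self.subdivision) <= 7):
            raise ValueError("subdivision must be a small non-negative integer")

    @property
    def outer_radius_mm(self) -> float:
        return self.outer_diameter_mm / 2.0

    @classmethod
    def standard(cls, subdivision: int = 3) -> "CupSpec":
        """44-mm cup with a 4-mm shell (the implanted component)."""
        return cls(44.0, 4.0, subdivision)

    @classmethod
    def eggshell(cls, subdivision: int = 3) -> "CupSpec":
        """44-mm cup with a 0.01-mm shell (the measurement surface)."""
        return cls(44.0, 0.01, subdivision)


@dataclass(frozen=True)
class CupPose:
    """Rigid placement of a cup: center + polar axis (out of the opening)."""

    center: np.ndarray
    polar_axis: np.ndarray
    abduction_deg: float = 45.0
    anteversion_deg: float = 20.0

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(3)
        u = np.asarray(self.polar_axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(u) - 1.0) > 1e-9:
            raise ValueError("polar_axis must be a unit vector")
        if not (44.0 <= self.abduction_deg <= 46.0):
            raise ValueError("abduction must stay within the 45° ± 1° band")
        if not (19.0 <= self.anteversion_deg <= 21.0):
            raise ValueError("anteversion must stay within the 20° ± 1° band")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "polar_axis", u)

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "polar_axis": [float(x) for x in self.polar_axis],
            "abduction_deg": float(self.abduction_deg),
            "anteversion_deg": float(self.anteversion_deg),
        }


def cup_axis_from_angles(
    abduction_deg: float, anteversion_deg: float, frame: PelvicFrame
) -> np.ndarray:
    """World-space unit polar axis from radiographic abduction/anteversion."""
    if not (0 <= abduction_deg < 90) or not (0 <= anteversion_deg < 90):
        raise ValueError("angles must be in [0, 90) degrees")
    ri = np.deg2rad(abduction_deg)
    ra = np.deg2rad(anteversion_deg)
    local = np.array([np.cos(ra) * np.sin(ri), np.sin(ra), -np.cos(ra) * np.cos(ri)])
    u = (
        local[0] * frame.lateral_axis
        + local[1] * frame.anterior_axis
        + local[2] * frame.superior_axis
    )
    return unit(u)


def angles_from_cup_axis(u, frame: PelvicFrame) -> tuple[float, float]:
    """Recover (abduction, anteversion) in degrees from a polar axis."""
    lat = float(u @ frame.lateral_axis)
    ant = float(u @ frame.anterior_axis)
    sup = float(u @ frame.superior_axis)
    anteversion = np.rad2deg(np.arcsin(np.clip(ant, -1, 1)))
    abduction = np.rad2deg(np.arctan2(lat, -sup))
    return float(abduction), float(anteversion)


def cup_basis(polar_axis, frame: PelvicFrame | None = None) -> np.ndarray:
    """Orthonormal (e1, e2, u) with u = polar axis.

    The azimuthal reference e1 is the anterior axis projected into the
    opening plane (deterministic given the frame); without a frame an
    arbitrary but deterministic perpendicular is used.
    """
    u = unit(np.asarray(polar_axis, dtype=float))
    ref = frame.anterior_axis if frame is not None else np.array([1.0, 0.0, 0.0])
    e1 = ref - (ref @ u) * u
    if np.linalg.norm(e1) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ u) * u
    e1 = unit(e1)
    e2 = np.cross(u, e1)
    return np.vstack([e1, e2, u])


def _hemisphere_local(radius: float, subdivision: int):
    """Lat-long triangulation of the hemisphere z <= 0, opening in z = 0.

    Returns (vertices, faces).  The rim (colatitude 90° from the -z dome
    apex) is an exact circle of the given radius in the z = 0 plane.
    """
    m = 3 * 2**subdivision  # colatitude rings from apex to rim
    n = 4 * m  # azimuthal steps
    alphas = np.pi / 2 * np.arange(1, m + 1) / m
    phis = 2 * np.pi * np.arange(n) / n
    verts = [np.array([0.0, 0.0, -radius])]
    for a in alphas:
        ring = np.column_stack(
            [
                radius * np.sin(a) * np.cos(phis),
                radius * np.sin(a) * np.sin(phis),
                -radius * np.cos(a) * np.ones(n),
            ]
        )
        verts.append(ring)
    verts = np.vstack(verts)

    faces = []
    # apex fan (wound so normals point outward, away from the sphere center)
    first = 1
    for j in range(n):
        faces.append([0, first + (j + 1) % n, first + j])
    # quads between rings, split into triangles
    for i in range(m - 1):
        a0 = 1 + i * n
        a1 = 1 + (i + 1) * n
        for j in range(n):
            j2 = (j + 1) % n
            faces.append([a0 + j, a1 + j2, a1 + j])
            faces.append([a0 + j, a0 + j2, a1 + j2])
    return verts, np.asarray(faces, dtype=np.int64)


def build_cup_mesh(
    spec: CupSpec,
    pose: CupPose,
    variant: str = "outer_shell_only",
    frame: PelvicFrame | None = None,
) -> trimesh.Trimesh:
    """Triangulated cup model in world coordinates.

    ``outer_shell_only`` is the open outer hemispherical surface (the
    uncoverage measurement surface); ``full_shell`` is the closed solid
    shell (outer + inner hemisphere + rim annulus).
    """
    if variant not in ("outer_shell_only", "full_shell"):
        raise ValueError(f"unknown cup variant: {variant!r}")
    r_out = spec.outer_radius_mm
    v_out, f_out = _hemisphere_local(r_out, spec.subdivision)
    if variant == "outer_shell_only":
        verts, faces = v_out, f_out
    else:
        r_in = r_out - spec.shell_thickness_mm
        v_in, f_in = _hemisphere_local(r_in, spec.subdivision)
        f_in = f_in[:, ::-1] + len(v_out)  # flip inner surface inward
        n = 4 * 3 * 2**spec.subdivision
        rim_out = np.arange(len(v_out) - n, len(v_out))
        rim_in = np.arange(len(v_in) - n, len(v_in)) + len(v_out)
        annulus = []
        for j in range(n):
            j2 = (j + 1) % n
            annulus.append([rim_out[j], rim_in[j2], rim_out[j2]])
            annulus.append([rim_out[j], rim_in[j], rim_in[j2]])
        verts = np.vstack([v_out, v_in])
        faces = np.vstack([f_out, f_in, np.asarray(annulus, dtype=np.int64)])

    B = cup_basis(pose.polar_axis, frame)
    world = verts @ B + pose.center  # rows of B are e1, e2, u
    return trimesh.Trimesh(vertices=world, faces=faces, process=False)


def cup_surface_dirs(subdivision: int) -> np.ndarray:
    """Unit outward directions at the outer-surface facet centroids.

    Projecting facet centroids of the lat-long hemisphere onto the unit
    sphere gives a deterministic, well-spread direction sample of the
    support hemisphere (all have a negative polar-axis component).
    """
    v, f = _hemisphere_local(1.0, subdivision)
    cent = v[f].mean(axis=1)
    return cent / np.linalg.norm(cent, axis=1, keepdims=True)


def rim_circle(pose: CupPose, radius: float, n: int = 720,
               frame: PelvicFrame | None = None) -> np.ndarray:
    """Points on the cup rim (the opening-plane circle), world coords."""
    B = cup_basis(pose.polar_axis, frame)
    phis = 2 * np.pi * np.arange(n) / n
    local = np.column_stack(
        [radius * np.cos(phis), radius * np.sin(phis), np.zeros(n)]
    )
    return local @ B + pose.center
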