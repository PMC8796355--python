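"""Cup coverage classification and the 3-D acetabular quadrant system.

A facet of the eggshell cup's outer surface counts as *covered* when its
centroid lies inside the host bone or within ``eps`` of the bone surface
(default 0.1 mm, which absorbs CT-scale mesh discretization without
inventing coverage).  The total uncoverage ratio (TUCR) is uncovered area
over total outer-surface area.

The quadrant system lifts the classic 2-D screw-zone construction to 3-D:
the *quadrantal sagittal plane* passes through both ASIS and the implanted
cup center; the *quadrantal horizontal plane* passes through the cup center,
perpendicular to the first, with its normal along the ipsilateral-ASIS →
cup-center direction.  The two planes split the cup into anterior-superior,
anterior-inferior, posterior-superior and posterior-inferior segments; each
segmental UCR uses the *total* cup surface area as denominator, so the four
segmental ratios sum exactly to the TUCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .frames import PelvicFrame, PelvicLandmarks
from .geometry import (
    DegenerateGeometryError,
    MeshQueries,
    Plane,
    plane_from_points,
)

_TIE_TOL = 1e-9  # mm; centroids this close to a quadrant plane tie-break


@dataclass(frozen=True)
class CoverageResult:
    """Per-facet coverage of the cup outer surface against host bone."""

    covered: np.ndarray  # (n,) bool
    facet_areas: np.ndarray  # (n,) mm²
    facet_centroids: np.ndarray  # (n, 3) mm
    eps_mm: float

    def __post_init__(self):
        if not (len(self.covered) == len(self.facet_areas) == len(self.facet_centroids)):
            raise ValueError("per-facet arrays must have equal length")

    @property
    def total_area_mm2(self) -> float:
        return float(self.facet_areas.sum())

    @property
    def uncovered_area_mm2(self) -> float:
        return float(self.facet_areas[~self.covered].sum())

    @property
    def tucr(self) -> float:
        return self.uncovered_area_mm2 / self.total_area_mm2


@dataclass(frozen=True)
class QuadrantPlanes:
    """The two planes of the 3-D acetabular quadrant system.

    ``sagittal_q``'s positive side is anterior; ``horizontal_q``'s positive
    side is inferior.  Both contain the cup center.
    """

    sagittal_q: Plane
    horizontal_q: Plane
    cup_center: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cup_center, dtype=float)
        for name, plane in (("sagittal_q", self.sagittal_q), ("horizontal_q", self.horizontal_q)):
            if abs(float(plane.signed_distance(c))) > 1e-9:
                raise ValueError(f"{name} does not contain the cup center")
        if abs(float(self.sagittal_q.normal @ self.horizontal_q.normal)) > 1e-9:
            raise ValueError("quadrant planes are not perpendicular")


@dataclass(frozen=True)
class QuadrantUCRs:
    """Total and segmental uncoverage ratios (total-area denominator)."""

    asucr: float
    aiucr: float
    psucr: float
    piucr: float
    tucr: float

    def __post_init__(self):
        for name in ("asucr", "aiucr", "psucr", "piucr", "tucr"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        s = self.asucr + self.aiucr + self.psucr + self.piucr
        if abs(s - self.tucr) > 1e-9:
            raise ValueError(
                f"segmental ratios sum to {s}, expected tucr={self.tucr}"
            )

    def as_dict(self) -> dict:
        return {
            "asucr": self.asucr,
            "aiucr": self.aiucr,
            "psucr": self.psucr,
            "piucr": self.piucr,
            "tucr": self.tucr,
        }


def classify_coverage(
    bone: trimesh.Trimesh | MeshQueries,
    cup_outer_surface: trimesh.Trimesh,
    eps_mm: float = 0.1,
) -> CoverageResult:
    """Classify every cup facet as covered/uncovered by the host bone."""
    if eps_mm < 0:
        raise ValueError("eps must be >= 0")
    queries = bone if isinstance(bone, MeshQueries) else MeshQueries(bone)
    centroids = cup_outer_surface.triangles.mean(axis=1)
    areas = cup_outer_surface.area_faces
    covered = queries.in_solid(centroids, eps=eps_mm)
    return CoverageResult(
        covered=covered,
        facet_areas=np.asarray(areas, dtype=float),
        facet_centroids=centroids,
        eps_mm=float(eps_mm),
    )


def quadrant_planes(
    landmarks: PelvicLandmarks, frame: PelvicFrame, cup_center
) -> QuadrantPlanes:
    """Build the quadrantal sagittal/horizontal planes for a seated cup."""
    c = np.asarray(cup_center, dtype=float)
    try:
        sagittal = plane_from_points(landmarks.asis_left, landmarks.asis_right, c)
    except DegenerateGeometryError as err:
        raise DegenerateGeometryError(
            "cup center is collinear with the two ASIS; quadrant plane undefined"
        ) from err
    if float(sagittal.normal @ frame.anterior_axis) < 0:
        sagittal = sagittal.flipped()
    n_h = c - landmarks.asis_ipsilateral
    horizontal = Plane.from_point_normal(c, n_h)
    return QuadrantPlanes(sagittal_q=sagittal, horizontal_q=horizontal, cup_center=c)


def quadrant_labels(points, planes: QuadrantPlanes) -> np.ndarray:
    """Assign each point to a quadrant: 0=A-S, 1=A-I, 2=P-S, 3=P-I.

    Tie-break: centroids within 1e-9 mm of a plane go to the anterior and
    superior side (deterministic, measure-zero).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    s_sag = p @ planes.sagittal_q.normal + planes.sagittal_q.d
    s_hor = p @ planes.horizontal_q.normal + planes.horizontal_q.d
    anterior = s_sag > -_TIE_TOL
    superior = s_hor < _TIE_TOL  # positive side of horizontal_q is inferior
    labels = np.empty(len(p), dtype=np.int64)
    labels[anterior & superior] = 0
    labels[anterior & ~superior] = 1
    labels[~anterior & superior] = 2
    labels[~anterior & ~superior] = 3
    return labels


def segmental_ucrs(cov: CoverageResult, planes: QuadrantPlanes) -> QuadrantUCRs:
    """Per-segment uncoverage ratios; denominator is the total cup area."""
    labels = quadrant_labels(cov.facet_centroids, planes)
    total = cov.total_area_mm2
    seg = np.zeros(4)
    un = ~cov.covered
    for q in range(4):
        seg[q] = cov.facet_areas[un & (labels == q)].sum() / total
    return QuadrantUCRs(
        asucr=float(seg[0]),
        aiucr=float(seg[1]),
        psucr=float(seg[2]),
        piucr=float(seg[3]),
        tucr=float(seg.sum()),
    )


def export_coverage_ply(cup_mesh: trimesh.Trimesh, cov: CoverageResult, path) -> None:
    """Write the cup colored by covered (green) / uncovered (red) for QC."""
    colored = cup_mesh.copy()
    colors = np.where(
        cov.covered[:, None],
        np.array([[60, 180, 75, 255]]),
        np.array([[230, 25, 75, 255]]),
    ).astype(np.uint8)
    colored.visual.face_colors = colors
    colored.export(str(path), file_type="ply")
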