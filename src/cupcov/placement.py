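"""Deterministic cup placement under the implantation rules.

The placement rules are: orient the cup at the configured abduction /
anteversion (45°/20° by default), medialize until the shell abuts the
medial wall, keep the front edge tangent to the anterior wall and the lower
edge tangent to the transverse ligament.  The rules were executed manually
in the original workflow; here they become a reproducible algorithm:

1. *Seating*: the cup translates along its own polar axis (the reaming /
   insertion direction, whose dominant component is medial) from a start
   position outside the bone.  The exact first-contact depth is found by
   casting one ray per outer-surface sample point along the seating
   direction and taking the smallest entry distance — the limit of an
   infinitesimal step march.  Contact is detected on the dome cap (within
   ~53° of the apex): rays from samples closer to the rim run nearly
   tangential to the socket wall, and a tessellated surface cannot localize
   a tangential contact.
2. *Tangency*: the rim point nearest the anterior-wall landmark is matched
   to it along the anterior axis, and the inferior-most rim point to the
   transverse-ligament landmark along the superior axis, by coordinate
   descent in the plane perpendicular to the cup axis (so in-plane moves do
   not change the seating depth), re-seating after each correction.

Residuals of both tangency constraints are reported rather than hidden;
when they cannot be brought within tolerance the placement raises with the
residuals listed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cup import CupPose, CupSpec, cup_axis_from_angles, cup_basis, cup_surface_dirs, rim_circle
from .frames import BoneModel, PelvicFrame
from .geometry import MeshQueries, unit

# Seating contact is detected on the dome cap only (|n·u| >= 0.6, i.e. within
# ~53° of the apex): a ray nearly tangent to the socket wall amplifies surface
# tessellation noise by 1/|n·u| and cannot localize contact reliably.
_SEAT_DIR_MAX_DZ = -0.6


class PlacementError(RuntimeError):
    """Cup placement failed (no contact, or infeasible tangency)."""


@dataclass(frozen=True)
class PlacementResult:
    """Converged pose plus diagnostics."""

    pose: CupPose
    residual_anterior_mm: float
    residual_inferior_mm: float
    medial_contact: bool
    active_constraints: tuple
    iterations: int
    seat_depth_mm: float  # translation along -axis from the raised start
    start_center: np.ndarray


def place_cup(
    bone: BoneModel,
    frame: PelvicFrame,
    spec: CupSpec,
    abduction_deg: float = 45.0,
    anteversion_deg: float = 20.0,
    step_mm: float = 0.1,
    tol_mm: float = 0.2,
    max_iter: int = 50,
    search_box_mm: float = 120.0,
    queries: MeshQueries | None = None,
    sample_subdivision: int = 3,
) -> PlacementResult:
    """Seat and align the cup; deterministic given the inputs."""
    if queries is None:
        queries = MeshQueries(bone.mesh)
    lm = bone.landmarks
    u = cup_axis_from_angles(abduction_deg, anteversion_deg, frame)
    r = spec.outer_radius_mm
    B = cup_basis(u, frame)  # rows e1, e2, u

    local_dirs = cup_surface_dirs(sample_subdivision)
    seat_local = local_dirs[local_dirs[:, 2] <= _SEAT_DIR_MAX_DZ]
    seat_world = seat_local @ B  # unit outward directions, world

    A = frame.anterior_axis
    S = frame.superior_axis
    a_perp = unit(A - (A @ u) * u)
    s_perp = unit(S - (S @ u) * u)

    # start: rim centroid raised along +u until the whole cup clears the bone
    bone_w_max = float((bone.mesh.vertices @ u).max())
    start_w = bone_w_max + r + 1.0
    center = lm.rim_centroid.astype(float).copy()
    center = center + (start_w - float(center @ u)) * u

    res_a = np.inf
    res_i = np.inf
    seat_depth = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # re-raise to the start height (in-plane position preserved)
        center = center + (start_w - float(center @ u)) * u
        origins = center + r * seat_world
        t = queries.first_entry(origins, -u, max_range_mm=search_box_mm + 2 * r)
        finite = np.isfinite(t)
        if not finite.any():
            raise PlacementError(
                "no medial contact achievable: no bone within the "
                f"{search_box_mm} mm search box along the seating direction"
            )
        seat_depth = float(t[finite].min())
        center = center - seat_depth * u

        rim = rim_circle(CupPose(center, u, abduction_deg, anteversion_deg),
                         r, n=720, frame=frame)
        near = rim[int(np.argmin(np.linalg.norm(rim - lm.anterior_wall, axis=1)))]
        res_a = float((near - lm.anterior_wall) @ A)
        low = rim[int(np.argmin(rim @ S))]
        res_i = float((low - lm.transverse_ligament) @ S)
        if abs(res_a) <= tol_mm and abs(res_i) <= tol_mm:
            break
        center = center - (res_a / float(a_perp @ A)) * a_perp
        center = center - (res_i / float(s_perp @ S)) * s_perp
    else:
        raise PlacementError(
            "tangency constraints not satisfiable within tolerance: "
            f"anterior residual {res_a:.3f} mm, inferior residual "
            f"{res_i:.3f} mm after {max_iter} iterations"
        )

    # medial-contact activity: one further step along -u must penetrate bone
    probe = center - step_mm * u
    penetrates = bool(queries.contains(probe + r * seat_world).any())

    active = []
    if penetrates:
        active.append("medial_contact")
    if abs(res_a) <= tol_mm:
        active.append("anterior_tangency")
    if abs(res_i) <= tol_mm:
        active.append("inferior_tangency")

    pose = CupPose(center, u, abduction_deg, anteversion_deg)
    return PlacementResult(
        pose=pose,
        residual_anterior_mm=res_a,
        residual_inferior_mm=res_i,
        medial_contact=penetrates,
        active_constraints=tuple(active),
        iterations=iterations,
        seat_depth_mm=seat_depth,
        start_center=center + (start_w - float(center @ u)) * u,
    )
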