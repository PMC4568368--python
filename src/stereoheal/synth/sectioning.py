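"""Virtual sectioning and microscopy of synthetic volumes.

Sections are isotropic uniform random (IUR): the section normal is drawn
uniformly on the sphere and the sectioning frame is rotated rather than the
volume. Fields are placed so the whole field box (counting frame × section
thickness) lies inside the volume; because every generating process is
stationary inside the box (plus-sampling), any realization-independent field
placement yields unbiased counts.

The counting frame is the unbiased (Gundersen) frame. For the point particles
counted here (nucleus centres, vessel centerline transects) the
inclusion/exclusion-edge rule reduces to half-open intervals on both frame
axes, and the dissector depth interval is half-open as well so a tiling of
dissectors counts every nucleus exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..estimators import DissectorSpec, FieldCounts, PointGrid
from .volume import PHASE_COLLAGEN, PHASE_HAIR, PHASE_VESSEL, SyntheticVolume

__all__ = ["SectionStack", "iur_stack", "field_counts_at", "render_field_counts"]


@dataclass
class SectionStack:
    """A stack of parallel thick sections through a volume.

    ``rotation`` is a 3×3 orthonormal matrix whose rows are the two in-plane
    axes followed by the section normal; ``z_positions`` are the lower faces
    of the sections along the normal (µm), disjoint and increasing.
    """

    volume: SyntheticVolume
    rotation: np.ndarray
    thickness: float
    z_positions: np.ndarray

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("section thickness must be positive")
        z = np.asarray(self.z_positions, dtype=float)
        if len(z) > 1 and np.any(np.diff(z) < self.thickness):
            raise ValueError("sections overlap: spacing below thickness")
        self.z_positions = z


def _orthonormal_frame(normal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rows: e1, e2, normal — with a random in-plane rotation."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    r1 = np.cos(phi) * e1 + np.sin(phi) * e2
    r2 = -np.sin(phi) * e1 + np.cos(phi) * e2
    return np.vstack([r1, r2, n])


def _field_margin(rotation: np.ndarray, spec: DissectorSpec) -> np.ndarray:
    """Per-axis half-extent of the oriented field box (frame × thickness).

    Eroding the volume box by this margin gives exactly the set of field
    centres whose field box lies inside the volume.
    """
    e1, e2, n = np.abs(rotation)
    return 0.5 * (spec.frame_width * e1 + spec.frame_height * e2
                  + spec.section_thickness * n)


def _eroded_box(volume: SyntheticVolume, rotation: np.ndarray,
                spec: DissectorSpec | None) -> tuple[np.ndarray, np.ndarray]:
    lo = np.zeros(3)
    hi = np.asarray(volume.extent, dtype=float)
    if spec is not None:
        m = _field_margin(rotation, spec)
        lo, hi = lo + m, hi - m
        if np.any(hi <= lo):
            raise ValueError("field box does not fit inside the volume")
    return lo, hi


def iur_stack(volume: SyntheticVolume, thickness: float, n_sections: int,
              rng: np.random.Generator,
              spec: DissectorSpec | None = None) -> SectionStack:
    """Systematic uniform random stack at an isotropic random orientation.

    The span of the box along the random normal is divided into
    ``n_sections`` equal intervals with a uniform random start; one section
    sits at the start of each interval. When a :class:`DissectorSpec` is
    given, the span is restricted to the region where a whole field box fits
    inside the volume, so every section can host fields.
    """
    from .volume import _random_unit_vectors
    normal = _random_unit_vectors(rng, 1)[0]
    rot = _orthonormal_frame(normal, rng)
    lo, hi = _eroded_box(volume, rot, spec)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1])
                        for z in (lo[2], hi[2])])
    proj = corners @ rot[2]
    # mid-planes must stay inside the eroded span
    span_lo, span_hi = proj.min() - 0.5 * thickness, proj.max() - 0.5 * thickness
    step = (span_hi - span_lo) / n_sections
    if step < thickness:
        raise ValueError("too many sections for the volume extent")
    start = span_lo + rng.uniform(0.0, step - thickness)
    z_positions = start + step * np.arange(n_sections)
    return SectionStack(volume=volume, rotation=rot, thickness=thickness,
                        z_positions=z_positions)


class _Projections:
    """Per-stack cache of geometry projected onto the stack's axes.

    The frame test becomes axis-aligned in the rotated coordinates, so per
    field only comparisons on these arrays are needed.
    """

    def __init__(self, volume: SyntheticVolume, rotation: np.ndarray):
        self.fib = (volume.fibroblast_centers @ rotation.T
                    if len(volume.fibroblast_centers) else np.empty((0, 3)))
        self.p0 = (volume.vessel_p0 @ rotation.T
                   if len(volume.vessel_p0) else np.empty((0, 3)))
        self.p1 = (volume.vessel_p1 @ rotation.T
                   if len(volume.vessel_p1) else np.empty((0, 3)))


def field_counts_at(volume: SyntheticVolume, center: np.ndarray, rotation: np.ndarray,
                    grid: PointGrid, spec: DissectorSpec,
                    rng: np.random.Generator,
                    _proj: "_Projections | None" = None) -> FieldCounts:
    """Record one field's counts at a given field centre and orientation.

    ``center`` is the 3D midpoint of the dissector box; ``rotation`` rows are
    (e1, e2, normal). Grid points for volume-density counting are classified
    on the section mid-plane; the dissector counts nucleus centres inside the
    guarded depth interval and the unbiased frame; vessel transects are
    centerline crossings of the mid-plane inside the frame, each contributing
    its profile minor axis (equal to the true local vessel diameter for a
    cylindrical vessel at any cut angle).
    """
    center = np.asarray(center, dtype=float)
    e1, e2, n = rotation
    fw, fh = spec.frame_width, spec.frame_height
    proj = _proj if _proj is not None else _Projections(volume, rotation)
    c_loc = rotation @ center

    # --- point-grid phase counts on the mid-plane
    grid_um = grid.spacing * 1000.0
    pts2 = PointGrid(spacing=grid_um).sample_points(fw, fh, rng=rng)
    pts3 = (center - 0.5 * fw * e1 - 0.5 * fh * e2
            + pts2[:, 0:1] * e1 + pts2[:, 1:2] * e2)
    codes = volume.phase_at(pts3)
    p_dermis = len(codes)

    # --- optical dissector: half-open frame and depth intervals
    if len(proj.fib):
        x = proj.fib[:, 0] - c_loc[0]
        y = proj.fib[:, 1] - c_loc[1]
        z = proj.fib[:, 2] - c_loc[2]
        z0 = -0.5 * spec.section_thickness + spec.guard_bottom
        in_frame = (x >= -fw / 2) & (x < fw / 2) & (y >= -fh / 2) & (y < fh / 2)
        in_depth = (z >= z0) & (z < z0 + spec.height)
        q_minus = int(np.count_nonzero(in_frame & in_depth))
    else:
        q_minus = 0

    # --- vessel transects: centerline crossings of the mid-plane
    transects = 0
    diameters: list[float] = []
    if len(proj.p0):
        za = proj.p0[:, 2] - c_loc[2]
        zb = proj.p1[:, 2] - c_loc[2]
        crossing = (za < 0) != (zb < 0)
        for i in np.flatnonzero(crossing):
            t = za[i] / (za[i] - zb[i])
            hit = proj.p0[i] + t * (proj.p1[i] - proj.p0[i])
            x, y = hit[0] - c_loc[0], hit[1] - c_loc[1]
            if -fw / 2 <= x < fw / 2 and -fh / 2 <= y < fh / 2:
                transects += 1
                diameters.append(2.0 * float(volume.vessel_radii[i]))

    return FieldCounts(
        p_collagen=int(np.count_nonzero(codes == PHASE_COLLAGEN)),
        p_vessel=int(np.count_nonzero(codes == PHASE_VESSEL)),
        p_hair=int(np.count_nonzero(codes == PHASE_HAIR)),
        p_dermis=p_dermis,
        q_minus=q_minus,
        frame_area_mm2=spec.frame_area_mm2,
        height_mm=spec.height_mm,
        vessel_transects=transects,
        vessel_profile_diameters=diameters,
    )


def render_field_counts(stack: SectionStack, grid: PointGrid, spec: DissectorSpec,
                        rng: np.random.Generator,
                        fields_per_section: int = 5,
                        max_attempts: int = 200) -> list[FieldCounts]:
    """Sample fields on each section of a stack and record their counts.

    Field centres are rejection-sampled on the section mid-plane so that the
    whole field box stays inside the volume (conservative spherical margin).
    Sections whose mid-plane misses the eroded box contribute no fields.
    """
    vol = stack.volume
    rot = stack.rotation
    e1, e2, n = rot
    lo, hi = _eroded_box(vol, rot, spec)

    inner_corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                              for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    a_rng = (inner_corners @ e1).min(), (inner_corners @ e1).max()
    b_rng = (inner_corners @ e2).min(), (inner_corners @ e2).max()

    proj = _Projections(vol, rot)
    fields: list[FieldCounts] = []
    for z_low in stack.z_positions:
        z_mid = z_low + 0.5 * stack.thickness
        origin = z_mid * n
        placed = 0
        attempts = 0
        while placed < fields_per_section and attempts < max_attempts:
            attempts += 1
            a = rng.uniform(*a_rng)
            b = rng.uniform(*b_rng)
            c = origin + a * e1 + b * e2
            if np.all(c >= lo) and np.all(c <= hi):
                fields.append(field_counts_at(vol, c, rot, grid, spec, rng, _proj=proj))
                placed += 1
    return fields
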