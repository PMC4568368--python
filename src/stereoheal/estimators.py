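"""Design-based stereological estimators.

All estimators operate on raw per-field counts (:class:`FieldCounts`) and pool
them within one animal as ratios of sums, never means of per-field ratios:
fields within an animal are not independent, and the ratio-of-sums form is the
standard unbiased pooling for two-stage stereological sampling.

Quantities and conventions
--------------------------
* area           — point-grid (Cavalieri-type) estimate, ``A = ΣP · a/p``.
* Vv (phase)     — volume density, grid points on phase / points on reference.
* Nv             — numerical density via the optical dissector,
                   ``Nv = ΣQ⁻ / (ΣA · h)`` with guard zones excluded from h.
* Lv             — vessel length density from profile counts on isotropic
                   uniform random (IUR) sections, ``Lv = 2 · Q_A``.
* mean diameter  — arithmetic mean of per-profile minor-axis widths; for a
                   cylinder the minor axis of the elliptical cut equals the
                   true diameter at any sectioning angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StereologyError",
    "PointGrid",
    "DissectorSpec",
    "FieldCounts",
    "StereologyEstimates",
    "estimate_area",
    "estimate_volume_density",
    "estimate_numerical_density",
    "estimate_length_density",
    "estimate_mean_diameter",
    "summarize_animal",
]

PHASES = ("collagen", "vessel", "hair")


class StereologyError(ValueError):
    """An estimate is undefined or its inputs violate an invariant."""


@dataclass(frozen=True)
class PointGrid:
    """A square point grid with systematic-uniform-random (SUR) placement.

    Parameters
    ----------
    spacing : float
        Distance between neighbouring crosses, in mm. The area associated
        with each point is ``a/p = spacing²`` (the area surrounded by every
        four crosses).
    rotation : float
        Grid rotation in radians (0 = axis-aligned).
    """

    spacing: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise StereologyError(f"grid spacing must be > 0, got {self.spacing}")

    @property
    def area_per_point(self) -> float:
        """a/p in mm²."""
        return self.spacing * self.spacing

    def sample_points(self, width: float, height: float, rng: np.random.Generator | None = None,
                      offset: tuple[float, float] | None = None) -> np.ndarray:
        """Lattice points covering ``[0, width) × [0, height)`` (same units as spacing).

        The offset is drawn uniformly in ``[0, spacing)²`` when ``rng`` is given
        (SUR mode); a fixed offset may be supplied instead. Rotation is applied
        about the rectangle centre; only points landing inside the rectangle
        are returned, as an (n, 2) array.
        """
        s = self.spacing
        if offset is None:
            if rng is None:
                offset = (0.5 * s, 0.5 * s)
            else:
                offset = tuple(rng.uniform(0.0, s, size=2))
        # generous index range so the rotated lattice still covers the rectangle
        diag = math.hypot(width, height)
        n = int(diag / s) + 2
        idx = np.arange(-n, n + 1) * s
        xx, yy = np.meshgrid(idx + offset[0], idx + offset[1], indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        if self.rotation:
            c, si = math.cos(self.rotation), math.sin(self.rotation)
            centre = np.array([width / 2.0, height / 2.0])
            pts = (pts - centre) @ np.array([[c, -si], [si, c]]).T + centre
        keep = (pts[:, 0] >= 0) & (pts[:, 0] < width) & (pts[:, 1] >= 0) & (pts[:, 1] < height)
        return pts[keep]

    def count_points_in_mask(self, mask: np.ndarray, mm_per_pixel: float,
                             rng: np.random.Generator | None = None) -> int:
        """Number of grid crosses landing on True pixels of a binary mask.

        The mask is row-major with the top-left origin; physical extent is
        ``mask.shape * mm_per_pixel``. Used for wound-photograph area
        estimation: ``estimate_area(ΣP, grid)`` then gives mm².
        """
        h_px, w_px = mask.shape
        pts = self.sample_points(w_px * mm_per_pixel, h_px * mm_per_pixel, rng=rng)
        if pts.size == 0:
            return 0
        col = np.floor(pts[:, 0] / mm_per_pixel).astype(int)
        row = np.floor(pts[:, 1] / mm_per_pixel).astype(int)
        inside = (row >= 0) & (row < h_px) & (col >= 0) & (col < w_px)
        return int(mask[row[inside], col[inside]].sum())


@dataclass(frozen=True)
class DissectorSpec:
    """Optical dissector geometry, in µm.

    The dissector height is the section thickness minus the top and bottom
    guard zones ("areas of safety") within which nuclei are never counted.
    Default: 15 µm sections with 5 µm guards top and bottom, h = 5 µm, and a
    100 µm square unbiased counting frame.
    """

    section_thickness: float = 15.0
    guard_top: float = 5.0
    guard_bottom: float = 5.0
    frame_width: float = 100.0
    frame_height: float = 100.0

    def __post_init__(self) -> None:
        if self.guard_top < 0 or self.guard_bottom < 0:
            raise StereologyError("guard zones must be non-negative")
        if not self.guard_top + self.guard_bottom < self.section_thickness:
            raise StereologyError("guard zones must leave a positive dissector height")
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise StereologyError("counting frame must have positive extent")

    @property
    def height(self) -> float:
        """Dissector height h in µm."""
        return self.section_thickness - self.guard_top - self.guard_bottom

    @property
    def frame_area_mm2(self) -> float:
        return self.frame_width * self.frame_height * 1e-6

    @property
    def height_mm(self) -> float:
        return self.height * 1e-3


@dataclass
class FieldCounts:
    """Raw counts recorded in one microscopic field.

    Point counts refer to grid crosses classified by the phase under the
    cross; ``p_dermis`` counts crosses on the reference space (here every
    cross, since the whole field is dermis). ``q_minus`` is the dissector
    count ΣQ⁻ for the field; ``vessel_transects`` the number of vessel
    profiles counted in the frame, with their minor-axis widths pooled in
    ``vessel_profile_diameters``.
    """

    p_collagen: int
    p_vessel: int
    p_hair: int
    p_dermis: int
    q_minus: int
    frame_area_mm2: float
    height_mm: float
    vessel_transects: int
    vessel_profile_diameters: list[float] = field(default_factory=list)
    animal_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_collagen", "p_vessel", "p_hair", "p_dermis", "q_minus",
                     "vessel_transects"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise StereologyError(f"{name} must be a non-negative integer, got {v!r}")
        if self.p_collagen + self.p_vessel + self.p_hair > self.p_dermis:
            raise StereologyError(
                "phase point counts exceed reference count: "
                f"{self.p_collagen}+{self.p_vessel}+{self.p_hair} > {self.p_dermis}"
            )
        if not self.frame_area_mm2 > 0:
            raise StereologyError("frame_area_mm2 must be > 0")
        if not self.height_mm > 0:
            raise StereologyError("height_mm must be > 0")
        if any(d <= 0 for d in self.vessel_profile_diameters):
            raise StereologyError("profile diameters must be positive")


@dataclass
class StereologyEstimates:
    """One animal's pooled estimates, on the reporting scale.

    ``nv_fibroblast`` is in ×10³ cells/mm³; volume densities in percent;
    ``lv_vessel`` in mm/mm³; ``vessel_diameter_mean`` in µm (NaN when no
    vessel profile was measured).
    """

    animal_id: str
    group: str
    nv_fibroblast: float
    vv_collagen: float
    vv_vessel: float
    vv_hair: float
    lv_vessel: float
    vessel_diameter_mean: float
    n_fields: int


def estimate_area(total_points: int, grid: PointGrid) -> float:
    """Point-grid area estimate ``A = ΣP · a/p`` in mm²."""
    if total_points < 0:
        raise StereologyError(f"point count must be non-negative, got {total_points}")
    return total_points * grid.area_per_point


def estimate_volume_density(field_counts: list[FieldCounts], phase: str) -> float:
    """Volume density Vv(phase/dermis) as a fraction in [0, 1].

    Ratio of sums across fields: ``Σ P(phase) / Σ P(dermis)``.
    """
    if phase not in PHASES:
        raise StereologyError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if not field_counts:
        raise StereologyError("no fields supplied")
    num = sum(getattr(f, f"p_{phase}") for f in field_counts)
    den = sum(f.p_dermis for f in field_counts)
    if den == 0:
        raise StereologyError("volume density undefined: zero reference point count")
    return num / den


def estimate_numerical_density(field_counts: list[FieldCounts]) -> float:
    """Optical-dissector numerical density ``Nv = ΣQ⁻ / (ΣA · h)`` in cells/mm³.

    All fields must share the same dissector height; mixed heights would make
    the pooled denominator ill-defined.
    """
    if not field_counts:
        raise StereologyError("no fields supplied")
    heights = np.array([f.height_mm for f in field_counts])
    if not np.allclose(heights, heights[0]):
        raise StereologyError("mixed dissector heights across fields")
    total_q = sum(f.q_minus for f in field_counts)
    total_a = sum(f.frame_area_mm2 for f in field_counts)
    if not total_a > 0:
        raise StereologyError("numerical density undefined: zero total frame area")
    return total_q / (total_a * heights[0])


def estimate_length_density(field_counts: list[FieldCounts]) -> float:
    """Vessel length density ``Lv = 2 · Q_A`` in mm/mm³ (valid for IUR sections)."""
    if not field_counts:
        raise StereologyError("no fields supplied")
    total_a = sum(f.frame_area_mm2 for f in field_counts)
    if not total_a > 0:
        raise StereologyError("length density undefined: zero total frame area")
    total_q = sum(f.vessel_transects for f in field_counts)
    return 2.0 * total_q / total_a


def estimate_mean_diameter(field_counts: list[FieldCounts]) -> float:
    """Mean vessel diameter in µm: arithmetic mean of pooled profile minor axes."""
    pooled = [d for f in field_counts for d in f.vessel_profile_diameters]
    if not pooled:
        raise StereologyError("mean diameter undefined: no vessel profiles measured")
    return float(np.mean(pooled))


def summarize_animal(animal_id: str, group: str,
                     field_counts: list[FieldCounts]) -> StereologyEstimates:
    """Pool one animal's fields into a single row of estimates.

    Nv is converted to ×10³/mm³ and volume densities to percent, matching the
    usual reporting scale. When no vessel profile was transected the mean
    diameter is NaN rather than an error, so cohort summaries degrade
    gracefully.
    """
    if not field_counts:
        raise StereologyError("no fields supplied")
    nv = estimate_numerical_density(field_counts) / 1e3
    try:
        diam = estimate_mean_diameter(field_counts)
    except StereologyError:
        diam = float("nan")
    return StereologyEstimates(
        animal_id=animal_id,
        group=group,
        nv_fibroblast=nv,
        vv_collagen=100.0 * estimate_volume_density(field_counts, "collagen"),
        vv_vessel=100.0 * estimate_volume_density(field_counts, "vessel"),
        vv_hair=100.0 * estimate_volume_density(field_counts, "hair"),
        lv_vessel=estimate_length_density(field_counts),
        vessel_diameter_mean=diam,
        n_fields=len(field_counts),
    )
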