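"""Synthetic 3D dermis with analytically known densities.

The tissue model is a superposition of independent stationary processes in a
box (all lengths in µm internally):

* fibroblast nuclei — homogeneous Poisson point process at intensity Nv;
* collagen bundles  — Boolean model of equal spheres whose grain intensity is
  solved from the target volume fraction via ``Vv = 1 − exp(−λ v̄)``;
* hair follicles    — Boolean model of spheres, same construction;
* blood vessels     — isotropically oriented random line segments (capsules)
  whose intensity is solved from the target length density, radii from a
  truncated normal diameter distribution.

Phases are made mutually exclusive with precedence vessel > hair > collagen >
ground, and the Boolean intensities are pre-compensated for that masking so
the *expected classified* fraction of each phase equals its target. Grain and
segment processes are generated in a guard band around the box
("plus-sampling") so densities are stationary up to the box boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "TissueParams", "SyntheticVolume", "simulate_volume",
    "PHASE_GROUND", "PHASE_COLLAGEN", "PHASE_HAIR", "PHASE_VESSEL",
]

PHASE_GROUND = 0
PHASE_COLLAGEN = 1
PHASE_HAIR = 2
PHASE_VESSEL = 3

# mm-based user units to µm-based internal units
_MM3_TO_UM3 = 1e9
_MM_PER_MM3_TO_UM_PER_UM3 = 1e-6


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth densities of one simulated animal's dermis.

    Units follow the reporting conventions: ``nv_fibroblast`` in cells/mm³,
    volume fractions in [0, 1], ``lv_vessel`` in mm/mm³, diameters in µm,
    ``volume_extent`` in µm.
    """

    nv_fibroblast: float
    vv_collagen: float
    vv_hair: float
    lv_vessel: float
    vessel_diameter_mean: float
    vessel_diameter_sd: float
    volume_extent: tuple[float, float, float] = (500.0, 500.0, 500.0)
    seed: int = 0
    collagen_grain_radius: float = 15.0
    hair_grain_radius: float = 40.0
    vessel_length_range: tuple[float, float] = (50.0, 200.0)

    def __post_init__(self) -> None:
        if self.nv_fibroblast < 0 or self.lv_vessel < 0:
            raise ValueError("densities must be non-negative")
        if not (0 <= self.vv_collagen < 1 and 0 <= self.vv_hair < 1):
            raise ValueError("volume fractions must lie in [0, 1)")
        if self.lv_vessel > 0 and self.vessel_diameter_mean <= 0:
            raise ValueError("vessel diameter mean must be positive when vessels are present")
        if self.vessel_diameter_sd < 0:
            raise ValueError("vessel diameter sd must be non-negative")
        if any(e <= 0 for e in self.volume_extent):
            raise ValueError("volume extent must be positive")
        lo, hi = self.vessel_length_range
        if not 0 < lo <= hi:
            raise ValueError("vessel length range must satisfy 0 < lo <= hi")


def _diameter_dist(params: TissueParams):
    """Truncated-at-zero normal distribution of vessel diameters (µm)."""
    mu, sd = params.vessel_diameter_mean, params.vessel_diameter_sd
    if sd == 0:
        return None
    return stats.truncnorm((0.0 - mu) / sd, np.inf, loc=mu, scale=sd)


def _vessel_raw_fraction(params: TissueParams) -> float:
    """Expected volume fraction of the vessel capsule Boolean model."""
    if params.lv_vessel == 0:
        return 0.0
    lv_um = params.lv_vessel * _MM_PER_MM3_TO_UM_PER_UM3
    lo, hi = params.vessel_length_range
    mean_len = 0.5 * (lo + hi)
    lam_seg = lv_um / mean_len  # segments per µm³
    d = _diameter_dist(params)
    if d is None:
        e_r2 = (params.vessel_diameter_mean / 2.0) ** 2
        e_r3 = (params.vessel_diameter_mean / 2.0) ** 3
    else:
        e_r2 = d.moment(2) / 4.0
        e_r3 = d.moment(3) / 8.0
    mean_grain = math.pi * e_r2 * mean_len + (4.0 / 3.0) * math.pi * e_r3
    return 1.0 - math.exp(-lam_seg * mean_grain)


@dataclass
class SyntheticVolume:
    """Realized geometry of one synthetic dermis block.

    Coordinates in µm; the reference box is ``[0, extent]³``. Grain and
    segment lists extend into the plus-sampling guard band.
    """

    extent: tuple[float, float, float]
    fibroblast_centers: np.ndarray        # (n, 3)
    collagen_centers: np.ndarray          # (m, 3)
    collagen_radius: float
    hair_centers: np.ndarray              # (k, 3)
    hair_radius: float
    vessel_p0: np.ndarray                 # (s, 3) segment endpoints
    vessel_p1: np.ndarray                 # (s, 3)
    vessel_radii: np.ndarray              # (s,)
    params: TissueParams | None = None
    _collagen_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _hair_tree: cKDTree | None = field(default=None, repr=False, compare=False)

    # -- phase queries -----------------------------------------------------

    def _in_spheres(self, pts: np.ndarray, centers: np.ndarray, radius: float,
                    which: str) -> np.ndarray:
        if len(centers) == 0:
            return np.zeros(len(pts), dtype=bool)
        tree = getattr(self, f"_{which}_tree")
        if tree is None:
            tree = cKDTree(centers)
            object.__setattr__(self, f"_{which}_tree", tree)
        dist, _ = tree.query(pts, k=1, distance_upper_bound=radius)
        return np.isfinite(dist)

    def _in_vessels(self, pts: np.ndarray) -> np.ndarray:
        if len(self.vessel_p0) == 0:
            return np.zeros(len(pts), dtype=bool)
        hit = np.zeros(len(pts), dtype=bool)
        d = self.vessel_p1 - self.vessel_p0                        # (s, 3)
        len2 = np.einsum("ij,ij->i", d, d)
        for start in range(0, len(pts), 20000):                    # bound memory
            chunk = pts[start:start + 20000]
            w = chunk[:, None, :] - self.vessel_p0[None, :, :]     # (c, s, 3)
            t = np.clip(np.einsum("csj,sj->cs", w, d) / len2, 0.0, 1.0)
            closest = self.vessel_p0[None] + t[..., None] * d[None]
            dist = np.linalg.norm(chunk[:, None, :] - closest, axis=-1)
            hit[start:start + 20000] = (dist <= self.vessel_radii[None, :]).any(axis=1)
        return hit

    def phase_at(self, pts: np.ndarray) -> np.ndarray:
        """Classify 3D points (n, 3) into phase codes with precedence
        vessel > hair > collagen > ground."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        code = np.zeros(len(pts), dtype=np.int8)
        code[self._in_spheres(pts, self.collagen_centers, self.collagen_radius, "collagen")] = PHASE_COLLAGEN
        code[self._in_spheres(pts, self.hair_centers, self.hair_radius, "hair")] = PHASE_HAIR
        code[self._in_vessels(pts)] = PHASE_VESSEL
        return code

    # -- realized ground truth ---------------------------------------------

    def clipped_vessel_length_density(self) -> float:
        """Realized vessel centerline length inside the box per unit volume, mm/mm³."""
        if len(self.vessel_p0) == 0:
            return 0.0
        total = 0.0
        lo = np.zeros(3)
        hi = np.asarray(self.extent, dtype=float)
        for p0, p1 in zip(self.vessel_p0, self.vessel_p1):
            d = p1 - p0
            tmin, tmax = 0.0, 1.0
            ok = True
            for ax in range(3):
                if d[ax] == 0.0:
                    if not (lo[ax] <= p0[ax] <= hi[ax]):
                        ok = False
                        break
                else:
                    t0 = (lo[ax] - p0[ax]) / d[ax]
                    t1 = (hi[ax] - p0[ax]) / d[ax]
                    if t0 > t1:
                        t0, t1 = t1, t0
                    tmin, tmax = max(tmin, t0), min(tmax, t1)
            if ok and tmax > tmin:
                total += (tmax - tmin) * float(np.linalg.norm(d))
        volume = float(np.prod(self.extent))
        return (total / volume) / _MM_PER_MM3_TO_UM_PER_UM3

    def phase_fraction_mc(self, phase_code: int, n_points: int,
                          rng: np.random.Generator) -> float:
        """Monte-Carlo volume fraction of a phase by uniform point sampling."""
        pts = rng.uniform(0.0, 1.0, size=(n_points, 3)) * np.asarray(self.extent)
        return float(np.mean(self.phase_at(pts) == phase_code))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "extent": list(self.extent),
            "fibroblast_centers": self.fibroblast_centers.tolist(),
            "collagen_centers": self.collagen_centers.tolist(),
            "collagen_radius": self.collagen_radius,
            "hair_centers": self.hair_centers.tolist(),
            "hair_radius": self.hair_radius,
            "vessel_p0": self.vessel_p0.tolist(),
            "vessel_p1": self.vessel_p1.tolist(),
            "vessel_radii": self.vessel_radii.tolist(),
            "params": asdict(self.params) if self.params is not None else None,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticVolume":
        d = json.loads(text)
        params = d.get("params")
        if params is not None:
            params["volume_extent"] = tuple(params["volume_extent"])
            params["vessel_length_range"] = tuple(params["vessel_length_range"])
            params = TissueParams(**params)
        return cls(
            extent=tuple(d["extent"]),
            fibroblast_centers=np.asarray(d["fibroblast_centers"], dtype=float).reshape(-1, 3),
            collagen_centers=np.asarray(d["collagen_centers"], dtype=float).reshape(-1, 3),
            collagen_radius=float(d["collagen_radius"]),
            hair_centers=np.asarray(d["hair_centers"], dtype=float).reshape(-1, 3),
            hair_radius=float(d["hair_radius"]),
            vessel_p0=np.asarray(d["vessel_p0"], dtype=float).reshape(-1, 3),
            vessel_p1=np.asarray(d["vessel_p1"], dtype=float).reshape(-1, 3),
            vessel_radii=np.asarray(d["vessel_radii"], dtype=float),
            params=params,
        )


def _poisson_points(rng: np.random.Generator, intensity: float,
                    lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    vol = float(np.prod(hi - lo))
    n = rng.poisson(intensity * vol)
    return lo + rng.uniform(0.0, 1.0, size=(n, 3)) * (hi - lo)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform directions on the sphere (Marsaglia's method)."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        xy = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 2))
        s = np.einsum("ij,ij->i", xy, xy)
        xy = xy[s < 1.0]
        s = s[s < 1.0]
        take = min(len(xy), n - filled)
        root = np.sqrt(1.0 - s[:take])
        out[filled:filled + take, 0] = 2.0 * xy[:take, 0] * root
        out[filled:filled + take, 1] = 2.0 * xy[:take, 1] * root
        out[filled:filled + take, 2] = 1.0 - 2.0 * s[:take]
        filled += take
    return out


def simulate_volume(params: TissueParams) -> SyntheticVolume:
    """Realize one synthetic dermis block from its ground-truth densities.

    Deterministic under ``params.seed``. Raises ``ValueError`` when the
    requested fractions imply a total solid fraction ≥ 1 after accounting for
    the vessel capsules.
    """
    p_vessel = _vessel_raw_fraction(params)
    if params.vv_collagen + params.vv_hair + p_vessel >= 1.0:
        raise ValueError(
            "implied total solid fraction exceeds 1 "
            f"(collagen {params.vv_collagen} + hair {params.vv_hair} "
            f"+ vessels {p_vessel:.3f})"
        )
    # pre-compensate Boolean fractions for precedence masking so the expected
    # *classified* fraction matches the target exactly
    p_hair_raw = params.vv_hair / (1.0 - p_vessel) if params.vv_hair > 0 else 0.0
    p_col_raw = (params.vv_collagen / ((1.0 - p_vessel) * (1.0 - p_hair_raw))
                 if params.vv_collagen > 0 else 0.0)
    if p_hair_raw >= 1.0 or p_col_raw >= 1.0:
        raise ValueError("implied total solid fraction exceeds 1")

    rng = np.random.default_rng(params.seed)
    lo = np.zeros(3)
    hi = np.asarray(params.volume_extent, dtype=float)

    # fibroblast nuclei: zero-size points need no guard band
    fib = _poisson_points(rng, params.nv_fibroblast / _MM3_TO_UM3, lo, hi)

    # collagen Boolean model, guard band = one grain diameter
    r_c = params.collagen_grain_radius
    lam_c = -math.log(1.0 - p_col_raw) / ((4.0 / 3.0) * math.pi * r_c ** 3) if p_col_raw else 0.0
    col = _poisson_points(rng, lam_c, lo - 2 * r_c, hi + 2 * r_c)

    # hair follicles likewise
    r_h = params.hair_grain_radius
    lam_h = -math.log(1.0 - p_hair_raw) / ((4.0 / 3.0) * math.pi * r_h ** 3) if p_hair_raw else 0.0
    hair = _poisson_points(rng, lam_h, lo - 2 * r_h, hi + 2 * r_h)

    # vessel segment process; guard covers half the longest segment plus a
    # generous radius allowance (mean + 5 sd)
    lo_len, hi_len = params.vessel_length_range
    mean_len = 0.5 * (lo_len + hi_len)
    lam_seg = (params.lv_vessel * _MM_PER_MM3_TO_UM_PER_UM3) / mean_len
    r_guard = 0.5 * (params.vessel_diameter_mean + 5.0 * params.vessel_diameter_sd)
    g = 0.5 * hi_len + r_guard
    centers = _poisson_points(rng, lam_seg, lo - g, hi + g)
    n_seg = len(centers)
    dirs = _random_unit_vectors(rng, n_seg)
    lengths = rng.uniform(lo_len, hi_len, size=n_seg)
    diam = _diameter_dist(params)
    if diam is None:
        radii = np.full(n_seg, params.vessel_diameter_mean / 2.0)
    else:
        radii = diam.rvs(size=n_seg, random_state=rng) / 2.0

    return SyntheticVolume(
        extent=tuple(float(e) for e in params.volume_extent),
        fibroblast_centers=fib,
        collagen_centers=col,
        collagen_radius=r_c,
        hair_centers=hair,
        hair_radius=r_h,
        vessel_p0=centers - 0.5 * lengths[:, None] * dirs,
        vessel_p1=centers + 0.5 * lengths[:, None] * dirs,
        vessel_radii=radii,
        params=params,
    )
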