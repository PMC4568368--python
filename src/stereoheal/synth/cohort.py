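"""Cohort-level simulation: four treatment groups of animals with
between-animal variation in the ground-truth densities.

Per-animal truths are drawn from normal distributions at each group's mean
and SD (truncated to stay physically valid), a volume is realized per animal,
and the virtual microscope renders its field counts. The default group
parameters are the study conditions: four groups (untreated control, vehicle
gel base, and 5%/10% treatment gels) of n = 12 diabetic rats each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..estimators import DissectorSpec, FieldCounts, PointGrid
from .sectioning import iur_stack, render_field_counts
from .volume import TissueParams, simulate_volume

__all__ = ["GroupTruth", "TABLE_GROUP_TRUTHS", "simulate_animal_counts", "simulate_cohort"]


@dataclass(frozen=True)
class GroupTruth:
    """Group-level mean/SD of each ground-truth density.

    ``nv`` in cells/mm³, volume fractions in [0, 1], ``lv`` in mm/mm³,
    diameter in µm. ``diam_within_sd`` is the within-animal spread of vessel
    diameters; ``diam_sd`` the between-animal spread of the mean.
    """

    name: str
    nv: float
    nv_sd: float
    vv_collagen: float
    vv_collagen_sd: float
    vv_hair: float
    vv_hair_sd: float
    lv: float
    lv_sd: float
    diam: float
    diam_sd: float
    diam_within_sd: float = 3.1


#: Group truths at the scale of the study's summary table: fibroblast Nv in
#: the 230–455 ×10³/mm³ range, collagen Vv 47–75%, vessel Lv 14–33 mm/mm³,
#: mean vessel diameter 11–27 µm.
TABLE_GROUP_TRUTHS: dict[str, GroupTruth] = {
    "control": GroupTruth("control", 284.5e3, 32.6e3, 0.474, 0.049, 0.026, 0.012,
                          17.2, 8.1, 11.7, 3.1),
    "hp5": GroupTruth("hp5", 454.1e3, 117.61e3, 0.731, 0.092, 0.028, 0.016,
                      29.3, 6.1, 17.1, 5.5),
    "hp10": GroupTruth("hp10", 429.8e3, 37.6e3, 0.743, 0.019, 0.029, 0.012,
                       32.9, 16.6, 26.6, 9.4),
    "gel base": GroupTruth("gel base", 231.1e3, 11.9e3, 0.481, 0.047, 0.024, 0.013,
                           14.1, 1.4, 11.2, 1.8),
}


def _truncated_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    """Normal draw truncated to (lo, hi) by resampling (bounds are wide here)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo + 1e-9, hi - 1e-9))


def draw_animal_params(truth: GroupTruth, extent: tuple[float, float, float],
                       seed: int, rng: np.random.Generator) -> TissueParams:
    """One animal's ground-truth densities drawn around its group's means."""
    vv_hair = _truncated_draw(rng, truth.vv_hair, truth.vv_hair_sd, 0.0, 0.2)
    vv_col = _truncated_draw(rng, truth.vv_collagen, truth.vv_collagen_sd,
                             0.0, 0.95 - vv_hair)
    return TissueParams(
        nv_fibroblast=_truncated_draw(rng, truth.nv, truth.nv_sd, 0.0, np.inf),
        vv_collagen=vv_col,
        vv_hair=vv_hair,
        lv_vessel=_truncated_draw(rng, truth.lv, truth.lv_sd, 0.0, np.inf),
        vessel_diameter_mean=_truncated_draw(rng, truth.diam, truth.diam_sd, 1.0, np.inf),
        vessel_diameter_sd=truth.diam_within_sd,
        volume_extent=extent,
        seed=seed,
    )


def simulate_animal_counts(params: TissueParams, grid: PointGrid, spec: DissectorSpec,
                           rng: np.random.Generator, n_stacks: int = 3,
                           n_sections: int = 5, fields_per_section: int = 2,
                           animal_id: str | None = None,
                           group: str | None = None) -> list[FieldCounts]:
    """Realize one animal's volume and render its microscopic field counts.

    Several independently oriented IUR stacks are cut per animal, mirroring
    the multi-block sampling of real studies; the default design yields 30
    fields per animal (3 stacks × 5 sections × 2 fields).
    """
    volume = simulate_volume(params)
    fields: list[FieldCounts] = []
    for _ in range(n_stacks):
        stack = iur_stack(volume, spec.section_thickness, n_sections, rng, spec=spec)
        fields.extend(render_field_counts(stack, grid, spec, rng,
                                          fields_per_section=fields_per_section))
    for f in fields:
        f.animal_id = animal_id
        f.group = group
    return fields


def simulate_cohort(group_truths: dict[str, GroupTruth] | None = None,
                    n_per_group: int = 12,
                    seed: int = 0,
                    extent: tuple[float, float, float] = (500.0, 500.0, 500.0),
                    grid: PointGrid | None = None,
                    spec: DissectorSpec | None = None,
                    n_stacks: int = 3,
                    n_sections: int = 5,
                    fields_per_section: int = 2,
                    ) -> tuple[list[FieldCounts], list[TissueParams]]:
    """Simulate a full multi-group cohort and render every animal's counts.

    Returns the flat list of field counts (tagged with animal and group) and
    the per-animal ground-truth parameters, in the same animal order.
    Deterministic under ``seed``.
    """
    truths = group_truths if group_truths is not None else TABLE_GROUP_TRUTHS
    grid = grid if grid is not None else PointGrid(spacing=0.025)
    spec = spec if spec is not None else DissectorSpec()
    master = np.random.SeedSequence(seed)
    group_seqs = master.spawn(len(truths))

    all_fields: list[FieldCounts] = []
    all_params: list[TissueParams] = []
    for truth, gseq in zip(truths.values(), group_seqs):
        animal_seqs = gseq.spawn(n_per_group)
        for i, aseq in enumerate(animal_seqs):
            rng = np.random.default_rng(aseq)
            vol_seed = int(rng.integers(0, 2**31 - 1))
            params = draw_animal_params(truth, extent, vol_seed, rng)
            animal_id = f"{truth.name}-{i:02d}"
            all_fields.extend(simulate_animal_counts(
                params, grid, spec, rng, n_stacks=n_stacks,
                n_sections=n_sections, fields_per_section=fields_per_section,
                animal_id=animal_id, group=truth.name))
            all_params.append(params)
    return all_fields, all_params
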