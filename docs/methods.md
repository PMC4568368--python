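# Methods

## Scope

`stereoheal` implements the quantitative chain of a design-based
stereological wound-healing study — wound-photograph area estimation and
closure kinetics, volume/numerical/length-density estimation on tissue
sections, and nonparametric group comparison — together with a synthetic 3D
tissue generator that makes every estimator testable against exactly known
ground truth. The package makes no attempt to model diabetes physiology,
staining, or image segmentation; wound masks are assumed given, and the
microscopy layer is a geometric abstraction (counts, not images).

## Estimators

**Point-grid area.** `A = ΣP · a/p`, with `a/p = spacing²` the area
associated with each grid cross. Grids are placed systematic-uniform-random
(SUR): a fixed lattice with an offset drawn uniformly in one grid cell. SUR
placement makes the estimator unbiased for any measurable region; the test
bed demonstrates this on a rasterized disk of known area.

**Volume density.** `Vv(phase/dermis) = P(phase)/P(dermis)`, pooled across
fields as a ratio of sums, never a mean of per-field ratios: fields within an
animal share tissue and are not independent, and the ratio-of-sums form is
invariant under replicating fields — a property the suite checks directly.
Grid points are classified on the section mid-plane; with the thin (≲5 µm)
sections this emulates, overprojection through section depth is ignored.

**Numerical density (optical dissector).** `Nv = ΣQ⁻ / (ΣA · h)`, where `Q⁻`
counts nuclei coming into focus inside the counting frame within the
dissector height `h`, `ΣA` is the total frame area and `h` excludes the guard
zones ("areas of safety"; default 15 µm sections, 5 µm guards top and bottom,
so h = 5 µm). The quantity printed by stereology software is sometimes
written `ΣQ/ΣA × h`; only division by the dissector *volume* `ΣA·h` is
dimensionally a numerical density, and that reading is implemented. For the
point particles counted here (nucleus centres) the Gundersen unbiased frame
reduces exactly to half-open intervals on both frame axes; the depth interval
is half-open as well, so a tiling of dissectors counts each nucleus once.

**Length density.** The package reports vessel length density as
`Lv = 2 · Q_A`, with `Q_A` the number of vessel-profile transects per unit
section area. This identity requires isotropic uniform random (IUR) section
orientations, which the virtual sectioner honours (and which the emulated
protocol prescribes). No formula for this quantity is printed in typical
reports; `2·Q_A` is the standard design-based choice and is flagged here as a
package decision rather than a reconstruction.

**Mean vessel diameter.** The mean of per-profile *minor-axis* widths. A
plane cutting a cylinder of diameter d at any angle produces an ellipse whose
minor axis is exactly d, so the measurement is angle-independent and unbiased
for cylindrical vessels; the synthetic profiles record it exactly. Whether
any given study measured all profiles or a subsample is typically unstated;
the default measures every transected profile.

**Pooling and units.** Fields pool within animal (ratio of sums); the animal
is the statistical unit everywhere downstream. Units are fixed per column and
written in file headers: areas mm², heights mm, Nv reported in ×10³/mm³, Vv
in percent, Lv in mm/mm³, diameters in µm. Reported cells are formatted to
one decimal.

## Synthetic tissue

One animal's dermis is a box (default 0.5 mm side) carrying four independent
stationary processes, all lengths internal in µm:

* **fibroblast nuclei** — homogeneous Poisson points at intensity `Nv`;
* **collagen bundles** — Boolean model of spheres (default radius 15 µm);
  grain intensity solved from `Vv = 1 − exp(−λv̄)`;
* **hair follicles** — Boolean model of spheres (default radius 40 µm);
* **vessels** — isotropically oriented segments (capsules), lengths uniform
  in [50, 200] µm, diameters truncated-normal; segment intensity solved from
  the target length density.

Phases are mutually exclusive with precedence vessel > hair > collagen >
ground, matching the treatment of tissue fractions as disjoint. Because
masking by a higher-precedence phase would deflate the classified fraction,
the Boolean intensities are pre-compensated (`p_raw = p_target / P(not
masked)`, using independence of the processes), so the *expected classified*
fraction of each phase equals its target exactly; the calibration tests
confirm this to < 0.01 absolute. Parameter sets whose implied total solid
fraction reaches 1 are rejected.

All grain/segment processes are generated in a guard band around the box
(plus-sampling: one grain diameter for spheres; half the maximum segment
length plus a generous radius allowance for vessels), so densities are
stationary up to the box boundary and interior probes are unbiased.

**Sectioning.** Section normals are drawn uniformly on the sphere
(Marsaglia's method) and the sectioning frame is rotated, not the volume.
Sections are parallel slabs at SUR positions along the normal; several
independently oriented stacks are cut per animal (default 3), mirroring
multi-block sampling in real protocols. Fields are placed uniformly on each
section mid-plane within the erosion of the box by the oriented field-box
half-extents, so the whole counting frame × thickness box always lies inside
the volume; for stationary processes any realization-independent placement
is unbiased. Vessel transects are centerline–plane crossings inside the
frame; each contributes its exact minor-axis width.

**Wound timecourse.** Each group follows a mean relative-area path applied
multiplicatively to a per-animal initial area drawn from N(103.53, 7.11²) mm²
on the visit grid {0, 3, 6, 9, 12, 15} days. Untreated profiles (control,
vehicle) rise linearly to day 3 — +20% and +15% respectively, producing the
characteristic negative early closure — then decay exponentially; treated
profiles decay from day 0. Decay constants are solved so the mean path
reaches each group's target final closure (control 66.3%, vehicle 73.8%,
5% gel 99%, 10% gel 97%), chosen so the final-closure/elapsed-days rates
echo the published ordering and the published control/vehicle magnitudes
(≈4.42 and 4.92 %/day). Visit noise is additive N(0, 3 mm²); negative
measurements are clipped to zero and flagged.

## Closure statistics

`closure(%) = 100·(A₀ − A_t)/A₀`; negative values are preserved. The per-day
rate has no universal definition; two conventions are implemented —
final-closure/elapsed-days (default) and the OLS slope of closure vs day —
and they agree exactly on linear profiles. Published per-day rates above
100/elapsed-days (e.g. 8.61 %/day over a 15-day study) cannot arise from the
default convention, so neither convention is asserted to be the published
one; the ambiguity is deliberate and documented.

## Group statistics

Kruskal-Wallis across all groups, pairwise Mann-Whitney U for each pair,
two-sided by default, α = 0.05. The Mann-Whitney p is exact by full
enumeration of the C(n₁+n₂, n₁) group assignments when the combined sample is
≤ 12, using midranks so ties are handled exactly; larger samples use the
tie-corrected normal approximation. Degenerate all-tied data return H = 0,
p = 1. No multiple-testing correction is applied by default (each pairwise
test at 0.05, matching common practice in this literature); a Holm option
exists. Group SDs use the n−1 convention; single-animal groups report SD 0
with a degenerate-n flag.

Percent differences between group means are `100·(a − b)/b` at full
precision. For printed-style output they are *truncated* (not rounded) to two
decimals: truncation is the convention that exactly reproduces published
two-decimal percentages recomputed from their one-decimal group means, which
ordinary rounding fails to do for half of them.

## Numerical and design choices

* Monte-Carlo validation size: 400 synthetic animals at fixed study-scale
  truths. Per-animal Lv scatter is floored at ~25% CV by realized
  segment-process fluctuation in a 0.5 mm box (~17 segments), so 400 animals
  put the standard error of the mean ratio near 1%, comfortably inside the
  ±5% recovery band asserted by the tests.
* Sampling design per synthetic animal in validation: 4 stacks × 8 sections
  × 4 fields, 100 µm frame, 25 µm grid spacing — dense enough that sampling
  noise is small against the realized-process floor.
* Default pipeline sampling (3 stacks × 5 sections × 2 fields = 30 fields
  per animal) mimics a realistic workload; the number of fields per animal is
  not dictated by the emulated protocol and is a config knob.
* Degenerate inputs: zero reference point counts, empty diameter pools,
  mixed dissector heights, non-positive percent-difference baselines and
  single-visit series raise explicit errors rather than returning NaN; the
  one exception is the per-animal mean diameter, which becomes NaN when no
  vessel was transected so cohort summaries degrade gracefully.
* Determinism: every stochastic component takes a seed or Generator;
  identical `TissueParams` give bitwise-identical geometry; pipeline runs
  with the same seed and configuration produce byte-identical CSV bodies,
  and every output carries the seed and a configuration hash in its header.

## What the synthetic test bed does and does not show

Passing recovery tests show the estimator implementations are unbiased for
the geometric model that generated the data: convex grains, straight
cylindrical vessel segments, homogeneous (stationary) tissue, perfect phase
classification at a point, and error-free focal sweeps. Real histology
violates all of these to some degree — anisotropic collagen bundles, curved
tapering vessels, section compression and lost caps, classification error at
stain boundaries — so the tests validate the *estimators*, not the biology.
Known internal tension in the emulated study's reported values: a vessel
length density of 17.2 mm/mm³ with 11.7 µm mean diameter implies a vessel
volume fraction of ≈0.2%, far below the ~3.3% reported; the generator treats
Lv and diameter as the truth, and its emergent vessel Vv is accordingly
small. Raw per-animal data for the emulated study were never published, so
its per-day closure rates, group means/SDs and p-values are not reproduced
number-for-number; the percent differences implied by the published group
means are reproduced exactly, and everything else is covered by recovery and
null-calibration properties.
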