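# stereoheal

Design-based stereology of wound healing, with a synthetic ground-truth test
bed.

Quantifying tissue regeneration from histology is a 3D problem attacked with
2D sections. Design-based stereology solves it with geometric probes whose
expectations are exact: a point grid estimates areas and volume fractions, an
optical dissector counts cells per volume without size or shape bias, and
profile counts on isotropic uniform random (IUR) sections estimate the total
length of curvilinear structures such as vessels. `stereoheal` implements the
full analysis chain of a stereological wound-healing study — for the analyst
who has count tables or wound masks, and for the methodologist who wants the
estimators validated against known truth:

* **wound closure** — point-grid area `A = ΣP · a/p` from photograph masks,
  closure `100·(A₀ − A_t)/A₀` per visit and per-day closure rates;
* **volume density** — `Vv = P(phase)/P(dermis)` by point counting, pooled
  ratio-of-sums within animal;
* **numerical density** — optical dissector `Nv = ΣQ⁻/(ΣA·h)` with guard
  zones (default 15 µm sections, 5 µm "areas of safety", h = 5 µm) and an
  unbiased counting frame;
* **length density and diameter** — `Lv = 2·Q_A` on IUR sections and mean
  minor-axis profile width (the minor axis of a plane–cylinder ellipse equals
  the true diameter at any cut angle);
* **group statistics** — Kruskal-Wallis omnibus plus pairwise Mann-Whitney U
  (exact by enumeration for small samples, tie-aware), percent differences
  between group means, and a publication-style mean (SD) grid with
  significance stars;
* **synthetic tissue** — 3D dermis blocks (Poisson nuclei, Boolean collagen
  and hair-follicle grains, isotropic vessel segments) with exactly known
  Nv/Vv/Lv/diameter, a virtual microscope that renders the same counts a
  stereologist records, and a wound-trajectory generator with the early
  expansion phase typical of untreated diabetic wounds.

Every estimator is validated by Monte-Carlo recovery: simulate many animals
at fixed truths, run the virtual microscope, and check mean estimate / truth.

## Worked example

Run the numbered analyses (each regenerates its inputs' downstream tables
under `results/`):

```bash
python analysis/01_simulate_cohort.py      # 4 groups × 12 animals
python analysis/02_estimate_stereology.py
python analysis/03_wound_timecourse.py
python analysis/04_group_comparisons.py
python analysis/05_estimator_validation.py
```

`03_wound_timecourse.py` prints, for the simulated cohort:

```
initial wound area (mm², mean ± SD):
    control: 101.02 ± 6.91
   gel base: 102.50 ± 5.17
        hp5: 104.35 ± 5.99
       hp10: 102.37 ± 7.85
closure rate (%/day, final-closure / elapsed-days convention):
    control: 4.42 ± 0.21
   gel base: 4.90 ± 0.18
        hp5: 6.52 ± 0.13
       hp10: 6.44 ± 0.16
```

— all four groups start near the configured 103.53 mm² wound, the treated
groups (hp5, hp10) close ~6.5 %/day while the untreated and vehicle groups
lag at 4.4–4.9 %/day, and (visible in `results/closure.csv`) the untreated
groups show *negative* closure at day 3, the early wound expansion phase.
`04_group_comparisons.py` then prints the mean (SD) grid; a cell like
`459.9 (114.8)*` means the hp5 fibroblast numerical density (×10³/mm³)
differs from both reference groups at P < 0.05 by Mann-Whitney. The same
script shows that percent differences recomputed from a published table's
group means, truncated to two decimals, reproduce the published comparison
statements exactly (e.g. fibroblast Nv, hp5 vs control: +59.61%).

`05_estimator_validation.py` prints the Monte-Carlo recovery at fixed truths
(400 animals, 0.5 mm blocks):

```
           truth  mean_estimate   ratio  cv_between_animals
nv    284500.000    283916.3294  0.9979              0.0292
vv         0.474         0.4726  0.9971              0.0309
lv        17.200        17.2489  1.0028              0.4202
diam      11.700        11.7306  1.0026              0.1165
```

— every estimator is unbiased to well within the between-animal scatter (the
large Lv scatter is the realized vessel content of a 0.5 mm block, not
estimator noise).

The same pipeline is scriptable via the CLI:

```bash
stereoheal full --seed 7 --out results/
stereoheal simulate --config cfg.yaml --seed 7 --out out/
```

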