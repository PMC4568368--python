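"""End-to-end pipeline: simulate → estimate → timecourse → compare.

Every run writes a ``manifest.json`` carrying the seed, a hash of the
resolved configuration, the package version and the list of artifacts, so a
run can be reproduced bit-for-bit. Any stage failure removes the partial
outputs created by this run before re-raising with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimators import DissectorSpec, PointGrid, summarize_animal
from .group_stats import table1_report
from .io import (_write_csv, read_field_counts, read_wound_series,
                 write_field_counts, write_wound_series)
from .synth import (DEFAULT_WOUND_PROFILES, TABLE_GROUP_TRUTHS, simulate_cohort,
                    simulate_wound_series)
from .timecourse import closure_series, group_closure_table

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("stereoheal")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)


MODES = ("simulate", "estimate", "timecourse", "compare", "full")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the study conditions: four groups × 12 animals, 0.5 mm
    synthetic blocks, 15 µm sections with 5 µm guards, 100 µm counting frame,
    0.025 mm grid spacing, visits every 3 days to day 15.
    """

    mode: str = "full"
    out_dir: str = "results"
    seed: int = 0
    n_per_group: int = 12
    extent: tuple[float, float, float] = (500.0, 500.0, 500.0)
    grid_spacing_mm: float = 0.025
    section_thickness_um: float = 15.0
    guard_um: float = 5.0
    frame_um: float = 100.0
    n_stacks: int = 3
    n_sections: int = 5
    fields_per_section: int = 2
    rate_convention: str = "final"
    counts_path: str | None = None
    wounds_path: str | None = None
    estimates_path: str | None = None

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "extent" in data:
            data = {**data, "extent": tuple(data["extent"])}
        return cls(**data)

    def dissector(self) -> DissectorSpec:
        return DissectorSpec(section_thickness=self.section_thickness_um,
                             guard_top=self.guard_um, guard_bottom=self.guard_um,
                             frame_width=self.frame_um, frame_height=self.frame_um)

    def grid(self) -> PointGrid:
        return PointGrid(spacing=self.grid_spacing_mm)

    def hash(self) -> str:
        """Hash of the scientific configuration (paths and mode excluded, so
        the same settings give byte-identical outputs wherever they land)."""
        payload = dataclasses.asdict(self)
        for key in ("mode", "out_dir", "counts_path", "wounds_path", "estimates_path"):
            payload.pop(key)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _hdr(cfg: RunConfig) -> str:
    return f"seed={cfg.seed} config={cfg.hash()}"


def _stage_simulate(cfg: RunConfig, out: Path, created: list[Path]) -> tuple[Path, Path]:
    counts_path = out / "field_counts.csv"
    wounds_path = out / "wound_areas.csv"
    fields, _ = simulate_cohort(
        TABLE_GROUP_TRUTHS, n_per_group=cfg.n_per_group, seed=cfg.seed,
        extent=cfg.extent, grid=cfg.grid(), spec=cfg.dissector(),
        n_stacks=cfg.n_stacks, n_sections=cfg.n_sections,
        fields_per_section=cfg.fields_per_section)
    write_field_counts(fields, counts_path, header_comment=_hdr(cfg))
    created.append(counts_path)
    series = []
    wound_seq = np.random.SeedSequence([cfg.seed, 1])
    for profile, seq in zip(DEFAULT_WOUND_PROFILES.values(),
                            wound_seq.spawn(len(DEFAULT_WOUND_PROFILES))):
        series.extend(simulate_wound_series(profile, cfg.n_per_group,
                                            seed=int(seq.generate_state(1)[0] % 2**31)))
    write_wound_series(series, wounds_path, header_comment=_hdr(cfg))
    created.append(wounds_path)
    return counts_path, wounds_path


def _stage_estimate(cfg: RunConfig, counts_path: Path, out: Path,
                    created: list[Path]) -> Path:
    fields = read_field_counts(counts_path)
    by_animal: dict[tuple[str, str], list] = {}
    for f in fields:
        by_animal.setdefault((f.animal_id or "?", f.group or "?"), []).append(f)
    rows = [dataclasses.asdict(summarize_animal(a, g, fl))
            for (a, g), fl in by_animal.items()]
    est_path = out / "estimates.csv"
    _write_csv(pd.DataFrame(rows), est_path, _hdr(cfg))
    created.append(est_path)
    return est_path


def _stage_timecourse(cfg: RunConfig, wounds_path: Path, out: Path,
                      created: list[Path]) -> None:
    series = read_wound_series(wounds_path)
    records = [dataclasses.asdict(r) for s in series for r in closure_series(s)]
    closure_path = out / "closure.csv"
    _write_csv(pd.DataFrame(records), closure_path, _hdr(cfg))
    created.append(closure_path)
    tables = group_closure_table(series, convention=cfg.rate_convention)
    for name, df in tables.items():
        p = out / f"closure_{name}.csv"
        _write_csv(df, p, _hdr(cfg))
        created.append(p)


def _stage_compare(cfg: RunConfig, est_path: Path, out: Path,
                   created: list[Path]) -> None:
    from .estimators import StereologyEstimates
    df = pd.read_csv(est_path, dtype={"animal_id": str, "group": str}, comment="#")
    estimates = [StereologyEstimates(**row) for row in df.to_dict("records")]
    report = table1_report(estimates)
    for name, frame in (("table1.csv", report["formatted"]),
                        ("table1_raw.csv", report["raw"]),
                        ("comparisons.csv", report["comparisons"])):
        p = out / name
        _write_csv(frame, p, _hdr(cfg), index=name == "table1.csv")
        created.append(p)
    md_path = out / "table1.md"
    md_path.write_text(report["formatted"].to_markdown()
                       + f"\n\n<!-- {_hdr(cfg)} -->\n")
    created.append(md_path)


def run_pipeline(config: RunConfig) -> list[Path]:
    """Run the requested mode; returns the list of artifacts written."""
    if config.mode not in MODES:
        raise ValueError(f"unknown mode {config.mode!r}; expected one of {MODES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    stage = "setup"
    try:
        counts_path = Path(config.counts_path) if config.counts_path else None
        wounds_path = Path(config.wounds_path) if config.wounds_path else None
        est_path = Path(config.estimates_path) if config.estimates_path else None
        if config.mode in ("simulate", "full"):
            stage = "simulate"
            log.info("stage simulate: cohort seed=%d", config.seed)
            counts_path, wounds_path = _stage_simulate(config, out, created)
        if config.mode in ("estimate", "full"):
            stage = "estimate"
            if counts_path is None:
                raise ValueError("estimate mode needs counts_path")
            log.info("stage estimate: %s", counts_path)
            est_path = _stage_estimate(config, counts_path, out, created)
        if config.mode in ("timecourse", "full"):
            stage = "timecourse"
            if wounds_path is None:
                raise ValueError("timecourse mode needs wounds_path")
            log.info("stage timecourse: %s", wounds_path)
            _stage_timecourse(config, wounds_path, out, created)
        if config.mode in ("compare", "full"):
            stage = "compare"
            if est_path is None:
                raise ValueError("compare mode needs estimates_path")
            log.info("stage compare: %s", est_path)
            _stage_compare(config, est_path, out, created)
        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": dataclasses.asdict(config),
            "version": __version__,
            "artifacts": [str(p) for p in created],
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        created.append(manifest_path)
        return created
    except Exception as exc:
        for p in created:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
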