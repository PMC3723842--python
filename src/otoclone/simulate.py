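"""Synthetic lineage-tracing experiment generator.

Simulates the biology and the observation process end to end so every
downstream stage (PCR recovery, clone calling, summaries) can be tested
against a known ground truth:

* **Infection** — a bounded number of otocyst progenitors, each infected
  independently during a window after injection; occasional co-infection
  puts two proviruses (two tags) into one founder.
* **Integration** — the provirus integrates at the founder's first
  mitosis after infection and labels exactly one daughter, so the clone
  descends from that single labeled daughter.
* **Growth** — the labeled daughter divides with i.i.d. cell-cycle times
  until its lineage's terminal-mitosis deadline; a deadline that
  precedes any division yields a single-cell clone.  Deadlines are a
  two-point mixture (an early-exiting majority and a late tail),
  mirroring birth-dating evidence that 50-70% of otic precursors exit
  the cycle two days after injection and the remainder within four.
* **Sectioning** — each clone is assigned an anatomical region; its
  cells land on serial-section indices around the founder's section via
  a per-region integer dispersion kernel.
* **Observation noise** — proviral silencing (undetectable clones),
  per-pick PCR failure, contaminating second-lineage tags, and a small
  negative-control false-positive rate.

Time is measured in hours from injection at E11.5 (0 h); embryonic days
convert at 24 h/day, so E13.5 = +48 h and E15.5 = +96 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from otoclone.clonecall import CELL_TYPES, REGIONS, PickRecord
from otoclone.taglib import DEFAULT_DESIGN, TagLibraryDesign, library_complexity, sample_tags

#: Cell types plausibly picked in each anatomical region.
REGION_CELL_TYPES: dict[str, tuple[str, ...]] = {
    "posterior crista sensory": ("hair cell", "supporting cell"),
    "posterior crista nonsensory": ("nonsensory epithelial",),
    "anterior crista sensory": ("hair cell", "supporting cell"),
    "anterior crista nonsensory": ("nonsensory epithelial",),
    "lateral crista sensory": ("hair cell", "supporting cell"),
    "lateral crista nonsensory": ("nonsensory epithelial",),
    "organ of corti": ("hair cell", "supporting cell", "claudius"),
    "utricular macula": ("hair cell", "supporting cell", "nonsensory epithelial"),
    "saccular macula": ("hair cell", "supporting cell", "nonsensory epithelial"),
    "spiral limbus": ("interdental", "mesenchyme"),
    "stria vascularis": ("marginal", "intermediate", "basal"),
    "reissner's membrane": ("reissner's membrane cell",),
    "spiral ligament": ("nonsensory epithelial",),
    "saccule": ("nonsensory epithelial",),
    "utricle": ("nonsensory epithelial",),
    "auditory ganglion": ("neuron", "non-neuronal"),
    "vestibular ganglion": ("neuron", "non-neuronal"),
}

assert set(REGION_CELL_TYPES) == set(REGIONS)
assert all(set(v) <= CELL_TYPES for v in REGION_CELL_TYPES.values())


@dataclass
class SimulationConfig:
    """All rates and timings for the synthetic experiment.

    Times are hours after otocyst injection at E11.5; distances in
    micrometers.  Defaults encode the study conditions: infection
    completes within 24 h of injection, cell cycles run 12-18 h,
    50-70% of precursor lineages reach terminal mitosis by E13.5
    (+48 h) and all by E15.5 (+96 h), and sections are 12-14 um thick.
    """

    injection_time: float = 0.0
    infection_window: float = 24.0
    n_progenitors: int = 500
    infection_probability: float = 0.08
    coinfection_probability: float = 0.05
    cycle_time_range: tuple[float, float] = (12.0, 18.0)
    early_deadline: float = 48.0
    late_deadline: float = 96.0
    p_early_exit: float = 0.6
    silent_fraction: float = 0.05
    section_thickness: float = 14.0
    n_sections: int = 100
    dispersion_scale_by_region: dict[str, float] = field(default_factory=dict)
    default_dispersion_scale: float = 2.0
    pick_pcr_success: float = 0.52
    pick_fraction: float = 1.0
    contamination_rate: float = 0.15
    negative_pick_fraction: float = 0.2
    negative_fpr: float = 0.028
    realized_library_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "infection_probability",
            "coinfection_probability",
            "p_early_exit",
            "silent_fraction",
            "pick_pcr_success",
            "pick_fraction",
            "contamination_rate",
            "negative_pick_fraction",
            "negative_fpr",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        lo, hi = self.cycle_time_range
        if not (0 < lo <= hi):
            raise ValueError("cycle_time_range must be positive and ordered")
        if self.infection_window <= 0:
            raise ValueError("infection_window must be positive")
        if not 12.0 <= self.section_thickness <= 14.0:
            raise ValueError("section_thickness must lie in [12, 14] um")
        if self.n_progenitors < 0 or self.n_sections < 1:
            raise ValueError("n_progenitors >= 0 and n_sections >= 1 required")

    def dispersion_scale(self, region: str) -> float:
        return self.dispersion_scale_by_region.get(
            region, self.default_dispersion_scale
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if "cycle_time_range" in raw:
            raw["cycle_time_range"] = tuple(raw["cycle_time_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cycle_time_range"] = list(self.cycle_time_range)
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


@dataclass(frozen=True)
class SimCell:
    """One labeled terminal cell of a ground-truth clone."""

    cell_id: str
    region: str
    cell_type: str
    section_index: int
    tags: tuple[str, ...]
    detectable: bool


@dataclass
class GroundTruthClone:
    """A founder's labeled descendants, with their proviral tags."""

    clone_id: str
    tags: tuple[str, ...]
    infection_time: float
    integration_time: float
    deadline: float
    region: str
    cells: list[SimCell] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def detectable(self) -> bool:
        return bool(self.cells) and self.cells[0].detectable


@dataclass
class SimulatedEar:
    """Ground truth for one simulated specimen."""

    ear_id: str
    clones: list[GroundTruthClone]
    tag_collisions: list[str] = field(default_factory=list)

    @property
    def n_labeled_cells(self) -> int:
        return sum(c.size for c in self.clones)

    def to_dict(self) -> dict:
        return {
            "ear_id": self.ear_id,
            "tag_collisions": self.tag_collisions,
            "clones": [
                {
                    "clone_id": c.clone_id,
                    "tags": list(c.tags),
                    "infection_time": c.infection_time,
                    "integration_time": c.integration_time,
                    "deadline": c.deadline,
                    "region": c.region,
                    "cells": [asdict(cell) | {"tags": list(cell.tags)} for cell in c.cells],
                }
                for c in self.clones
            ],
        }


def max_divisions(integration_time: float, cycle_time: float, deadline: float) -> int:
    """Number of post-integration divisions possible before the deadline.

    ``floor((deadline - integration_time) / cycle_time)``, floored at 0.
    With integration at +24 h, an 18 h cycle, and the +96 h (E15.5)
    deadline this gives 4 — the canonical 0-4 division expectation; a
    12 h cycle over the same span permits 6.
    """
    if cycle_time <= 0:
        raise ValueError("cycle_time must be positive")
    return max(0, math.floor((deadline - integration_time) / cycle_time))


def _grow(
    birth_time: float,
    deadline: float,
    cycle_range: tuple[float, float],
    rng: np.random.Generator,
) -> int:
    """Terminal-cell count of a lineage started by one cell at ``birth_time``.

    A cell born at t draws a cycle length c and divides iff t + c is
    within the deadline; with a deterministic cycle this yields exactly
    2**max_divisions terminal cells.
    """
    lo, hi = cycle_range
    terminal = 0
    frontier = [birth_time]
    while frontier:
        t = frontier.pop()
        cycle = lo if lo == hi else rng.uniform(lo, hi)
        division = t + cycle
        if division <= deadline:
            frontier.extend((division, division))
        else:
            terminal += 1
    return terminal


def draw_deadline(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Two-point terminal-deadline mixture: early with p_early_exit, else late."""
    if rng.random() < config.p_early_exit:
        return config.early_deadline
    return config.late_deadline


def simulate_clone(
    founder_infection_time: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    deadline: float | None = None,
) -> tuple[float, float, int]:
    """Grow one clone; returns (integration_time, deadline, n_cells).

    Integration happens at the founder's first mitosis after infection
    (a fraction of one cycle later), labeling exactly one daughter; that
    daughter's lineage divides until the deadline.  A deadline that
    precedes any post-integration division leaves a single-cell clone.
    """
    lo, hi = config.cycle_time_range
    first_mitosis_delay = lo if lo == hi else rng.uniform(lo, hi)
    # the founder is at a uniformly random phase of its cycle when infected
    integration_time = founder_infection_time + rng.uniform(0.0, 1.0) * first_mitosis_delay
    if deadline is None:
        deadline = draw_deadline(config, rng)
    if deadline <= integration_time:
        return integration_time, deadline, 1
    n_cells = _grow(integration_time, deadline, config.cycle_time_range, rng)
    return integration_time, deadline, n_cells


def _founder_tags(
    config: SimulationConfig,
    realized_library: list[str] | None,
    design: TagLibraryDesign,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    n_proviruses = 2 if rng.random() < config.coinfection_probability else 1
    if realized_library is not None:
        idx = rng.integers(len(realized_library), size=n_proviruses)
        return tuple(realized_library[i] for i in idx)
    return tuple(t.sequence for t in sample_tags(design, n_proviruses, rng))


def simulate_ear(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    ear_id: str = "sim-1",
    design: TagLibraryDesign = DEFAULT_DESIGN,
) -> SimulatedEar:
    """Simulate one specimen: infection, growth, placement, detectability.

    Founder tags are drawn uniformly from the library (optionally a
    smaller realized library, for collision experiments); any tag drawn
    by two founders is logged in ``tag_collisions``.  Each clone gets a
    region uniformly over the region vocabulary; cells land on section
    indices offset from the founder's section by a rounded zero-mean
    normal kernel with per-region scale, clipped to the section range.
    A provirus is silent (never yields detectable marker) with
    probability ``silent_fraction``; a clone is undetectable only if all
    its proviruses are silent.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    realized_library = None
    if config.realized_library_size is not None:
        if config.realized_library_size > library_complexity(design):
            raise ValueError("realized library exceeds the design space")
        realized_library = [
            t.sequence
            for t in sample_tags(design, config.realized_library_size, rng)
        ]

    regions = sorted(REGIONS)
    clones: list[GroundTruthClone] = []
    seen_tags: set[str] = set()
    collisions: list[str] = []

    n_infected = rng.binomial(config.n_progenitors, config.infection_probability)
    for k in range(n_infected):
        infection_time = config.injection_time + rng.uniform(
            0.0, config.infection_window
        )
        tags = _founder_tags(config, realized_library, design, rng)
        for tag in tags:
            if tag in seen_tags:
                collisions.append(tag)
            seen_tags.add(tag)
        integration_time, deadline, n_cells = simulate_clone(
            infection_time, config, rng
        )
        region = regions[rng.integers(len(regions))]
        founder_section = int(rng.integers(config.n_sections))
        scale = config.dispersion_scale(region)
        detectable = any(
            rng.random() >= config.silent_fraction for _ in tags
        )
        type_pool = REGION_CELL_TYPES[region]
        cells = []
        for j in range(n_cells):
            offset = int(np.rint(rng.normal(0.0, scale))) if scale > 0 else 0
            section = int(np.clip(founder_section + offset, 0, config.n_sections - 1))
            cells.append(
                SimCell(
                    cell_id=f"{ear_id}-c{k:03d}-{j:03d}",
                    region=region,
                    cell_type=type_pool[rng.integers(len(type_pool))],
                    section_index=section,
                    tags=tags,
                    detectable=detectable,
                )
            )
        clones.append(
            GroundTruthClone(
                clone_id=f"{ear_id}-c{k:03d}",
                tags=tags,
                infection_time=infection_time,
                integration_time=integration_time,
                deadline=deadline,
                region=region,
                cells=cells,
            )
        )
    return SimulatedEar(ear_id=ear_id, clones=clones, tag_collisions=sorted(set(collisions)))


def simulate_picks(
    ear: SimulatedEar,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    design: TagLibraryDesign = DEFAULT_DESIGN,
) -> list[PickRecord]:
    """Observe an ear: emit marker-positive picks and negative controls.

    Each detectable cell is picked with probability ``pick_fraction``.
    A picked cell returns no product with probability
    ``1 - pick_pcr_success``; otherwise it reports multiple tags when
    co-infected or contaminated by a second lineage
    (``contamination_rate``), else its single tag.  Negative-control
    picks are emitted in proportion ``negative_pick_fraction`` of the
    positive picks and return a (spurious) product with probability
    ``negative_fpr``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    picks: list[PickRecord] = []
    counter = 0
    for clone in ear.clones:
        for cell in clone.cells:
            if not cell.detectable:
                continue
            if rng.random() >= config.pick_fraction:
                continue
            counter += 1
            pick_id = f"p{counter:05d}"
            if rng.random() >= config.pick_pcr_success:
                outcome, tag = "no_product", None
            elif len(set(cell.tags)) > 1 or rng.random() < config.contamination_rate:
                outcome, tag = "multiple_tags", None
            else:
                outcome, tag = "single_tag", cell.tags[0]
            picks.append(
                PickRecord(
                    ear_id=ear.ear_id,
                    pick_id=pick_id,
                    plap_status="positive",
                    region=cell.region,
                    cell_type=cell.cell_type,
                    section_index=cell.section_index,
                    outcome=outcome,
                    tag=tag,
                )
            )

    n_negative = int(round(config.negative_pick_fraction * counter))
    regions = sorted(REGIONS)
    for _ in range(n_negative):
        counter += 1
        if rng.random() < config.negative_fpr:
            outcome = "single_tag"
            tag = sample_tags(design, 1, rng)[0].sequence
        else:
            outcome, tag = "no_product", None
        picks.append(
            PickRecord(
                ear_id=ear.ear_id,
                pick_id=f"p{counter:05d}",
                plap_status="negative",
                region=regions[rng.integers(len(regions))],
                cell_type="indeterminate",
                section_index=int(rng.integers(config.n_sections)),
                outcome=outcome,
                tag=tag,
            )
        )
    return picks


def simulate_experiment(
    config: SimulationConfig,
    n_ears: int = 6,
    seed: int | None = None,
) -> tuple[list[SimulatedEar], list[PickRecord]]:
    """Simulate a multi-ear experiment under one config and seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ears, picks = [], []
    for i in range(n_ears):
        ear = simulate_ear(config, rng, ear_id=f"sim-{i + 1}")
        ears.append(ear)
        picks.extend(simulate_picks(ear, config, rng))
    return ears, picks


def noise_free_config(**overrides) -> SimulationConfig:
    """A config with every observation-noise channel switched off.

    Under this config the clone caller must recover the simulator's
    ground-truth partition exactly (up to logged tag collisions).
    """
    base = dict(
        silent_fraction=0.0,
        contamination_rate=0.0,
        negative_fpr=0.0,
        pick_pcr_success=1.0,
        pick_fraction=1.0,
        coinfection_probability=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
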