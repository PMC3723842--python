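"""Packaged count tables and primers from the source lineage study.

The study deposited no sequence accessions; its entire quantitative
surface is a set of printed tables, which ship here as structured,
citable fixtures:

* ``table1`` — qualitative presence of marker-positive cells per
  (region, ear) in the six analyzed specimens.
* ``table2`` — the pick/tag accounting: 655 picks, 547 positive,
  108 negative controls (3 with product), 285 positives with product,
  230 single tags vs 55 multi-tag, 195 single-cell vs 35 multicellular
  clones.
* ``table3`` — the 195 single-cell clones by region and cell type.
* ``table4`` — the 35 multicellular clones: ear, anatomy, per-type cell
  counts, and clonal spread (two rows, clones 17 and 35, print no cell
  count and are stored as unknown).
* ``primers`` — the nested-PCR primer pairs.

``fixture_picks`` renders the tables as a synthetic pick table (one
record per counted cell, per-clone distinct tags drawn under a fixed
seed, section indices consistent with each clone's printed spread) so
the whole analysis pipeline can be exercised on them.

Known internal inconsistencies of the source tables are preserved, not
silently repaired; see the notes on :data:`TABLE2` and
:func:`fixture_picks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from otoclone.clonecall import NONDISPERSED, PickRecord
from otoclone.pcr import INNER_PAIR, OUTER_PAIR, PrimerPair
from otoclone.taglib import DEFAULT_DESIGN, sample_tags

EARS = ("HJ-5", "HJ-6", "HJ-8", "HJ-9", "HJ-11", "HJ-12")


@dataclass(frozen=True)
class Table2Counts:
    """Pick/tag accounting counts.

    Note two internal inconsistencies of the source table, preserved
    as printed: the positive-with-product percentage is printed as
    51.1% although 285/547 = 52.1%; and 230 is used both as the number
    of single-tag picks and as the number of unique tags, which cannot
    both hold when 35 clones have two or more member picks.
    """

    n_picks: int = 655
    n_positive: int = 547
    n_negative: int = 108
    n_negative_with_product: int = 3
    n_positive_with_product: int = 285
    n_single_tag: int = 230
    n_multi_tag: int = 55
    n_single_cell_clones: int = 195
    n_multicellular_clones: int = 35
    printed_pct_positive_with_product: float = 51.1
    citation: str = "Table 2"


TABLE2 = Table2Counts()


@dataclass(frozen=True)
class SingleCellCloneRow:
    """One row of the single-cell-clone census (region, type, count)."""

    region: str
    cell_type: str
    count: int
    citation: str = "Table 3"


TABLE3 = (
    SingleCellCloneRow("posterior crista sensory", "hair cell", 18),
    SingleCellCloneRow("posterior crista nonsensory", "nonsensory epithelial", 15),
    SingleCellCloneRow("organ of corti", "hair cell", 10),
    SingleCellCloneRow("organ of corti", "supporting cell", 16),
    SingleCellCloneRow("organ of corti", "claudius", 13),
    SingleCellCloneRow("auditory ganglion", "neuron", 53),
    SingleCellCloneRow("spiral limbus", "interdental", 10),
    SingleCellCloneRow("spiral limbus", "mesenchyme", 10),
    SingleCellCloneRow("stria vascularis", "indeterminate", 25),
    SingleCellCloneRow("reissner's membrane", "reissner's membrane cell", 15),
    SingleCellCloneRow("saccular macula", "hair cell", 3),
    SingleCellCloneRow("saccular macula", "supporting cell", 1),
    SingleCellCloneRow("saccular macula", "nonsensory epithelial", 2),
    SingleCellCloneRow("utricular macula", "hair cell", 2),
    SingleCellCloneRow("utricular macula", "supporting cell", 1),
    SingleCellCloneRow("utricular macula", "nonsensory epithelial", 1),
)


@dataclass(frozen=True)
class CloneComposition:
    """One composition line of a multicellular-clone row.

    ``count`` is None for the two rows whose cell counts are not
    printed (clones 17 and 35); their clones expand to the minimum
    multicellular size of 2, flagged estimated.
    """

    region: str
    cell_type: str
    count: int | None


@dataclass(frozen=True)
class MulticellularCloneRow:
    """One multicellular clone: ear, composition lines, printed spread."""

    ear_id: str
    clone_number: int
    composition: tuple[CloneComposition, ...]
    spread_um: float | None  # None encodes nondispersed "(-)"
    citation: str = "Table 4"

    @property
    def size(self) -> int | None:
        """Total printed cell count, or None if any line is unknown."""
        if any(c.count is None for c in self.composition):
            return None
        return sum(c.count for c in self.composition)

    @property
    def size_estimated(self) -> int:
        """Size with unknown-count clones taken at the minimum of 2."""
        return self.size if self.size is not None else 2

    @property
    def spread(self):
        return NONDISPERSED if self.spread_um is None else self.spread_um


def _mc(ear, num, spread, *comp):
    return MulticellularCloneRow(
        ear_id=ear,
        clone_number=num,
        composition=tuple(CloneComposition(r, t, c) for (r, t, c) in comp),
        spread_um=spread,
    )


_PCS = "posterior crista sensory"
_PCN = "posterior crista nonsensory"
_OC = "organ of corti"
_AG = "auditory ganglion"
_VG = "vestibular ganglion"
_SL = "spiral limbus"
_RM = "reissner's membrane"
_SV = "stria vascularis"

TABLE4 = (
    _mc("HJ-9", 25, 84.0, (_PCS, "hair cell", 4), (_PCS, "supporting cell", 8),
        (_PCS, "indeterminate", 6)),
    _mc("HJ-6", 19, 42.0, (_PCS, "hair cell", 2), (_PCN, "nonsensory epithelial", 3)),
    _mc("HJ-6", 16, 56.0, (_PCS, "hair cell", 2), (_PCN, "nonsensory epithelial", 3)),
    _mc("HJ-5", 8, None, (_PCN, "nonsensory epithelial", 3)),
    _mc("HJ-12", 31, 56.0, (_PCS, "hair cell", 3)),
    _mc("HJ-5", 5, None, (_OC, "hair cell", 1), (_OC, "supporting cell", 1)),
    _mc("HJ-5", 1, None, (_OC, "hair cell", 2)),
    _mc("HJ-5", 4, 70.0, (_OC, "hair cell", 1), (_OC, "supporting cell", 1)),
    _mc("HJ-5", 6, 406.0, (_OC, "claudius", 4)),
    _mc("HJ-5", 3, 378.0, (_AG, "neuron", 2)),
    _mc("HJ-5", 7, 238.0, (_AG, "neuron", 3)),
    _mc("HJ-5", 9, 140.0, (_AG, "neuron", 4)),
    _mc("HJ-5", 10, 224.0, (_AG, "neuron", 6)),
    _mc("HJ-5", 11, 56.0, (_AG, "neuron", 3)),
    _mc("HJ-6", 12, 112.0, (_AG, "neuron", 2)),
    _mc("HJ-6", 13, None, (_AG, "neuron", 2)),
    _mc("HJ-6", 15, 42.0, (_AG, "neuron", 3)),
    _mc("HJ-6", 21, None, (_AG, "neuron", 2)),
    _mc("HJ-8", 22, None, (_AG, "neuron", 2)),
    _mc("HJ-11", 26, None, (_AG, "neuron", 2)),
    _mc("HJ-11", 27, 70.0, (_AG, "neuron", 4)),
    _mc("HJ-12", 33, None, (_AG, "neuron", 2)),
    _mc("HJ-12", 32, 28.0, (_AG, "neuron", 3), (_SL, "interdental", 1)),
    _mc("HJ-9", 24, 140.0, (_VG, "neuron", 4)),
    _mc("HJ-12", 29, 224.0, (_AG, "non-neuronal", 1), (_SL, "mesenchyme", 3)),
    _mc("HJ-12", 30, 210.0, (_AG, "non-neuronal", 1), (_SL, "mesenchyme", 2)),
    _mc("HJ-5", 2, 140.0, (_SL, "interdental", 4)),
    _mc("HJ-12", 28, 140.0, (_SL, "interdental", 2)),
    _mc("HJ-8", 23, None, (_SL, "mesenchyme", 2)),
    _mc("HJ-6", 14, 28.0, (_RM, "reissner's membrane cell", 2)),
    _mc("HJ-6", 20, None, (_RM, "reissner's membrane cell", 2)),
    _mc("HJ-6", 18, 42.0, (_RM, "reissner's membrane cell", 2)),
    _mc("HJ-12", 34, 84.0, (_RM, "reissner's membrane cell", 4),
        (_SV, "basal", 1), (_SV, "indeterminate", 1)),
    _mc("HJ-6", 17, 70.0, (_SV, "marginal", None)),
    _mc("HJ-12", 35, 308.0, (_SV, "intermediate", None)),
)

#: (region token, ear) -> present, transcribed from the qualitative grid.
TABLE1_PRESENCE: dict[tuple[str, str], bool] = {}


def _presence(region: str, *present_ears: str) -> None:
    for ear in EARS:
        TABLE1_PRESENCE[(region, ear)] = ear in present_ears


_presence("posterior crista sensory", *EARS)
_presence("organ of corti", "HJ-5", "HJ-6", "HJ-8", "HJ-11", "HJ-12")
_presence("anterior crista sensory", "HJ-5")
_presence("lateral crista sensory", "HJ-6")
_presence("utricular macula", "HJ-6")
_presence("saccular macula", "HJ-5")
_presence("posterior crista nonsensory", "HJ-5", "HJ-6", "HJ-9", "HJ-11", "HJ-12")
_presence("spiral limbus", "HJ-5", "HJ-6", "HJ-8", "HJ-11", "HJ-12")
_presence("stria vascularis", "HJ-5", "HJ-6", "HJ-9", "HJ-12")
_presence("reissner's membrane", "HJ-5", "HJ-6", "HJ-9", "HJ-12")
_presence("spiral ligament", "HJ-5", "HJ-6", "HJ-8")
_presence("saccule", "HJ-5", "HJ-9")
_presence("anterior crista nonsensory", "HJ-5", "HJ-12")
_presence("utricle", "HJ-6", "HJ-12")
_presence("lateral crista nonsensory", "HJ-6")
_presence("auditory ganglion", "HJ-5", "HJ-6", "HJ-8", "HJ-11", "HJ-12")
_presence("vestibular ganglion", "HJ-5", "HJ-6", "HJ-9", "HJ-12")

TABLE1_CITATION = "Table 1"


@dataclass(frozen=True)
class PaperFixture:
    """The packaged tables and primers as one typed bundle."""

    table1_presence_grid: dict = field(default_factory=lambda: dict(TABLE1_PRESENCE))
    table2_counts: Table2Counts = TABLE2
    table3_single_cell_rows: tuple = TABLE3
    table4_clone_rows: tuple = TABLE4
    outer_primers: PrimerPair = OUTER_PAIR
    inner_primers: PrimerPair = INNER_PAIR
    citation: str = "Tables 1-4; nested-PCR primer listings"


class UnknownFixtureError(KeyError):
    """Requested fixture name is not in the registry."""

    def __init__(self, name: str, available):
        self.available = sorted(available)
        super().__init__(f"unknown fixture {name!r}; available: {self.available}")


def _sample_distinct_tags(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    tags: set[str] = set()
    while len(tags) < n:
        for t in sample_tags(DEFAULT_DESIGN, n - len(tags), rng):
            tags.add(t.sequence)
    return sorted(tags)


def expand_table4_picks(
    rows=TABLE4,
    thickness_um: float = 14.0,
    seed: int = 0,
) -> list[PickRecord]:
    """Expand multicellular-clone rows into synthetic pick records.

    One pick per counted cell; per-clone distinct tags sampled under the
    given seed; section indices placed as evenly as possible across
    ``[0, spread/thickness]`` with both endpoints occupied, so the
    recomputed spread reproduces the printed value.  Unknown-count
    clones expand to the minimum multicellular size of 2.
    """
    tags = _sample_distinct_tags(len(rows), seed)
    picks: list[PickRecord] = []
    for row, tag in zip(rows, tags):
        cells: list[tuple[str, str]] = []
        for comp in row.composition:
            count = comp.count if comp.count is not None else 2
            cells.extend([(comp.region, comp.cell_type)] * count)
        span = 0 if row.spread_um is None else int(round(row.spread_um / thickness_um))
        sections = np.rint(np.linspace(0, span, len(cells))).astype(int)
        for j, ((region, cell_type), section) in enumerate(zip(cells, sections)):
            picks.append(
                PickRecord(
                    ear_id=row.ear_id,
                    pick_id=f"t4-{row.clone_number:02d}-{j:02d}",
                    plap_status="positive",
                    region=region,
                    cell_type=cell_type,
                    section_index=int(section),
                    outcome="single_tag",
                    tag=tag,
                )
            )
    return picks


def expand_full_picks(thickness_um: float = 14.0, seed: int = 0) -> list[PickRecord]:
    """Render all tables as one synthetic 655-pick table.

    Comprises the 35 multicellular clones (one pick per counted cell),
    195 single-cell clones with distinct tags, 55 multiple-tag picks,
    enough no-product positive picks to total 547 positives, and 108
    negative controls of which 3 return a spurious tag.  Ears for the
    single-cell rows are allocated round-robin (the census prints no
    ear column); multiple-tag and false-positive picks sit in the
    auditory ganglion, where nearly all were reported.

    Because the source accounting is internally inconsistent (230
    single-tag *picks* cannot yield 195 + 35 = 230 distinct *tags* when
    35 clones are multicellular), this rendering is faithful to the
    clone structure, not to the printed 285 positive-with-product pick
    count.
    """
    counts = TABLE2
    picks = expand_table4_picks(thickness_um=thickness_um, seed=seed)
    n_mc_picks = len(picks)
    singles_tags = _sample_distinct_tags(
        len(picks) + sum(r.count for r in TABLE3) + counts.n_negative_with_product,
        seed + 1,
    )
    used = {p.tag for p in picks}
    singles_tags = [t for t in singles_tags if t not in used]

    idx = 0
    k = 0
    for row in TABLE3:
        for _ in range(row.count):
            picks.append(
                PickRecord(
                    ear_id=EARS[k % len(EARS)],
                    pick_id=f"t3-{k:03d}",
                    plap_status="positive",
                    region=row.region,
                    cell_type=row.cell_type,
                    section_index=k % 40,
                    outcome="single_tag",
                    tag=singles_tags[idx],
                )
            )
            idx += 1
            k += 1

    for j in range(counts.n_multi_tag):
        picks.append(
            PickRecord(
                ear_id=EARS[j % len(EARS)],
                pick_id=f"mt-{j:03d}",
                plap_status="positive",
                region="auditory ganglion",
                cell_type="indeterminate",
                section_index=j % 40,
                outcome="multiple_tags",
            )
        )

    n_no_product = counts.n_positive - n_mc_picks - sum(r.count for r in TABLE3) - counts.n_multi_tag
    for j in range(n_no_product):
        picks.append(
            PickRecord(
                ear_id=EARS[j % len(EARS)],
                pick_id=f"np-{j:03d}",
                plap_status="positive",
                region="posterior crista sensory",
                cell_type="indeterminate",
                section_index=j % 40,
                outcome="no_product",
            )
        )

    for j in range(counts.n_negative):
        spurious = j < counts.n_negative_with_product
        picks.append(
            PickRecord(
                ear_id=EARS[j % len(EARS)],
                pick_id=f"nc-{j:03d}",
                plap_status="negative",
                region="auditory ganglion" if spurious else "posterior crista sensory",
                cell_type="indeterminate",
                section_index=j % 40,
                outcome="single_tag" if spurious else "no_product",
                tag=singles_tags[idx + j] if spurious else None,
            )
        )
    return picks


_REGISTRY = {
    "table1": lambda: dict(TABLE1_PRESENCE),
    "table2": lambda: TABLE2,
    "table3": lambda: TABLE3,
    "table4": lambda: TABLE4,
    "table4_picks": lambda: expand_table4_picks(),
    "full_picks": lambda: expand_full_picks(),
    "primers": lambda: {"outer": OUTER_PAIR, "inner": INNER_PAIR},
    "all": lambda: PaperFixture(),
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def load_fixture(name: str):
    """Return a packaged fixture by name.

    Raises
    ------
    UnknownFixtureError
        Listing the available names.
    """
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise UnknownFixtureError(name, _REGISTRY) from None
    return factory()


def mean_multicellular_clone_size(
    rows=TABLE4, include_estimated: bool = True
) -> float:
    """Average cells per multicellular clone.

    With ``include_estimated`` the two unknown-count clones enter at
    their minimum size of 2 (120 cells / 35 clones = 3.4); without
    them the mean runs over the 33 clones with printed counts.
    """
    if include_estimated:
        sizes = [r.size_estimated for r in rows]
    else:
        sizes = [r.size for r in rows if r.size is not None]
    return sum(sizes) / len(sizes)
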