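"""Clone calling from cell-pick records.

The unit of observation is a *pick*: one microdissected fragment from a
serial cryosection containing a marker-positive cell (or a
marker-negative control fragment), annotated with ear, anatomical
region, cell type, and section index, together with its nested-PCR
outcome (no product, a single sequence tag, or multiple tags).

A *clone* is the set of same-ear picks sharing one tag, inferred to
descend from one infected progenitor.  This module groups picks into
clones, estimates the negative-control false-positive rate, measures
clonal spread across serial sections, and aggregates everything into a
summary mirroring the experiment's count tables.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

__all__ = [
    "REGIONS",
    "CELL_TYPES",
    "NONDISPERSED",
    "PickRecord",
    "Clone",
    "ClonalSummary",
    "call_clones",
    "cross_ear_collision_check",
    "false_positive_rate",
    "clonal_spread",
    "summarize",
    "tag_match",
    "percent",
]

#: Canonical anatomical-region vocabulary for picks (lowercase tokens).
REGIONS = frozenset(
    {
        "posterior crista sensory",
        "posterior crista nonsensory",
        "anterior crista sensory",
        "anterior crista nonsensory",
        "lateral crista sensory",
        "lateral crista nonsensory",
        "organ of corti",
        "utricular macula",
        "saccular macula",
        "spiral limbus",
        "stria vascularis",
        "reissner's membrane",
        "spiral ligament",
        "saccule",
        "utricle",
        "auditory ganglion",
        "vestibular ganglion",
    }
)

#: Canonical cell-type vocabulary (assigned histologically upstream).
CELL_TYPES = frozenset(
    {
        "hair cell",
        "supporting cell",
        "nonsensory epithelial",
        "claudius",
        "interdental",
        "mesenchyme",
        "neuron",
        "non-neuronal",
        "marginal",
        "intermediate",
        "basal",
        "reissner's membrane cell",
        "indeterminate",
    }
)

_OUTCOMES = frozenset({"no_product", "single_tag", "multiple_tags"})


class _Nondispersed:
    """Distinguished spread value: all clone members share one section.

    Deliberately not 0 um — a clone confined to a single physical
    section gives no information about spread below one section
    thickness and is reported as "(-)" rather than as zero distance.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "(-)"

    def __reduce__(self):
        return (_Nondispersed, ())


NONDISPERSED = _Nondispersed()


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over an empty denominator (e.g. no negatives)."""


def percent(numerator: int, denominator: int) -> float:
    """Percentage from integer counts, rounded half-up to one decimal."""
    if denominator == 0:
        raise UndefinedRateError("percentage over a zero denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PickRecord:
    """One microdissected cell pick.

    Parameters
    ----------
    ear_id, pick_id
        Specimen and within-specimen identifiers.
    plap_status
        ``"positive"`` for a marker-positive cell pick, ``"negative"``
        for a control pick of unlabeled neighboring tissue.
    region, cell_type
        Anatomical annotations from the controlled vocabularies.
    section_index
        Serial-section number (>= 0) the pick was taken from.
    outcome
        Nested-PCR result: ``"no_product"``, ``"single_tag"`` or
        ``"multiple_tags"``.
    tag
        The recovered tag sequence for single-tag outcomes, else None.
    section_lost
        True when the nominal section was damaged/lost during
        sectioning; the index is preserved for spread computation.
    """

    ear_id: str
    pick_id: str
    plap_status: str
    region: str
    cell_type: str
    section_index: int
    outcome: str
    tag: str | None = None
    section_lost: bool = False

    def __post_init__(self) -> None:
        if self.plap_status not in ("positive", "negative"):
            raise ValueError(f"plap_status {self.plap_status!r} not positive/negative")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.section_index < 0:
            raise ValueError("section_index must be >= 0")
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "single_tag":
            if not self.tag:
                raise ValueError("single_tag outcome requires a tag sequence")
            object.__setattr__(self, "tag", self.tag.upper())
        elif self.tag is not None:
            raise ValueError(f"outcome {self.outcome!r} must not carry a tag")

    @property
    def is_false_positive(self) -> bool:
        """A negative-control pick that nonetheless returned a product."""
        return self.plap_status == "negative" and self.outcome != "no_product"


@dataclass(frozen=True)
class Clone:
    """Same-ear picks sharing one tag, inferred to share a progenitor."""

    ear_id: str
    tag: str
    members: tuple[PickRecord, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a clone needs at least one member")
        if any(m.ear_id != self.ear_id for m in self.members):
            raise ValueError("clone members span multiple ears")
        if any(m.tag != self.tag for m in self.members):
            raise ValueError("clone members carry differing tags")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_multicellular(self) -> bool:
        return self.size >= 2

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted({m.region for m in self.members}))

    @property
    def cell_type_counts(self) -> Counter:
        return Counter(m.cell_type for m in self.members)

    def spread_um(self, thickness_um: float = 14.0):
        """Clonal spread of the members' section indices (see clonal_spread)."""
        return clonal_spread([m.section_index for m in self.members], thickness_um)


def tag_match(tag_a: str, tag_b: str, max_mismatches: int = 0) -> bool:
    """True iff the Hamming distance between equal-length tags is within bound.

    The default ``max_mismatches=0`` is the exact-identity rule used to
    assign clonal relationships; a tolerance > 0 accommodates sequencing
    error at the cost of potentially merging distinct lineages.
    """
    if len(tag_a) != len(tag_b):
        raise ValueError(
            f"tags have unequal lengths {len(tag_a)} and {len(tag_b)}"
        )
    mismatches = sum(a != b for a, b in zip(tag_a.upper(), tag_b.upper()))
    return mismatches <= max_mismatches


def call_clones(picks: Iterable[PickRecord]) -> list[Clone]:
    """Group marker-positive single-tag picks into clones by (ear, tag).

    Multiple-tag picks cannot be assigned a lineage and are excluded
    from membership (they are still counted by :func:`summarize`);
    identical tags in different ears are never merged — see
    :func:`cross_ear_collision_check`.  Output order is deterministic:
    by ear, then by each clone's first pick ID.
    """
    groups: dict[tuple[str, str], list[PickRecord]] = defaultdict(list)
    for pick in picks:
        if pick.plap_status == "positive" and pick.outcome == "single_tag":
            groups[(pick.ear_id, pick.tag)].append(pick)
    clones = [
        Clone(ear_id=ear, tag=tag, members=tuple(members))
        for (ear, tag), members in groups.items()
    ]
    clones.sort(key=lambda c: (c.ear_id, c.members[0].pick_id))
    return clones


def cross_ear_collision_check(clones: Sequence[Clone]) -> list[str]:
    """Tags observed in more than one ear (library collisions/contamination).

    An empty list is the expected outcome for a library of ~2**24 tags
    and a few hundred draws; a nonempty list flags either a genuine
    birthday collision or cross-specimen contamination, never lineage.
    """
    ears_by_tag: dict[str, set[str]] = defaultdict(set)
    for clone in clones:
        ears_by_tag[clone.tag].add(clone.ear_id)
    return sorted(tag for tag, ears in ears_by_tag.items() if len(ears) > 1)


def false_positive_rate(picks: Iterable[PickRecord]) -> float:
    """Fraction of negative-control picks that returned a PCR product.

    Raises
    ------
    UndefinedRateError
        If there are no negative picks (the rate is undefined, not 0).
    """
    negatives = [p for p in picks if p.plap_status == "negative"]
    if not negatives:
        raise UndefinedRateError("no negative-control picks")
    return sum(p.outcome != "no_product" for p in negatives) / len(negatives)


def clonal_spread(section_indices: Sequence[int], thickness_um: float = 14.0):
    """Maximum separation of clone members perpendicular to the sections.

    Returns ``(max(index) - min(index)) * thickness_um`` in micrometers;
    members three 14-um sections apart are spread by 42 um.  When every
    member lies in the same section the distinguished
    :data:`NONDISPERSED` value is returned (rendered ``"(-)"``), not
    0 um.
    """
    indices = list(section_indices)
    if not indices:
        raise ValueError("at least one section index is required")
    if thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    span = max(indices) - min(indices)
    if span == 0:
        return NONDISPERSED
    return span * thickness_um


@dataclass
class CloneRow:
    """One summary row per clone: anatomy, composition, and dispersion."""

    ear_id: str
    tag: str
    size: int
    regions: tuple[str, ...]
    cell_types: dict[str, int]
    spread_um: object  # float um or NONDISPERSED

    @property
    def spread_display(self) -> str:
        if self.spread_um is NONDISPERSED:
            return "(-)"
        return f"{self.spread_um:g}"


@dataclass
class ClonalSummary:
    """Pipeline accounting: pick counts, tag outcomes, and clone structure.

    All percentages are recomputed from the integer counts (never
    copied from a source table) with half-up rounding to one decimal.
    Fractions over empty denominators are ``None`` and listed in
    ``undefined_fractions``.
    """

    n_picks: int
    n_positive: int
    n_negative: int
    n_negative_with_product: int
    n_positive_with_product: int
    n_single_tag: int
    n_multi_tag: int
    n_single_cell_clones: int
    n_multicellular_clones: int
    clone_rows: list[CloneRow] = field(default_factory=list)
    presence_grid: dict[tuple[str, str], bool] = field(default_factory=dict)
    cross_ear_collisions: list[str] = field(default_factory=list)

    def _pct(self, num: int, den: int) -> float | None:
        try:
            return percent(num, den)
        except UndefinedRateError:
            return None

    @property
    def pct_positive(self) -> float | None:
        return self._pct(self.n_positive, self.n_picks)

    @property
    def pct_negative(self) -> float | None:
        return self._pct(self.n_negative, self.n_picks)

    @property
    def fpr(self) -> float | None:
        """Negative-control false-positive rate, as a fraction in [0, 1]."""
        if self.n_negative == 0:
            return None
        return self.n_negative_with_product / self.n_negative

    @property
    def pct_fpr(self) -> float | None:
        return self._pct(self.n_negative_with_product, self.n_negative)

    @property
    def pct_positive_with_product(self) -> float | None:
        return self._pct(self.n_positive_with_product, self.n_positive)

    @property
    def pct_single_tag(self) -> float | None:
        return self._pct(self.n_single_tag, self.n_positive_with_product)

    @property
    def pct_multi_tag(self) -> float | None:
        return self._pct(self.n_multi_tag, self.n_positive_with_product)

    @property
    def n_clones(self) -> int:
        return self.n_single_cell_clones + self.n_multicellular_clones

    @property
    def pct_single_cell(self) -> float | None:
        return self._pct(self.n_single_cell_clones, self.n_clones)

    @property
    def pct_multicellular(self) -> float | None:
        return self._pct(self.n_multicellular_clones, self.n_clones)

    @property
    def undefined_fractions(self) -> list[str]:
        names = [
            "pct_positive",
            "pct_negative",
            "pct_fpr",
            "pct_positive_with_product",
            "pct_single_tag",
            "pct_multi_tag",
            "pct_single_cell",
            "pct_multicellular",
        ]
        return [n for n in names if getattr(self, n) is None]

    @classmethod
    def from_counts(
        cls,
        n_picks: int,
        n_positive: int,
        n_negative: int,
        n_negative_with_product: int,
        n_positive_with_product: int,
        n_single_tag: int,
        n_multi_tag: int,
        n_single_cell_clones: int,
        n_multicellular_clones: int,
    ) -> "ClonalSummary":
        """Build a summary directly from tabulated counts (no pick records)."""
        return cls(
            n_picks=n_picks,
            n_positive=n_positive,
            n_negative=n_negative,
            n_negative_with_product=n_negative_with_product,
            n_positive_with_product=n_positive_with_product,
            n_single_tag=n_single_tag,
            n_multi_tag=n_multi_tag,
            n_single_cell_clones=n_single_cell_clones,
            n_multicellular_clones=n_multicellular_clones,
        )

    def to_dict(self) -> dict:
        """JSON-serializable rendering (spread as number or null)."""
        return {
            "counts": {
                "n_picks": self.n_picks,
                "n_positive": self.n_positive,
                "n_negative": self.n_negative,
                "n_negative_with_product": self.n_negative_with_product,
                "n_positive_with_product": self.n_positive_with_product,
                "n_single_tag": self.n_single_tag,
                "n_multi_tag": self.n_multi_tag,
                "n_single_cell_clones": self.n_single_cell_clones,
                "n_multicellular_clones": self.n_multicellular_clones,
            },
            "percentages": {
                "positive": self.pct_positive,
                "negative": self.pct_negative,
                "false_positive_rate": self.pct_fpr,
                "positive_with_product": self.pct_positive_with_product,
                "single_tag": self.pct_single_tag,
                "multi_tag": self.pct_multi_tag,
                "single_cell_clones": self.pct_single_cell,
                "multicellular_clones": self.pct_multicellular,
            },
            "clones": [
                {
                    "ear_id": row.ear_id,
                    "tag": row.tag,
                    "size": row.size,
                    "regions": list(row.regions),
                    "cell_types": dict(row.cell_types),
                    "spread_um": None if row.spread_um is NONDISPERSED else row.spread_um,
                }
                for row in self.clone_rows
            ],
            "presence_grid": [
                {"ear_id": ear, "region": region, "present": present}
                for (ear, region), present in sorted(self.presence_grid.items())
            ],
            "cross_ear_collisions": self.cross_ear_collisions,
            "undefined_fractions": self.undefined_fractions,
        }

    def render_text(self) -> str:
        """Aligned-text panel mirroring the pick/tag accounting table."""
        def fmt(pct):
            return "na" if pct is None else f"{pct:.1f}"

        lines = [
            "Description                                         Quantity  Percentage",
            f"Number of marker+ and marker- cell picks            {self.n_picks:8d}  na",
            f"  Marker+ cell picks                                {self.n_positive:8d}  {fmt(self.pct_positive)}",
            f"  Marker- cell picks                                {self.n_negative:8d}  {fmt(self.pct_negative)}",
            f"Marker- picks that returned a sequence tag          {self.n_negative_with_product:8d}  {fmt(self.pct_fpr)}",
            f"Marker+ picks that returned one or more tags        {self.n_positive_with_product:8d}  {fmt(self.pct_positive_with_product)}",
            f"  Single sequence tags                              {self.n_single_tag:8d}  {fmt(self.pct_single_tag)}",
            f"  Multiple sequence tags                            {self.n_multi_tag:8d}  {fmt(self.pct_multi_tag)}",
            "Distribution of single and multicellular clones:",
            f"  Single cell clones                                {self.n_single_cell_clones:8d}  {fmt(self.pct_single_cell)}",
            f"  Clones with 2 or more cells                       {self.n_multicellular_clones:8d}  {fmt(self.pct_multicellular)}",
        ]
        return "\n".join(lines)


def summarize(
    picks: Sequence[PickRecord],
    clones: Sequence[Clone] | None = None,
    thickness_um: float = 14.0,
) -> ClonalSummary:
    """Aggregate picks (and their called clones) into a :class:`ClonalSummary`.

    The presence grid scores a (region, ear) cell as present when two or
    more marker-positive picks were made there.  An empty pick set
    yields an all-zero summary whose fractions are flagged undefined
    rather than raising.
    """
    picks = list(picks)
    if clones is None:
        clones = call_clones(picks)

    positives = [p for p in picks if p.plap_status == "positive"]
    negatives = [p for p in picks if p.plap_status == "negative"]
    n_pos_product = sum(p.outcome != "no_product" for p in positives)
    n_single = sum(p.outcome == "single_tag" for p in positives)
    n_multi = sum(p.outcome == "multiple_tags" for p in positives)

    rows = [
        CloneRow(
            ear_id=c.ear_id,
            tag=c.tag,
            size=c.size,
            regions=c.regions,
            cell_types=dict(c.cell_type_counts),
            spread_um=c.spread_um(thickness_um),
        )
        for c in clones
    ]

    grid_counts: Counter = Counter(
        (p.ear_id, p.region) for p in positives
    )
    ears = sorted({p.ear_id for p in picks})
    grid = {
        (ear, region): grid_counts.get((ear, region), 0) >= 2
        for ear in ears
        for region in sorted(REGIONS)
    }

    return ClonalSummary(
        n_picks=len(picks),
        n_positive=len(positives),
        n_negative=len(negatives),
        n_negative_with_product=sum(p.outcome != "no_product" for p in negatives),
        n_positive_with_product=n_pos_product,
        n_single_tag=n_single,
        n_multi_tag=n_multi,
        n_single_cell_clones=sum(not c.is_multicellular for c in clones),
        n_multicellular_clones=sum(c.is_multicellular for c in clones),
        clone_rows=rows,
        presence_grid=grid,
        cross_ear_collisions=cross_ear_collision_check(clones),
    )
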