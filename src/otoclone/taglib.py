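"""Degenerate oligonucleotide tag-library model.

The lineage vector carries a short degenerate cassette built from a
repeated unit of per-position base alternatives — by default
``[(G or C)(A or T)]`` repeated 12 times, giving 24-nt tags and a design
space of 4**12 = 16,777,216 distinct sequences.  Because two independently
infected progenitors essentially never draw the same tag from a library
this complex, tag identity between picked cells is evidence of shared
lineage.  This module provides the design object, tag validation,
uniform sampling, and the birthday-collision statistics that quantify
"essentially never".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

_BASES = frozenset("ACGT")


class InvalidDesignError(ValueError):
    """The library design is malformed (e.g. an empty allowed-base set)."""


class MalformedSequenceError(ValueError):
    """A putative tag contains characters outside A/C/G/T."""


def _parse_pattern(pattern: str) -> tuple[frozenset[str], ...]:
    """Expand an IUPAC pattern string (e.g. ``"SW"``) into allowed-base sets."""
    sets = []
    for code in pattern.upper():
        try:
            bases = ambiguous_dna_values[code]
        except KeyError:
            raise InvalidDesignError(f"unknown IUPAC code {code!r} in pattern")
        sets.append(frozenset(bases))
    return tuple(sets)


@dataclass(frozen=True)
class TagLibraryDesign:
    """The degenerate repeat pattern defining the space of legal tags.

    Parameters
    ----------
    unit_pattern
        Ordered per-position allowed-base sets for one repeat unit.
        Default ``({G, C}, {A, T})``, the IUPAC pattern "SW".
    repeat_count
        Number of unit repeats; the default 12 yields 24-nt tags.
    """

    unit_pattern: tuple[frozenset[str], ...] = field(
        default=(frozenset("GC"), frozenset("AT"))
    )
    repeat_count: int = 12

    def __post_init__(self) -> None:
        if self.repeat_count < 0:
            raise InvalidDesignError("repeat_count must be nonnegative")
        if not isinstance(self.unit_pattern, tuple):
            object.__setattr__(self, "unit_pattern", tuple(
                frozenset(s) for s in self.unit_pattern
            ))
        for pos, allowed in enumerate(self.unit_pattern):
            if not allowed:
                raise InvalidDesignError(f"empty allowed-base set at unit position {pos}")
            if not frozenset(allowed) <= _BASES:
                raise InvalidDesignError(
                    f"allowed set {sorted(allowed)} at unit position {pos} "
                    "is not a subset of A/C/G/T"
                )

    @classmethod
    def from_pattern(cls, pattern: str = "SW", repeat_count: int = 12) -> "TagLibraryDesign":
        """Build a design from an IUPAC pattern string, e.g. ``("SW", 12)``."""
        return cls(unit_pattern=_parse_pattern(pattern), repeat_count=repeat_count)

    @property
    def tag_length(self) -> int:
        return self.repeat_count * len(self.unit_pattern)

    def allowed_at(self, position: int) -> frozenset[str]:
        """Allowed bases at absolute tag position (repeat-wise indexing)."""
        return self.unit_pattern[position % len(self.unit_pattern)]

    def enumerate_tags(self) -> Iterable[str]:
        """Exhaustively generate every legal tag (use only for small designs)."""
        import itertools

        pools = [sorted(self.allowed_at(i)) for i in range(self.tag_length)]
        for combo in itertools.product(*pools):
            yield "".join(combo)


DEFAULT_DESIGN = TagLibraryDesign()


@dataclass(frozen=True)
class Tag:
    """A single tag sequence validated against a library design.

    Sequences compare case-insensitively and are stored uppercase.
    """

    sequence: str
    design: TagLibraryDesign = DEFAULT_DESIGN

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not validate_tag(self.design, seq):
            raise ValueError(f"sequence {seq!r} is not legal under the design")

    def __str__(self) -> str:
        return self.sequence


def library_complexity(design: TagLibraryDesign) -> int:
    """Number of distinct legal tags: the product of allowed-set sizes.

    For the default ``[(G|C)(A|T)] x 12`` design this is
    4**12 = 16,777,216 — the "approximately 10^7 unique sequence tags"
    complexity that underwrites clone calling by tag identity.
    """
    per_unit = math.prod(len(s) for s in design.unit_pattern)
    return per_unit ** design.repeat_count


def validate_tag(design: TagLibraryDesign, sequence: str) -> bool:
    """True iff ``sequence`` has the design's length and per-position bases.

    Raises
    ------
    MalformedSequenceError
        If the sequence contains non-A/C/G/T characters (distinct from a
        well-formed sequence that merely violates the design).
    """
    seq = sequence.upper()
    if not set(seq) <= _BASES:
        bad = sorted(set(seq) - _BASES)
        raise MalformedSequenceError(f"non-ACGT characters {bad} in sequence")
    if len(seq) != design.tag_length:
        return False
    return all(base in design.allowed_at(i) for i, base in enumerate(seq))


def sample_tags(
    design: TagLibraryDesign,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> list[Tag]:
    """Draw ``n`` tags independently and uniformly over legal tags.

    Each position is sampled uniformly from its allowed set, which is
    equivalent to a uniform draw over the full library (an idealization:
    the physical library's per-tag abundance skew is not modeled).
    Reproducible given a seed; an existing Generator may be passed to
    share a random stream.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pools = [sorted(design.allowed_at(i)) for i in range(design.tag_length)]
    tags = []
    for _ in range(n):
        seq = "".join(pool[rng.integers(len(pool))] for pool in pools)
        tags.append(Tag(seq, design))
    return tags


def collision_probability(
    n_draws: int, library_size: int, method: str = "exact"
) -> float:
    """Probability that at least two of ``n_draws`` uniform draws coincide.

    ``method="exact"`` evaluates the birthday product
    ``1 - prod_{i<n}(1 - i/N)``; ``method="poisson"`` uses the matched
    approximation ``1 - exp(-C(n,2)/N)``.  With 230 draws from the
    default 2**24-tag library the exact value is ~1.6e-3, consistent
    with observing zero cross-location tag repeats.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be nonnegative")
    if library_size < 1:
        raise ValueError("library_size must be positive")
    if n_draws <= 1:
        return 0.0
    if method == "poisson":
        return float(1.0 - math.exp(-math.comb(n_draws, 2) / library_size))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n_draws > library_size:
        return 1.0  # pigeonhole
    # log-space product for numerical robustness at large n
    log_no_collision = sum(
        math.log1p(-i / library_size) for i in range(n_draws)
    )
    return float(min(1.0, max(0.0, -math.expm1(log_no_collision))))


def expected_pairwise_collisions(n_draws: int, library_size: int) -> float:
    """Expected number of coincident pairs among the draws: C(n,2)/N."""
    if n_draws < 0:
        raise ValueError("n_draws must be nonnegative")
    if library_size < 1:
        raise ValueError("library_size must be positive")
    return math.comb(n_draws, 2) / library_size


def tags_to_fasta(tags: Sequence[Tag], ids: Sequence[str], path) -> None:
    """Write tags as FASTA records (one per tag, record ID = pick/clone ID)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    if len(tags) != len(ids):
        raise ValueError("tags and ids must have equal length")
    records = [SeqRecord(Seq(t.sequence), id=i, description="") for t, i in zip(tags, ids)]
    SeqIO.write(records, path, "fasta")


def tags_from_fasta(path, design: TagLibraryDesign = DEFAULT_DESIGN) -> dict[str, Tag]:
    """Read tags from FASTA, validating each against the design."""
    from Bio import SeqIO

    return {rec.id: Tag(str(rec.seq), design) for rec in SeqIO.parse(path, "fasta")}
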