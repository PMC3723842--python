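"""In-silico nested PCR for tag recovery.

The 24-nt tag is recovered from a picked cell by two sequential
amplifications: an outer primer pair on the proviral template, then an
inner pair on the outer product.  The inner product runs at 160 bp on a
gel, and the tag sits at a fixed offset inside it.  This module provides
exact-match primer-site search, amplicon extraction, and tag pull-out,
plus a reference template builder used throughout the test suite.

Primer matching is exact (zero mismatches): the nested design makes
spurious exact double-hits negligible, and no mismatch tolerance is part
of the protocol being modeled.

The vector sequence between primer sites is proprietary to the physical
construct and is not modeled; the packaged flanks below are synthetic
constants sized so that the inner amplicon is exactly
25 + 43 + 24 + 43 + 25 = 160 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from otoclone.taglib import DEFAULT_DESIGN, Tag, TagLibraryDesign, validate_tag

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, each written 5'->3' on its own strand."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not set(seq.upper()) <= _BASES:
                raise ValueError(f"primer {seq!r} contains non-ACGT characters")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


# The published nested-PCR primers for the tag cassette.
BOLAP5 = "CCAGGGACTGCAGGTTGTGCCCTGT"
BOLAP6 = "AGACACACATTCCACAGGGTCGAAG"
BOLAP7 = "GGCTGCCTGCACCCCAGGAAAGGAG"
BOLAP8 = "GGTCTCGGAAGCCCTCAGCCCAGTC"

OUTER_PAIR = PrimerPair(BOLAP5, BOLAP6, name="outer (BOLAP5/6)")
INNER_PAIR = PrimerPair(BOLAP7, BOLAP8, name="inner (BOLAP7/8)")

# Synthetic flanks (43 nt each) between the inner primer sites and the tag
# cassette, chosen once so that no primer site recurs anywhere in an
# assembled template; they stand in for unpublished vector sequence.
INNER_FLANK_5 = "TACAATTAGGGAGCTTGTCGATAGGGGTGCTAGACTGGAAATC"
INNER_FLANK_3 = "TCCGTTGTCCACATGTCTTCATTTAATTCCCCGGTAGACTTTT"
# Synthetic spacers between the outer primer sites and the inner amplicon.
OUTER_SPACER_5 = "CTGCCCACGTCGGCGGAGAG"
OUTER_SPACER_3 = "TACGGTAAAAGCCACGGGGG"

#: Offset of the tag cassette within the inner amplicon (primer + 5' flank).
TAG_OFFSET = len(BOLAP7) + len(INNER_FLANK_5)
#: Expected inner amplicon length for a 24-nt tag.
INNER_AMPLICON_LENGTH = (
    len(BOLAP7) + len(INNER_FLANK_5) + 24 + len(INNER_FLANK_3) + len(BOLAP8)
)


class AmbiguousTemplateError(ValueError):
    """Multiple candidate amplification products exist on one template.

    Carries every candidate product; surfaced upstream as a
    multiple-tag pick.
    """

    def __init__(self, products: list[str]):
        self.products = products
        super().__init__(
            f"{len(products)} candidate products from multiple primer sites"
        )


class NoProductError(RuntimeError):
    """An amplification round produced no product (missing/misordered site)."""

    def __init__(self, round_number: int, message: str = ""):
        self.round_number = round_number
        super().__init__(
            message or f"no amplification product in PCR round {round_number}"
        )


class InvalidTagError(ValueError):
    """The extracted cassette is not a legal tag under the library design."""

    def __init__(self, message: str, bad_positions: list[int] | None = None):
        self.bad_positions = bad_positions or []
        super().__init__(message)


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1:
            return hits
        hits.append(idx)
        start = idx + 1


def find_amplicon(template: str, pair: PrimerPair) -> str | None:
    """Locate the product of ``pair`` on ``template`` by exact-match search.

    The forward primer must match the given strand and the reverse
    primer's reverse complement must occur downstream; the returned
    amplicon spans both primer sites inclusively.  Returns ``None`` when
    either site is absent or the sites are misordered.

    Raises
    ------
    AmbiguousTemplateError
        If more than one (forward, reverse) site combination yields a
        product; the error lists all candidates.
    """
    template = template.upper()
    fwd_hits = _find_all(template, pair.forward)
    rev_site = reverse_complement(pair.reverse)
    rev_hits = _find_all(template, rev_site)

    products = []
    for f in fwd_hits:
        for r in rev_hits:
            if r >= f + len(pair.forward):
                products.append(template[f : r + len(rev_site)])
    if not products:
        return None
    if len(products) > 1:
        raise AmbiguousTemplateError(products)
    return products[0]


def nested_pcr(
    template: str,
    outer_pair: PrimerPair = OUTER_PAIR,
    inner_pair: PrimerPair = INNER_PAIR,
) -> str:
    """Two-round amplification: outer pair on the template, inner on round 1.

    Raises
    ------
    NoProductError
        With ``round_number`` 1 or 2 identifying the failed round.
    AmbiguousTemplateError
        If either round finds multiple candidate products (e.g. a pick
        containing two proviruses); callers treat this as a
        multiple-tag observation.
    """
    round1 = find_amplicon(template, outer_pair)
    if round1 is None:
        raise NoProductError(1)
    round2 = find_amplicon(round1, inner_pair)
    if round2 is None:
        raise NoProductError(2)
    return round2


def extract_tag(
    amplicon: str,
    design: TagLibraryDesign = DEFAULT_DESIGN,
    offset: int = TAG_OFFSET,
) -> Tag:
    """Pull the tag cassette from an inner amplicon at its fixed offset.

    Raises
    ------
    InvalidTagError
        If the amplicon is too short, or the cassette violates the
        design (the error reports the offending positions).
    """
    amplicon = amplicon.upper()
    end = offset + design.tag_length
    if len(amplicon) < end:
        raise InvalidTagError(
            f"amplicon length {len(amplicon)} < cassette end {end}"
        )
    cassette = amplicon[offset:end]
    bad = [
        i
        for i, base in enumerate(cassette)
        if base not in design.allowed_at(i)
    ]
    if bad:
        raise InvalidTagError(
            f"cassette {cassette!r} violates the design at positions {bad}",
            bad_positions=bad,
        )
    return Tag(cassette, design)


def build_template(tag: Tag | str, design: TagLibraryDesign = DEFAULT_DESIGN) -> str:
    """Assemble a synthetic proviral template carrying ``tag``.

    Layout 5'->3': outer-forward site, spacer, inner-forward site,
    5' flank, tag cassette, 3' flank, reverse complement of the inner
    reverse site, spacer, reverse complement of the outer reverse site.
    The inner amplicon of this template is exactly 160 nt.
    """
    sequence = tag.sequence if isinstance(tag, Tag) else Tag(tag, design).sequence
    inner = BOLAP7 + INNER_FLANK_5 + sequence + INNER_FLANK_3 + reverse_complement(BOLAP8)
    return BOLAP5 + OUTER_SPACER_5 + inner + OUTER_SPACER_3 + reverse_complement(BOLAP6)


def recover_tag(template: str, design: TagLibraryDesign = DEFAULT_DESIGN) -> Tag:
    """Convenience: nested PCR followed by tag extraction."""
    return extract_tag(nested_pcr(template), design)
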