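# Methods

## Tag library model

The degenerate cassette is an ordered repeat of per-position allowed-base
sets, default `[(G|C)(A|T)]` repeated 12 times (IUPAC "SW" × 12), giving
24-nt tags and a design space of `(2·2)¹² = 2²⁴ = 16,777,216` sequences.
Draws are modeled as independent and uniform over legal tags: each
position samples uniformly from its allowed set.  The physical library's
per-tag abundance skew is not modeled — no abundance data exist for it —
so collision probabilities computed here are lower bounds with respect
to any skewed reality.  Because the realized complexity of a physical
library can fall short of the design space, a `realized_library_size`
can be set in the simulator to draw founder tags from a smaller sampled
library.

Collision statistics use the exact birthday product
`P = 1 − ∏_{i<n}(1 − i/N)`, evaluated in log space
(`Σ log1p(−i/N)`, then `−expm1`) for robustness at large `n`, with the
Poisson approximation `1 − exp(−C(n,2)/N)` exposed separately.  For
`n > N` the exact value is 1 by pigeonhole.  Tags compare
case-insensitively and are stored uppercase.

## In-silico nested PCR

Primer matching is exact-match string search: the forward primer on the
given strand, the reverse primer as its reverse complement strictly
downstream; the amplicon spans both sites inclusively.  No thermodynamic
modeling (melting temperature, hairpins, cycle efficiency) is attempted
— the nested two-round design makes spurious exact double-hits
negligible, and product *identity*, not yield, is what the analysis
consumes.  Multiple candidate (forward, reverse) site combinations raise
an ambiguous-template error carrying all candidates; upstream this is
interpreted as a multiple-tag pick.  Failures distinguish round 1
(outer pair found no product) from round 2.

The published construct's inter-primer geometry is not public.  The
packaged template layout places synthetic 43-nt flanks (fixed arbitrary
constants of this repository, screened so that no primer site recurs)
between the inner primer sites and the cassette, so the inner amplicon
is exactly `25 + 43 + 24 + 43 + 25 = 160` nt — the product length the
experiment verifies on a gel — with the tag at offset 68.  Sequencing
is modeled as error-free by default; the clone caller's
`tag_match(…, max_mismatches)` provides Hamming-distance tolerance for
workflows that inject a per-base substitution error.

## Clone calling

Clones are the equivalence classes of marker-positive single-tag picks
under exact tag identity *within one ear*.  Identical tags in different
ears are never merged: cross-specimen identity is evidence of library
collision or contamination, not lineage, and is surfaced by
`cross_ear_collision_check`.  Multiple-tag picks are counted but
excluded from clone membership, since no single lineage can be
assigned.  Clone ordering is deterministic (ear, then first pick ID).

The false-positive rate is the fraction of negative-control picks
returning any product; with zero negative picks the rate is an error,
never silently 0.

**Clonal spread** is `(max − min section index) × thickness` µm,
measured perpendicular to the plane of section.  This convention
reproduces both published worked examples (3 sections → 42 µm,
29 sections → 406 µm).  A clone confined to one section returns a
distinguished *nondispersed* token rather than 0 µm: the measurement
has no resolution below one section thickness.  One published clone row
is internally ambiguous under any fixed convention ("18 cells in six
serial sections" with spread 84 µm = 6 × 14); the fixture stores the
printed spread and the expansion places cells to reproduce it, without
forcing the prose's section count.  Thickness defaults to 14 µm (both
worked examples use 14) but is a per-call parameter since sectioning
ran 12–14 µm.  Lost sections (reported rate < 1%) keep their nominal
indices with a flag; spread uses nominal indices.

Percentages in summaries are always recomputed from integer counts with
half-up rounding to one decimal, never transcribed.  Two
inconsistencies of the source accounting are therefore *preserved and
flagged* rather than repaired: the positive-with-product percentage
prints as 51.1% where 285/547 = 52.1%; and 230 is printed both as the
number of single-tag picks and as the number of distinct tags, which
cannot both hold when 35 clones have ≥ 2 member picks.  Consequently
the full synthetic pick rendering of the tables
(`fixtures.expand_full_picks`) is faithful to the *clone structure*
(195 single-cell + 35 multicellular clones, 655 total picks, 108
negatives with 3 spurious products) and not to the printed 285
positive-with-product pick count.  Count-level accounting uses
`ClonalSummary.from_counts` on the table's own integers.

The per-(region, ear) presence grid scores a cell as present when two
or more marker-positive picks were made there, matching the qualitative
census convention.

## Fixture expansion

The multicellular-clone table expands to one synthetic pick per counted
cell.  Per-clone tags are distinct draws from the default library under
a fixed seed (expansion is byte-deterministic given the seed).  Section
indices are placed as evenly as possible across `[0, spread/thickness]`
with both endpoints occupied, so re-measuring spread reproduces the
printed value; only the min/max separation is published, so the interior
placement is a modeling choice.  The two rows that print no cell count
(clones 17 and 35) expand to the minimum multicellular size of 2,
flagged estimated and excluded from known-size assertions.  The mean
multicellular clone size is reported two ways: over all 35 clones with
the minimum-size estimates (120/35 = 3.4, matching the published
average) and over the 33 clones with printed counts (116/33 ≈ 3.5).
The single-cell-clone census prints no ear column, so its 195 picks are
allocated round-robin across the six specimens; multiple-tag picks and
the three spurious negative products are placed in the auditory
ganglion, where nearly all were reported.

## Simulator

The generator reproduces the experiment's causal chain with times in
hours from injection at E11.5 (0 h; embryonic days convert at 24 h/day):

- **Infection**: `n_progenitors` (default 500) each infected with
  probability `infection_probability` (default 0.08, the analog of the
  diluted titer that yielded pickable ears), at a uniform time within
  the 24 h `infection_window`.  Co-infection (two proviruses, two tags)
  with probability 0.05.
- **Integration** occurs at the founder's first mitosis after
  infection — modeled as a uniform fraction of one cycle after the
  infection time — and labels exactly one daughter.
- **Growth**: the labeled daughter's lineage divides with i.i.d. cycle
  times uniform on 12–18 h.  A cell born at `t` divides iff
  `t + cycle ≤ deadline`; otherwise it is terminal.  With a
  deterministic cycle `c` this yields exactly
  `2^⌊(deadline − integration)/c⌋` cells, the analytic anchor used in
  tests.  Deadlines are a two-point mixture: the early deadline
  (+48 h, E13.5) with probability `p_early_exit = 0.6` — the middle of
  the published 50–70% early-exit range — else the late deadline
  (+96 h, E15.5).  The published "0–4 divisions" expectation
  corresponds to 18 h cycles against the late deadline; 12 h cycles
  permit 6, and the simulator exposes both without privileging either.
  No cell death or inter-region migration is modeled (no rates exist).
- **Placement**: each clone draws a region uniformly from the region
  vocabulary and a founder section uniformly over `n_sections`
  (default 100 sections of 14 µm); cells offset from the founder's
  section by a rounded zero-mean normal kernel with per-region scale
  (default 2 sections).  Regions are categorical labels; no 3-D
  morphogenesis is modeled, and the dispersion kernel is a device for
  producing realistic spread statistics, not a migration mechanism.
- **Observation noise**: a provirus is silent (clone undetectable when
  all its proviruses are) with probability 0.05 — silencing is
  reported as present but not widespread; a picked cell returns a
  product with probability `pick_pcr_success = 0.52` (285/547 in the
  source accounting); a single-provirus pick is contaminated by a
  second lineage's tag (becoming multiple-tag) with probability 0.15,
  sized so that contamination plus co-infection lands near the
  observed 19.3% multiple-tag fraction; negative controls are emitted
  at 0.2 per positive pick (108/547) and return a spurious product
  with probability `negative_fpr = 0.028`.

All randomness flows through one `numpy.random.Generator` seeded
explicitly; no global state.  Identical seeds give identical ears,
picks, and files.

What passing tests show — and don't.  The simulator validates the
*pipeline*: partition recovery under zero noise, estimator calibration
(FPR, PCR success, co-infection fraction) within binomial error, and
geometry round trips.  It does not establish anything about real
tissue: region assignment is uniform rather than reflecting the strong
observed bias toward the posterior crista and auditory ganglion, clone
cell types are drawn independently per cell, and the dispersion kernel
is symmetric where real morphogenetic displacement (e.g. 406 µm
Claudius'-cell spreads) is directional.

## Numerical and interface choices

- Percentages: `Decimal` half-up rounding to one decimal; fractions
  over empty denominators are `None` and listed in
  `undefined_fractions`, never a division error.
- Collision probability clamps to [0, 1] and switches to log-space
  accumulation; exactness is verified against brute-force enumeration
  (all `Nⁿ` assignments) for small `n, N` and against the falling
  factorial closed form `1 − N!/((N−n)!·Nⁿ)` elsewhere.
- Picks TSV: tab-separated, header row, UTF-8, trailing newline;
  parse errors name the offending 1-based row.  Configs are YAML;
  clones and summaries JSON; tags and templates FASTA.
- Problem sizes in the default test run and acceptance script are
  desk-scale by design — the source study's quantitative surface is
  counts and geometry over printed tables (hundreds of picks, 1000-tag
  PCR round trips, 10⁴-replicate Monte-Carlo checks), and the whole
  suite completes in well under a minute.

## Known limitations

- Uniform tag abundance and uniform region assignment are
  idealizations (see above).
- The exact-match PCR model cannot produce partial or mismatched
  primer products; primer-binding kinetics are out of scope.
- The synthetic template flanks are repository constants, not the true
  vector sequence; only the 160-nt product length and the nested-site
  ordering are anchored to the published construct.
- The clone caller's mismatch-tolerant mode uses per-pair Hamming
  matching; it does not implement full single-linkage clustering over
  large tag sets.
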