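# Methods

## Data model

An *ethogram* of 13 behavior classes (acronyms `Ld, P, F, W, Db, Wf, Sf, E,
D, R, St, Ll, Ex`) is the vocabulary; `Ex` (explore: interacting with
enrichment objects) is flagged as possible only in enriched pens, and the
registry's insertion order is the canonical ordering used everywhere output
must be deterministic. Acronyms are the identifiers throughout; names and
descriptions are display-only. An override file (YAML/CSV) can replace the
registry for other species.

Raw observations are *bouts*: `(broiler, condition, day, window, onset,
duration, behavior)`. Windowing converts them to the sequence-database
model:

- a bout registers as a behavioral event only if it lasts ≥ `min_bout_s`
  (default 10 s) — the sustained-activity rule used by the annotation
  protocol. Sub-threshold bouts are *discarded*, not merged into neighbors:
  the protocol defines a transition only after 10 s of sustained activity
  and says nothing about shorter interruptions, and discarding is the
  choice that keeps windowing idempotent.
- bouts are assigned to the window containing their onset and truncated at
  the window boundary; the truncated remainder counts only if it still
  meets the floor. Windows are analyzed independently.
- consecutive surviving events of the same behavior merge into one code
  occurrence, so window elements never contain adjacent repeats.
- every sequence keeps all `n_windows` elements (empty ones included), so
  transaction times stay aligned across broilers. Empty windows support
  nothing. Printed output is 1-indexed; internals are 0-indexed.
- each assessment day / condition is a separate database; pooling is
  refused unless explicitly requested.

Defaults are `min_bout_s = 10 s`, `window_s = 300 s`, `n_windows = 14`
(14 five-minute clips, ≈ 140 events per broiler-day at the default
simulator density). The protocol literature is not arithmetically
consistent about the recording span, so the grid is configuration, not a
constant.

## Containment and support

A pattern element matches a window when its codes embed as an
order-preserving, multiplicity-respecting subsequence — gaps *inside* an
element are allowed. This is a deliberate semantic choice: published tables
distinguish `<{Ld,P,F}>` from `<{Ld,F,P}>` (ruling out set semantics), and
requiring contiguity would make long elements practically unmineable.
Pattern elements map to strictly increasing windows (no window reuse).
Support is the fraction of database sequences containing the pattern, each
broiler counted once however many embeddings exist; the frequency test is
the closed comparison `support ≥ minsup`, so 2 of 10 broilers is frequent
at the 20% level. Greedy earliest-window matching decides containment
exactly, because matching an element to the first feasible window never
forecloses a later embedding.

One consequence worth knowing: under gap-allowed matching, some published
reference rows are mutually inconsistent (a pattern printed with a lower
carrier count than one of its superpatterns at a higher level), which
indicates the original tool matched within elements more strictly. The
packaged tables are therefore treated as verbatim *data* for the tally
layer; mining invariants are asserted only on this engine's own output.

## Mining

Level-wise GSP on total item count: frequent single items seed the join;
`s1` joins `s2` when dropping `s1`'s first item equals dropping `s2`'s last
item, appending `s2`'s last item merged into the final element or as a new
element according to its position in `s2` (for 1-item seeds, every ordered
pair contributes both structures). Candidates with an infrequent
one-item-deletion subpattern are pruned (Apriori). Because windowed data
never contains adjacent in-element repeats, patterns whose elements do are
excluded from the search space, and deletion subpatterns that would contain
such repeats are skipped during pruning rather than required — they are
outside the mined space even when their support would be positive. No time
constraints (max-gap/min-gap/sliding windows) are implemented; the method
under study uses none.

Two size notions coexist and both are exposed: `item_count` (the mining
level variable) and `size` = element count (the reporting convention, where
a 4-step pattern of 8 items has size 4).

The brute-force oracle enumerates the identical pattern space by
depth-first one-item extension, recursing only below frequent prefixes
(sound by anti-monotonicity, exhaustive because every pattern is reachable
by trailing appends). It bounds itself to ≤ 12 sequences, ≤ 6 windows, a
≤ 6-code alphabet, ≤ 5 items and a support-evaluation budget, and is the
independent completeness/soundness check for the join-based miner.

Output ordering is canonical — (item count, size, ethogram order) — so
repeated runs are byte-identical.

## Sweep reporting

`sweep` mines once at the lowest level and, per level of a strictly
decreasing grid (default 1.0…0.2 step 0.1), reports the *maximal* frequent
patterns at that level (no frequent proper superpattern at the same level)
minus anything that is a subpattern of, or identical to, a pattern reported
at a higher level. Maximality is applied level-locally first and cross-level
suppression second; the published convention states the suppression rule but
not its order of operations, and this order reproduces the published top
rows (the shared `<{Ld,P}>` shown alone) and the lower-row pruning. Rows
that report nothing print `None`; for display, each reported set is grouped
with the following empty levels, reproducing rows like "1.0 to 0.5 | None".
Every frequent pattern at a level is then either reported there, reported
higher, or a subpattern of something reported — nothing is silently lost.

## Synthetic flocks

The generator is a seeded semi-Markov chain per broiler per window — the
minimal structure that supports bout order, dwell floors and condition
contrasts. Within a window: an initial behavior is drawn from the preset's
stationary propensities, dwell times are `min_bout_s +
Exponential(dwell_mean_s[code] / activity_scale)`, and the next behavior is
drawn from the current row of the transition-weight matrix (self-weights
zero; a dwell ends with a switch). The final bout of a window is truncated
at the boundary, and windowing discards it when the remainder is below the
floor — so post-windowing, every code occurrence derives from a ≥ 10-s bout.

Four presets encode the study's qualitative structure, not fitted
magnitudes (no raw data exists to fit against):

- **Propensities/motifs.** Resting, preening, foraging, walking and feeding
  dominate; the chains `Ld→P`, `P↔F`, `E→W`, `W→D/F` are boosted.
- **Density.** Dwell means target ≈ 10 events per 5-min window at
  thermoneutrality (≈ 140 events per broiler-day over 14 windows).
- **Heat.** `activity_scale` drops from 1.0 to 0.55, lengthening dwells and
  reducing events per window; lying laterally (`Ll`) is reachable only in
  heat presets; the `St→Ll` transition is boosted ×6 in the non-enriched
  heat preset and damped ×0.5 in the enriched one, mirroring the observed
  heat-dissipation signature and its absence under enrichment.
- **Environment closure.** `Ex` exists only in enriched presets, by
  construction of the allowed-code set.

`plant_pattern` splices a pattern into ⌈carrier_fraction × n⌉ broilers:
each element's codes are inserted at the start of distinct increasing
windows as floor-length bouts, displacing existing bouts later in time
(truncated or dropped at the boundary). Carriers are then guaranteed to
contain the pattern; when the pattern uses a code the preset cannot emit
(e.g. `Ll` at thermoneutrality), mined support equals the carrier fraction
exactly, giving a sharp recovery test.

What passing these tests shows — and does not. The simulator validates the
*mechanics* (windowing, containment, support, sweep) and the *direction* of
the condition contrasts (fewer bouts and fewer frequent patterns under
heat; no `Ex` without enrichment; exact planted recovery). It does not
reproduce real flocks' bout-duration distributions, social synchrony,
diurnal rhythm, or the published tables' specific patterns, and no inverse
construction of a database reproducing those tables is attempted.

## Problem sizes and numerics

Under gap-allowed containment, the number of frequent patterns at a 20%
threshold grows combinatorially with events per window; randomized
direction/recovery runs and the CLI demo therefore use reduced flocks
(6 windows of 60 s) chosen to keep complete mining exact and fast, while
full-scale (14 × 300 s) generation is exercised with direct Eq.-style
support measurement. Support comparisons use counts with a 1e-9 slack so
floating thresholds like 0.3 × n never drop a pattern to quantization;
supports are exact multiples of 1/n by construction. All randomness flows
through explicit integer seeds (NumPy `default_rng`), and identical seeds
give byte-identical outputs.

## Known limitations

- The engine's within-element semantics intentionally differ from the
  (apparently contiguous) matcher behind the published tables; absolute
  pattern counts on dense data are therefore not comparable, only the
  reporting format and the tally layer are.
- Maximal/closed mining is not implemented inside the engine; maximality is
  a reporting concern.
- Preset parameters are illustrative; per-behavior base rates and dwell
  distributions of real broilers are not recoverable from summary tables.
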