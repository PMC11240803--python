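# broilerseq

Sequential pattern mining for ethogram-coded broiler chicken behavior.

Conventional behavioral welfare analysis counts how often or how long a bird
performs each behavior and discards the *order* in which behaviors occur.
`broilerseq` targets that gap for precision-livestock work on broilers housed
under controlled thermal and enrichment treatments: it turns bout-level
behavior annotations into per-bird sequence databases, mines recurring
behavioral sequences with the Generalized Sequential Pattern (GSP) algorithm,
and reproduces the threshold-sweep tables this literature reports. Because the
underlying climate-chamber annotation data are typically not deposited, the
package also ships a condition-dependent semi-Markov flock simulator, so every
stage of the pipeline can be exercised end to end with known ground truth.

It is written for welfare researchers and engineers who have (or can
simulate) time-stamped ethogram annotations and want frequent behavioral
sequences — e.g. the stretch-then-lie-laterally (`St→Ll`) heat-dissipation
signature — rather than behavior frequencies alone.

## The model

Each broiler contributes one data sequence: its 5-min analysis windows in
chronological order, where a window element is the ordered run of behaviors
the bird sustained for at least 10 s each (shorter bouts are not events;
consecutive same-behavior events merge). A *pattern* is an ordered list of
elements, written `<{Ld,P} {Ld,F}>`: the items of one element must co-occur
within a single window, and successive elements must map to strictly
increasing windows. The support of a pattern *s* in a database *D* of *n*
broiler sequences is

    supp(s) = |{ i : s ⊑ D_i }| / n  ∈ [0, 1],

the fraction of broilers whose sequence contains *s* (each broiler counts
once). Given a minimum support threshold (minsup), GSP finds **all** patterns
with `supp(s) ≥ minsup` level-wise: frequent single items seed the candidate
join, each pass grows candidates by one item and prunes those with an
infrequent subpattern (the Apriori property), and the loop stops when a pass
yields nothing. A brute-force depth-first enumerator with the same output
contract serves as an independent completeness oracle in the tests.

The report layer reproduces the field's presentation convention: sweep
minsup from 1.0 down to 0.2, and at each level show only the *new maximal*
patterns — anything that is a subpattern of something already shown at a
higher level is suppressed.

## Worked example

The canonical two-broiler example database — broiler 1 ate, walked, then
drank; broiler 2 lay down, then preened:

```python
from broilerseq import worked_example_database, sequence_size, mine

db = worked_example_database()
for seq in db:
    print(seq.sid, "size", sequence_size(seq))
for fp in mine(db, 0.5):
    print(fp.notation(), "support =", fp.support)
```

prints

```
broiler_1 size 3
broiler_2 size 2
<{Ld}> (n = 1) support = 0.5
<{P}> (n = 1) support = 0.5
<{W}> (n = 1) support = 0.5
<{E}> (n = 1) support = 0.5
<{D}> (n = 1) support = 0.5
<{Ld} {P}> (n = 1) support = 0.5
<{W} {D}> (n = 1) support = 0.5
<{E} {W}> (n = 1) support = 0.5
<{E} {D}> (n = 1) support = 0.5
<{E} {W} {D}> (n = 1) support = 0.5
```

Broiler 1's sequence has size 3 (three windows, one behavior each) and
broiler 2's has size 2. At minsup 0.5 a pattern needs only one of the two
broilers, so every subsequence of either bird is frequent — ten patterns in
all, each with support 1/2. At minsup 1.0 nothing is frequent: the two birds
share no behavior.

The same pipeline is available from the shell. A complete synthetic run over
all four condition presets (thermoneutral/heat × plain/enriched pens):

```
$ broilerseq demo --seed 1
# demo seed = 1
condition	bouts	frequent@0.2	reported@0.2
thermoneutral_plain	152	2032	285
thermoneutral_enriched	152	1202	179
heat_plain	117	673	133
heat_enriched	115	538	106
```

Heat-stressed flocks move less (fewer bouts), so fewer sequences clear the
20% support threshold — the directional effect the simulator is built to
reproduce. `broilerseq simulate / build-db / mine / sweep / parse-tables`
expose the individual stages; see `broilerseq --help`.

## Reference tables

The package ships machine-readable transcriptions of the four published
sweep tables for a 10-broiler proof-of-concept study (two pen environments ×
two thermal conditions, assessment days 21–22) under
`src/broilerseq/data/*.tsv`, parsed by `load_reference_table`. Tally
operations (`total_patterns`, `tally_sizes`, `behavior_coverage`,
`max_reported_size`) and the `parse-tables` subcommand run on them directly.

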