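# Methods

## Mass arithmetic

Monoisotopic atomic masses are hard-coded CODATA/AME2020 values (most
abundant isotope); the electron mass (0.00054858 Da) is subtracted once per
positive charge.  Molecular formulas carry signed element counts so net
reaction changes can be written symbolically (`+NH2OH-H2O` collapses to
`NH`); the trailing charge is a run of sign characters (`+`, `--`) because a
digit-magnitude charge is ambiguous against element counts.  Reaction
Δm/z values are always recomputed from the net change, never stored: this
yields 121.0197 (A), 170.0480 (B) and 15.0109 (C) Da at 4 decimals.  The AQC
value differs from a commonly quoted 170.0481 by 0.0001 Da, which is a
rounding artifact of the quoted figure — straight summation of C10H6N2O
gives 170.04801.

## Reaction registry and reactivity model

A reaction is (reagent, net elemental change, SMARTS pattern list, minimum
yield).  The shipped SMARTS sets cover the groups each chemistry labels:

* **A, cysteine (electrophiles):** enone and acrylate Michael acceptors,
  1,4-naphthoquinone core, α,β-epoxyketone, β-lactone, macrocyclic ester
  (ring ≥ 8 atoms, the size at which thioester ring-opening is plausible;
  expressed directly in the SMARTS via `r{8-}` so users can change it),
  terminal alkene.
* **B, AQC (nucleophilic N/O):** primary and secondary amines with amide and
  imine nitrogens excluded (AQC acylates free amines, not amides), phenol,
  N-hydroxy.
* **C, hydroxylamine:** aldehyde, ketone.

Patterns are deliberately editable: registries round-trip through YAML, so a
published or lab-specific SMARTS set can replace the curated one without
touching code.  In-silico reactivity (`simulate_reactivity`) is the
error-free model: a reaction is predicted iff at least one pattern matches.
Validation against known structures uses the standard four-cell truth table
per reaction; the false-positive rate is FP/(TP+FP) over detected events, in
exact rational arithmetic, and is reported absent when nothing reacted.

## Feature linking

Pairing accepts an ordered feature pair (p, q) for reaction r when the m/z
difference matches r's Δ within tolerance and the features co-elute.
Defaults: 10 ppm with a 0.002 Da floor (evaluated at the product's m/z) and
0.05 min RT tolerance — typical values for high-resolution orbitrap/QTOF
feature tables.  Edges are directed with the product strictly heavier, as
all three net changes add mass.  A feature may be the precursor of many
edges (multiplexed reactions) but the product of at most one edge per
reaction; competing precursors are resolved by smallest |mass error|, then
smallest |RT difference|, then precursor id — a deterministic total order.
Pearson correlation of per-sample areas stands in for chromatographic-shape
correlation (raw profiles are not present in feature tables); it requires at
least 3 shared samples and is off by default, since Δm/z + co-elution is the
minimum contract and small designed experiments rarely have the replicate
support for a meaningful correlation gate.  An optional flag additionally
requires the product to be absent from reagent-free runs.

Conversion yield is product/(product + educt) × 100 % over
derivatized-condition areas, either pooled (`summed-areas`, default) or
averaged per shared sample.  Edges whose endpoints carry no
derivatized-condition signal are flagged `undefined_yield` and kept, so the
user sees them rather than silently losing them.  The reaction-A yield cut
is strict: yields below 5 % are dropped, exactly 5 % is kept.

## Modified cosine and analog search

Peak intensities are square-root scaled and L2-normalized (the convention of
the molecular-networking ecosystem; raw intensities are a flag away).  A
peak in the query may pair with a library peak either directly (|Δm/z| ≤
fragment tolerance) or shifted by the precursor mass difference; a pair
eligible both ways counts once.  The score is the maximum, over one-to-one
pairings, of the summed intensity products — solved exactly as a
maximum-weight bipartite assignment (Hungarian algorithm on the candidate
pair matrix).  A tiny per-pair epsilon (1e-9/|pairs|) makes the solver
prefer more matched peaks among score-equal assignments, which only matters
in the presence of zero-intensity peaks.  A greedy pairing is available for
comparison and can only score lower.  Scores are clipped to [0, 1] against
floating-point overshoot.

Analog search applies the relaxed open-modification thresholds (minimum
cosine 0.5, minimum 4 matched peaks, 0.5 Da fragment tolerance, top 30
analogs) and imposes **no** precursor window — the 2.0 Da precursor
tolerance is used only to classify hits as exact-mass matches during
removal/reporting.  Exact-match removal compares canonical SMILES; duplicate
structures keep their best-scoring hit, and the list is refilled from
below the top-30 cut so the analog set stays complete.

## Functional-group reranking

Given the observed reaction set of a query, a match is FG-consistent when
its structure contains at least one reactive-group hit for *every* observed
reaction (an `any` mode is available; the stricter default reflects that
each observed derivatization is independent evidence).  Reranking is a
stable partition — consistent matches first, original (cosine) order
preserved inside each block — so it is a permutation of its input,
idempotent, and the identity when nothing was observed.  The same partition
reranks in-silico candidate lists; when the true structure genuinely carries
every observed group, its rank can only improve or stay, which the tests
assert as a property.

## Tanimoto evaluation

Structural similarity is the Tanimoto coefficient over 2048-bit path-based
(RDKit daylight-type) fingerprints at default settings.  Fingerprints are
lossy, so distinct molecules can reach similarity 1.0; two all-zero
fingerprints are defined as similarity 1.0 to keep the measure reflexive.
Cohort evaluation restricts to queries with at least one analog at ≥ 0.5
similarity to the truth (inclusive), mirrors the three-way
improved/decreased/unchanged split with strict inequalities, and computes
top-k accuracy only over queries whose truth exists in the candidate set.
Percentages are reported to 1 decimal, means to 2.

## Synthetic data: what it emulates and what it does not

The feature-table generator plants, per structure, an educt at [M+H]+
present in control and reagent runs and one product per predicted reaction,
present only in reagent runs, at educt m/z + Δ.  Study conditions (defaults,
chosen once): 3 replicate samples per condition; per-reaction conversion
drawn uniformly from 10–95 % (divided by the number of reactions per
structure so total conversion stays below 100 %); RT jitter sd 0.01 min,
inside the 0.05 min co-elution window; mass error sd 0.0003 Da clipped at
±0.001 Da, below half the 0.002 Da tolerance floor; 2 decoys per structure,
placed so no decoy sits within a safety margin of any reaction Δ from any
other feature (bounded rejection sampling, then failure).  Product areas
realize the same yield fraction in every sample, so both yield modes recover
the planted value exactly.

Toy spectra are template-generated — random fragment m/z per structure,
analogs share a configurable fraction of fragments and carry a precursor
offset (half the shared fragments shifted by it).  The analog benchmark (50
queries) gives each ketone query one homologous, FG-bearing analog with
moderate fragment overlap and three alcohol decoys with higher overlap, so
plain cosine ranks low-similarity structures first and the FG partition must
repair the ordering — the non-trivial case for the reranker.

None of this models isotope envelopes, adduct ladders, in-source
fragmentation, peak shapes, or physical fragmentation chemistry.  Passing
tests therefore demonstrate the correctness of the pairing, scoring, and
ranking machinery against planted truth — not detection performance on real
chromatograms, where overlapping peaks, shared adducts and matrix effects
add failure modes the generator does not produce.

## Numerical and design choices

* Substructure counts are symmetry-deduplicated (unique atom sets); the
  pipeline only needs presence/absence, but counts are exposed for tests.
* All randomness flows through one `numpy.random.Generator` (PCG64) per
  generator call; a fixed seed reproduces every artifact byte-for-byte, and
  the CLI records seed, parameters and versions in `provenance.json`.
* Degenerate inputs: empty formula has mass 0; empty peak lists are
  rejected; a yield with both areas zero is an error at the formula level
  and a flagged edge at the pipeline level; constant area vectors have
  undefined correlation (absent, not 0).
* Problem sizes in the test suite (oracle equivalence on 100 random tables
  of ≤ 350 features and 200 spectrum pairs of ≤ 6 peaks; a 50-query
  benchmark) were chosen to exercise every code path of the quadratic
  reference scans while keeping the whole suite fast enough to run on every
  commit.

## Known limitations

* The curated SMARTS sets approximate each chemistry; electronic
  deactivation, sterics and pH are not modeled, so borderline groups
  (e.g. weakly activated alkenes, hindered ketones) may be mispredicted.
  Replace the patterns via a YAML registry for lab-specific chemistry.
* Analog-search absolute Tanimoto values depend on the fingerprint
  implementation and version; comparisons are only meaningful within one
  toolkit configuration.
* Linking starts from aligned feature tables; peak picking, adduct and
  isotopologue deconvolution are out of scope.
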