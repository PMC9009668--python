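# Methods

## The audit model

A market survey yields, per purchased sample: provenance metadata (city,
vendor type, source of the commercial name — label, menu or verbal), the
commercial name as sold, and a COI barcode. The analysis proceeds in four
stages.

### 1. Barcode identification

Queries are compared against one or more species-annotated reference
libraries. Percent identity comes from a global alignment with cost-free
terminal gaps (match +1, mismatch −1, gap −2, linear), computed by
Biopython's `PairwiseAligner`; identity = 100 × matches / aligned columns,
with terminal-gap columns excluded from the denominator and internal gap
columns counted as mismatches. Both strands are always tried (queries are
not assumed oriented).

One numerical subtlety: for two *unrelated* sequences the optimal
free-end-gap alignment is a short perfect overlap, which the bare formula
would score as 100% identity over a handful of columns. Ranking hits by
that number alone would be unsound. We therefore floor the denominator at
half the shorter sequence's length: alignments covering at least half the
shorter sequence are scored exactly by the bare formula, while fragmentary
overlaps are down-weighted — the same effect a score-based ranking (as in
megablast) produces. All quality hits in the barcode regime (≥90% identity
over near-full length) are unaffected.

Searches use a k-mer prefilter (word size 12, default): only entries
sharing at least one exact 12-mer with the query on either strand are
aligned. At barcode-level identities the top hit always shares many words,
so the prefilter cannot change top hits; this is asserted against
exhaustive search in the tests. A query sharing no word with any entry
yields an empty, flagged hit list.

Consensus assignment across libraries, at threshold *t* (default 98%) and
genus floor *g* (default 90%):

1. every library's best hit names the same species at ≥ *t* → species-level;
2. best species differ but share the genus, each ≥ *t* → the single highest
   identity across libraries decides (noted "genus-level agreement");
3. two or more species tie exactly (identities equal after rounding to
   0.01%, sequencer-scale reproducibility) at the top of a library at ≥ *t*
   → all tied species are reported as a multi-species candidate set;
4. best identity < *t* → genus-level call if ≥ *g*, else unidentified.

Libraries whose best hit falls below *t* do not veto a call supported by
others; top hits in different genera, both ≥ *t*, are reported as a
two-species candidate set with a "library conflict" note (a case with no
observed precedent; the conservative choice preserves both hypotheses).
The 98% rule is applied per library, with the cross-library maximum used
only to resolve genus-level agreement; this matters only when libraries
disagree near the threshold.

Reading-frame screening uses the vertebrate mitochondrial code (stop codons
TAA, TAG, AGA, AGG), forward frames only; COI barcodes are mid-gene so no
start codon is required. A sequence passes if any forward frame is free of
stops over its complete codons; the lowest passing frame is reported.

### 2. Mislabel calling

Commercial names are normalized (case-fold, diacritics stripped, whitespace
collapsed) and matched against catalogs mapping names to accepted species.
Correctness is the union over catalogs: one listing anywhere suffices.
Decisions taken where the calling rule was open:

- multi-species (tied) identifications are correct if *any* candidate is
  accepted — conservative, avoids inflating mislabeling;
- genus-level identifications are called through their representative
  candidate and flagged in the notes, so sensitivity re-runs can exclude
  them;
- a commercial name found in no catalog is reported as its own excluded
  status (`excluded_unknown_name`), never auto-mislabeled;
- the substitute species recorded for a mislabeled sample is the
  highest-identity candidate, ties broken alphabetically.

### 3. Substitutability audit

Exact integer identities per focal name: verbal = correct + mislabeled;
confirmed = correct + substitutability frequency; over/sub-representation =
verbal − confirmed. Substitutability diversity counts distinct *commercial
names* substituted (not species), matching how the framework's published
tables use the term. A substitute species maps to focal names through the
catalogs; when a species is accepted under several names, each substitution
event is credited once, to the name with the most samples in the survey
(deterministic, ties alphabetical), with a `credit="all"` switch. The
over/sub percentage is emitted as missing (never ±inf) when confirmed = 0.
Reported percentages are rounded half-up to 2 decimals; internal arithmetic
is exact.

### 4. Inference

- Wilson score intervals (α = 0.05 default, z computed from the normal
  quantile so α is configurable) for all rates; bounds are clamped to
  [0, rate] ∪ [rate, 100] against floating-point dust at k = 0 / k = n.
- Pearson 2×2 chi-square without continuity correction (this choice
  reproduces published vendor-type statistics exactly); all margins must be
  positive. Pairwise stratum comparisons are reported unadjusted.
- OLS with R² = squared Pearson correlation and the slope's F(1, n−2) test;
  landings tonnage is log10-transformed before regression (tonnage spans
  orders of magnitude; the base does not affect R²).

## The synthetic-data generator

The generator emulates the survey conditions the pipeline is meant for:

- **Species pool**: ~160 candidate species in three origin categories
  (70% wild marine bony, 15% elasmobranch, 15% aquaculture/freshwater),
  grouped into genera (about two species per genus on average), with
  Zipf rank-frequency supply weights (default exponent 0.65).
- **Reference libraries**: one frame-clean anchor per species per library.
  Each genus gets an independent random stop-free backbone; congeners are
  derived at the minimum inter-species divergence (default 0.05), so
  congeners are more similar to each other than to other genera while all
  inter-species identities stay ≤ 95% (verified exhaustively; bounded
  re-draws, explicit failure when infeasible). Libraries share anchors —
  they emulate overlapping public databases — and drop an exact fraction of
  species independently when dropout is requested.
- **Mutation**: queries are anchors with an exact number of substitutions
  (`round(d·L)`), no indels, substitutions that would create an in-frame
  stop re-drawn elsewhere. Intra-species divergence is uniform on
  [0, 0.01] by default; with the 5% inter-species floor the 98% rule
  separates the two levels cleanly (the standard barcode-gap situation).
- **Survey**: 48 commercial names with Zipf-like sample counts totalling
  376; per-name mislabeling probabilities drawn Beta(1.1, 2.45), mean
  ≈ 0.31 to match a ~31% study-wide rate; substitution weights default to
  supply weights (availability-driven substitution), overridable per name;
  each catalog is an incomplete subset of the generating acceptance
  mapping, whose union recovers it. One PRNG stream is seeded per run; the
  whole survey is byte-identical under a fixed seed. With these defaults
  about half of the observed species appear exactly once (the heavy-tailed
  spectrum typical of such surveys); pool size and exponent were calibrated
  once to that shape and are not tuned per run.

What the generator does **not** emulate: chimeric or heteroplasmic reads,
indels and sequencing noise, bacterial contaminants (upstream attrition can
only be approximated by an unidentifiable sample class), price structure
beyond a lognormal placeholder, and geographic structure in species
composition (cities/vendors are drawn uniformly). Passing tests on
synthetic data therefore demonstrate the correctness of the identification,
calling, audit and inference logic under clean barcode-gap conditions — not
robustness to degraded sequence data.

## Problem sizes and numerical choices

Tests run on small corpora (10–50 species, tens of queries) with a
brute-force dynamic-programming aligner, direct Wilson/chi-square formulas
and exhaustive searches as independent oracles; the acceptance script runs
the full 376-sample scenario once. Determinism: hypothesis runs
derandomized; every stochastic test is seeded. Identity ties are defined
after rounding to 0.01%. Percentages are compared against published tables
after truncation where the tables truncate (this is how the published
values were printed: e.g. 53.84 for 7/13, and R² 0.459 for 0.4598).

## Known limitations

- The identity measure approximates, but is not, megablast percent
  identity; absolute identities for diverged pairs (< 90%) depend on the
  gap model.
- Substitutability crediting for species accepted under several names has
  no published convention; both implemented policies ("largest name",
  "all") are deterministic but can differ on dense catalogs.
- The chi-square comparisons assume independent samples within strata;
  repeated purchases from one vendor violate this mildly, as in the
  original survey design.
- Genus-level calls are included in mislabeling rates (flagged); excluding
  them is a one-line sensitivity re-run but not the default.
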