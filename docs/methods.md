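# Methods

## The procedure

Intrinsically disordered regions (IDRs) of proteins often carry short
segments that fold upon binding a partner ("coupled folding and binding").
Experimentally verified examples — protean segments — are scarce, but
human-curated feature annotations plus practical-grade disorder prediction
let one mine candidates at proteome scale.  This package implements that
mining procedure and its downstream statistics:

1. **Feature extraction.**  Each protein carries UniProt-style feature
   annotations: a type, a free-text description, and a 1-based inclusive
   residue location.  Three classes are candidate carriers of binding
   segments: *region of interest*, *mutagenesis site*, and *short sequence
   motif*.
2. **Length rule.**  Only annotations covering at most 29 residues
   (non-redundantly, over all their intervals) qualify — verified protean
   segments are mostly shorter than 30 residues.
3. **Keyword rule.**  Regions of interest are kept when their description
   contains *interact*, *bind* or *motif*; mutagenesis sites when they
   contain *interact* or *bind* and neither *no* nor *not*; short sequence
   motifs are kept unconditionally.  Keywords match case-insensitively at
   word starts (so "interact" hits "Interaction with USP7"); negation words
   match as whole words only, because descriptions like "Loss of interaction
   with MDM2" describe a binding site and must survive, while "no"/"not"
   must not fire inside words such as "nuclear" or "noted".
4. **Consensus disorder.**  Three per-residue disorder tracks (MobiDB-lite,
   DISOPRED3, DICHOT — consumed as input, never recomputed) vote per
   residue; a residue is consensus-disordered with ≥ 2 votes.  An absent or
   empty track contributes zero votes, so a protein with two informative
   predictors can still reach consensus.
5. **Calling.**  A selected annotation whose residues lie inside consensus
   disorder at a fraction ≥ the coverage threshold (default 1.0, full
   containment) is called a *possible protean segment* (pProS).  Overlapping
   annotations yield separate calls — they can describe distinct binding
   events — but residue accounting is always non-redundant: annotations at
   360–365 and 360–362 cover six residues, counted once.

Downstream statistics over the calls:

* **Cohort and category tables.**  Counts of proteins and short annotations
  per class, per-category protein coverage (% of a disease category's
  proteins with ≥ 1 call), average annotations (unique calls per
  call-containing protein), and the redundant call count in which each call
  is re-counted once per disease assignment in the category (their ratio is
  the category's redundancy, < 1 when proteins carry several diseases of
  one category).  A protein assigned to k categories contributes to all k
  rows.  Printed-style percentages and ratios use half-up rounding to one
  decimal; the integer columns they derive from are emitted alongside.
* **Disorder fractions.**  Per subset (whole cohort, disease proteins,
  call-containing/non-containing, per category) both the residue-weighted
  fraction (Σ disordered / Σ length) and the mean per-protein fraction are
  reported, since published disorder ratios rarely state which convention
  they use.
* **Localization enrichment.**  Proteins with both cytoplasm and nucleus
  terms are the shuttling CN class; exactly one of nucleus / cytoplasm /
  membrane gives N / C / M; everything else is *other*.  Over-representation
  of a group against a background is log₂(group fraction / background
  fraction); the base is configurable and recorded in `config.json`.  A zero
  fraction on either side is flagged, not reported as a number.  The
  pipeline uses the all-protein superset background (whether a published
  "all proteins" background excludes the group itself is never stated; the
  superset is the reproducible choice).
* **PPI–disease correlation.**  Disease proteins are binned by distinct
  disease count; Pearson's r between the bin value and the per-bin mean (or
  median) interactor count is the primary statistic — hub proteins with
  hundreds of partners dominate raw pairs — with the raw per-protein pair
  correlation emitted for comparison, plus the per-bin quartile table for
  box-plot reproduction.  The "few diseases" restriction keeps bins with
  ≤ 9 diseases.
* **Generic coverage surveys.**  The same feature-vs-disorder intersection
  runs on pass-through classes (sequence variants, modified residues) with
  no keyword filtering, for mutation-site and phosphosite-in-IDR surveys.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `max_feature_length` | 29 aa | longest qualifying annotation |
| `min_predictor_votes` | 2 of 3 | consensus disorder votes |
| `idr_coverage_threshold` | 1.0 | fraction of the annotation inside consensus |
| keyword sets | interact/bind/motif; interact/bind | per-class positive vocabulary |
| negation tokens | no, not | mutagenesis discard list (whole words) |
| `enrichment_log_base` | 2 | localization log ratio base |

The coverage threshold deserves note: the source procedure mentions an IDR
coverage requirement without stating its value, so the strictest consistent
reading — full containment — is the default, exposed in the config and
echoed into every report's `config.json`.  The 32-residue partner-binding
region of the SMN-like fixture documents the interplay: fully inside
disorder yet excluded by length alone.

## The synthetic-data generator

Real inputs (UniProt + KEGG DISEASE + BioGRID snapshots) require downloads
and carry no ground truth, so the generator emulates all five input tables
with every planted fact recorded:

* chain lengths log-normal, median 400 aa, σ = 0.6, clipped to [60, 5000]
  (human Swiss-Prot-like);
* per-protein disorder fraction Beta-distributed around the 0.30 target
  (concentration 50), placed as one or two segments with probability 0.8 at
  a terminus — known disease exemplars of this segment class carry terminal
  IDRs;
* each predictor echoes the true per-residue state with agreement
  probability 0.9 (1.0 = noise-free).  Note that symmetric per-residue noise
  inflates the measured 2-of-3 consensus slightly above the true fraction:
  at a 0.30 true fraction and 0.9 agreement the expectation is
  0.30·0.972 + 0.70·0.028 ≈ 0.311, still inside the ±0.02 recovery band;
* planted binding segments: Poisson(0.4) per protein, 3–29 residues, fully
  inside true disorder, descriptions templated on real annotation phrasing
  ("Interaction with X", "Loss of interaction with X", "LXXLL motif");
* decoys that must never be called: keyword features in ordered regions,
  negated mutagenesis descriptions ("Does not affect interaction with X"),
  over-length (31–45 aa) segments inside disorder, keyword-free regions;
* disease counts: 17% of proteins are disease-related; their distinct
  disease count is Zipf(exponent 2), truncated at 60, over a 300-entry
  catalog whose entries each map to one of the 15 category codes (disease
  multiplicity in real annotation is heavy-tailed);
* localization classes drawn per group — the planted-segment group gets CN
  probability 0.30 vs 0.20 for the rest (a 1.5× plant), N 0.22 vs 0.15, the
  remainder spread over C/M/other;
* interactor counts: 5 + 20·(distinct diseases) + Gaussian noise (σ = 15),
  clipped at 0 and rounded; 5% of proteins lack interaction data.  With
  zero noise the per-bin means are exactly linear in the disease count, so
  the binned Pearson correlation is exactly 1.

What the generator does **not** emulate: amino-acid sequences (lengths
suffice for every operation), predictor-specific error structure (errors
are independent per residue, real predictors err in runs), correlation
between disorder content and disease category, and the long tail of real
location vocabularies.  Passing tests therefore demonstrate that the
*bookkeeping and statistics* are correct and that planted signal is
recovered at the stated rates — not that the biological effect sizes of any
real proteome are reproduced.

## Numerical choices

* Coordinates are 1-based inclusive everywhere; interval sets normalize by
  sorting and merging overlapping *and adjacent* spans, so `total_length`
  is always the non-redundant residue count.
* Printed percentages/ratios: decimal half-up to one decimal place (2.55 →
  2.6), matching published table formatting conventions; raw integers are
  always emitted so every rounded value is recomputable.
* An empty category (no call-containing protein) reports average
  annotations as 0 with an `empty_category` flag rather than NaN.
* Ranking ties on pProS residues break lexicographically by accession.
* Correlation is undefined (raised, and flagged in the report) with < 2
  bins or zero variance on either axis.
* Report determinism: every table sorts on documented keys, and run
  timings go to the log, never into report files, so identical inputs and
  config give byte-identical reports regardless of input row order.
* The pipeline stages its report to a temporary directory and renames it
  into place, so a failed run leaves no partial output.

## Scale of the bundled analyses

The test suite and the acceptance script run entirely on generated or
hand-coded cohorts: oracle-equivalence checks use ~1000 random small
instances per operation, parameter-recovery runs use 500–2000 proteins.
These sizes give binomial sampling errors comfortably inside the asserted
tolerances (e.g. ±0.02 on a 0.30 disorder fraction needs n ≈ 500 at the
chosen Beta concentration) while keeping a full run in seconds.

## Known limitations

* The keyword rule is lexical; descriptions whose binding semantics hide
  behind other vocabulary ("docking", "recruitment") are missed unless the
  keyword sets are extended in the config.
* Feature locations must have explicit integer endpoints; UniProt's unknown
  or fuzzy endpoints (`?`, `<`, `>`) are out of dialect.
* The localization classifier matches exact normalized terms; GO ontology
  resolution is out of scope.
* Disorder tracks are consumed, never computed: conclusions inherit the
  predictors' biases.
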