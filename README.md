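# pross

Mining short binding segments in consensus-predicted intrinsically
disordered regions of proteins, with disease-category, subcellular-
localization and protein-interaction statistics over the calls.

## The problem

Intrinsically disordered regions (IDRs) lack a fixed structure but often
carry short segments — typically well under 30 residues — that fold when
they bind a partner protein.  Experimentally verified examples of such
*protean segments* number only in the hundreds, yet curated feature
annotations ("Interaction with USP7", "Loss of interaction with MDM2",
"LXXLL motif") plus practical-grade disorder predictors let one mine
candidates proteome-wide.  `pross` implements that procedure for anyone
analysing UniProt-style annotation tables of disease cohorts: it calls
**possible protean segments (pProSs)** and computes the downstream
statistics such a study reports.

## The method in brief

For each protein with feature annotations and up to three per-residue
disorder tracks (MobiDB-lite, DISOPRED3, DICHOT — consumed as input):

1. keep annotations of the classes *region of interest*, *mutagenesis site*
   and *short sequence motif* that span ≤ 29 residues (non-redundantly);
2. keep binding-associated descriptions: regions matching
   `interact|bind|motif`, mutagenesis sites matching `interact|bind` without
   a whole-word `no`/`not`, and all short sequence motifs;
3. a residue is consensus-disordered when ≥ 2 of 3 predictors call it;
4. a kept annotation fully inside consensus disorder (coverage threshold
   1.0, configurable) is a pProS.

Over the calls the pipeline computes per-disease-category protein coverage
(% of category proteins with ≥ 1 call), average annotations per
call-containing protein, redundancy under multiple disease assignments,
non-redundant pProS residue rankings (overlapping annotations 360–365 and
360–362 count six residues, once), residue-weighted IDR fractions per
subset, location-class enrichment as log₂ of a ratio of ratios (N / C / M /
CN classes, CN = cytoplasm-and-nucleus shuttling proteins), and the Pearson
correlation between per-bin interactor counts and disease multiplicity.
Details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

The packaged `p53_like` fixture is a 393-residue transcription-factor-like
protein with disordered termini and eleven short binding annotations,
three of them stacked at residues 15–25:

```sh
pross fixture p53_like --out demo_in
pross run --features demo_in/features.tsv --tracks demo_in/tracks.tsv \
          --diseases demo_in/diseases.tsv --locations demo_in/locations.tsv \
          --ppi demo_in/ppi.tsv --out demo_report
# 11 segment calls in 1 proteins (1 proteins analyzed); report in demo_report
```

`demo_report/pros_calls.tsv` (abridged):

```
accession  feature_id  feature_type          start  end  idr_coverage  selection_reason
P53LIKE    F01         short_sequence_motif  15     25   1.0           motif_class
P53LIKE    F02         mutagenesis_site      15     25   1.0           keyword_mutagenesis
P53LIKE    F03         mutagenesis_site      15     25   1.0           keyword_mutagenesis
...
P53LIKE    F11         region_of_interest    368    387  1.0           keyword_region
```

All eleven annotations sit fully inside the two-vote consensus IDRs, so all
are called; the three entries at 15–25 stay separate calls because they
describe different binding events.  `table2.tsv` then shows the category
bookkeeping — the protein carries eight cancer diseases, so its 11 unique
calls count 88 times redundantly in that category (redundancy 0.125), but
only once in the nervous-system row (redundancy 1.0):

```
category  n_unique_pros  n_proteins_with_pros  n_proteins  coverage_pct  avg_annotations  pros_counts_redundant  pros_redundancy
Can       11             1                     1           100.0         11.0             88                     0.125
Ner       11             1                     1           100.0         11.0             11                     1.0
```

and `table3.tsv` ranks the protein at 62 non-redundant pProS residues
across 9 distinct diseases.

For realistic cohorts, generate synthetic inputs with known ground truth
(five tables plus `ground_truth.tsv` listing every planted segment, true
disorder interval, location class and disease count):

```sh
pross generate --seed 7 --n-proteins 500 --out cohort
pross run --features cohort/features.tsv --tracks cohort/tracks.tsv \
          --diseases cohort/diseases.tsv --locations cohort/locations.tsv \
          --ppi cohort/ppi.tsv --out report
```

Everything is also available as a library: `pross.analyze_cohort(records)`
returns the per-protein consensus, calls and all report tables in memory.

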