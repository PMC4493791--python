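# Methods

## The analysis problem

A single PCR amplicon (~2–2.5 kb, one primer pair, + strand only) captures
alleles of every *Hd1* homologue in a *Miscanthus* accession: two to five
distinct sequences per diploid, implying at least `ceil(max/2) = 3` loci.
The analysis must (i) discover transposable-element insertion polymorphisms
among the alleles, (ii) decide which alleles are functional, (iii) separate
the two diverged loci phylogenetically, and (iv) summarize the geography of
functional vs non-functional alleles and its (lack of) relation to heading
date. Every stage is driven purely by the sequences plus accession metadata.

## Gene model and coordinates

The reference frame is a `GeneModel`: a single + strand sequence, two exons
as 0-based half-open intervals, the ATG offset within the spliced
transcript, and a polyadenylation site 159 bp downstream of the stop codon.
All coordinates elsewhere (insertion sites, event truth records) are offsets
on this reference. Exon intervals are lifted onto an allele through a global
pairwise alignment (biopython `PairwiseAligner`; match +1, mismatch −2, gap
open −10, extend −0.5 — open ≫ extend so a transposon insertion aligns as
one contiguous gap). Boundary convention for lifting an interval `[s, e)`:
insertions strictly inside are retained in the CDS, insertions placed
exactly at either boundary fall outside it (UTR- or intron-side). An
unliftable coding-exon boundary (e.g. deleted in the allele) is an error
naming the exon.

## MITE discovery

Between a functional reference and a query allele, every maximal query-only
alignment run is an insertion candidate. The discovery rule:

- gaps of length ≥ 500 bp are plain insertions, never MITEs (strict
  inequality: 499 accepted, 500 rejected);
- shorter gaps are MITEs when a TSD and a TIR are found;
- 6 bp gaps without MITE structure are possible excision footprints.

**TIR** (`detect_tir`): the longest k ≤ len/2 with the first k bases equal
to the reverse complement of the last k, tolerating `max_mismatch`
mismatches (default 1; minimum length 4). **TSD** (`detect_tsd`): the
longest exact direct repeat of 2–12 bp shared by the element's flanks, ties
to the longest. Both windows are config knobs (`ScanConfig`); the printed
superfamily criteria — TSD 8 with TIR > 5 → *hAT*, TSD 3 with TIR > 4 →
*PIF/Harbinger*, all else unclassified — are a fixed total rule table.

**Placement ambiguity.** A gap bounded by repeated sequence can be placed at
several reference offsets with equal alignment score, and on diverged
queries the score-optimal placement can sit a few bases from the biological
insertion point; the scanner therefore enumerates all equivalent placements
plus a ±12 bp window. Distinct (placement, TSD) readings of one gap can each
show genuine terminal structure — shifting the element window by one
complementary flank base converts (TSD 8, TIR t) into (TSD 6, TIR t+1), and
peeling one base off each terminus converts it into (TSD 10, TIR t−1).
Readings are ranked by (1) whether (TSD length, detected TIR) satisfies a
known superfamily criterion — the prior an annotator applies when naming an
element — then (2) the combined exact evidence `2·TIR_exact + TSD`, then the
exact TIR alone. The reported position is the element start of the chosen
reading; plain insertions and footprints report the leftmost equivalent
placement, and every candidate keeps its equivalent-placement interval so
site comparisons are rotation-proof.

**Families** are single-linkage clusters of element sequences at ≥ 80%
ungapped identity (position-wise matches over the longer length), numbered
by first appearance; the pipeline then renumbers so families inserted into
the coding sequence come first, preserving the convention that the family-1
code implies loss of function. **Footprints**: an allele is a revertant
candidate when it carries exactly a 6 bp insertion whose placement interval,
widened by ±8 bp (substitutions adjacent to a site shift the optimal gap
placement by a few columns, so a strict ±0 match would miss true footprints
on polymorphic backgrounds), covers a known element insertion site; known
sites are the discovered element start positions across the panel.

## Allele classification

`translate` applies the standard code from position 0, renders stops as `*`
(reading through them) and ambiguous codons as `X`. An ORF is *intact* when
the translation has no stop before the reference terminal codon **and** the
CDS length is congruent to the reference length mod 3 — both observed
loss-of-function mechanisms (a 1 bp insertion; a MITE-introduced stop)
reduce to these two tests. Decision order of `classify_allele`:

1. any MITE hit of family k → code `Mk`, functional iff the ORF is intact
   (covers loss-of-function exonic insertions as well as harmless
   intronic/UTR ones);
2. footprint with intact ORF → `R` (revertant), functional;
3. footprint with disrupted ORF → `N` — a footprint plus an additional
   loss-of-function mutation is not a revertant;
4. disrupted ORF → `N`;
5. otherwise `F`.

The result is independent of the listing order of MITE hits (hits are
sorted by position; the lowest-position family names the code, further
families go into the record's notes).

## Phylogenetics

The K2P distance is computed from transition (P) and transversion (Q)
fractions over retained columns, `d = -½ ln((1-2P-Q)√(1-2Q))`; columns with
a gap or N in either sequence are dropped per pair (pairwise deletion —
"ignoring indels"). Arguments outside the formula's domain raise a
saturation error rather than returning a pseudo-distance. Alleles are
near-identical, so no multiple alignment is built: each allele's base at
each reference column (via its pairwise alignment) forms a
reference-anchored matrix; insertions are invisible there, which matches
the distance model.

Neighbor-Joining follows Saitou & Nei exactly (Q-matrix minimization,
limb-length formulas, matrix reduction; final three taxa joined at an
unrooted trifurcation); on additive matrices the tree reproduces the input
distances (tested to 1e-9). Ties in the Q matrix break on the lowest index
pair; negative limb estimates are clamped to zero with the deficit moved to
the sister edge. Bootstrap supports resample alignment columns with
replacement (implemented as column weights against precomputed per-pair
transition/transversion/valid masks, so 100–1000 replicates on >100 taxa
stay fast); support is the percentage of replicates containing each
internal bipartition of the full-data tree, replicates hitting saturation
are skipped with a warning but still count in the denominator. Rooting
places the root at the midpoint of the outgroup's pendant edge; rooting is
idempotent and preserves edge lengths and supports. The two locus clades
are the children of the ingroup subtree root; when marker alleles (carriers
of the pseudogene-diagnostic 5'-UTR element family) are supplied, the
partition's concordance is the largest fraction of markers falling in one
clade.

## Synthetic panels

The generator emulates the assumed evolutionary scenario with a recorded
ground truth per allele. Construction order (one seeded `numpy` stream,
consumed in a fixed order: family elements, reference, locus ancestors,
outgroup, then accessions in creation order):

- **Reference** — the duplication-point ancestor: a random CDS of 400
  codons (built from non-stop codons, hence a clean ORF) split near its
  midpoint by a GT..AG intron, with 150 bp 5' UTR, 600 bp intron and 200 bp
  3' UTR by default (~2.15 kb; the full-scale acceptance run uses 800/250
  for ~2.4 kb). The polyA offset is 159 bp.
- **Loci** — the *Hd1a* and *Hd1b* ancestors each diverge by half the
  configured locus divergence (default 0.08 substitutions/site between
  them) from the duplication point; the outgroup diverges 0.15 from the
  same point. This mirrors the history in which the duplication postdates
  the split from the outgroup lineage, and it is what places the outgroup
  on the inter-locus edge so the deepest ingroup split is the locus split.
- **Substitutions** — a K2P process whose per-site transition/transversion
  probabilities are the exact K2P transition probabilities at the requested
  divergence, so the distance estimator is consistent for the configured
  rate (checked at 10 kb). Functional lineages evolve under purifying
  selection on the reading frame: a substitution creating a premature
  in-frame stop, or destroying the terminal stop, is reverted. The
  pseudogene lineage is unconstrained.
- **Events** — per *Hd1a* allele, a mutually exclusive categorical draw with
  region-specific probabilities: MITE1 insertion (hAT-like, 180 bp, TSD 8,
  TIR 10, at a fixed codon-boundary site in exon 1 → code M1,
  non-functional), an excision footprint `CCAGAT` at the same site (in
  frame: the protein gains proline + aspartate → code R; with probability
  `p_frameshift` an additional independent 1 bp exonic insertion is also
  planted → code N, the revertant exception), a plain 1 bp frameshift
  (→ N), or a MITE5 insertion in the intron (hAT-like, 120 bp → code M5,
  functional). *Hd1b* alleles all carry the shared 1 bp pseudogenizing
  insertion plus a 5'-UTR MITE2 (PIF/Harbinger-like, 250 bp, TSD 3) → code
  M2, non-functional. Events are planted after the substitutions, so TSDs
  and TIRs are exact — the noise-free regime in which the scanner's
  perfect-recovery property is meaningful.
- **Default event probabilities** mirror the published panel's proportions
  (Japan: M1 0.25, footprint 0.03, frameshift 0.22; mainland: footprint
  0.37, M5 0.04; second locus present in 35% / 50% of accessions); they are
  config-exposed, not asserted as biology.
- **Heading dates** — day-of-year = 430 − 5.2·latitude + N(0, 12²) per year
  (two trial years), matching the published cline's slope and spread;
  latitudes are uniform over each region's range (Japan 26–44°N, mainland
  19–42°N).

What the generator does **not** emulate: coalescent genealogies and shared
polymorphism among alleles of one accession, recombination, indel noise
other than the planted events, tetraploid genotypes, and non-uniform
geographic sampling. Passing round-trip tests therefore demonstrate the
correctness of the discovery and classification logic under clean planted
signals, not performance on noisy real amplicons.

## Published-table transcription

The packaged TSV transcribes the published 44-accession table one row per
allele call: codes printed under the *Hd1a* heading (including M1/M5) are
locus *Hd1a*; codes in the M2/M3/M4 columns are *Hd1b*. This reconstruction
reproduces the printed totals (46 mainland *Hd1a* alleles, all functional;
35/68 functional Japanese alleles; 2–5 alleles per accession). Tokens like
`M2/4` denote one allele carrying two elements in tandem (primary code M2,
the second element noted). The one footprint-bearing allele with an
additional loss-of-function mutation is stored with its printed code R plus
the note `footprint+LOF`; the loader normalises it to code N,
functional = false. The two M5 alleles are marked functional with a
provenance note, consistent with the statement that all mainland alleles
appeared functional. Heading cells: dashes are missing; `non` is a
did-not-head sentinel, excluded from correlations (no imputation is
attempted; the choice is logged).

Correlation conventions: the between-year correlation uses accessions with
a real date in both years (n = 7); the latitude cline uses the mean
day-of-year over whichever years were recorded, all species, n = 24. The
printed values (0.889 and −0.853) come from an inclusion set the source
does not enumerate; the recomputed values (0.904 and −0.851) agree within
±0.05 and the tests assert exactly that tolerance.

## Numerical and scale choices

Tolerances: NJ additive recovery 1e-9; K2P closed-form checks 1e-12;
correlations ±0.05 (see above); the simulated latitude cline is checked
against the generating model within ±0.1 at n = 100 accessions. The
full-scale acceptance run uses 40 accessions (2–5 alleles each, ~2.4 kb
gene) and 200 bootstrap replicates — enough for stable supports on ~130
taxa while keeping a complete run within a few minutes on one CPU; the
published setting of 1000 replicates is the CLI default for real use.
`scripts/acceptance.py` derives all randomness from `--seed` and re-runs
the packaged-table analysis, a 100-plant scanner experiment, a
16-accession round-trip panel with elevated event probabilities (so every
classification rule occurs), and a default-scale end-to-end pipeline with
100 replicates.

## Known limitations

- Deletion polymorphisms (element present in the reference, absent in the
  query) are out of scope; the annotator resolves polarity by choosing a
  functional allele as reference.
- Footprint detection requires a known historical insertion site discovered
  elsewhere in the panel; a panel containing only revertants (no extant
  element carrier) yields R-alleles classified F.
- The locus partition assumes the pseudogene lineage is monophyletic and
  the outgroup attaches outside both locus radiations; with very low locus
  divergence or saturated outgroups the deepest ingroup split need not be
  the locus split.
- Family naming is panel-relative: numbering depends on discovery order,
  so codes are comparable within one analysis, not across panels (the
  round-trip tests map families by consensus identity).
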