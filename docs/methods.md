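# Methods

## Somatic calling model

The caller is a deterministic hard-filter design, not a probabilistic
genotyper: it is intended for well-covered exome pileups where a handful of
fixed thresholds separate clonal somatic substitutions from noise. For each
tumor site the highest-count non-reference allele is taken (ties broken to
the lexicographically smaller base and flagged multi-allelic); only base
calls at Phred ≥ `min_base_quality` (default 30, error ≤ 0.001) count toward
the allele, while depths and percent denominators use the full pileup depth.
A call requires tumor depth ≥ 20, alternate count ≥ 6 and alternate integer
percent ≥ 25; the matched normal must be covered (`min_normal_depth`,
default 1 — sites with no normal coverage are not callable, configurable)
and may carry the allele at ≤ 10 %. "Integer percent" is
`100·count/depth` rounded half away from zero, computed in exact integer
arithmetic (`(200c + d) // 2d`); this is the rounding that reproduces
printed mutation fractions such as 8/23 → 35 % and 1/14 → 7 %.

Indels in the pileup base string are parsed past but never called, and the
`*` deletion placeholder occupies a quality slot without counting toward any
allele: the pipeline's targets are substitutions at splice sites.

## Coordinates and naming

All internal coordinates are 1-based inclusive; BED input is converted from
0-based half-open at the parser, and the two-number locus format in TSV
output (`contig,pos−1,pos,1,REF/ALT`) keeps both conventions visible.
Intronic positions are named `c.N+k` after the donor whose last coding base
is N, or `c.N−k` before the acceptor whose first coding base is N, anchored
at the nearer intron end (exact midpoint → donor side). Reported alleles
default to the plus (genomic) strand even for minus-strand genes — the
convention used in the tabulated variant names this package mirrors — with a
`transcript` option for strict coding-strand HGVS. UTR-aware forms
(`c.*`, `c.−`) are out of scope; naming requires CDS bounds.

## Splice-region annotation

A variant is *splicing* when its intronic offset to the nearest boundary is
≤ 20 bp, inclusive at both ends. The 20-bp collection window is deliberately
wider than the scoring footprint: variants at offsets beyond the footprint
are annotated and scored as "site intact" rather than dropped. Known-variant
and segmental-duplication exclusions are hard filters; conservation is an
annotation only (with an optional `require_conserved` hard filter), because
conservation is a prioritization preference rather than a validity
criterion.

## Site models and the consensus loss call

Scoring windows are a 9-mer donor (3 exonic + 6 intronic) and a 23-mer
acceptor (20 intronic + 3 exonic) — conventional footprints that cover the
canonical GT/AG cores, the donor +3…+6 consensus and the polypyrimidine
tract. Three models are trained on aligned canonical-site sequences with
pseudocount 0.1 and background 0.25:

- **wmm** — per-position base probabilities; score is the summed log2 odds.
- **wam** — first-position marginal plus first-order conditionals
  P(bᵢ | bᵢ₋₁); its attainable maximum is found by dynamic programming over
  the base chain.
- **consensus_ic** — per-position information content IC = 2 − H and modal
  base; the score is the IC-weighted fraction of matched positions
  multiplied by ∏(1 − IC/2) over mismatched positions, so a mismatch at a
  near-invariant position (IC → 2) disqualifies the site regardless of how
  well the rest matches.

Log-odds scores are normalized to [0, 1] by flooring the raw score at 0 (the
uniform-background score) and dividing by the model's attainable maximum.
A full min–max over the attainable range was considered and rejected: with
two or more informative positions, a single-base substitution can remove at
most its own per-position share of the total range, so no threshold can
separate intact sites from every single-base core kill under that scale.
With the background floor, the drop from destroying one core position is
measured against the positive (signal) range only, and a single recognition
threshold works.

A site is *recognized* at normalized score ≥ 0.4. The bundled training sets
are authored with invariant donor +1/+2/+5 and acceptor −2/−1 columns and
deliberately weak flanks, calibrated so that all three models score
canonical sites ≥ 0.4 and any single-base substitution of an invariant core
position < 0.4. A loss is called only when every method recognizes the
wild-type window and none recognizes the mutant (all-of-3 consensus); the
reported probability, 1 − ∏ min(1, mutᵢ/wtᵢ), is a monotone summary of the
score drop in [0, 1] and is not comparable to any external classifier's
posterior. N bases score as background in all models.

## RNA-seq event quantification

Junctions come from the `N` CIGAR operations of primary, mapped records
(deletions keep an aligned block contiguous; splices break it). At a mutated
boundary the informative reads are:

- **wild-type** — junction reads matching either canonical junction of the
  mutated exon (both flanks are counted: a skip event's wild-type support is
  the sum of the two canonical junctions around the skipped exon);
- **exon skip** — the junction joining the two exons flanking the mutated
  exon;
- **intron retention** — reads whose aligned blocks continuously cover
  `[boundary − a + 1, boundary + a]` with anchor a = 6 bp (a read whose
  splice starts exactly at the boundary is spliced, not spanning);
- **cryptic** — a junction sharing one end with a canonical boundary whose
  other end lies within ±50 bp of the mutated boundary.

Percentages are integer percents of the sum of these counts; junctions
elsewhere on the contig are ignored, and zero informative reads yields an
explicit `not_expressed` status rather than percentages. Allele support in
retained-intron reads reports mutant/wild-type counts and an
`exclusive_mutant` flag (≥ 1 mutant, 0 wild-type); the flag is evidence
that retention segregates with the mutation, never a causal claim by
itself. FPKM is `count / ((L/1000)·(total/10⁶))` over the exon-union model
length, pairs counted once; percentile rank is the percent of dataset
values ≤ the value, over whichever gene universe the caller supplies
(default: all genes in the table, including zeros).

## Synthetic scenarios

`synthetic_data.build_scenario` writes a complete miniature study per named
scenario: a single-contig reference with one engineered transcript, GTF,
tumor/normal pileups, spliced SAM, exclusion BEDs and `truth.json`. The
planted numbers are the conditions the pipeline is validated against:
tumor/normal depth and allele counts (23/8 vs 65/0; 186/87 vs 153/0; 59/30
vs 36/0; 90/73 vs 63/0; 93/48 vs 14/1; 37/19 vs 43/0), junction tables
(28/5/3 exon-skip; 7 canonical + 5 all-mutant spanning retention; 58
canonical + 37 reference-allele spanning + 5 cryptic at +5 into the exon),
and exon ladders whose cumulative coding lengths land the planted variants
at c.735+1, c.1662−1, c.1783−1, c.1312+5, c.568−2 and c.10242+5. Splice
sites are painted with the motifs the bundled models are trained on
(`CAG|GTAAGT`, CT-repeat tract + `AG|GTC`); base qualities are Phred 40 so
the quality filter is inert unless a scenario plants low-quality calls.

What the generator does **not** emulate: sequencing error, mapping
ambiguity, indels, multi-isoform gene models, coverage variation along the
gene, and fragment-pair geometry. Passing tests therefore demonstrate the
correctness of the arithmetic and decision logic under clean planted
conditions, not robustness to real-data noise.

`random_scenario` plants n randomized variants (default 50, depths 10–120,
fractions 5–95 %, 15 % of alternate calls at Phred 20) and labels each
callable/uncallable by an independent re-statement of the filters written at
generation time, so caller recall/precision can be scored without circular
use of the caller itself. All generation is `numpy` seeded and byte-stable.

## Numerical and degenerate-input choices

- Percent arithmetic is exact-integer; no floats in any threshold decision.
- Probability rows of trained models must sum to 1 within 1e-9.
- Degenerate training (all sequences identical) gives the consensus
  sequence a score of exactly 1.0; uniform training gives maximum raw score
  ≤ 0 and every sequence scores 0.
- A variant inside the 20-bp window but outside the scoring footprint
  yields an explicit no-change prediction (wt ≡ mut), not an error;
  `predict` on literally identical windows is a caught usage error.
- Zero-depth percent, zero-length/zero-total FPKM and empty percentile
  datasets raise; a depth-0 pileup site round-trips with empty call/quality
  columns.

## Problem sizes

Scenario contigs are 1–19 kb with 4–53 exons; pileups contain ≤ 5 sites and
SAM files ≤ 100 reads; randomized caller fixtures use 50–100 sites. The full
test suite and the acceptance script each complete in a few seconds.

## Known limitations

- The three scoring models are transparent stand-ins honoring a
  recognized/lost decision contract with 0–1 scores; their absolute score
  values are not comparable to published neural-network or Bayes-classifier
  splice tools, and no attempt is made to reproduce such scores.
- Annotation is per transcript; overlapping isoforms are not collapsed.
- Cryptic sites are detected from RNA junctions only, not predicted de novo
  from DNA.
- The caller has no likelihood model, so marginal sites near the thresholds
  flip deterministically with single reads — by design.
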