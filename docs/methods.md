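# Methods

`founderscan` implements the analysis arc of a pedigree identity-by-descent
(IBD) study in a deep founder kindred: find chromosomal segments that three
or more distantly related affected individuals inherited from a common
ancestor, reduce them to plausible risk haplotypes, reconstruct each
haplotype's full allele sequence, and prioritize the rare deleterious
variants that ride on it. Because the real whole-genome data for such
studies are access-controlled, the package includes a first-class gene-drop
simulator that reproduces the study design and provides exact transmission
truth for validation.

## The pedigree model

A pedigree is a directed acyclic ancestry graph. Six labelled founder
couples ("founder pairs", A–F) sit at generation 0; married-in individuals
are unlabelled founders. Two queries drive the analysis:

* **founder ancestry** — the set of founder pairs an individual descends
  from, by graph reachability (a founder-pair member counts as its own
  descendant);
* **meiotic distance** — the minimum, over common ancestors, of the number
  of parent–child steps separating two individuals.

Diagnoses are sets (tic disorders co-occur with OCD and ADHD labels);
"affected" means a confirmed or probable diagnosis of Tourette syndrome or
chronic motor/vocal tic disorder. OCD-only and unaffected individuals are
pedigree controls. Coordinates are 1-based inclusive throughout and
interval length is `end_bp − start_bp`.

## Synthetic data: what the gene drop emulates

`simulate_dataset` builds one replicate of the study design:

* **Pedigree skeleton.** Each of 19 sampled individuals receives a private
  descent chain from its founder pairs, with the ancestry-set mix copied
  from the published carrier matrix (9 descendants of pair B, etc.).
  Private chains mean sampled individuals are related only through the
  founder couples, keeping pairwise meiotic distances ≥ 10 at the default
  6 generations — the desk-scale stand-in for the real 11-generation
  design. Fewer generations than the founder-set sizes allow is an error.
* **Markers and founder haplotypes.** Two 50 Mb chromosomes at 100
  WGS-like markers/Mb (an array-like subset of every 5th common marker,
  20/Mb, models the control genotyping chips). Background alt frequencies
  are uniform on [0.05, 0.5]; founder haplotypes are independent
  Bernoulli(f) draws. There is deliberately no background LD: linkage in
  the data arises only from transmission, which is the signal the IBD
  machinery must detect. This is the main idealisation relative to real
  data — population LD would lengthen chance allele-sharing runs and is
  not exercised by these tests.
* **Transmission.** Each meiosis draws a Poisson crossover count (map
  length in Morgans, 1 cM/Mb, no interference) with breakpoints uniform in
  cM, and the child's chromosome is recorded as an exact mosaic of founder
  haplotype origins (the truth record). Haplotype allele errors are
  applied i.i.d. at rate 0.001 by default.
* **Planted risk haplotype.** A 3.53 Mb interval of one founder-pair-B
  chromosome (matching the scale of the study's chromosome 1 haplotype)
  carries two embedded rare variants: a qualifying deleterious missense
  variant (AMR AF 0.002, damaging SIFT/PolyPhen, CADD 23.8) and a
  non-qualifying intronic decoy (CADD 6.5, ncER 80). Embedded alt alleles
  have background frequency 0, so no other founder or control carries
  them. Transmission to a chosen set of 4 sampled descendants of pair B
  uses *conditional gene drop*: meioses on those lineages are resampled
  until they transmit the planted interval. Unconditional transmission
  down ≥ 5 private meioses per lineage would almost never reach three
  carriers at desk scale; conditioning is the standard way to guarantee
  segregation without altering the crossover model elsewhere. Note that
  carriers also co-inherit founder sequence *flanking* the planted window,
  so the recoverable shared segment — reported by
  `TransmissionTruth.shared_interval` — is generally larger than the
  planted window. All truth comparisons use that interval.
* **Phasing model.** The phased panel omits a random 3.2% of markers plus
  all planted rare variants (rare alleles are exactly what statistical
  phasing against a reference panel misses); those sites exist only in the
  unphased WGS genotype matrix and must be recovered by fine-mapping.
* **Phenotypes.** Carriers of a planted haplotype are affected with
  penetrance 0.8, non-carriers with phenocopy rate 0.1 by default. When
  phenocopies are possible, the number of affected non-carriers is then
  resampled so exactly 17 of 19 sampled individuals are affected,
  emulating the ascertained design; with a phenocopy rate of 0 the pure
  penetrance model stands (so penetrance 1 / phenocopy 0 makes the
  affected set equal the carrier set, the configuration used for the
  recovery benchmarks).
* **Controls.** Two cohorts of 49 and 42 unphased array-genotyped
  controls drawn from the background frequencies. For negative-control
  experiments, the contaminating founder chromosome can be planted (one
  copy, whole chromosome) into the first 5 controls of each cohort — a
  founder haplotype that is common in the population.

## QC

Fixed filter order: individual missingness (> 0.05 removed) → marker
missingness (> 0.01) → exact Hardy–Weinberg test (p < 0.001) → MAF
(≤ 0.05) → Mendelian-inconsistency screen over genotyped parent–offspring
pairs → LD pruning. The HWE test is the exact conditional test (two-sided
by probability mass, computed with log-gamma weights); asymptotic tests
are invalid at 19 samples. By default all samples enter the HWE test — on
a pedigree this inflates heterozygote correlation slightly, and a
founder-independent subset can be supplied instead (`hwe_sample_ids`).

LD pruning slides 500 kb windows advanced by 50 markers; within a window
the worse member of the highest-r² offending pair (> 0.6) is removed —
lower MAF first, ties to the later position. Because stepped windows can
miss a pair that is within 500 kb but never shares an examined window, a
completeness sweep then scans every remaining within-window pair and
prunes by the same rule, which also makes the result idempotent. r² is the
squared Pearson correlation of dosages over pairwise-complete
observations; zero variance yields r² = 0 (never prunes).

## IBD detection

Detection is seed-and-extend on phased haplotypes, per chromosome and
ordered haplotype pair:

1. **Seeds** are maximal runs of identical alleles with ≥ 64 informative
   sites (missing calls are neutral, observed mismatches break a run). At
   the default frequency spectrum the chance of a random 64-marker match
   is ~1e-13 per position, so seeds are effectively error-free anchors.
2. **Extension** accumulates per-site LOD contributions outward and stops
   once the running sum drops 2.5 LOD below its running maximum; each
   flank is trimmed to its argmax. The per-site LOD is
   log10 P(a,b | IBD) / P(a,b | not IBD), with
   P(a,b | IBD) = Σ_c f_c·q(a|c)·q(b|c), q(x|c) = 1−ε if x = c else ε
   (ε = 0.0025 by default; it also caps mismatch penalties at a finite
   value, ~−2 LOD per error) and P(a,b | not IBD) = f_a·f_b. Sites with
   degenerate frequency (0 or 1) are skipped with a warning.
3. **Merging and thresholds.** Overlapping or near-adjacent intervals from
   the same haplotype pair merge (gap ≤ 100 kb — isolated allele errors
   split one true segment into abutting pieces); segments must exceed 1 Mb
   and LOD 3, the standard high-confidence thresholds.

The LOD here matches published IBD callers in form (log10 likelihood
ratio), not necessarily in value; correctness is assessed against
transmission truth and the length/LOD thresholds, never LOD equality.

Total detected sharing gives a kinship estimate
φ = (ΣIBD1/2 + ΣIBD2)/(2G) (IBD2 where both copies of each individual
participate), binned to a relatedness degree with midpoints 2^−(d+1);
pairs beyond the 9th degree are reported unrelated.

## Multi-IBD clustering

Each chromosome is tiled into 250 kb windows. Per window, a graph over
haplotype copies has an edge for every pairwise segment fully covering the
window; connected components with ≥ 3 copies are window-clusters.
Maximal runs of adjacent windows with identical membership merge, and the
cluster interval is the run intersected with every supporting segment, so
each contributing pair is IBD across the full reported region. Grouping is
transitive by default (multi-IBD tools chain pairwise sharing); a
`require_clique` flag gives the strict alternative. Individuals appearing
with both copies are IBD2 for the cluster haplotype.

## The filter cascade

Fixed order, with a telescoping trace: length (> 1 Mb, strict) →
founder-pair clustering (≥ 3 carriers sharing a founder pair; the
label(s) attaining the maximum count are the main founder pair(s), ties
kept as a set) → control screen → phenotype (every carrier affected;
`confirmed_only` narrows to confirmed diagnoses) → boundary refinement.

The **control screen** works on unphased array genotypes: a control
"carries" the candidate if at every shared marker its genotype contains at
least one copy of the backbone allele (mismatch fraction ≤ 0 by default);
any carrying control removes the candidate. This is conservative by
design: a haplotype common enough to appear in 91 controls — even only
het-compatibly — is exactly what the screen must discard. Fewer than 20
shared markers makes the screen unevaluable (error).

**Boundary refinement** re-defines the interval on the full (unpruned)
phased data: find the largest run inside the cluster interval where all
member copies agree, then extend each flank while agreement holds. Flank
edges are placed at the argmax of a change-point score (+0.45 per
consistent marker, −4.5 per disagreement — the log-ratio of
inside-vs-outside consistency rates), and extension stops after a total
mismatch budget (default 0; the pipeline uses 50) or when 3 of the last 10
markers disagree. Isolated disagreements are allele errors inside a real
segment; locally dense disagreement is the segment end. Members
disagreeing over more than half the original interval mark the cluster
spurious (error).

## Fine-mapping

The haplotype's **backbone** is read directly off the phased data: after
refinement the member copies are mutually identical over the interval, so
each phased marker contributes its allele (strict mode errors on
disagreement; the pipeline uses majority consensus with ties deferred to
genotype assignment, tolerating residual allele errors). Every remaining
WGS site is assigned by genotype contrast: allele x is *consistent* iff
every observed carrier's dosage of x is at least its copy number (an IBD2
carrier must be homozygous). A unique consistent allele is assigned; if
both are consistent, the allele absent from every non-carrier is assigned
when exactly one exists; otherwise the site is explicitly unassigned. No
consistent allele flags the site discordant (genotyping error), reported
rather than dropped. This rule is validated exhaustively against a
diplotype-enumeration oracle for all configurations of ≤ 4 carriers and
≤ 4 non-carriers.

**Haplotype-specific variants** are assigned-alt sites whose alt allele
has dosage 0 in every sampled pedigree individual outside the carrier set.

## Prioritization

Variants are classified by reference-population (AMR) frequency —
ultra-rare < 0.001, rare < 0.01, common otherwise, boundaries excluded;
a missing AF is treated as rarest and flagged. Common variants are
dropped; the rest route by consequence:

* **coding** (missense, frameshift, nonsense, splice-site): SIFT
  deleterious (including low-confidence), PolyPhen probably- or
  possibly-damaging, and CADD phred > 20 — a conjunction, with
  `cadd_or_predictors` for the disjunctive reading and `strict_polyphen`
  to exclude possibly-damaging;
* **non-coding** (intronic, UTR, promoter, intergenic, non-coding
  transcript): CADD phred > 10 and ncER percentile > 95. ncER values are
  consumed precomputed; sites with unstable GRCh38→hg19 conversion carry a
  null ncER and fail with reason "unliftable".

All inequalities are strict. The report is one row per variant with
scores, rarity class, branch, maximum population AF (ties to the
lexicographically first population, flagged), and failure reasons.

PolyPhen "possibly damaging" is accepted by default because the published
variant table retains a possibly-damaging missense variant; SIFT
"deleterious low confidence" likewise counts as deleterious for the same
reason.

## Fixtures

The three published result tables are transcribed as package data. Two
rows' printed lengths disagree with their printed coordinates (haplotypes
4.1 and 20.1); they are stored verbatim and flagged, not corrected. One
row's carrier-id column is not cleanly recoverable from the published table;
the stored ids are the unique assignment consistent with the printed
founder-pair sets and the stated coverage of fourteen affected
individuals, flagged ambiguous. Where a carrier's founder-pair set
conflicts between the haplotype table and the carrier matrix (ids 9 and
19), the carrier matrix is followed and the conflict recorded. A synthetic
pedigree realising the carrier matrix's ancestry sets (private descent
chains per individual) stands in for the protected real pedigree in tests.

## Problem sizes and verification

The default desk-scale configuration (2 × 50 Mb, 100 markers/Mb, 19
sampled, 91 controls) runs the full pipeline in a few seconds, so the
benchmarks use 20 replicates: under penetrance 1 / phenocopy 0, the
planted haplotype survives the cascade with both refined boundaries within
0.25 Mb of the truth shared interval in ≥ 90% of replicates, the planted
missense variant is the unique prioritized variant in those replicates,
and a control-contaminated haplotype is removed in 100% of replicates.
What these tests do *not* show: behaviour under population LD, real
phasing error structure, or genome-scale marker counts.

## Known limitations

* No background LD, mutation, interference, or X-chromosome inheritance
  in the simulator.
* IBD detection requires phased input; there is no unphased-genotype mode.
* The refinement/backbone error tolerances assume sporadic, independent
  allele errors; systematic phasing switch errors are not modelled.
* Headline counts from the real study (339 clusters → 11 haplotypes;
  546,047 QC-surviving variants) depend on the protected genotypes and are
  covered property-style, not numerically.
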