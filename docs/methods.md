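# Methods

This note documents the models, statistics and numerical conventions
implemented by `codonramp`, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Encoded translation speed

Per-codon translation speed is taken from a **ribosome residence time
(RRT)** table: one positive, dimensionless value per sense codon, measuring
how long a ribosome dwells with that codon in the A-site (higher = slower).
The table is an input (`io_formats.load_rrt_table`); the package validates
that exactly the 61 sense codons are present and positive. Stop codons have
no residence time and any lookup of one fails loudly. A *neutral* residence
time (default **1.0189**) is attached to the table; it is the value
substituted when a codon's speed signal is deliberately masked (see
*Neutralization*).

A gene's **speed profile** is the RRT of each codon at positions
1..N−1, where position N is the stop. Profiles refuse genes with internal
stop codons.

## The RIT statistic

The **relative initial translation speed (RIT)** of a gene compares a
terminal window to the rest of the same gene on the RRT scale:

    RIT = log2( mean RRT(codons 2..W) / mean RRT(codons W+1..N−1) )

* Position 1 is omitted: it is the invariant initiator ATG, one of the
  fastest codons, and would bias every gene identically.
* The stop codon is omitted.
* **Sign convention: positive RIT = slow start.** A window slower (higher
  RRT) than the body gives a ratio > 1 and a positive log. This matches the
  reporter-construct convention in which a deliberately slow leader scores
  ≈ +0.2 and a fast one ≈ −0.17. (Describing the same quantity on the
  *speed* scale inverts the sign; this package reports the RRT scale.)
* For the 3' end the numerator is the last W sense codons (positions
  N−W..N−1) and the denominator is positions 2..N−W−1.
* A gene needs at least W+2 sense codons so both parts are non-empty.

Genes with RIT > 0 are classified **SIT** (slow initial translation),
otherwise **FIT** (fast); the measure-zero tie at exactly 0 goes to FIT for
determinism. The default window is **W = 40** codons (the region classically
examined for the 5' "ramp"); the reporter-construct analyses use W = 41 to
cover a 41-codon recoded leader.

**Genome-wide slowdown** averages the per-gene window/body RRT ratio:
`mean_ratio_pct = 100 × mean(2^RIT − 1)`, and tests the paired per-gene
(window mean, body mean) differences with a two-sided Wilcoxon signed-rank
test. The pairing is within genes, which is why the signed-rank form is
correct here but not for between-group contrasts (below). A `scale="speed"`
flag averages the inverse-RRT ratio instead; the two scales differ slightly
because averaging does not commute with inversion.

**Neutralization** (`speed_metrics.neutralize`) maps a chosen codon set to
the neutral RRT, leaving the rest untouched. Its purpose is attribution:
recomputing the slowdown after neutralizing the Start-like codons
(ATG, ATT, TTG, ATA — all fast, all depleted in natural 5' leaders because
spurious initiation sites are dangerous there) shows how much of the 5'
effect is due to Start-codon depletion rather than rare-codon enrichment.

**Metaprofiles** report, per codon position p ≥ 2, the mean inverse RRT
over all genes long enough to contain p, with an optional centered
moving-average smoother (odd width, truncated at the edges; width 1 = no
smoothing — the positional width of published sliding-window profiles is
not standardized, so per-position is the default).

## Codon usage and enrichment

`codon_usage.count_usage` pools codon counts over a region of every gene:
`initial_window` = positions 2..W, `rest` = positions W+1..N−1, `whole` =
their union. Position 1 and stops are never counted, so the two parts
partition `whole` exactly. Enrichment ratios are relative frequency in the
initial window over relative frequency in the body, computed over all 61
codons (per-amino-acid normalization is available separately as
`per_aa_frequencies`). A codon never seen in the body has an undefined
ratio and is reported as NaN — no pseudocount is invented. Counting is
pooled over codons, not gene-weighted.

## Terminal Conservation Scores

Conservation of protein termini is scored from protein-BLAST tabular output
(`-outfmt 6`) against a panel of related species, on three 40-residue
windows per query of length M ≥ 100:

* N-terminal: residues 1..40
* middle: residues ⌊M/2⌋+1 .. ⌊M/2⌋+40 (displaced 20 residues C-terminal
  of the exact middle)
* C-terminal: residues M−39..M

Queries are BLASTed as two halves ([1, ⌊M/2⌋] and [⌊M/2⌋+1, M]) and each
window is scored only from its own half's hits. The halving keeps the
comparison fair: local aligners seed more easily in the interior of a
query, so the middle window is deliberately scored from hits where the
homology had to be found at the *start* of a query, exactly as for the true
termini. (The variant that takes the last 40 residues of the first half
instead is available as `alt_mid_window`.)

Scoring, per query window:

1. **Deduplication.** Databases contain multiple submissions per species.
   Per (query, half, species), only the subject whose best HSP bit-score is
   maximal is kept (ties → lexicographically smallest subject id).
2. **Qualification.** A species qualifies if any of its HSPs reaches
   bit-score ≥ 50. Qualifying species with no strong homology still count
   in the denominator, with coverage 0.
3. **Coverage.** For each qualified species, the number of window positions
   (closed 1-based intervals; an HSP [35, 60] covers 6 positions of window
   [1, 40]) covered by the union of its HSP query intervals with bit-score
   ≥ 200. The 200 threshold is the "red" strong-homology band of the BLAST
   graphic summary, applied to the bit-score since that is what tabular
   output provides; both thresholds are parameters.
4. **Score = mean coverage over qualified species**, i.e. equivalently the
   sum over homology lengths L of L × (proportion of qualified species with
   that coverage). Range 0 (no strong homology in the window for any
   species) to 40 (every species covered every position). Species are
   weighted equally.
5. Scores are flagged `ok` only when ≥ 40 species qualify (`min_species`);
   proteins shorter than 100 aa are not scored.

Species assignment uses an explicit subject→species two-column map rather
than parsing subject headers, which vary by database dialect.

## Grouping and correlation

`tertile_split` ranks a gene→value table ascending and cuts it into
bottom/middle/top thirds (remainder genes to the top-most groups; ties
broken by gene id, so the partition is deterministic). Between-group
contrasts use the **two-sided Mann–Whitney rank-sum test** with
**Holm–Bonferroni** adjustment over the three pairs. A paired signed-rank
test is deliberately *not* used here: the groups contain different genes,
so no pairing exists — the signed-rank form is reserved for the within-gene
window-vs-body comparison. Genes missing from the response table are
dropped and counted. Correlations are Spearman's over the gene-id
intersection (average ranks for ties); distribution contrasts use the
two-sample two-sided Kolmogorov–Smirnov test. All tests are nonparametric;
no normality is assumed anywhere.

## Leader recoding and the collision pair

`recoder.recode_window` rewrites codon positions 2..W (default W = 41) of a
source ORF with synonyms chosen per position: **fast** = minimum-RRT
synonym, **slow** = maximum, **medium** = synonym closest to the neutral
RRT. The window-mean objective is separable over positions, so the
per-position choice is provably globally optimal for fast/slow. Synonym
ties break lexicographically. With `avoid_starts` (default), Start-like
synonyms are skipped whenever an alternative exists, mirroring their
depletion in natural leaders. The protein sequence is preserved exactly —
a tested invariant.

`insert_collision_pair` substitutes the rare codon pair **CGA-CGG** (a
putative ribosome collision / stalling site) at a chosen position pair,
leaving length unchanged; the encoded amino acids change (Asn-Asp →
Arg-Arg by default), intentionally. Because the pair slows the gene *body*,
inserting it downstream of the leader lowers every construct's RIT via the
denominator — a property the tests check.

`construct_report` tabulates each construct's leader mean RRT and RIT.
Whether the leader average includes position 1 is a reporting convention;
both are reachable (`include_first`), and reference-matching checks try
both and record which one matches.

## The synthetic-data generators

### Turnover ("young terminus") genome model

`synthetic_data.gen_genome` draws genes under a minimal one-parameter
selection model. Amino acids come from a fixed composition (default uniform
over 20; configurable); within an amino acid, body codons are drawn with

    P(c | aa) ∝ exp(−s · RRT(c)),

a Boltzmann-style family chosen because it makes expectations closed-form,
not as a claim about real population genetics. With probability τ a gene's
5' block (positions 2..K+1, default K = 40) is *young*: codons drawn
uniformly among synonyms, emulating a terminus recently formed from de novo
sequence that selection has not yet purged of slow codons. A 3' block (last
K₃ sense codons, default K₃ = 100) has its own probability τ₃.

Because both per-codon distributions are known, the generator emits exact
truth: per-gene draw-mode masks, from which
`GenomeTruth.expected_slowdown_pct(window, end)` computes the expected
measured slowdown for any analysis window as the mean over genes of the
ratio of expected window/body means (first-order in the per-codon
distributions; the Monte-Carlo scatter of the realized statistic sits
around it). For a turnover block matching the window this reduces to the
simple blend 100·τ·(E_uniform[RRT]/E_selected[RRT] − 1).

**Default study conditions** (`yeastlike_model`): gene lengths uniform
101–600 codons (the 100-aa analysis floor, with a yeast-like mean of ~350);
every gene 5'-young (τ = 1, K = 40) with the selection strength s
calibrated so the expected measured first-40 slowdown is **1.2%**; τ₃
calibrated so the expected measured last-100 slowdown is **0.19%**. The
calibration is joint: each end's young block sits inside the *other* end's
statistic denominator, so s and τ₃ are solved together against the exact
expected window/body ratios averaged over the length distribution
(`_joint_terminal_calibration`). Under these conditions roughly 60% of
genes come out SIT, close to the ~57% observed in real data, purely from
Monte-Carlo scatter around the small mean effect.

A synthetic RRT table (`gen_rrt_table`) is provided for self-contained
runs: lognormal around 1 with a ~3-fold fastest-to-slowest range, the
dynamic range reported for measured per-codon residence times. It is a
stand-in, not a measurement; analyses of real genomes should load a
measured table.

### Homology-block geometry

`gen_blast_hits` emits per-half BLAST-like hit tables: per species, one
subject whose alignment block starts `offset` residues into the first half
(N-terminal loss; default geometric, mean ~20 aa) and ends `trim` residues
short of the protein end (C-terminal loss; default geometric, mean ~14 aa),
with bit-scores sampled around `region_bits_mean`. The generator records
each window's exact truth coverage by its own single-interval arithmetic,
independent of the scoring code — the two must agree exactly, which is the
oracle test for `conservation_score`.

### Coupled gene-level values

`gen_gene_values` produces expression (read counts, exp-transformed and
rounded, with the standard <10 floor applied) or ribosome-density tables
whose per-gene covariate is the negated expected terminal slowdown:
well-selected termini ↔ high expression. The covariate only varies between
genes when 0 < τ < 1 (a mixture of young and selected termini), so
grouping/correlation demonstrations use mixed genomes.

### What the generators do *not* emulate

No phylogeny, no indels, no real amino-acid composition, no codon
autocorrelation along genes, no mRNA secondary structure, no
signal-sequence biology (the mitochondrial/ER arginine enrichment that
drives part of the real 5' effect), and no Start-codon depletion in
leaders — so neutralization experiments on synthetic data show ≈ no effect,
by construction. Passing tests on generator output therefore validate the
*statistical machinery* (estimators unbiased against known truth, exact
score arithmetic, calibrated type-I error), not biological conclusions
about real genomes.

## Numerical conventions and degenerate inputs

* All windows and intervals are 1-based inclusive; coverage arithmetic is
  on closed intervals.
* Wilcoxon on all-zero differences (e.g. a genome of constant-codon genes)
  is reported as p = 1 rather than an error.
* Filters are strict inequalities exactly as stated: ORFs *shorter than*
  303 nt drop (303 itself is kept, counting the stop codon in the length,
  the standard ORF convention), read counts *less than* 10 drop (10 is
  kept).
* FASTA records whose length is not a multiple of 3 are skipped with a
  warning, never silently truncated; every load reports kept/dropped
  counts by reason, and kept + dropped = input always.
* mRNA-style input (U instead of T, lower case) is normalized on load.
* Dubious/pseudogene exclusion is an explicit gene-id list, decoupled from
  any annotation file dialect. Non-ATG-start ORFs are kept and flagged.
* All generators are pure functions of (parameters, seed): bitwise
  reproducible.

## Problem sizes used by the shipped checks

The self-contained checks run at sizes chosen to make Monte-Carlo
confidence intervals meaningful while staying quick on one CPU: 5000-gene
genomes for parameter recovery (injected slowdowns 0.5/1/3% recovered
within the 95% CI), 1000 null replicates of 60-gene genomes for type-I
calibration of the paired test, 1000 random hit sets for the
conservation-score oracle, and 1000 random proteins for recoder
translation invariance. `scripts/acceptance.py` reruns the full stack on a
3000-gene default-condition genome plus a 1200-gene mixed genome and
reports the headline quantities it computes.

## Known limitations

* The expected-slowdown truth is a ratio of expectations; the measured
  statistic is an expectation of ratios. For very short genes (3'
  denominators of a handful of codons) the Jensen gap is visible, and the
  measured 3' slowdown runs slightly above the first-order expectation.
* Conservation scoring trusts the hit table it is given; it does not model
  BLAST's seeding behaviour, which is precisely why the halving scheme
  exists upstream.
* The recoder recodes *every* window position; published reporter leaders
  recoded only some codons, so recoded sequences are not expected to be
  base-identical to any particular published construct — only the report
  operation applied to given sequences reproduces given scores.
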